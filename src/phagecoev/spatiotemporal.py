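"""Growth–lysis dynamics from dark-field time-lapse stacks.

A spatially expanding bacterial population appears as a bright traveling
wave; phage predation shows up as local intensity collapses followed by
regrowth.  This module quantifies those dynamics per spatial block:

1. ``preprocess_stack``   — first-frame subtraction, channel selection, crop;
2. ``block_average``      — 10x10 px spatial averaging;
3. ``temporal_smooth``    — 4-frame sliding mean per block trace;
4. ``detect_peaks``       — prominence/distance peak picking (one peak per
   growth–lysis cycle);
5. ``cycle_and_dominance_map`` — per-block cycle counts plus the dominance
   summary (final intensity vs. lost intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

DEFAULT_BLOCK = 10
DEFAULT_WINDOW = 4
DEFAULT_MIN_DISTANCE = 20
DEFAULT_MIN_PROMINENCE = 4.0


@dataclass
class IntensityStack:
    """T x H x W intensity field, values in [0, 255].

    ``frame_interval`` is the acquisition period in minutes and is carried
    through so peak indices can be mapped back to wall-clock time.
    """

    values: np.ndarray
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("IntensityStack requires a T x H x W array")
        if self.values.shape[0] < 2:
            raise ValueError("IntensityStack requires at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class SiteTrace:
    """Intensity over time at one block location."""

    block_coords: tuple[int, int]
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)


@dataclass
class PeakSet:
    """Detected peaks of one trace: frame indices and their prominences."""

    indices: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class DominanceMap:
    """Per-block summary of who holds the territory at the end.

    ``eta_final`` is the last-frame intensity (bacterial dominance),
    ``eta_diff`` the maximal minus final intensity (territory lost to
    lysis), and ``cycle_count`` the number of growth–lysis cycles.
    ``median_cycles`` summarises cycle counts over blocks whose maximal
    intensity exceeds the activity floor (blocks the wave never reached
    would otherwise bias the median toward zero).
    """

    eta_final: np.ndarray
    eta_diff: np.ndarray
    cycle_count: np.ndarray
    median_cycles: float
    active_mask: np.ndarray = field(repr=False, default=None)


def preprocess_stack(
    raw: np.ndarray,
    crop: tuple[int, int, int, int] | None = None,
    channel: int | None = 0,
) -> IntensityStack:
    """Background-subtract, channel-select and crop a raw stack.

    The first frame (pre-inoculation background) is subtracted from every
    later frame and negative differences are clamped to zero, so the output
    has one frame fewer than the input.  ``raw`` may be T x H x W or
    T x H x W x C; for multi-channel input ``channel`` selects the channel
    (default 0 = red, the channel with the best dark-field signal-to-noise).
    ``crop`` is (x, y, w, h) in pixel coordinates.
    """
    raw = np.asarray(raw)
    if raw.ndim == 4:
        raw = raw[..., channel if channel is not None else 0]
    elif raw.ndim != 3:
        raise ValueError("raw stack must be T x H x W or T x H x W x C")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 frames (background + signal)")
    frames = raw.astype(np.float64)
    out = frames[1:] - frames[0]
    np.clip(out, 0.0, 255.0, out=out)
    if crop is not None:
        x, y, w, h = crop
        H, W = out.shape[1:]
        if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > W or y + h > H:
            raise ValueError(f"crop {crop} outside image bounds {(H, W)}")
        out = out[:, y : y + h, x : x + w]
    return IntensityStack(out)


def block_average(stack: IntensityStack, block: int = DEFAULT_BLOCK) -> IntensityStack:
    """Average pixel values over non-overlapping block x block squares.

    Trailing rows/columns that do not fill a whole block are dropped.
    """
    v = stack.values
    T, H, W = v.shape
    if H < block or W < block:
        raise ValueError("image smaller than one block")
    nh, nw = H // block, W // block
    v = v[:, : nh * block, : nw * block]
    v = v.reshape(T, nh, block, nw, block).mean(axis=(2, 4))
    return IntensityStack(v, frame_interval=stack.frame_interval)


def temporal_smooth(trace: SiteTrace, window: int = DEFAULT_WINDOW) -> SiteTrace:
    """Trailing moving average of ``window`` frames, length-preserving.

    The first ``window - 1`` positions average only the frames available so
    far (shrinking window), keeping frame indices aligned with acquisition
    times.
    """
    x = np.asarray(trace.intensity, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(x) < window:
        raise ValueError("trace shorter than smoothing window")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty_like(x)
    idx = np.arange(len(x))
    lo = np.maximum(idx - window + 1, 0)
    out = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
    return SiteTrace(trace.block_coords, out)


def detect_peaks(
    trace: SiteTrace | np.ndarray,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> PeakSet:
    """Detect local maxima by topographic prominence, then thin by distance.

    Prominence is the height of a peak above the higher of the two minima
    separating it from higher terrain.  A maximum at the first or last frame
    counts as a peak (a colony still growing at the end of the movie is one
    cycle), which plain ``scipy.signal.find_peaks`` would miss; the trace is
    therefore padded with its own minimum before detection, which leaves
    interior prominences untouched.  Candidates passing the prominence floor
    are then thinned greedily in order of descending height (ties broken by
    earlier index) so that retained peaks are at least ``min_distance``
    frames apart.
    """
    x = np.asarray(trace.intensity if isinstance(trace, SiteTrace) else trace, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    pad = x.min()
    xp = np.concatenate(([pad], x, [pad]))
    cand, props = find_peaks(xp, prominence=min_prominence)
    cand = cand - 1  # undo padding offset
    prom = props["prominences"]
    # greedy distance thinning, highest first, earlier index on ties
    order = sorted(range(len(cand)), key=lambda i: (-x[cand[i]], cand[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(cand[i] - cand[j]) >= min_distance for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: cand[i])
    return PeakSet(indices=cand[kept], prominences=prom[kept])


def cycle_and_dominance_map(
    stack: IntensityStack,
    window: int = DEFAULT_WINDOW,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    activity_floor: float = DEFAULT_MIN_PROMINENCE,
) -> DominanceMap:
    """Cycle counts and dominance summaries for a block-resolution stack.

    Per block: the trace is smoothed, peaks are counted (cycle count),
    ``eta_final`` is the last-frame intensity and ``eta_diff`` the maximum
    minus the final intensity.  The plate-wide median cycle count is taken
    only over blocks whose maximal smoothed intensity exceeds
    ``activity_floor`` — locations the bacterial wave never colonised carry
    no cycle information.
    """
    v = stack.values
    T, nh, nw = v.shape
    cycles = np.zeros((nh, nw), dtype=int)
    eta_final = np.empty((nh, nw))
    eta_diff = np.empty((nh, nw))
    active = np.zeros((nh, nw), dtype=bool)
    for r in range(nh):
        for c in range(nw):
            tr = temporal_smooth(SiteTrace((r, c), v[:, r, c]), window=window)
            peaks = detect_peaks(tr, min_distance=min_distance, min_prominence=min_prominence)
            cycles[r, c] = len(peaks)
            eta_final[r, c] = tr.intensity[-1]
            eta_diff[r, c] = tr.intensity.max() - tr.intensity[-1]
            active[r, c] = tr.intensity.max() > activity_floor
    med = float(np.median(cycles[active])) if active.any() else float("nan")
    return DominanceMap(
        eta_final=eta_final,
        eta_diff=eta_diff,
        cycle_count=cycles,
        median_cycles=med,
        active_mask=active,
    )
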