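"""Per-spot infectivity and turbidity scores from cross-infection plates.

A plate carries a lawn of one bacterial isolate spotted with a grid of
phage isolates (8 x 12 = 96 spots by default).  Each spot is scored inside
its own L x L region (L = 181 px):

    infectivity  = phageFraction * clearance
    phageFraction = phageArea / L^2
    clearance    = 1 - mean(V_norm over lysed pixels)
    turbidity    = sum(V) / (255 * L^2)

where V_norm = V / 255 on the per-region normalised image.  In dark-field
imaging the bacterial lawn is bright and lysis zones are dark, so the phage
mask selects pixels *below* a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

V_MAX = 255.0
DEFAULT_REGION_SIDE = 181
DEFAULT_NORM_PERCENTILE = 90.0


@dataclass
class PlateLayout:
    """Grid geometry of one plate: spot centres and region size.

    ``empty_spots`` are grid positions deliberately left phage-free; any
    lysis detected there indicates phage carryover (see ``carryover_qc``).
    """

    grid: tuple[int, int]
    centers: list[tuple[int, int]]  # (row_px, col_px), row-major grid order
    region_side: int = DEFAULT_REGION_SIDE
    empty_spots: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if len(self.centers) != rows * cols:
            raise ValueError("centers must list one point per grid position")
        if self.region_side % 2 == 0:
            raise ValueError("region_side must be odd so a centre pixel exists")

    @classmethod
    def regular(
        cls,
        grid: tuple[int, int],
        origin: tuple[int, int],
        pitch: tuple[int, int],
        region_side: int = DEFAULT_REGION_SIDE,
        empty_spots: set[tuple[int, int]] | None = None,
    ) -> "PlateLayout":
        """Layout with spot centres on a regular grid."""
        rows, cols = grid
        centers = [
            (origin[0] + r * pitch[0], origin[1] + c * pitch[1])
            for r in range(rows)
            for c in range(cols)
        ]
        return cls(grid, centers, region_side, empty_spots or set())


@dataclass
class SpotRegion:
    """One spot's L x L pixel square."""

    pixels: np.ndarray
    grid_pos: tuple[int, int]
    plate_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("SpotRegion must be square")


@dataclass
class SpotScore:
    grid_pos: tuple[int, int]
    phage_area: int
    phage_fraction: float
    clearance: float
    infectivity: float
    turbidity: float
    plate_id: str = ""


def extract_spot_grid(image: np.ndarray, layout: PlateLayout,
                      plate_id: str = "") -> list[SpotRegion]:
    """Cut the plate image into one square region per spot, row-major.

    A region may touch the image border exactly; extending beyond it is an
    error (the plate was cropped too tight or the layout is wrong).
    """
    image = np.asarray(image)
    L = layout.region_side
    half = L // 2
    regions = []
    rows, cols = layout.grid
    for idx, (cy, cx) in enumerate(layout.centers):
        y0, x0 = cy - half, cx - half
        if y0 < 0 or x0 < 0 or y0 + L > image.shape[0] or x0 + L > image.shape[1]:
            raise ValueError(f"spot region at centre {(cy, cx)} outside image bounds")
        pos = (idx // cols, idx % cols)
        regions.append(SpotRegion(image[y0 : y0 + L, x0 : x0 + L], pos, plate_id))
    return regions


def normalize_region(region: SpotRegion,
                     percentile: float = DEFAULT_NORM_PERCENTILE) -> SpotRegion:
    """Rescale so every pixel at or above the region's 90th percentile is 255.

    Pixels are multiplied by 255 / p90 and clipped at 255; an all-dark
    region (p90 = 0) is returned unchanged.  The rescale-then-clip form is
    idempotent and removes per-spot illumination differences.
    """
    v = region.pixels
    p = np.percentile(v, percentile)
    if p <= 0:
        return SpotRegion(v.copy(), region.grid_pos, region.plate_id)
    out = np.minimum(v / p * V_MAX, V_MAX)  # v == p maps to exactly 255
    return SpotRegion(out, region.grid_pos, region.plate_id)


def phage_mask(region: SpotRegion, threshold: float) -> np.ndarray:
    """Binary lysis mask: pixels strictly below ``threshold`` (dark = lysed)."""
    if not 0 < threshold < V_MAX:
        raise ValueError("threshold must be in (0, 255)")
    return region.pixels < threshold


def plate_threshold(regions: list[SpotRegion]) -> float:
    """Plate-wide lysis threshold: Otsu's method on pooled normalised pixels."""
    pooled = np.concatenate([r.pixels.ravel() for r in regions])
    if np.ptp(pooled) == 0:
        return V_MAX / 2.0
    return float(threshold_otsu(pooled))


def score_spot(region: SpotRegion, mask: np.ndarray) -> SpotScore:
    """Score one normalised spot region against its lysis mask.

    With no lysed pixels the clearance mean is undefined; it is set to 0 so
    infectivity is 0 for a spot showing no lysis.
    """
    v = region.pixels
    if mask.shape != v.shape:
        raise ValueError("mask shape must match region")
    L2 = v.size
    area = int(mask.sum())
    frac = area / L2
    clearance = 1.0 - float(v[mask].mean()) / V_MAX if area > 0 else 0.0
    return SpotScore(
        grid_pos=region.grid_pos,
        phage_area=area,
        phage_fraction=frac,
        clearance=clearance,
        infectivity=frac * clearance,
        turbidity=turbidity(region),
        plate_id=region.plate_id,
    )


def turbidity(region: SpotRegion) -> float:
    """Normalised total intensity: high for an intact lawn, low after lysis."""
    v = region.pixels
    return float(v.sum()) / (V_MAX * v.size)


def score_plate(
    image: np.ndarray,
    layout: PlateLayout,
    threshold: float | str = "auto",
    plate_id: str = "",
) -> pd.DataFrame:
    """Extract, normalise and score every spot of a plate; returns a table.

    ``threshold='auto'`` derives the lysis threshold from the pooled
    normalised plate histogram (Otsu); a number fixes it for all spots.
    """
    regions = [normalize_region(r) for r in extract_spot_grid(image, layout, plate_id)]
    thr = plate_threshold(regions) if threshold == "auto" else float(threshold)
    rows = []
    for reg in regions:
        sc = score_spot(reg, phage_mask(reg, thr))
        rows.append(
            {
                "plate_id": plate_id,
                "row": sc.grid_pos[0],
                "col": sc.grid_pos[1],
                "phageFraction": sc.phage_fraction,
                "clearance": sc.clearance,
                "infectivity": sc.infectivity,
                "turbidity": sc.turbidity,
            }
        )
    return pd.DataFrame(rows)


def carryover_qc(scores: pd.DataFrame, layout: PlateLayout,
                 tol: float = 0.02) -> pd.DataFrame:
    """Flag designated phage-free spots whose infectivity exceeds ``tol``.

    Roughly a quarter of spots are left phage-free by design; a plaque there
    means phage carryover during colony isolation.  Returns the empty-spot
    table with a boolean ``flagged`` column; the plate passes iff none is
    flagged.
    """
    key = scores.set_index(["row", "col"])
    missing = [p for p in layout.empty_spots if p not in key.index]
    if missing:
        raise ValueError(f"scores missing for designated empty spots: {missing}")
    rows = []
    for (r, c) in sorted(layout.empty_spots):
        inf = float(key.loc[(r, c), "infectivity"])
        rows.append({"row": r, "col": c, "infectivity": inf, "flagged": inf > tol})
    return pd.DataFrame(rows, columns=["row", "col", "infectivity", "flagged"])
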