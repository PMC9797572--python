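"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the statistical structure of the experiment's data:

* ``gen_timelapse``          — a radially expanding bacterial wave with
  planted lysis/regrowth dips, so per-block growth–lysis cycle counts are
  known by construction;
* ``gen_plate_image``        — a 96-spot cross-infection plate with plaques
  of known area and clearance, so per-spot infectivity/turbidity scores have
  closed-form truth;
* ``gen_genotype_phenotype`` — isolate mutation tables with planted sparse
  additive effects on infectivity, so the association stage's recoverable
  support is known;
* ``gen_toy_genome``         — a miniature annotated genome whose per-site
  nonsynonymous substitution probability is analytic, so the adaptive
  evolution permutation test has an exact binomial oracle.

All generators are pure functions of their spec (including its seed):
repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .spatiotemporal import (
    DEFAULT_MIN_DISTANCE,
    DEFAULT_MIN_PROMINENCE,
    IntensityStack,
)

# --------------------------------------------------------------------------
# time-lapse
# --------------------------------------------------------------------------


@dataclass
class LysisEvent:
    """One planted lysis/regrowth dip in a single block trace."""

    block: tuple[int, int]
    onset: int  # frame at which the dip starts
    depth: float  # intensity units at the dip minimum


@dataclass
class SimTimelapseSpec:
    """Specification of a synthetic growth–lysis time lapse.

    The bacterial wave expands radially from the plate centre at
    ``wave_speed`` px/frame, ramping each block from 0 to ``plateau``
    intensity over ``ramp_frames`` frames after arrival.  Each
    ``LysisEvent`` subtracts a raised-cosine dip of duration
    ``event_duration`` frames and the stated depth, returning to the
    plateau, so a block with *k* events shows exactly ``1 + k`` intensity
    maxima.  Validation rejects geometries where that identity would not
    hold (events overlapping the ramp, each other, or the end of the
    recording).
    """

    frames: int = 300
    height: int = 500
    width: int = 500
    wave_speed: float = 5.0
    lysis_events: list[LysisEvent] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    block: int = 10
    plateau: float = 60.0
    ramp_frames: int = 20
    event_duration: int = 30

    def validate(self) -> None:
        if self.frames < 8:
            raise ValueError("frames must be >= 8")
        if self.height < self.block or self.width < self.block:
            raise ValueError("degenerate image dimensions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.wave_speed <= 0:
            raise ValueError("wave_speed must be positive")
        arrivals = _block_arrival_frames(self)
        by_block: dict[tuple[int, int], list[LysisEvent]] = {}
        for ev in self.lysis_events:
            by_block.setdefault(ev.block, []).append(ev)
        min_gap = self.event_duration + DEFAULT_MIN_DISTANCE
        for blk, evs in by_block.items():
            r, c = blk
            if not (0 <= r < arrivals.shape[0] and 0 <= c < arrivals.shape[1]):
                raise ValueError(f"event block {blk} outside block grid")
            evs = sorted(evs, key=lambda e: e.onset)
            t_ready = arrivals[r, c] + self.ramp_frames + DEFAULT_MIN_DISTANCE
            for ev in evs:
                if ev.depth <= 0:
                    raise ValueError("event depth must be positive")
                if ev.onset < t_ready:
                    raise ValueError(
                        f"event at {blk} onset {ev.onset} too close to wave arrival"
                    )
                if ev.onset + self.event_duration + DEFAULT_MIN_DISTANCE > self.frames:
                    raise ValueError(
                        f"event at {blk} onset {ev.onset} does not fit the recording"
                    )
            for a, b in zip(evs, evs[1:]):
                if b.onset - a.onset < min_gap:
                    raise ValueError(f"events at {blk} closer than {min_gap} frames")


def _block_arrival_frames(spec: SimTimelapseSpec) -> np.ndarray:
    """Frame at which the wave front reaches each block centre."""
    nh = spec.height // spec.block
    nw = spec.width // spec.block
    rows = (np.arange(nh) + 0.5) * spec.block
    cols = (np.arange(nw) + 0.5) * spec.block
    cy, cx = spec.height / 2.0, spec.width / 2.0
    dist = np.hypot(rows[:, None] - cy, cols[None, :] - cx)
    return dist / spec.wave_speed


def gen_timelapse(spec: SimTimelapseSpec) -> tuple[IntensityStack, np.ndarray]:
    """Render the synthetic time lapse and its planted cycle-count map.

    Returns the 8-bit stack (background-free, i.e. already on the
    first-frame-subtracted scale the analysis operates on) and an integer
    array of planted cycle counts per block: 0 where the wave never
    completes its ramp within the recording, otherwise 1 plus the number of
    planted lysis events in that block.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nh = spec.height // spec.block
    nw = spec.width // spec.block
    arrivals = _block_arrival_frames(spec)
    t = np.arange(spec.frames, dtype=float)

    # ramp: raised-cosine rise from 0 to plateau over ramp_frames
    prog = np.clip((t[None, None, :] - arrivals[:, :, None]) / spec.ramp_frames, 0, 1)
    traces = spec.plateau * 0.5 * (1.0 - np.cos(np.pi * prog))

    truth = np.where(arrivals + spec.ramp_frames <= spec.frames - 1, 1, 0)
    for ev in spec.lysis_events:
        r, c = ev.block
        phase = (t - ev.onset) / spec.event_duration
        inside = (phase >= 0) & (phase <= 1)
        dip = np.zeros_like(t)
        dip[inside] = ev.depth * 0.5 * (1.0 - np.cos(2 * np.pi * phase[inside]))
        traces[r, c] -= dip
        truth[r, c] += 1

    pixels = np.repeat(np.repeat(traces, spec.block, axis=0), spec.block, axis=1)
    # pad partial trailing blocks with zeros so the stack has the exact size;
    # float32 keeps large stacks (hundreds of frames) at half the footprint
    full = np.zeros((spec.height, spec.width, spec.frames), dtype=np.float32)
    full[: nh * spec.block, : nw * spec.block] = pixels
    stack = np.ascontiguousarray(np.moveaxis(full, -1, 0))
    if spec.noise_sd > 0:
        stack += rng.standard_normal(stack.shape, dtype=np.float32) * spec.noise_sd
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    return IntensityStack(stack), truth


def random_timelapse_spec(
    seed: int,
    frames: int = 300,
    blocks: tuple[int, int] = (50, 50),
    block: int = 10,
    max_extra_cycles: int = 3,
    depth_range: tuple[float, float] = (12.0, 30.0),
    noise_sd: float = 0.0,
) -> SimTimelapseSpec:
    """Draw a valid random spec with planted cycle counts in many blocks.

    The wave speed is chosen so every block completes its ramp within the
    first third of the recording, leaving room for up to
    ``max_extra_cycles`` well-separated lysis events per block.
    """
    rng = np.random.default_rng(seed)
    nh, nw = blocks
    height, width = nh * block, nw * block
    max_dist = np.hypot(height / 2.0, width / 2.0)
    spec = SimTimelapseSpec(
        frames=frames,
        height=height,
        width=width,
        wave_speed=float(max_dist / (frames / 3.0 - 25)),
        noise_sd=noise_sd,
        seed=seed,
        block=block,
    )
    arrivals = _block_arrival_frames(spec)
    min_gap = spec.event_duration + DEFAULT_MIN_DISTANCE
    events: list[LysisEvent] = []
    for r in range(nh):
        for c in range(nw):
            first = int(np.ceil(arrivals[r, c])) + spec.ramp_frames + DEFAULT_MIN_DISTANCE
            last = frames - spec.event_duration - DEFAULT_MIN_DISTANCE
            n_max = min(max_extra_cycles, max(0, (last - first) // min_gap + 1))
            k = int(rng.integers(0, n_max + 1))
            if k == 0:
                continue
            slack = last - first - (k - 1) * min_gap
            offsets = np.sort(rng.integers(0, slack + 1, size=k))
            for i in range(k):
                onset = first + i * min_gap + int(offsets[i])
                depth = float(rng.uniform(*depth_range))
                events.append(LysisEvent((r, c), onset, depth))
    spec.lysis_events = events
    return spec


# --------------------------------------------------------------------------
# plate images
# --------------------------------------------------------------------------


@dataclass
class SimPlateSpec:
    """Specification of a synthetic cross-infection plate image.

    ``plaques`` maps grid positions (row, col) to
    (area_fraction, interior_mean_intensity) pairs; unlisted positions get
    no plaque.  Lysis zones are darker than the bacterial lawn in
    dark-field, so interior intensity must not exceed the background.
    """

    grid: tuple[int, int] = (8, 12)
    spot_region_side: int = 181
    plaques: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    background_intensity: float = 200.0
    empty_spots: frozenset[tuple[int, int]] = frozenset()
    noise_sd: float = 0.0
    seed: int = 0
    margin: int = 4  # px of lawn between adjacent spot regions

    def validate(self) -> None:
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.spot_region_side % 2 == 0:
            raise ValueError("spot_region_side must be odd")
        if not 0 < self.background_intensity <= 255:
            raise ValueError("background_intensity must be in (0, 255]")
        if self.margin < 0:
            raise ValueError("margin must be >= 0: spot regions may not overlap")
        for pos, (af, interior) in self.plaques.items():
            r, c = pos
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"plaque position {pos} outside grid")
            if not 0.0 <= af <= 1.0:
                raise ValueError("area_fraction must be in [0, 1]")
            if not 0.0 <= interior <= self.background_intensity:
                raise ValueError(
                    "plaque interior must be darker than the lawn (dark-field)"
                )
            # a plaque in a designated empty spot is allowed: it emulates
            # phage carryover, which carryover_qc exists to detect


def _disk_mask(side: int, n_pixels: int) -> np.ndarray:
    """Boolean mask selecting exactly ``n_pixels`` pixels closest to centre."""
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    d = (yy - c) ** 2 + (xx - c) ** 2
    order = np.argsort(d.ravel(), kind="stable")
    mask = np.zeros(side * side, dtype=bool)
    mask[order[:n_pixels]] = True
    return mask.reshape(side, side)


def gen_plate_image(spec: SimPlateSpec):
    """Render a plate image plus the analytic per-spot score table.

    Returns ``(image, layout, truth)`` where ``layout`` is the
    :class:`~phagecoev.plaque_scoring.PlateLayout` matching the rendering and
    ``truth`` is a DataFrame with the closed-form phageFraction, clearance,
    infectivity and turbidity of each spot on the post-normalisation scale
    (plaque pixels count exactly, so truth is exact up to the 1/L**2 area
    discretisation).
    """
    from .plaque_scoring import PlateLayout  # deferred: avoids import cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    L = spec.spot_region_side
    pitch = L + spec.margin
    H = rows * pitch + spec.margin
    W = cols * pitch + spec.margin
    img = np.full((H, W), spec.background_intensity, dtype=float)

    centers = []
    records = []
    for r in range(rows):
        for c in range(cols):
            y0 = spec.margin + r * pitch
            x0 = spec.margin + c * pitch
            cy, cx = y0 + L // 2, x0 + L // 2
            centers.append((cy, cx))
            af, interior = spec.plaques.get((r, c), (0.0, 0.0))
            n_px = int(round(af * L * L))
            if n_px > 0:
                mask = _disk_mask(L, n_px)
                region = img[y0 : y0 + L, x0 : x0 + L]
                region[mask] = interior
            # analytic scores on the normalised scale: the region is a
            # two-valued multiset, so its 90th percentile is computable
            # without touching the rendered image
            vals = np.concatenate(
                [
                    np.full(n_px, interior),
                    np.full(L * L - n_px, spec.background_intensity),
                ]
            )
            p90 = float(np.percentile(vals, 90))
            v_int = min(interior / p90 * 255.0, 255.0) if p90 > 0 else interior
            v_bg = (min(spec.background_intensity / p90 * 255.0, 255.0)
                    if p90 > 0 else spec.background_intensity)
            frac = n_px / (L * L)
            clearance = (1.0 - v_int / 255.0) if n_px > 0 else 0.0
            records.append(
                {
                    "row": r,
                    "col": c,
                    "phageFraction": frac,
                    "clearance": clearance,
                    "infectivity": frac * clearance,
                    "turbidity": (n_px * v_int + (L * L - n_px) * v_bg) / (255.0 * L * L),
                }
            )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    layout = PlateLayout(
        grid=spec.grid,
        centers=centers,
        region_side=L,
        empty_spots=set(spec.empty_spots),
    )
    return img, layout, pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# genotypes and phenotypes
# --------------------------------------------------------------------------

MUTATION_TABLE_COLUMNS = [
    "isolate_id",
    "replicate_id",
    "genome",
    "type",
    "start",
    "end",
    "ref",
    "alt",
    "copy_number",
    "effect_annotation",
]


@dataclass
class SimGenotypeSpec:
    """Planted sparse additive genotype→infectivity model.

    Each of ``n_mutations`` mutations is assigned to either the bacterial or
    the phage genome and carried by ``carrier_fraction`` of that organism's
    isolates (exactly, via permutation) — evolved mutations are minority
    variants, so the fraction is small by default.  A fraction ``sparsity``
    of mutations get a nonzero effect drawn uniformly from
    ±[effect_min, effect_max]; pair infectivity is
    ``clip(baseline + sum(beta * x) + noise, 0, 1)``.

    ``n_pairs`` pairs are measured, sampled without replacement from the
    full cross (``None`` measures every pair).  The default library is large
    relative to the number of measured pairs so each mutation predictor
    varies across many distinct isolates: in a small fully crossed library
    the joint design is rank-deficient (rank <= n_bacteria + n_phage - 1)
    and the planted support would not be recoverable by any method, which
    would defeat the generator's purpose.
    """

    n_bacteria: int = 250
    n_phage: int = 200
    n_mutations: int = 50
    n_pairs: int | None = 500
    baseline: float = 0.5
    noise_sd: float = 0.05
    sparsity: float = 0.1
    effect_min: float = 0.3
    effect_max: float = 0.4
    carrier_fraction: float = 0.08
    effect_vector: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_bacteria, self.n_phage, self.n_mutations) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must be in [0, 1]")
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_pairs is not None and not 1 <= self.n_pairs <= self.n_bacteria * self.n_phage:
            raise ValueError("n_pairs must be in [1, n_bacteria * n_phage]")
        if self.effect_vector is not None and len(self.effect_vector) != self.n_mutations:
            raise ValueError("effect_vector length must equal n_mutations")


def gen_genotype_phenotype(spec: SimGenotypeSpec):
    """Generate mutation tables, genotype matrices, infectivity and true effects.

    Returns a dict with keys ``bacteria_mutations`` / ``phage_mutations``
    (tidy mutation tables), ``bacteria_genotypes`` / ``phage_genotypes``
    (isolate x predictor 0/1 DataFrames), ``infection_matrix`` (phage rows x
    bacteria columns) and ``beta`` (true effect per predictor, indexed like
    the concatenated genotype columns).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bact_ids = [f"Bac{i + 1:03d}" for i in range(spec.n_bacteria)]
    phage_ids = [f"Phi{i + 1:03d}" for i in range(spec.n_phage)]

    organism = rng.permutation(
        np.array(["bacterium"] * (spec.n_mutations // 2)
                 + ["phage"] * (spec.n_mutations - spec.n_mutations // 2))
    )
    labels = [f"mut{j + 1:03d}:{'B' if o == 'bacterium' else 'P'}"
              for j, o in enumerate(organism)]

    if spec.effect_vector is not None:
        beta = np.asarray(spec.effect_vector, dtype=float)
    else:
        beta = np.zeros(spec.n_mutations)
        k = int(round(spec.sparsity * spec.n_mutations))
        support = rng.choice(spec.n_mutations, size=k, replace=False)
        mag = rng.uniform(spec.effect_min, spec.effect_max, size=k)
        sign = rng.choice([-1.0, 1.0], size=k)
        beta[support] = mag * sign

    def carriers(n_iso: int) -> np.ndarray:
        n_carry = int(round(spec.carrier_fraction * n_iso))
        v = np.zeros(n_iso, dtype=int)
        v[rng.permutation(n_iso)[:n_carry]] = 1
        return v

    Xb = np.zeros((spec.n_bacteria, spec.n_mutations), dtype=int)
    Xp = np.zeros((spec.n_phage, spec.n_mutations), dtype=int)
    for j, org in enumerate(organism):
        if org == "bacterium":
            Xb[:, j] = carriers(spec.n_bacteria)
        else:
            Xp[:, j] = carriers(spec.n_phage)

    bact_cols = [j for j, o in enumerate(organism) if o == "bacterium"]
    phage_cols = [j for j, o in enumerate(organism) if o == "phage"]
    bact_geno = pd.DataFrame(Xb[:, bact_cols], index=bact_ids,
                             columns=[labels[j] for j in bact_cols])
    phage_geno = pd.DataFrame(Xp[:, phage_cols], index=phage_ids,
                              columns=[labels[j] for j in phage_cols])

    # pair infectivity: additive signal then clip to [0, 1]
    contrib = Xp @ np.where(organism == "phage", beta, 0.0)[:, None] \
        + (Xb @ np.where(organism == "bacterium", beta, 0.0)[:, None]).T
    scores = spec.baseline + contrib
    if spec.noise_sd > 0:
        scores = scores + rng.normal(0.0, spec.noise_sd, size=scores.shape)
    scores = np.clip(scores, 0.0, 1.0)
    if spec.n_pairs is not None and spec.n_pairs < scores.size:
        measured = np.zeros(scores.size, dtype=bool)
        measured[rng.permutation(scores.size)[: spec.n_pairs]] = True
        scores = np.where(measured.reshape(scores.shape), scores, np.nan)
    infection = pd.DataFrame(scores, index=phage_ids, columns=bact_ids)

    def mutation_table(geno: pd.DataFrame, genome_name: str) -> pd.DataFrame:
        rows = []
        for j, col in enumerate(geno.columns):
            pos = 100 * (j + 1)
            for iso in geno.index[geno[col] == 1]:
                rows.append(
                    {
                        "isolate_id": iso,
                        "replicate_id": "R1",
                        "genome": genome_name,
                        "type": "SNP",
                        "start": pos,
                        "end": pos,
                        "ref": "A",
                        "alt": "G",
                        "copy_number": "",
                        "effect_annotation": "nonsynonymous",
                    }
                )
        return pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)

    beta_series = pd.Series(beta, index=labels)
    joint_cols = list(bact_geno.columns) + list(phage_geno.columns)
    return {
        "bacteria_mutations": mutation_table(bact_geno, "bacterium"),
        "phage_mutations": mutation_table(phage_geno, "phage"),
        "bacteria_genotypes": bact_geno,
        "phage_genotypes": phage_geno,
        "infection_matrix": infection,
        "beta": beta_series.loc[joint_cols],
    }


# --------------------------------------------------------------------------
# toy genomes
# --------------------------------------------------------------------------

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class ToyGenome:
    """Miniature annotated genome with analytic substitution-effect fractions."""

    sequence: str
    orfs: list[tuple[int, int, str]]  # 1-based inclusive, strand '+'/'-'
    gene_names: list[str]

    def __post_init__(self) -> None:
        for (s, e, strand) in self.orfs:
            if (e - s + 1) % 3 != 0:
                raise ValueError("ORF length must be divisible by 3")
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError("ORF outside sequence")
            if strand not in "+-":
                raise ValueError("strand must be + or -")

    def nonsyn_prob(self, snp_class: str) -> float:
        """Probability that a uniformly placed intragenic SNP of the given
        class (``transition`` or ``transversion``, alt drawn uniformly within
        class) is nonsynonymous, by exhaustive codon-table enumeration."""
        total = 0.0
        n_sites = 0
        for (s, e, strand) in self.orfs:
            sub = self.sequence[s - 1 : e]
            if strand == "-":
                sub = str(Seq(sub).reverse_complement())
            for i in range(len(sub)):
                ref = sub[i]
                if snp_class == "transition":
                    alts = [_TRANSITION[ref]]
                elif snp_class == "transversion":
                    alts = list(_TRANSVERSIONS[ref])
                else:
                    raise ValueError("snp_class must be transition or transversion")
                p = 0.0
                for alt in alts:
                    cs = (i // 3) * 3
                    codon = sub[cs : cs + 3]
                    mutated = codon[: i % 3] + alt + codon[i % 3 + 1 :]
                    if Seq(codon).translate() != Seq(mutated).translate():
                        p += 1.0 / len(alts)
                total += p
                n_sites += 1
        return total / n_sites

    def to_fasta(self, path, name: str = "toy_genome") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def to_gff3(self, path, seqid: str = "toy_genome") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for (s, e, strand), name in zip(self.orfs, self.gene_names):
                attrs = f"ID={name};Name={name}"
                fh.write(
                    f"{seqid}\tphagecoev\tCDS\t{s}\t{e}\t.\t{strand}\t0\t{attrs}\n"
                )


def gen_toy_genome(
    n_orfs: int = 4,
    orf_len: int = 300,
    composition: str = "random",
    seed: int = 0,
    spacer: int = 20,
    require_start: bool = True,
) -> ToyGenome:
    """Build a toy genome of ``n_orfs`` plus-strand ORFs separated by spacers.

    ``composition`` is either ``"random"`` (codons drawn uniformly over the
    61 sense codons) or a repeated codon such as ``"TGG"`` (with
    ``require_start=False`` the ORF is the pure repeat — e.g. an all-TGG
    genome in which every possible substitution is nonsynonymous).
    """
    if orf_len % 3 != 0:
        raise ValueError("orf_len must be divisible by 3")
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    sense = [a + b + c for a in _BASES for b in _BASES for c in _BASES
             if a + b + c not in stops]
    if composition != "random":
        if len(composition) != 3 or any(b not in _BASES for b in composition):
            raise ValueError("composition must be 'random' or a single codon")
        if composition in stops:
            raise ValueError("composition codon must not be a stop codon")

    seq_parts: list[str] = []
    orfs: list[tuple[int, int, str]] = []
    names: list[str] = []
    pos = 0
    for g in range(n_orfs):
        gap = "".join(rng.choice(list("ACGT"), size=spacer))
        seq_parts.append(gap)
        pos += spacer
        n_codons = orf_len // 3
        if composition == "random":
            codons = list(rng.choice(sense, size=n_codons))
        else:
            codons = [composition] * n_codons
        if require_start:
            codons[0] = "ATG"
        orf = "".join(codons)
        seq_parts.append(orf)
        orfs.append((pos + 1, pos + orf_len, "+"))
        names.append(f"gene{g + 1}")
        pos += orf_len
    seq_parts.append("".join(rng.choice(list("ACGT"), size=spacer)))
    return ToyGenome("".join(seq_parts), orfs, names)
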