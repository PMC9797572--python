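"""From raw mutation tables to a deduplicated predictor matrix.

Mutation tables are tidy TSVs, one row per isolate x mutation, with columns
``isolate_id, replicate_id, genome, type, start, end, ref, alt, copy_number,
effect_annotation`` (coordinates 1-based inclusive; ``type`` is one of SNP,
insertion, deletion, IS, amplification).  The encoding pipeline is:

1. ``segment_overlapping_events`` — interval events (deletions,
   amplifications) overlapping between isolates are cut at all interval
   endpoints so shared stretches become shared predictors;
2. ``encode_predictors``         — binary columns for SNP/insertion/
   deletion/IS, integer copy-number columns for amplifications (ancestral
   state 1); synonymous SNPs carry no phenotypic information under the
   additive model and are omitted;
3. ``join_cooccurring``          — predictors with identical carrier
   patterns are indistinguishable to a regression and are merged (never
   amplifications, whose integer values are copy-number dependent);
4. ``build_observations``        — one observation per distinct joint
   (bacterium, phage) genotype, with the mean infectivity of all pairs
   sharing it and the pooled pair count as weight.

``normalize_coverage`` supports amplification/deletion discovery from
sequencing depth, automated as a thresholded candidate report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MUTATION_TYPES = {"SNP", "insertion", "deletion", "IS", "amplification"}
INTERVAL_TYPES = {"deletion", "amplification"}
EFFECTS = {"intergenic", "synonymous", "nonsynonymous", "frameshift", "inframe",
           "disruption"}


def read_mutation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"isolate_id": str, "replicate_id": str})
    _check_records(df)
    return df


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _check_records(df: pd.DataFrame) -> None:
    required = {"isolate_id", "genome", "type", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"mutation table must contain columns {sorted(required)}")
    bad = set(df["type"]) - MUTATION_TYPES
    if bad:
        raise ValueError(f"unknown mutation types: {sorted(bad)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("interval start must be <= end")
    amp = df["type"] == "amplification"
    if amp.any():
        cn = pd.to_numeric(df.loc[amp, "copy_number"], errors="coerce")
        if cn.isna().any() or (cn < 2).any():
            raise ValueError("amplifications require integer copy_number >= 2")


# --------------------------------------------------------------------------
# coverage normalisation
# --------------------------------------------------------------------------


@dataclass
class CnvCandidate:
    start: int  # 1-based inclusive
    end: int
    kind: str  # 'amplification' or 'deletion'
    mean_cnorm: float


def normalize_coverage(
    isolate: np.ndarray,
    ancestor: np.ndarray,
    high: float = 1.5,
    low: float = 0.5,
    min_span: int = 100,
) -> tuple[np.ndarray, list[CnvCandidate]]:
    """Two-step coverage normalisation plus a CNV candidate report.

    Each vector is divided by its own median (removing library-size effects)
    and the isolate track is then divided position-wise by the normalised
    ancestral track (removing mappability/GC structure shared with the
    ancestor).  Contiguous runs of ``min_span`` or more positions with
    normalised coverage >= ``high`` (candidate amplification) or <= ``low``
    (candidate deletion) are reported.  Positions with zero ancestral
    coverage cannot be normalised; they are masked to NaN with a warning and
    never contribute to candidates.
    """
    iso = np.asarray(isolate, dtype=float)
    anc = np.asarray(ancestor, dtype=float)
    if iso.shape != anc.shape or iso.ndim != 1:
        raise ValueError("coverage vectors must be equal-length 1-D arrays")
    if (iso < 0).any() or (anc < 0).any():
        raise ValueError("coverage must be non-negative")
    anc_norm = anc / np.median(anc)
    iso_norm = iso / np.median(iso)
    zero = anc_norm == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} positions with zero ancestral coverage masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        c_norm = np.where(zero, np.nan, iso_norm / anc_norm)

    candidates: list[CnvCandidate] = []
    for kind, mask in (
        ("amplification", c_norm >= high),
        ("deletion", c_norm <= low),
    ):
        mask = mask & ~np.isnan(c_norm)
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_span:
                candidates.append(
                    CnvCandidate(start=int(s) + 1, end=int(e),
                                 kind=kind, mean_cnorm=float(c_norm[s:e].mean()))
                )
    candidates.sort(key=lambda c: c.start)
    return c_norm, candidates


# --------------------------------------------------------------------------
# event segmentation
# --------------------------------------------------------------------------


def segment_overlapping_events(records: pd.DataFrame) -> pd.DataFrame:
    """Cut overlapping interval events at all interval endpoints.

    Deletions (and, separately, amplifications) that partially overlap
    between isolates are replaced by their covered segments, so a stretch
    deleted in several isolates becomes a single shared predictor.  Events
    are segmented within one genome and one event type; point events pass
    through unchanged.  Coordinates stay 1-based inclusive (segments are
    half-open internally and rendered back inclusive).
    """
    _check_records(records)
    out_rows: list[pd.Series] = []
    interval = records["type"].isin(INTERVAL_TYPES)
    out_rows.extend(row for _, row in records[~interval].iterrows())
    for (_genome, _typ), grp in records[interval].groupby(["genome", "type"]):
        # half-open endpoint partition: [start, end + 1)
        points = np.unique(np.concatenate([grp["start"].to_numpy(int),
                                           grp["end"].to_numpy(int) + 1]))
        for _, row in grp.iterrows():
            cuts = points[(points > row["start"]) & (points <= row["end"])]
            bounds = np.concatenate(([row["start"]], cuts, [row["end"] + 1]))
            bounds = np.unique(bounds)
            for s, e in zip(bounds[:-1], bounds[1:]):
                seg = row.copy()
                seg["start"], seg["end"] = int(s), int(e) - 1
                out_rows.append(seg)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    return out.sort_values(["genome", "type", "start", "end", "isolate_id"],
                           kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# predictor encoding
# --------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Isolates x predictors with a metadata sidecar (one row per column)."""

    values: pd.DataFrame
    metadata: pd.DataFrame  # columns: predictor, genome, type, start, end, effect, members


def _predictor_label(row: pd.Series) -> str:
    abbrev = {"SNP": "S", "insertion": "I", "deletion": "D", "IS": "IS",
              "amplification": "CN"}
    t = abbrev[row["type"]]
    if row["type"] == "SNP":
        return f"{row['genome']}:{t}:{row['start']}{row.get('ref', '')}>{row.get('alt', '')}"
    return f"{row['genome']}:{t}:{row['start']}-{row['end']}"


def encode_predictors(
    records: pd.DataFrame, isolates: list[str] | None = None
) -> GenotypeMatrix:
    """Encode segmented mutation records into a predictor matrix.

    SNPs, insertions, deletions and IS insertions become 0/1 columns;
    amplifications become integer copy-number columns with ancestral value
    1.  Synonymous SNPs are omitted.  Identical (genome, type, interval,
    allele) records across isolates share a column.
    """
    _check_records(records)
    if isolates is None:
        isolates = list(pd.unique(records["isolate_id"]))
    recs = records[records.get("effect_annotation", "") != "synonymous"]
    key_cols = ["genome", "type", "start", "end"]
    if "alt" in recs.columns:
        key_cols += ["ref", "alt"]
    groups = recs.groupby(key_cols, dropna=False, sort=True)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    iso_index = {iso: i for i, iso in enumerate(isolates)}
    for key, grp in groups:
        row0 = grp.iloc[0]
        label = _predictor_label(row0)
        is_amp = row0["type"] == "amplification"
        col = np.ones(len(isolates), dtype=int) if is_amp else np.zeros(len(isolates), dtype=int)
        seen: dict[str, int] = {}
        for _, r in grp.iterrows():
            iso = r["isolate_id"]
            if iso not in iso_index:
                raise ValueError(f"isolate {iso} not in isolate list")
            val = int(float(r["copy_number"])) if is_amp else 1
            if iso in seen and seen[iso] != val:
                raise ValueError(f"conflicting records for {iso} at predictor {label}")
            seen[iso] = val
            col[iso_index[iso]] = val
        columns[label] = col
        meta_rows.append(
            {
                "predictor": label,
                "genome": row0["genome"],
                "type": row0["type"],
                "start": int(row0["start"]),
                "end": int(row0["end"]),
                "effect": row0.get("effect_annotation", ""),
                "members": label,
            }
        )
    values = pd.DataFrame(columns, index=pd.Index(isolates, name="isolate_id"))
    return GenotypeMatrix(values=values, metadata=pd.DataFrame(meta_rows))


def join_cooccurring(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Merge non-amplification predictors with identical carrier patterns.

    Perfectly co-occurring mutations cannot be distinguished by any
    regression on these isolates, so they are represented by one compound
    predictor whose label concatenates the members with '+' in genomic
    order.  Amplification columns are never merged (their integer values
    depend on copy number).
    """
    vals, meta = matrix.values, matrix.metadata.set_index("predictor")
    amp_cols = [c for c in vals.columns if meta.loc[c, "type"] == "amplification"]
    other = [c for c in vals.columns if c not in amp_cols]
    pattern_groups: dict[bytes, list[str]] = {}
    for c in other:
        pattern_groups.setdefault(vals[c].to_numpy().tobytes(), []).append(c)

    new_cols = {}
    meta_rows = []
    for cols in pattern_groups.values():
        cols = sorted(cols, key=lambda c: (meta.loc[c, "genome"], meta.loc[c, "start"]))
        label = "+".join(cols)
        new_cols[label] = vals[cols[0]]
        first = meta.loc[cols[0]]
        meta_rows.append(
            {
                "predictor": label,
                "genome": first["genome"],
                "type": first["type"] if len(cols) == 1 else "joined",
                "start": int(first["start"]),
                "end": int(meta.loc[cols[-1], "end"]),
                "effect": first["effect"] if len(cols) == 1 else "compound",
                "members": "+".join(meta.loc[c, "members"] for c in cols),
            }
        )
    for c in amp_cols:
        new_cols[c] = vals[c]
        meta_rows.append(meta.loc[c].to_dict() | {"predictor": c})
    values = pd.DataFrame(new_cols, index=vals.index)
    order = np.argsort([m["predictor"] for m in meta_rows], kind="stable")
    meta_df = pd.DataFrame([meta_rows[i] for i in order])
    return GenotypeMatrix(values=values[list(meta_df["predictor"])], metadata=meta_df)


# --------------------------------------------------------------------------
# paired observations
# --------------------------------------------------------------------------


def build_observations(
    bacteria: GenotypeMatrix | pd.DataFrame,
    phage: GenotypeMatrix | pd.DataFrame,
    infection_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """One observation per distinct joint (bacterium, phage) genotype.

    Every scored pair contributes; pairs whose concatenated genotype vectors
    coincide are pooled into one observation carrying their mean infectivity
    (``response``) and the pooled pair count (``weight``).  Observation
    weights therefore sum to the number of scored pairs.  The returned frame
    has the joint predictor columns plus ``response`` and ``weight``.
    """
    Xb = bacteria.values if isinstance(bacteria, GenotypeMatrix) else bacteria
    Xp = phage.values if isinstance(phage, GenotypeMatrix) else phage
    missing_b = set(infection_matrix.columns) - set(Xb.index)
    missing_p = set(infection_matrix.index) - set(Xp.index)
    if missing_b or missing_p:
        raise ValueError(
            f"isolates scored but not genotyped: {sorted(missing_b | missing_p)}"
        )
    overlap = set(Xb.columns) & set(Xp.columns)
    if overlap:
        raise ValueError(f"predictor labels shared across organisms: {sorted(overlap)}")

    long = infection_matrix.stack(future_stack=True).rename("response").reset_index()
    long.columns = ["phage_id", "bacterium_id", "response"]
    long = long.dropna(subset=["response"]).reset_index(drop=True)  # unmeasured pairs
    joint = pd.concat(
        [
            Xb.loc[long["bacterium_id"]].reset_index(drop=True),
            Xp.loc[long["phage_id"]].reset_index(drop=True),
        ],
        axis=1,
    )
    joint["response"] = long["response"].to_numpy()
    pred_cols = [c for c in joint.columns if c != "response"]
    obs = (
        joint.groupby(pred_cols, sort=False)
        .agg(response=("response", "mean"), weight=("response", "size"))
        .reset_index()
    )
    return obs
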