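"""Permutation tests for adaptive evolution.

Two null-model tests ask whether the observed mutation spectrum shows more
adaptation than random mutation would produce:

* ``dnds_permutation`` — is the nonsynonymous fraction of intragenic SNPs
  higher than expected?  Each unique intragenic SNP is re-placed uniformly
  over all ORF positions, its alternative allele drawn so as to preserve its
  own transition/transversion class, and the simulated nonsynonymous count
  is compared with the observed one (P_dN/dS).
* ``multihit_simulation`` — did any gene accumulate more independent
  mutation events than uniform placement over the genome allows?  Events
  recurring in m replicates are re-placed m times; interval events mark
  every overlapped gene; the family-wise threshold is set where at most 5%
  of simulations reach a per-gene count that high.

Effect classification (``classify_snp``) uses the standard genetic code;
stop gains and losses count as nonsynonymous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

PURINES = {"A", "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def snp_class(ref: str, alt: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or
    'transversion'."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if (ref in PURINES) == (alt in PURINES) else "transversion"


@dataclass
class GenomeAnnotation:
    """Reference sequence with ORF coordinates (1-based inclusive)."""

    sequence: str
    orfs: list[tuple[int, int, str]]
    gene_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for (s, e, strand) in self.orfs:
            if not (1 <= s <= e <= n):
                raise ValueError("ORF outside sequence")
            if (e - s + 1) % 3 != 0:
                raise ValueError("ORF length must be divisible by 3")
            if strand not in "+-":
                raise ValueError("strand must be + or -")
        if len(self.gene_names) != len(self.orfs):
            raise ValueError("one gene name per ORF required")

    @classmethod
    def from_fasta_gff3(cls, fasta_path, gff3_path) -> "GenomeAnnotation":
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        by_type: dict[str, list[tuple[tuple[int, int, str], str]]] = {}
        with open(gff3_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] not in ("CDS", "gene"):
                    continue
                start, end, strand = int(parts[3]), int(parts[4]), parts[6]
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or f"orf_{start}"
                by_type.setdefault(parts[2], []).append(((start, end, strand), name))
        # prefer CDS features; gene rows are a fallback for sparse files
        feats = by_type.get("CDS") or by_type.get("gene") or []
        seen: set[tuple[int, int, str]] = set()
        orfs, names = [], []
        for orf, name in feats:
            if orf not in seen:
                seen.add(orf)
                orfs.append(orf)
                names.append(name)
        return cls(str(record.seq).upper(), orfs, names)

    def containing_orfs(self, position: int) -> list[int]:
        return [i for i, (s, e, _) in enumerate(self.orfs) if s <= position <= e]


def classify_snp(genome: GenomeAnnotation, position: int, ref: str, alt: str) -> str:
    """Effect of a SNP: 'intergenic', 'synonymous' or 'nonsynonymous'.

    The containing codon is translated before and after the change
    (reverse-complementing on minus-strand ORFs).  A change that alters the
    amino acid — including stop gains and losses — is nonsynonymous.  A
    position inside several overlapping ORFs is classified against each and
    reported nonsynonymous if nonsynonymous in any (with a warning).
    """
    if not 1 <= position <= len(genome.sequence):
        raise ValueError("position outside genome")
    if genome.sequence[position - 1] != ref:
        raise ValueError(
            f"ref allele {ref} does not match genome at {position} "
            f"({genome.sequence[position - 1]})"
        )
    hits = genome.containing_orfs(position)
    if not hits:
        return "intergenic"
    if len(hits) > 1:
        warnings.warn(f"position {position} lies in {len(hits)} overlapping ORFs")
    effects = []
    for i in hits:
        s, e, strand = genome.orfs[i]
        if strand == "+":
            off = position - s
            cs = s - 1 + (off // 3) * 3
            codon = genome.sequence[cs : cs + 3]
            within = off % 3
            mutated = codon[:within] + alt + codon[within + 1 :]
        else:
            coding = str(Seq(genome.sequence[s - 1 : e]).reverse_complement())
            off = e - position
            cs = (off // 3) * 3
            codon = coding[cs : cs + 3]
            within = off % 3
            alt_rc = str(Seq(alt).reverse_complement())
            mutated = codon[:within] + alt_rc + codon[within + 1 :]
        same = Seq(codon).translate() == Seq(mutated).translate()
        effects.append("synonymous" if same else "nonsynonymous")
    return "nonsynonymous" if "nonsynonymous" in effects else "synonymous"


# --------------------------------------------------------------------------
# dN/dS permutation
# --------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray = field(repr=False)
    p_value: float
    n_reps: int
    seed: int


def _orf_site_tables(genome: GenomeAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Per concatenated-ORF-site nonsynonymy indicators.

    Returns ``(ts, tv)`` where ``ts[i]`` says whether the (unique)
    transition at site i is nonsynonymous and ``tv[i, j]`` the same for the
    site's two transversions.  Sites are the coding-strand positions of all
    ORFs concatenated, so uniform placement over them weights ORFs by
    length.
    """
    ts_list, tv_list = [], []
    for (s, e, strand) in genome.orfs:
        coding = genome.sequence[s - 1 : e]
        if strand == "-":
            coding = str(Seq(coding).reverse_complement())
        for i in range(len(coding)):
            cs = (i // 3) * 3
            codon = coding[cs : cs + 3]
            aa = str(Seq(codon).translate())
            ref = coding[i]

            def nonsyn(alt: str) -> bool:
                mut = codon[: i % 3] + alt + codon[i % 3 + 1 :]
                return str(Seq(mut).translate()) != aa

            ts_list.append(nonsyn(_TRANSITION[ref]))
            tv_list.append([nonsyn(a) for a in _TRANSVERSIONS[ref]])
    return np.array(ts_list, dtype=bool), np.array(tv_list, dtype=bool)


def dnds_permutation(
    genome: GenomeAnnotation,
    snps: pd.DataFrame,
    n: int = 10_000,
    seed: int = 0,
    weight_by_multiplicity: bool = False,
) -> PermutationResult:
    """Empirical test for an excess of nonsynonymous intragenic SNPs.

    ``snps`` needs columns ``position``, ``ref``, ``alt`` and optionally
    ``multiplicity`` (number of independent replicates carrying the event).
    Intergenic SNPs are excluded.  Per permutation replicate, each unique
    intragenic SNP is placed uniformly over all ORF positions and its alt
    allele drawn to preserve its transition/transversion class (the
    transition partner is unique; transversions pick one of two partners
    uniformly).  By default a recurrent event counts once both observed and
    simulated; with ``weight_by_multiplicity`` its outcome is weighted by
    its replicate count in both.  p = (1 + #{sim >= obs}) / (1 + n).
    """
    if not genome.orfs:
        raise ValueError("genome has no ORFs")
    events = snps.drop_duplicates(subset=["position", "ref", "alt"]).copy()
    events["effect"] = [
        classify_snp(genome, int(r.position), r.ref, r.alt)
        for r in events.itertuples()
    ]
    intragenic = events[events["effect"] != "intergenic"]
    if intragenic.empty:
        raise ValueError("no intragenic SNPs to permute")
    mult = (
        intragenic["multiplicity"].to_numpy(float)
        if weight_by_multiplicity and "multiplicity" in intragenic.columns
        else np.ones(len(intragenic))
    )
    observed = float(mult[(intragenic["effect"] == "nonsynonymous").to_numpy()].sum())

    ts_tab, tv_tab = _orf_site_tables(genome)
    n_sites = len(ts_tab)
    is_ts = np.array(
        [snp_class(r, a) == "transition"
         for r, a in zip(intragenic["ref"], intragenic["alt"])]
    )
    rng = np.random.default_rng(seed)
    s_events = len(intragenic)
    sites = rng.integers(0, n_sites, size=(n, s_events))
    outcome = np.empty((n, s_events), dtype=bool)
    if is_ts.any():
        outcome[:, is_ts] = ts_tab[sites[:, is_ts]]
    if (~is_ts).any():
        partner = rng.integers(0, 2, size=(n, int((~is_ts).sum())))
        outcome[:, ~is_ts] = tv_tab[sites[:, ~is_ts], partner]
    null = (outcome * mult).sum(axis=1)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n)
    return PermutationResult(observed=observed, null=null, p_value=p,
                             n_reps=n, seed=seed)


# --------------------------------------------------------------------------
# multiply-mutated genes
# --------------------------------------------------------------------------


@dataclass
class MultiHitResult:
    observed_counts: pd.Series
    null_max: np.ndarray = field(repr=False)
    threshold: int
    flagged: list[str]
    n_reps: int
    alpha: float
    seed: int


def multihit_simulation(
    mutations: pd.DataFrame,
    genome: GenomeAnnotation,
    n_reps: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    per_gene: bool = False,
) -> MultiHitResult:
    """Detect genes mutated more often than uniform placement allows.

    ``mutations`` needs ``start``, ``end`` (1-based inclusive; equal for
    point events) and optionally ``multiplicity``.  Observed per-gene counts
    sum event multiplicities over all events overlapping the gene.  Per
    simulation replicate every event is re-positioned uniformly over the
    genome, keeping its length, with ``multiplicity`` independent draws for
    parallel events; genes overlapped by a placed event are incremented.

    By default the null statistic is the replicate-wise *maximum* per-gene
    count (family-wise control): the threshold c* is the smallest count
    reached by at most ``alpha`` of replicates, and genes with observed
    count >= c* are flagged.  With ``per_gene=True`` the threshold is
    instead computed per gene from that gene's own null counts.
    """
    if mutations.empty:
        raise ValueError("empty mutation set")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    G = len(genome.sequence)
    order = np.argsort([s for (s, _, _) in genome.orfs], kind="stable")
    starts = np.array([genome.orfs[i][0] for i in order])
    ends = np.array([genome.orfs[i][1] for i in order])
    names = [genome.gene_names[i] for i in order]
    n_genes = len(names)

    mult = (
        mutations["multiplicity"].to_numpy(int)
        if "multiplicity" in mutations.columns
        else np.ones(len(mutations), dtype=int)
    )
    lengths = (mutations["end"] - mutations["start"] + 1).to_numpy(int)
    if (lengths > G).any():
        raise ValueError("event longer than the genome")

    # observed per-gene counts (an interval event hits every overlapped gene)
    obs = np.zeros(n_genes, dtype=int)
    for (s, e), m in zip(mutations[["start", "end"]].to_numpy(int), mult):
        hit = (starts <= e) & (ends >= s)
        obs[hit] += m

    draw_len = np.repeat(lengths, mult)
    rng = np.random.default_rng(seed)
    # difference-array accumulation: +1 at first overlapped gene, -1 after last
    diff = np.zeros((n_reps, n_genes + 1), dtype=np.int32)
    rows = np.arange(n_reps)
    for ln in np.unique(draw_len):
        k = int((draw_len == ln).sum())
        pos = rng.integers(1, G - ln + 2, size=(n_reps, k))  # event start
        end = pos + ln - 1
        for j in range(k):
            lo = np.searchsorted(ends, pos[:, j], side="left")
            hi = np.searchsorted(starts, end[:, j], side="right")
            valid = hi > lo
            np.add.at(diff, (rows[valid], lo[valid]), 1)
            np.add.at(diff, (rows[valid], hi[valid]), -1)
    null_counts = np.cumsum(diff[:, :-1], axis=1)
    null_max = null_counts.max(axis=1)

    if per_gene:
        thresholds = np.array(
            [_threshold(null_counts[:, g], alpha) for g in range(n_genes)]
        )
        flagged = [names[g] for g in range(n_genes) if obs[g] >= thresholds[g]]
        c_star = int(thresholds.min())
    else:
        c_star = _threshold(null_max, alpha)
        flagged = [names[g] for g in range(n_genes) if obs[g] >= c_star]
    return MultiHitResult(
        observed_counts=pd.Series(obs, index=names, name="n_mutations"),
        null_max=null_max,
        threshold=int(c_star),
        flagged=flagged,
        n_reps=n_reps,
        alpha=alpha,
        seed=seed,
    )


def _threshold(null: np.ndarray, alpha: float) -> int:
    """Smallest c with P(null >= c) <= alpha."""
    c = 1
    while np.mean(null >= c) > alpha:
        c += 1
    return c
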