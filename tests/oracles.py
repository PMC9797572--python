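"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from their definitions (per-pair
loops, exhaustive partition enumeration, per-base coverage counting) and
share no code with the vectorised implementations they check.
"""

import itertools

import numpy as np


def nodf_oracle(A):
    """Literal per-pair NODF definition."""
    A = np.asarray(A, int)
    A = A[A.sum(1) > 0][:, A.sum(0) > 0]
    contributions = []
    for M in (A, A.T):
        k = M.sum(1)
        for i, j in itertools.combinations(range(M.shape[0]), 2):
            if k[i] == k[j] or min(k[i], k[j]) == 0:
                contributions.append(0.0)
            else:
                sparse, dense = (i, j) if k[i] < k[j] else (j, i)
                contributions.append((M[sparse] & M[dense]).sum() / k[sparse])
    return float(np.mean(contributions))


def all_partitions(n):
    """Every set partition of n items as canonical label vectors."""
    out = []

    def rec(i, labels, kmax):
        if i == n:
            out.append(tuple(labels))
            return
        for lab in range(kmax + 1):
            labels.append(lab)
            rec(i + 1, labels, max(kmax, lab + 1) if lab == kmax else kmax)
            labels.pop()

    rec(1, [0], 1)
    return np.array(out)


def brute_force_barber_q(A, partitions=None):
    """Maximum Barber modularity by exhaustive partition enumeration."""
    A = np.asarray(A, float)
    r, c = A.shape
    m = A.sum()
    B = A - np.outer(A.sum(1), A.sum(0)) / m
    parts = all_partitions(r + c) if partitions is None else partitions
    g, h = parts[:, :r], parts[:, r : r + c]
    delta = (g[:, :, None] == h[:, None, :]).astype(float)
    return float((np.einsum("rc,prc->p", B, delta) / m).max())


def per_base_coverage(records, genome_length=2000):
    """Per-isolate per-base coverage counts of interval records."""
    cover = {}
    for _, row in records.iterrows():
        base = cover.setdefault(row["isolate_id"], np.zeros(genome_length, int))
        base[row["start"] - 1 : row["end"]] += 1
    return cover


def multihit_null_max_oracle(starts_lengths, gene_len, n_genes, n_reps, rng):
    """Plain-python Monte-Carlo of the multi-hit null maximum for a genome of
    equal-length genes tiling [1, n_genes * gene_len]."""
    G = n_genes * gene_len
    maxima = np.empty(n_reps, int)
    for rep in range(n_reps):
        counts = [0] * n_genes
        for ln in starts_lengths:
            start = int(rng.integers(1, G - ln + 2))
            end = start + ln - 1
            first = (start - 1) // gene_len
            last = (end - 1) // gene_len
            for gidx in range(first, min(last, n_genes - 1) + 1):
                counts[gidx] += 1
        maxima[rep] = max(counts)
    return maxima
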