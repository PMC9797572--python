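"""Structure of the phage x bacteria cross-infection network.

Assembles per-spot scores into an infection matrix, measures wildtype
control concordance, clusters isolates into phenotypic classes
(complete-linkage on Euclidean profile distances, cut at 40% of the maximum
merge height), and quantifies bipartite structure: NODF nestedness and
Barber modularity, with significance against the EQUIPROBABLE null
(independent Bernoulli entries at the observed fill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr

DEFAULT_CUT_FRACTION = 0.4
DEFAULT_NULL_REPS = 10_000


# --------------------------------------------------------------------------
# matrix assembly and controls
# --------------------------------------------------------------------------


def assemble_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long score table into a phage (rows) x bacteria (columns) matrix.

    ``scores`` needs columns ``phage_id``, ``bacterium_id``, ``infectivity``
    and optionally ``plate_id``.  A pair may be scored at most once per
    plate; measurements of the same pair from different plates are averaged.
    Unmeasured pairs become NaN.
    """
    required = {"phage_id", "bacterium_id", "infectivity"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table must contain columns {sorted(required)}")
    key = ["phage_id", "bacterium_id"]
    if "plate_id" in scores.columns:
        dup = scores.duplicated(subset=key + ["plate_id"])
        if dup.any():
            raise ValueError("a pair was scored more than once on the same plate")
    vals = scores["infectivity"]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("infectivity scores must lie in [0, 1]")
    return scores.pivot_table(
        index="phage_id", columns="bacterium_id", values="infectivity", aggfunc="mean"
    )


def concordance_r2(
    matrix: pd.DataFrame, control_ids: list[str], axis: str = "rows"
) -> pd.DataFrame:
    """Squared Pearson correlation between control replicate profiles.

    For each pair of wildtype controls on one axis, the score vectors across
    the other axis are compared (missing entries dropped pairwise).  High
    R^2 between replicates validates the infectivity score.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    M = matrix if axis == "rows" else matrix.T
    missing = [c for c in control_ids if c not in M.index]
    if missing:
        raise ValueError(f"control ids not in matrix: {missing}")
    if len(control_ids) < 2:
        raise ValueError("need at least 2 controls")
    rows = []
    for i, a in enumerate(control_ids):
        for b in control_ids[i + 1 :]:
            va, vb = M.loc[a].to_numpy(float), M.loc[b].to_numpy(float)
            ok = ~(np.isnan(va) | np.isnan(vb))
            if ok.sum() < 3:
                raise ValueError(f"controls {a},{b} share fewer than 3 observations")
            r = pearsonr(va[ok], vb[ok]).statistic
            rows.append({"control_a": a, "control_b": b,
                         "n_shared": int(ok.sum()), "r2": r * r})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# phenotypic classes
# --------------------------------------------------------------------------


@dataclass
class ClassAssignment:
    """Complete-linkage tree with classes cut at a fraction of its height."""

    linkage: np.ndarray
    labels: pd.Series  # class id per isolate
    cut_height: float
    leaf_order: list


def cluster_isolates(
    matrix: pd.DataFrame, axis: str = "rows",
    cut_fraction: float = DEFAULT_CUT_FRACTION,
) -> ClassAssignment:
    """Cluster isolate profiles into phenotypic classes.

    Euclidean pairwise distances, complete-linkage agglomeration, classes by
    cutting the tree at ``cut_fraction`` of the maximum merge height.
    Profiles must be complete (impute or drop missing values first).
    """
    M = matrix if axis == "rows" else matrix.T
    if M.shape[0] < 2:
        raise ValueError("need at least 2 isolates to cluster")
    X = M.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("profiles contain missing values; impute first")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    cut = cut_fraction * Z[:, 2].max()
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    order = hierarchy.leaves_list(Z)
    return ClassAssignment(
        linkage=Z,
        labels=pd.Series(labels, index=M.index, name="class"),
        cut_height=float(cut),
        leaf_order=[M.index[i] for i in order],
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with merge-height
    branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# --------------------------------------------------------------------------
# imputation and binarisation
# --------------------------------------------------------------------------


def impute_missing(matrix: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Fill each missing cell with the mean of its window x window
    neighbourhood in the class-sorted matrix (truncated at edges).

    The matrix should already be sorted by cluster leaf order so neighbours
    are phenotypically similar.  A missing cell whose whole neighbourhood is
    missing is an error.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    X = matrix.to_numpy(float).copy()
    out = X.copy()
    h = window // 2
    miss = np.argwhere(np.isnan(X))
    for (i, j) in miss:
        sub = X[max(0, i - h) : i + h + 1, max(0, j - h) : j + h + 1]
        vals = sub[~np.isnan(sub)]
        if vals.size == 0:
            raise ValueError(f"missing cell ({i},{j}) has an all-missing neighbourhood")
        out[i, j] = vals.mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def binarize(matrix: pd.DataFrame | np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """1 where score strictly exceeds ``threshold``, else 0."""
    X = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if np.isnan(X).any():
        raise ValueError("binarize requires a complete (imputed) matrix")
    return (X > threshold).astype(int)


def _drop_empty(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    A = A[A.sum(axis=1) > 0][:, A.sum(axis=0) > 0]
    return A


# --------------------------------------------------------------------------
# nestedness (NODF)
# --------------------------------------------------------------------------


def nodf(matrix: np.ndarray) -> float:
    """NODF nestedness of a binary matrix, on a 0-1 scale.

    Empty rows and columns are ignored.  Every ordered pair of rows (and of
    columns) contributes the fraction of the sparser line's 1s that are
    shared with the denser line, *if* their marginal totals strictly differ,
    and 0 otherwise; NODF is the mean contribution over all row pairs and
    column pairs.  1.0 means perfectly nested (specialists' hosts are strict
    subsets of generalists'), 0.0 means no decreasing-fill overlap at all.
    """
    A = _drop_empty(np.asarray(matrix, dtype=int))
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("matrix smaller than 2x2 after removing empty lines")

    def axis_sum(M: np.ndarray) -> tuple[float, int]:
        k = M.sum(axis=1)
        O = M @ M.T
        kmin = np.minimum.outer(k, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(kmin > 0, O / kmin, 0.0)
        frac[np.equal.outer(k, k)] = 0.0  # equal marginals contribute nothing
        iu = np.triu_indices(len(k), 1)
        return float(frac[iu].sum()), len(iu[0])

    s_rows, n_rows = axis_sum(A)
    s_cols, n_cols = axis_sum(A.T)
    return (s_rows + s_cols) / (n_rows + n_cols)


# --------------------------------------------------------------------------
# Barber modularity
# --------------------------------------------------------------------------


@dataclass
class ModularityResult:
    q: float
    row_labels: np.ndarray
    col_labels: np.ndarray


def barber_q(A: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber bipartite modularity of a given partition:
    Q_b = (1/m) * sum_ij (A_ij - k_i d_j / m) [g_i == h_j]."""
    A = np.asarray(A, dtype=float)
    m = A.sum()
    if m == 0:
        raise ValueError("matrix has no edges")
    B = A - np.outer(A.sum(axis=1), A.sum(axis=0)) / m
    delta = np.equal.outer(np.asarray(row_labels), np.asarray(col_labels))
    return float((B * delta).sum() / m)


def modularity(
    matrix: np.ndarray, n_restarts: int = 24, seed: int = 0, max_iter: int = 60
) -> ModularityResult:
    """Maximise Barber modularity with a BRIM-style alternating search.

    Starting from several column-label initialisations (one-module,
    all-distinct, and seeded random ones, advanced simultaneously), row and
    column module assignments are alternately set to their best response
    until labels stabilise; the best restart wins.  Q_b of the single-module
    partition is 0, so the result is never negative.  Deterministic given
    the seed.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("matrix must be 2-D and nonempty")
    m = A.sum()
    if m == 0:
        raise ValueError("matrix has no edges")
    r, c = A.shape
    K = max(min(r, c), 1)
    B = A - np.outer(A.sum(axis=1), A.sum(axis=0)) / m

    rng = np.random.default_rng(seed)
    S = max(n_restarts, 2)
    col_lab = np.empty((S, c), dtype=int)
    col_lab[0] = 0  # single module
    col_lab[1] = np.arange(c) % K  # all-distinct (up to K)
    for s in range(2, S):
        col_lab[s] = rng.integers(0, K, size=c)

    eye = np.eye(K)
    T = eye[col_lab]  # (S, c, K)
    prev = None
    for _ in range(max_iter):
        row_lab = np.einsum("rc,sck->srk", B, T).argmax(axis=2)  # (S, r)
        R = eye[row_lab]
        col_lab = np.einsum("rc,srk->sck", B, R).argmax(axis=2)  # (S, c)
        T = eye[col_lab]
        state = np.concatenate([row_lab, col_lab], axis=1)
        if prev is not None and np.array_equal(state, prev):
            break
        prev = state

    q_all = np.einsum("srk,rc,sck->s", R, B, T) / m
    best = int(q_all.argmax())
    q, rl, cl = float(q_all[best]), row_lab[best], col_lab[best]
    if q < 0.0:  # single-module partition is always available
        q, rl, cl = 0.0, np.zeros(r, dtype=int), np.zeros(c, dtype=int)
    # canonical relabelling by first appearance across rows then columns
    remap: dict[int, int] = {}
    for lab in list(rl) + list(cl):
        if lab not in remap:
            remap[lab] = len(remap)
    return ModularityResult(
        q=q,
        row_labels=np.array([remap[x] for x in rl]),
        col_labels=np.array([remap[x] for x in cl]),
    )


# --------------------------------------------------------------------------
# EQUIPROBABLE null
# --------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed statistic vs. draws from a null ensemble."""

    observed: float
    null: np.ndarray = field(repr=False)
    p_value: float
    n_reps: int
    seed: int


def equiprobable_null(
    matrix: np.ndarray,
    statistic: str = "nodf",
    n: int = DEFAULT_NULL_REPS,
    seed: int = 0,
    modularity_restarts: int = 6,
) -> PermutationResult:
    """Significance of nestedness or modularity under the EQUIPROBABLE null.

    Null matrices are i.i.d. Bernoulli(p) of the observed shape with p equal
    to the observed fill fraction.  The p-value uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n), so it is never exactly zero.  Null
    draws whose non-empty submatrix degenerates below 2x2 score 0 (no
    structure).
    """
    A = np.asarray(matrix, dtype=int)
    p = A.mean()
    if p <= 0 or p >= 1:
        raise ValueError("matrix fill must be strictly between 0 and 1")

    def stat(M: np.ndarray) -> float:
        try:
            if statistic == "nodf":
                return nodf(M)
            if statistic == "modularity":
                M2 = _drop_empty(M)
                if M2.shape[0] < 1 or M2.shape[1] < 1 or M2.sum() == 0:
                    return 0.0
                return modularity(M2, n_restarts=modularity_restarts, seed=seed).q
            raise ValueError("statistic must be 'nodf' or 'modularity'")
        except ValueError as err:
            if "smaller than 2x2" in str(err):
                return 0.0
            raise

    observed = stat(A)
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        null[i] = stat((rng.random(A.shape) < p).astype(int))
    p_value = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n)
    return PermutationResult(observed=observed, null=null, p_value=p_value,
                             n_reps=n, seed=seed)
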