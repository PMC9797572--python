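"""Sparse genotype–phenotype association by cross-validated Lasso.

The infectivity score of each (bacterium, phage) pair is modelled as a
linear function of the pair's joint mutation predictors with an L1 penalty:

    min_b  (1/2n) * ||y - b0 - X b||^2  +  lambda * ||b||_1

Predictors are standardised internally (coefficients are reported on the
original scale) and the intercept is unpenalised.  The penalty is chosen by
k-fold cross-validation with the one-standard-error rule: the largest
lambda whose CV mean squared error is within one standard error of the
minimum, i.e. the sparsest model statistically indistinguishable from the
best one.

The penalty grid is geometric with ``n_lambda`` points, anchored at the
analytic critical penalty lambda_max = max|X'(y - ybar)|/n (above which
every coefficient is exactly zero by the KKT conditions) and descending
four decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

DEFAULT_N_LAMBDA = 200
DEFAULT_FOLDS = 5
LAMBDA_DECADES = 4.0


@dataclass
class LassoFit:
    """Full regularisation path with its cross-validation curve."""

    lambdas: np.ndarray
    coef_path: np.ndarray = field(repr=False)  # p x n_lambda, original scale
    cv_mse: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    coef: pd.Series  # original-scale coefficients at lambda_1se
    intercept: float
    predictors: list[str]
    seed: int

    @property
    def nonzero(self) -> pd.Series:
        return self.coef[self.coef != 0.0]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns stay zero after centring
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    n = len(y)
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    if lam_max == 0:
        raise ValueError("response is constant or orthogonal to all predictors")
    return np.geomspace(lam_max, lam_max * 10 ** (-LAMBDA_DECADES), n_lambda)


def fit_lasso(
    observations: pd.DataFrame,
    k: int = DEFAULT_FOLDS,
    n_lambda: int = DEFAULT_N_LAMBDA,
    seed: int = 0,
    weighted: bool = False,
) -> LassoFit:
    """Fit the Lasso path with k-fold CV and select by the 1-SE rule.

    ``observations`` is the frame from
    :func:`phagecoev.genotype_encoding.build_observations`: predictor
    columns plus ``response`` (and optionally ``weight``, used only when
    ``weighted=True``).  Folds are contiguous blocks after a seeded
    shuffle, so the fit is deterministic given the seed.
    """
    pred_cols = [c for c in observations.columns if c not in ("response", "weight")]
    X = observations[pred_cols].to_numpy(float)
    y = observations["response"].to_numpy(float)
    w = observations["weight"].to_numpy(float) if weighted and "weight" in observations \
        else None
    n, p = X.shape
    if n < k:
        raise ValueError("need at least k observations")
    if np.ptp(y) == 0:
        raise ValueError("constant response: no association model can be fit")

    Xs_full, mu, sd = _standardize(X)
    lambdas = _lambda_grid(Xs_full, y, n_lambda)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_of[chunk] = f

    sq_err = np.zeros((k, n_lambda))
    for f in range(k):
        tr, te = fold_of != f, fold_of == f
        Xtr, mtr, str_ = _standardize(X[tr])
        Xte = (X[te] - mtr) / str_
        coefs, icepts = _path(Xtr, y[tr], lambdas, None if w is None else w[tr])
        resid = y[te][:, None] - (Xte @ coefs + icepts)
        if w is None:
            sq_err[f] = (resid ** 2).mean(axis=0)
        else:
            sq_err[f] = (w[te][:, None] * resid ** 2).sum(axis=0) / w[te].sum()
    cv_mse = sq_err.mean(axis=0)
    cv_se = sq_err.std(axis=0, ddof=1) / np.sqrt(k)

    i_min = int(cv_mse.argmin())
    thresh = cv_mse[i_min] + cv_se[i_min]
    # lambdas descend along the grid; the 1-SE lambda is the largest within threshold
    i_1se = int(np.flatnonzero(cv_mse <= thresh)[0])

    coefs_std, icepts = _path(Xs_full, y, lambdas, w)
    coef_path = coefs_std / sd[:, None]
    coef_1se = coef_path[:, i_1se]
    intercept = float(icepts[i_1se] - mu @ coef_1se)
    return LassoFit(
        lambdas=lambdas,
        coef_path=coef_path,
        cv_mse=cv_mse,
        cv_se=cv_se,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        coef=pd.Series(coef_1se, index=pred_cols, name="coefficient"),
        intercept=intercept,
        predictors=pred_cols,
        seed=seed,
    )


def _path(Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
          w: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path and intercepts on standardised predictors."""
    if w is None:
        _, coefs, _ = lasso_path(Xs, y - y.mean(), alphas=lambdas,
                                 max_iter=10000, tol=1e-6)
        return coefs, np.full(len(lambdas), y.mean())
    # sample-weighted path: warm-started coordinate descent along the grid
    coefs = np.zeros((Xs.shape[1], len(lambdas)))
    icepts = np.zeros(len(lambdas))
    model = Lasso(alpha=lambdas[0], fit_intercept=True, warm_start=True,
                  max_iter=10000, tol=1e-6)
    for i, lam in enumerate(lambdas):
        model.set_params(alpha=lam)
        model.fit(Xs, y, sample_weight=w)
        coefs[:, i] = model.coef_
        icepts[i] = model.intercept_
    return coefs, icepts


def report_associations(
    fit: LassoFit, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tabulate nonzero coefficients, most negative (resistance) first.

    ``metadata`` (the predictor sidecar from genotype encoding) is merged in
    when given, so each association carries its gene/pathway annotation.
    """
    nz = fit.nonzero
    table = pd.DataFrame(
        {"predictor": nz.index, "coefficient": nz.to_numpy(),
         "sign": np.sign(nz.to_numpy()).astype(int)}
    ).sort_values("coefficient", kind="stable").reset_index(drop=True)
    if metadata is not None and len(table):
        table = table.merge(metadata, on="predictor", how="left")
    return table
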