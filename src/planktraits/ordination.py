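"""Redundancy analysis (RDA) of functional-group abundances against
environmental variables.

RDA is a constrained ordination: a principal-component decomposition of
the fitted values of the multivariate linear regression of the community
matrix on the predictors.  The response is ln(x+1)-transformed and
column-centered; predictors are column-standardized.  The fraction of the
response variance captured by the fit,

    explained_fraction = trace(Yhat' Yhat) / trace(Y' Y),

is the headline statistic; its significance is assessed by permuting
station rows of the response.

Scaling convention (fixed): site scores are the projections of the fitted
values onto the constrained axes (``U * S``); species scores are the
response loadings scaled to covariances (``V * S / sqrt(n - 1)``); biplot
scores are Pearson correlations of each standardized predictor with the
site-score axes.  The natural log is used for the log(x+1) transform; the
base only rescales columns and cancels from explained_fraction after
centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError

__all__ = ["RDAResult", "rda_fit", "rda_permutation_test"]

_EIG_TOL = 1e-10


@dataclass
class RDAResult:
    """Eigenvalues, explained variance and scores of one RDA fit."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    explained_fraction: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    predictors_used: list[str]

    @property
    def total_variance(self) -> float:
        return float(
            self.constrained_eigenvalues.sum() + self.unconstrained_eigenvalues.sum()
        )


def _as_matrix(obj, what: str) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(obj, pd.DataFrame):
        return obj.to_numpy(dtype=float), list(map(str, obj.index)), list(
            map(str, obj.columns)
        )
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{what} must be 2-dimensional")
    return (
        arr,
        [f"row{i}" for i in range(arr.shape[0])],
        [f"col{j}" for j in range(arr.shape[1])],
    )


def _prune_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop predictors until the standardized design has full rank.

    The later column of the most correlated remaining pair is dropped
    first, and a warning names every dropped predictor.
    """
    keep = list(range(X.shape[1]))
    while keep:
        sub = X[:, keep]
        if np.linalg.matrix_rank(sub, tol=1e-8) == len(keep):
            break
        corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        a, b = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        drop = keep[max(a, b)]
        warnings.warn(
            f"dropping collinear predictor {names[drop]!r}", stacklevel=3
        )
        keep.remove(drop)
    return X[:, keep], [names[i] for i in keep]


def rda_fit(response, predictors) -> RDAResult:
    """Fit an RDA of ``response`` (station x group abundances, raw scale)
    on ``predictors`` (station x environmental variables).

    Accepts DataFrames (preferred; labels survive into the score tables)
    or plain arrays with matching row order.
    """
    Yraw, sites, groups = _as_matrix(response, "response")
    Xraw, xsites, variables = _as_matrix(predictors, "predictors")
    if Yraw.shape[0] != Xraw.shape[0]:
        raise ValidationError("response and predictors must share stations")
    n = Yraw.shape[0]
    if n < 2:
        raise ValidationError("RDA requires at least 2 stations")
    if np.any(Yraw < 0):
        raise ValidationError("response abundances must be non-negative")

    Y = np.log1p(Yraw)
    Y = Y - Y.mean(axis=0)
    sd = Xraw.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        bad = [v for v, c in zip(variables, constant) if c]
        warnings.warn(f"dropping constant predictors {bad}", stacklevel=2)
        Xraw = Xraw[:, ~constant]
        variables = [v for v, c in zip(variables, constant) if not c]
    if not variables:
        raise ValidationError("no usable (non-constant) predictors")
    X = (Xraw - Xraw.mean(axis=0)) / Xraw.std(axis=0, ddof=1)
    X, variables = _prune_collinear(X, variables)
    if n <= len(variables) + 2:
        warnings.warn(
            f"only {n} stations for {len(variables)} predictors; "
            "fit is saturated or nearly so",
            stacklevel=2,
        )

    total = float((Y**2).sum())
    if total == 0:
        raise ValidationError("response has zero variance after transform")

    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ B
    resid = Y - Yhat

    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    r = int((S**2 > _EIG_TOL * total).sum())
    Ur, Sr, Vr = U[:, :r], S[:r], Vt[:r].T
    _, S_res, _ = np.linalg.svd(resid, full_matrices=False)
    r_res = int((S_res**2 > _EIG_TOL * max(total, 1.0)).sum())

    denom = n - 1
    constrained_eig = Sr**2 / denom
    unconstrained_eig = S_res[:r_res] ** 2 / denom
    explained = float((Sr**2).sum() / total)

    axes = [f"RDA{a + 1}" for a in range(r)]
    site_scores = pd.DataFrame(Ur * Sr, index=sites, columns=axes)
    species_scores = pd.DataFrame(
        Vr * (Sr / np.sqrt(denom)), index=groups, columns=axes
    )
    biplot = np.zeros((len(variables), r))
    for a in range(r):
        axis = site_scores.to_numpy()[:, a]
        if axis.std(ddof=0) > 0:
            biplot[:, a] = [
                float(np.corrcoef(X[:, v], axis)[0, 1]) for v in range(len(variables))
            ]
    biplot_scores = pd.DataFrame(biplot, index=variables, columns=axes)

    return RDAResult(
        constrained_eigenvalues=constrained_eig,
        unconstrained_eigenvalues=unconstrained_eig,
        explained_fraction=explained,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot_scores,
        predictors_used=variables,
    )


def rda_permutation_test(
    response, predictors, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p value for the RDA explained fraction.

    Station rows of the response are permuted ``n_perm`` times and the
    explained fraction recomputed; ``p = (1 + #{perm >= observed}) /
    (1 + n_perm)``.  At least 99 permutations are recommended for a stable
    p value.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    Yraw, _, _groups = _as_matrix(response, "response")
    Xraw, _, variables = _as_matrix(predictors, "predictors")
    if Yraw.shape[0] != Xraw.shape[0]:
        raise ValidationError("response and predictors must share stations")
    n = Yraw.shape[0]
    if n < 2:
        raise ValidationError("RDA requires at least 2 stations")

    # Row permutation commutes with column centering (column means are
    # permutation invariant), so the statistic for each permutation is the
    # squared norm of the projection of the permuted centered response onto
    # the fixed predictor column space.
    Y = np.log1p(Yraw)
    Y = Y - Y.mean(axis=0)
    denom = float((Y**2).sum())
    if denom == 0:
        raise ValidationError("response has zero variance after transform")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sd = Xraw.std(axis=0, ddof=1)
        Xraw = Xraw[:, sd > 0]
        variables = [v for v, s in zip(variables, sd) if s > 0]
        X = (Xraw - Xraw.mean(axis=0)) / Xraw.std(axis=0, ddof=1)
        X, _ = _prune_collinear(X, variables)
    Q, _ = np.linalg.qr(X)

    def frac(Z: np.ndarray) -> float:
        return float((np.linalg.norm(Q.T @ Z) ** 2) / denom)

    observed = frac(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        stat = frac(Y[rng.permutation(n), :])
        if stat >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
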