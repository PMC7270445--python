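"""Model fitting, classical tests, Bonferroni families and power arithmetic.

Linear models are ordinary least squares with t-based two-sided
p-values; logistic models are fitted by iteratively reweighted least
squares (via ``statsmodels`` GLM with a binomial family) with Wald
standard errors.  A multinomial outcome is decomposed into
one-vs-reference binary logistic fits, which keeps every reported
contrast available without a joint softmax likelihood.

All fits are complete-case: rows with any missing value among the
outcome or design columns are dropped, and the number actually used is
recorded on the :class:`ModelFit`.

A :class:`TestFamily` captures a declared set of hypothesis tests and
its Bonferroni-corrected threshold (family alpha divided by the number
of tests); the unrounded threshold is used for decisions, with a
3-decimal display value alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelFit", "TestFamily", "SampleSizeInput",
    "fit_linear", "fit_logistic", "fit_multinomial", "interaction_fit",
    "two_sample_t", "paired_t", "pearson", "ks_normality",
    "bonferroni", "sample_size",
]


class RankDeficientError(ValueError):
    """Design matrix is not full rank; names the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix rank-deficient; collinear columns: {self.columns}")


@dataclass
class ModelFit:
    """Coefficients, Wald statistics and the adjustment set of one fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    n_used: int
    adjustment_set: list[str] = field(default_factory=list)
    converged: bool = True
    family: str = "gaussian"

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "stat": float(self.stat[i]),
            "p": float(self.p[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "stat": self.stat,
                "p": self.p,
                "n_used": self.n_used,
            }
        )


@dataclass(frozen=True)
class TestFamily:
    """A named family of m tests controlled at a family-wise alpha."""

    name: str
    m: int
    alpha_family: float
    threshold: float          # alpha_family / m, unrounded
    threshold_display: float  # rounded to 3 decimals for reporting

    def significant(self, p: float) -> bool:
        return p <= self.threshold


@dataclass(frozen=True)
class SampleSizeInput:
    """Inputs to the two-group mean-difference sample size formula."""

    z_alpha: float
    z_beta: float
    s: float      # outcome standard deviation
    diff: float   # difference in group means (U1 - U2)

    def __post_init__(self):
        for name in ("z_alpha", "z_beta", "s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.diff == 0:
            raise ValueError("diff must be non-zero")


# ---------------------------------------------------------------------------
# design-matrix plumbing

def _as_design(X, names: Optional[Sequence[str]]) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{i}" for i in range(arr.shape[1])]
    return arr, list(names)


def _complete_cases(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.isfinite(y) & np.isfinite(X).all(axis=1)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify columns whose removal restores full column rank
    collinear = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            collinear.append(names[j])
    raise RankDeficientError(collinear or list(names))


def _prepare(y, X, names, add_intercept):
    Xa, names = _as_design(X, names)
    ya = np.asarray(y, dtype=float)
    if add_intercept:
        Xa = np.column_stack([np.ones(len(Xa)), Xa])
        names = ["intercept"] + names
    keep = _complete_cases(ya, Xa)
    ya, Xa = ya[keep], Xa[keep]
    if len(ya) <= Xa.shape[1]:
        raise ValueError(
            f"too few complete cases (n={len(ya)}) for {Xa.shape[1]} coefficients"
        )
    _check_rank(Xa, names)
    return ya, Xa, names


# ---------------------------------------------------------------------------
# model fits

def fit_linear(
    y,
    X,
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    adjustment_set: Optional[Sequence[str]] = None,
) -> ModelFit:
    """Ordinary least squares with t-based two-sided p-values.

    Standard errors use the unbiased residual variance (denominator
    n - p).  Incomplete rows are dropped; a rank-deficient design raises
    :class:`RankDeficientError` naming the collinear columns.
    """
    ya, Xa, names = _prepare(y, X, names, add_intercept)
    res = sm.OLS(ya, Xa).fit()
    return ModelFit(
        terms=names,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        stat=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        n_used=int(res.nobs),
        adjustment_set=list(adjustment_set or []),
        family="gaussian",
    )


def fit_logistic(
    y,
    X,
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    adjustment_set: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelFit:
    """Binary logistic regression by iteratively reweighted least squares.

    Wald z statistics and p-values.  Complete separation does not raise:
    the fit is returned with ``converged=False`` so callers can flag it.
    """
    ya, Xa, names = _prepare(y, X, names, add_intercept)
    classes = np.unique(ya)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("logistic outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(ya, Xa, family=sm.families.Binomial())
        res = model.fit(maxiter=max_iter, tol=tol)
        for w in caught:
            if "separat" in str(w.message).lower():
                converged = False
    if not res.converged or np.max(np.abs(res.params)) > 15.0:
        converged = False
    return ModelFit(
        terms=names,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        stat=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        n_used=int(res.nobs),
        adjustment_set=list(adjustment_set or []),
        converged=converged,
        family="binomial",
    )


def fit_multinomial(
    y: Sequence,
    X,
    reference,
    names: Optional[Sequence[str]] = None,
    adjustment_set: Optional[Sequence[str]] = None,
) -> dict[str, ModelFit]:
    """Categorical outcome as one-vs-reference binary logistic fits.

    For each non-reference level, rows belonging to that level or the
    reference are kept and a binary logistic model (level = 1,
    reference = 0) is fitted.  With exactly two levels this coincides
    with :func:`fit_logistic`.
    """
    y_arr = np.asarray(y, dtype=object)
    levels = [lv for lv in pd.unique(y_arr[pd.notna(y_arr)]) if lv != reference]
    if not levels:
        raise ValueError("outcome has no non-reference level")
    Xa, names = _as_design(X, names)
    fits: dict[str, ModelFit] = {}
    for level in levels:
        mask = (y_arr == level) | (y_arr == reference)
        y_bin = (y_arr[mask] == level).astype(float)
        fits[str(level)] = fit_logistic(
            y_bin, Xa[mask], names=names, adjustment_set=adjustment_set
        )
    return fits


def interaction_fit(
    outcome,
    grs,
    exposure,
    covariates: Optional[pd.DataFrame] = None,
    grs_name: str = "grs",
    exposure_name: str = "vitd",
) -> ModelFit:
    """Gene-environment interaction model for a continuous outcome.

    Fits ``outcome ~ grs + exposure + grs:exposure + covariates`` by
    OLS.  The product term is named ``"<grs_name>:<exposure_name>"``;
    its row carries the interaction coefficient, standard error and
    p-value.  The GRS may be the continuous allele count (default
    analysis coding) or a 0/1 group indicator for the stratified
    display.
    """
    g = np.asarray(grs, dtype=float)
    e = np.asarray(exposure, dtype=float)
    cols = {grs_name: g, exposure_name: e, f"{grs_name}:{exposure_name}": g * e}
    adjustment = []
    if covariates is not None:
        for name in covariates.columns:
            cols[name] = covariates[name].to_numpy(dtype=float)
            adjustment.append(name)
    X = pd.DataFrame(cols)
    return fit_linear(outcome, X, adjustment_set=adjustment)


def linear_f_test(y, X_full, X_reduced) -> tuple[float, float, int]:
    """Partial F test comparing nested OLS models on the same rows.

    Both designs must be DataFrames (or arrays) over the same
    observations; rows incomplete in *either* design are dropped from
    both so the comparison is nested.  Returns (F, p, n_used).
    """
    Xf, _ = _as_design(X_full, None)
    Xr, _ = _as_design(X_reduced, None)
    ya = np.asarray(y, dtype=float)
    keep = _complete_cases(ya, Xf) & np.isfinite(Xr).all(axis=1)
    ya, Xf, Xr = ya[keep], Xf[keep], Xr[keep]
    Xf = np.column_stack([np.ones(len(Xf)), Xf])
    Xr = np.column_stack([np.ones(len(Xr)), Xr])
    q = Xf.shape[1] - Xr.shape[1]
    if q < 1:
        raise ValueError("full model must have more columns than reduced model")
    res_f = sm.OLS(ya, Xf).fit()
    res_r = sm.OLS(ya, Xr).fit()
    df_resid = res_f.df_resid
    f = ((res_r.ssr - res_f.ssr) / q) / (res_f.ssr / df_resid)
    p = float(sps.f.sf(f, q, df_resid))
    return float(f), p, int(res_f.nobs)


# ---------------------------------------------------------------------------
# classical tests

def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Student t test for independent samples (pooled variance)."""
    a, b = _clean(group_a), _clean(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("two_sample_t: each group needs n >= 3")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("two_sample_t: zero variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def paired_t(before, after) -> tuple[float, float]:
    """Two-sided paired t test on within-subject differences."""
    x, y = np.asarray(before, dtype=float), np.asarray(after, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("paired_t: needs n >= 3 complete pairs")
    if np.allclose(x, y):
        return 0.0, 1.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValueError("pearson: needs n >= 3 complete pairs")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("pearson: zero variance input")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


def ks_normality(x) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and SD.  No Lilliefors
    correction is applied, so p-values are conservative (anti-
    conservative for rejection); this matches the common one-sample KS
    output of legacy statistical packages.
    """
    arr = _clean(x)
    if len(arr) < 5:
        raise ValueError("ks_normality: needs n >= 5")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("ks_normality: zero variance input")
    d, p = sps.kstest(arr, "norm", args=(float(np.mean(arr)), sd))
    return float(d), float(p)


# ---------------------------------------------------------------------------
# multiplicity and power

def bonferroni(alpha_family: float, m: int, name: str = "family") -> TestFamily:
    """Bonferroni-corrected per-test threshold for a family of m tests."""
    if m < 1:
        raise ValueError("bonferroni: m must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValueError("bonferroni: alpha_family must be in (0, 1)")
    threshold = alpha_family / m
    return TestFamily(
        name=name,
        m=m,
        alpha_family=alpha_family,
        threshold=threshold,
        threshold_display=round(threshold, 3),
    )


def sample_size(inputs: SampleSizeInput) -> tuple[float, int]:
    """Per-group n for detecting a mean difference between two groups.

    n = 2 (z_alpha + z_beta)^2 s^2 / diff^2; returns the raw value and
    its ceiling.  Invariant under sign flip of the difference.
    """
    n = 2 * (inputs.z_alpha + inputs.z_beta) ** 2 * inputs.s**2 / inputs.diff**2
    return n, math.ceil(n)
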