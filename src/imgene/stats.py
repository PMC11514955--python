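"""Shared statistical machinery: exact/categorical tests, rank tests,
FDR correction and logistic models.

All hypothesis tests return a :class:`TestResult` so downstream modules can
tabulate mixed test families uniformly.  The logistic machinery covers both
fitting (maximum likelihood via statsmodels) and scoring with a fixed,
externally supplied coefficient vector, e.g. the published multivariable
model for nodal metastasis (:data:`LN_METASTASIS_MODEL`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


class InputError(ValueError):
    """Raised when a statistical routine receives invalid input."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``estimate`` carries the method's natural effect measure (odds ratio for
    Fisher, rho for Spearman, U for Mann-Whitney); it may be ``None``.
    """

    statistic: float
    p_value: float
    method: str
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise InputError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class FdrResult:
    """Benjamini-Hochberg adjusted p-values in original input order."""

    p_values: np.ndarray
    q_values: np.ndarray
    threshold: float = 0.1

    def rejected(self) -> np.ndarray:
        return self.q_values < self.threshold


@dataclass
class LogisticModel:
    """A (fitted or externally specified) binary logistic model.

    ``coefficients`` maps covariate name -> slope on the logit scale.
    Optional inference fields are populated by :func:`fit_logistic`.
    """

    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float] | None = None
    p_values: dict[str, float] | None = None
    conf_int: dict[str, tuple[float, float]] | None = None
    converged: bool = True
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if len(set(self.coefficients)) != len(self.coefficients):
            raise InputError("duplicate coefficient names")

    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}

    @property
    def covariates(self) -> list[str]:
        return list(self.coefficients)


# ---------------------------------------------------------------------------
# categorical tests
# ---------------------------------------------------------------------------

def _validate_counts(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise InputError("contingency table must be 2-dimensional")
    if not np.issubdtype(arr.dtype, np.number):
        raise InputError("contingency table must be numeric")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise InputError("contingency table must hold non-negative integers")
    return arr.astype(np.int64)


def fisher_exact(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value sums all hypergeometric tables with the observed
    margins whose probability does not exceed that of the observed table.
    The conditional odds ratio is reported; zero cells yield 0 or inf.
    """
    arr = _validate_counts(table)
    if arr.shape != (2, 2):
        raise InputError("fisher_exact requires a 2x2 table")
    odds, p = sps.fisher_exact(arr, alternative=alternative)
    return TestResult(statistic=float(odds), p_value=float(p),
                      method="fisher_exact", estimate=float(odds))


def pearson_chi2(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on an r x c table."""
    arr = _validate_counts(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise InputError("zero marginal total in contingency table")
    res = sps.chi2_contingency(arr, correction=continuity_correction)
    return TestResult(statistic=float(res[0]), p_value=float(res[1]),
                      method="pearson_chi2")


def categorical_test(table, method: str = "fisher") -> TestResult:
    """Dispatch between Fisher (2x2) and Pearson chi-squared tests."""
    if method == "fisher":
        return fisher_exact(table)
    if method == "chi2":
        return pearson_chi2(table)
    raise InputError(f"unknown categorical test {method!r}")


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _validate_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise InputError(f"sample {name!r} is empty")
    return arr


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise (scipy's "auto" policy).
    """
    xa = _validate_sample(x, "x")
    ya = _validate_sample(y, "y")
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mann_whitney_u", estimate=float(res.statistic))


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups."""
    if len(groups) < 2:
        raise InputError("kruskal_wallis needs >= 2 groups")
    arrs = [_validate_sample(g, f"group {i}") for i, g in enumerate(groups)]
    res = sps.kruskal(*arrs)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="kruskal_wallis")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p."""
    xa = _validate_sample(x, "x")
    ya = _validate_sample(y, "y")
    if xa.size != ya.size:
        raise InputError("spearman requires equal-length samples")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult(statistic=float(rho), p_value=float(p),
                      method="spearman", estimate=float(rho))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values, threshold: float = 0.1) -> FdrResult:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(p, p.copy(), threshold)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return FdrResult(p, q, threshold)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

#: Published multivariable model for pathologic nodal metastasis, scoring
#: preoperative clinicopathologic covariates and driver-gene mutation
#: indicators on the logit scale.  The tumor-size slope is used exactly as
#: printed (-0.035) even though the accompanying odds ratio (1.036) implies
#: the opposite sign; the discrepancy is inherited from the source model.
LN_METASTASIS_MODEL = LogisticModel(
    intercept=-3.07,
    coefficients={
        "Nodule_type": -1.28,
        "Tumor_size": -0.035,
        "Histologic_subtype": 0.69,
        "Path_STAS": -0.46,
        "Path_VPI": 0.72,
        "Path_LVI": 1.35,
        "EGFR": 0.084,
        "TP53": -0.34,
        "RBM10": -0.83,
        "STK11": 0.17,
        "ATM": 0.75,
        "HGF": 1.33,
        "KEAP1": 0.97,
        "PIK3CG": 2.66,
    },
)

_SEPARATION_BETA = 20.0  # |beta| beyond this on standardized-ish covariates


def fit_logistic(y, X, maxiter: int = 100, tol: float = 1e-8) -> LogisticModel:
    """Maximum-likelihood logistic regression with Wald inference.

    Parameters
    ----------
    y : binary vector.
    X : DataFrame (or 2-D array) of covariates; an intercept is added.

    Complete or quasi-complete separation is detected from convergence
    failures or diverging coefficients and flagged on the returned model
    rather than raised.
    """
    yv = np.asarray(y, dtype=float)
    Xdf = pd.DataFrame(X).copy()
    Xdf.columns = [str(c) for c in Xdf.columns]
    if yv.ndim != 1 or Xdf.shape[0] != yv.size:
        raise InputError("y and X are not aligned")
    if len(np.unique(yv)) < 2:
        raise InputError("outcome has a single class")
    if yv.size <= Xdf.shape[1]:
        raise InputError("need more observations than covariates")

    Xc = sm.add_constant(Xdf, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, Xc).fit(disp=0, maxiter=maxiter, tol=tol)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:  # perfect separation raises in statsmodels
            fit = sm.Logit(yv, Xc).fit_regularized(disp=0, alpha=1e-6)
            converged = False
    params = fit.params
    if not converged or np.any(np.abs(np.asarray(params)[1:]) > _SEPARATION_BETA):
        separation = True

    names = list(Xdf.columns)
    coef = {n: float(params[n]) for n in names}
    try:
        bse = fit.bse
        pvals = fit.pvalues
        ci = fit.conf_int()
        se = {n: float(bse[n]) for n in names}
        pv = {n: float(pvals[n]) for n in names}
        cints = {n: (float(ci.loc[n, 0]), float(ci.loc[n, 1])) for n in names}
    except Exception:
        se = pv = cints = None
    return LogisticModel(
        intercept=float(params["const"]),
        coefficients=coef,
        std_errors=se,
        p_values=pv,
        conf_int=cints,
        converged=converged and not separation,
        separation_flag=separation,
    )


def score_logistic(model: LogisticModel, covariates: Mapping[str, float] | pd.DataFrame):
    """Evaluate Pr(outcome) = expit(b0 + sum b_i x_i) for one or many subjects.

    Every covariate named by the model must be present; extras are ignored.
    """
    names = model.covariates
    if isinstance(covariates, pd.DataFrame):
        missing = [n for n in names if n not in covariates.columns]
        if missing:
            raise InputError(f"missing covariates: {missing}")
        z = model.intercept + covariates[names].to_numpy(dtype=float) @ np.array(
            [model.coefficients[n] for n in names])
        return expit(z)
    missing = [n for n in names if n not in covariates]
    if missing:
        raise InputError(f"missing covariates: {missing}")
    z = model.intercept + sum(model.coefficients[n] * float(covariates[n]) for n in names)
    return float(expit(z))
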