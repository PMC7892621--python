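"""Survey psychometrics: internal consistency, dimensionality, associations.

* Cronbach's alpha with a Feldt F-based (default) or bootstrap confidence
  interval; under the tau-equivalent one-factor model with standardized
  loading lambda the population value is ``k*lambda^2 / (1 + (k-1)*lambda^2)``.
* Horn's parallel analysis: the number of leading eigenvalues of the item
  correlation matrix exceeding the chosen percentile of eigenvalues from
  resampled null data of the same shape.
* Severity-association models: linear regressions of the PGSI total on a
  no-gambling indicator, on the gambling-type count and on gambling
  frequency, and a Poisson (log link) regression of type count on frequency,
  fitted by maximum likelihood via statsmodels (IRLS for the Poisson GLM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PsychometricsReport",
    "cronbach_alpha",
    "alpha_confidence_interval",
    "parallel_analysis",
    "fit_severity_associations",
    "simulate_one_factor",
    "tau_equivalent_alpha",
    "psychometrics_report",
]


def _item_matrix(items) -> np.ndarray:
    X = np.asarray(items, dtype=float)
    if X.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional (participants x items)")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 items")
    if np.isnan(X).any():
        raise ValueError("item matrix contains missing values")
    return X


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: ``(k/(k-1)) * (1 - sum var_i / var_total)``.

    Invariant to adding constants to items and to item order; 1 for k
    identical non-constant items.  Undefined (raises) when the total score
    has zero variance.
    """
    X = _item_matrix(items)
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance: alpha undefined")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def alpha_confidence_interval(
    items,
    level: float = 0.95,
    method: str = "feldt",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Confidence interval for Cronbach's alpha.

    ``feldt`` uses the classical F-distribution interval with
    ``(n-1, (n-1)(k-1))`` degrees of freedom; ``bootstrap`` resamples
    participants and takes percentile bounds.
    """
    X = _item_matrix(items)
    n, k = X.shape
    a = cronbach_alpha(X)
    if method == "feldt":
        df1, df2 = n - 1, (n - 1) * (k - 1)
        lower = 1.0 - (1.0 - a) * stats.f.ppf(0.5 + level / 2, df1, df2)
        upper = 1.0 - (1.0 - a) * stats.f.ppf(0.5 - level / 2, df1, df2)
        return float(lower), float(upper)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(n, size=n)
            try:
                draws.append(cronbach_alpha(X[idx]))
            except ValueError:  # degenerate resample (constant total)
                continue
        lo, hi = np.percentile(draws, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}; use 'feldt' or 'bootstrap'")


def tau_equivalent_alpha(k: int, loading: float) -> float:
    """Population alpha of a one-factor tau-equivalent scale."""
    return k * loading**2 / (1.0 + (k - 1) * loading**2)


def simulate_one_factor(
    n: int,
    k: int,
    loading: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Gaussian one-factor items: ``x_ij = loading * f_i + sqrt(1-loading^2) e_ij``."""
    if not 0.0 <= loading < 1.0:
        raise ValueError("loading must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, k))
    return loading * f + np.sqrt(1.0 - loading**2) * e


def parallel_analysis(
    items,
    n_resamples: int = 1000,
    percentile: float = 95.0,
    seed: Optional[int] = None,
    method: str = "normal",
) -> dict:
    """Horn's parallel analysis on the item correlation matrix.

    Retains the leading observed eigenvalues that exceed the given percentile
    of the corresponding null eigenvalues, where the null is ``n_resamples``
    datasets of the same shape drawn standard normal (``method="normal"``) or
    obtained by independently permuting each observed column
    (``method="permute"``).  Counting stops at the first non-exceeding
    eigenvalue, so the retained count is non-increasing in the percentile.
    """
    X = _item_matrix(items)
    n, k = X.shape
    if k > n:
        warnings.warn(f"more items ({k}) than observations ({n}); proceeding")
    observed = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_resamples, k))
    for i in range(n_resamples):
        if method == "normal":
            Z = rng.standard_normal((n, k))
        elif method == "permute":
            Z = np.column_stack([rng.permutation(X[:, j]) for j in range(k)])
        else:
            raise ValueError(f"unknown null method {method!r}")
        null[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresholds = np.percentile(null, percentile, axis=0)
    retained = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            retained += 1
        else:
            break
    return {
        "n_components": retained,
        "observed_eigenvalues": observed,
        "null_percentiles": thresholds,
        "null_means": null.mean(axis=0),
        "percentile": percentile,
    }


def _check_nonconstant(df: pd.DataFrame, column: str) -> None:
    if df[column].nunique() <= 1:
        raise ValueError(f"predictor column {column!r} is constant")


def fit_severity_associations(survey: pd.DataFrame) -> dict:
    """Association models between severity, frequency, and breadth of gambling.

    Expects columns ``pgsi_total``, ``gambling_frequency`` and either
    ``type_count`` or per-type indicator columns.  Fits four models:

    * OLS: PGSI total ~ no-gambling indicator (frequency == 0);
    * OLS: PGSI total ~ gambling-type count;
    * OLS: PGSI total ~ gambling frequency;
    * Poisson GLM (log link): type count ~ frequency, fitted among
      participants reporting any gambling — non-gamblers select no types by
      construction (structural zeros that a Poisson mean model should not be
      forced through).

    Returns slope coefficient, SE and two-sided Wald p per model.
    """
    df = survey.copy()
    if "type_count" not in df.columns:
        from .survey import GAMBLING_TYPES

        cols = [t for t in GAMBLING_TYPES if t in df.columns]
        if not cols:
            raise ValueError("survey table lacks 'type_count' and per-type columns")
        df["type_count"] = df[cols].sum(axis=1)
    df["no_gambling"] = (df["gambling_frequency"] == 0).astype(float)

    def slope(res, name):
        return {
            "coef": float(res.params[name]),
            "se": float(res.bse[name]),
            "p": float(res.pvalues[name]),
        }

    out = {}
    for label, predictor in (
        ("pgsi_on_no_gambling", "no_gambling"),
        ("pgsi_on_type_count", "type_count"),
        ("pgsi_on_frequency", "gambling_frequency"),
    ):
        _check_nonconstant(df, predictor)
        X = sm.add_constant(df[[predictor]].astype(float))
        # severity totals are heteroskedastic (zero floor, variance rising
        # with the mean), so the linear models use HC3 robust covariance
        res = sm.OLS(df["pgsi_total"].astype(float), X).fit(cov_type="HC3")
        out[label] = slope(res, predictor)

    gamblers = df[df["gambling_frequency"] > 0]
    _check_nonconstant(gamblers, "gambling_frequency")
    Xp = sm.add_constant(gamblers[["gambling_frequency"]].astype(float))
    pois = sm.GLM(
        gamblers["type_count"].astype(float), Xp, family=sm.families.Poisson()
    ).fit()
    out["types_on_frequency_poisson"] = slope(pois, "gambling_frequency")
    return out


@dataclass(frozen=True)
class PsychometricsReport:
    """Alpha (full and nonzero-score subsample), parallel analysis, and
    association models for one survey table."""

    alpha: float
    alpha_ci: tuple[float, float]
    alpha_nonzero: Optional[float]
    alpha_nonzero_ci: Optional[tuple[float, float]]
    n_components: int
    observed_eigenvalues: tuple[float, ...]
    null_percentiles: tuple[float, ...]
    associations: dict = field(default_factory=dict)
    n: int = 0
    n_nonzero: int = 0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def psychometrics_report(
    survey: pd.DataFrame,
    n_resamples: int = 1000,
    percentile: float = 95.0,
    seed: Optional[int] = None,
) -> PsychometricsReport:
    """Full psychometric work-up of a survey table.

    Alpha is recomputed on the subsample with PGSI total > 0 (dropping the
    all-zero floor that can inflate internal consistency); parallel analysis
    runs on the 9 item columns; association models as in
    :func:`fit_severity_associations`.
    """
    item_cols = [c for c in survey.columns if c.startswith("pgsi_item_")]
    if len(item_cols) != 9:
        raise ValueError(f"expected 9 pgsi_item_* columns, found {len(item_cols)}")
    X = survey[item_cols].to_numpy(dtype=float)
    alpha = cronbach_alpha(X)
    ci = alpha_confidence_interval(X)
    totals = X.sum(axis=1)
    nz = X[totals > 0]
    alpha_nz = ci_nz = None
    if len(nz) >= 3:
        try:
            alpha_nz = cronbach_alpha(nz)
            ci_nz = alpha_confidence_interval(nz)
        except ValueError:
            pass
    pa = parallel_analysis(X, n_resamples=n_resamples, percentile=percentile, seed=seed)
    return PsychometricsReport(
        alpha=alpha,
        alpha_ci=ci,
        alpha_nonzero=alpha_nz,
        alpha_nonzero_ci=ci_nz,
        n_components=pa["n_components"],
        observed_eigenvalues=tuple(float(x) for x in pa["observed_eigenvalues"]),
        null_percentiles=tuple(float(x) for x in pa["null_percentiles"]),
        associations=fit_severity_associations(survey),
        n=len(survey),
        n_nonzero=int((totals > 0).sum()),
    )
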