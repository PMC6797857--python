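"""Model-performance auditing: Brier score, binned calibration, median-split
incidence comparison, and a Spearman correlation matrix.

All routines take raw (uncapped) predicted probabilities; truncation of
forecasts — needed to score against tables whose entries are printed as
">0.99" — is an explicit option of :func:`brier_score`, never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = ["CalibrationResult", "MedianSplitResult", "brier_score",
           "calibration", "median_split_comparison", "correlation_matrix",
           "dose_parameter_table"]


def brier_score(predicted, events, cap: float | None = None) -> float:
    """Mean squared error of probability forecasts against binary outcomes.

    ``cap`` truncates forecasts from above before scoring (e.g. cap=0.99 to
    reproduce scoring from a table whose entries are printed as ">0.99").
    The no-skill reference is p*(1-p) for a constant forecast at the event
    rate p.
    """
    f = np.asarray(predicted, dtype=float)
    o = np.asarray(events, dtype=float)
    if f.size == 0:
        raise ValueError("empty cohort")
    if f.shape != o.shape:
        raise ValueError("predictions and outcomes differ in length")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("forecast probabilities must lie in [0, 1]")
    if not np.all(np.isin(o, (0.0, 1.0))):
        raise ValueError("outcomes must be binary")
    if cap is not None:
        f = np.minimum(f, cap)
    return float(np.mean((f - o) ** 2))


@dataclass
class CalibrationResult:
    """Equal-size-bin calibration of predicted risk against observed incidence.

    ``bin_membership`` maps each input record (original order) to its bin
    index; bins are ordered by ascending predicted risk and sized as equally
    as possible, with any remainder going to the lowest-risk bins.  The
    recalibration line is an unweighted OLS of observed incidence on mean
    predicted risk across bins: intercept 0 and slope 1 indicate perfect
    calibration.  Per-bin incidence CIs are 95% Wilson intervals.
    """

    n_bins: int
    bin_membership: np.ndarray
    bin_sizes: np.ndarray
    mean_predicted: np.ndarray
    observed_incidence: np.ndarray
    incidence_ci_low: np.ndarray
    incidence_ci_high: np.ndarray
    intercept: float
    slope: float
    r_squared: float
    intercept_pvalue: float
    slope_pvalue: float

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "bin_sizes": self.bin_sizes.tolist(),
            "mean_predicted": self.mean_predicted.tolist(),
            "observed_incidence": self.observed_incidence.tolist(),
            "incidence_ci_low": self.incidence_ci_low.tolist(),
            "incidence_ci_high": self.incidence_ci_high.tolist(),
            "intercept": self.intercept,
            "slope": self.slope,
            "r_squared": self.r_squared,
            "intercept_pvalue": self.intercept_pvalue,
            "slope_pvalue": self.slope_pvalue,
        }


def _bin_sizes(n: int, n_bins: int) -> np.ndarray:
    base, rem = divmod(n, n_bins)
    # remainder to the lowest-risk bins first
    return np.array([base + 1] * rem + [base] * (n_bins - rem))


def calibration(predicted, events, n_bins: int = 3) -> CalibrationResult:
    """Group records into equal-size bins of ascending predicted risk and
    regress observed incidence on mean predicted risk.

    Ties in predicted risk are broken by input order (stable sort), so the
    result is invariant to permutations of records with distinct predictions.
    """
    f = np.asarray(predicted, dtype=float)
    o = np.asarray(events, dtype=int)
    n = f.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} records for {n_bins} bins, got {n}")
    order = np.argsort(f, kind="stable")
    sizes = _bin_sizes(n, n_bins)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    membership = np.empty(n, dtype=int)
    mean_pred = np.empty(n_bins)
    inc = np.empty(n_bins)
    ci_lo = np.empty(n_bins)
    ci_hi = np.empty(n_bins)
    for b in range(n_bins):
        idx = order[edges[b]:edges[b + 1]]
        membership[idx] = b
        mean_pred[b] = f[idx].mean()
        k = int(o[idx].sum())
        inc[b] = k / idx.size
        ci_lo[b], ci_hi[b] = proportion_confint(k, idx.size, alpha=0.05,
                                                method="wilson")
    X = sm.add_constant(mean_pred)
    fit = sm.OLS(inc, X).fit()
    tss = float(fit.centered_tss)
    r_squared = float(1.0 - fit.ssr / tss) if tss > 0 else float("nan")
    return CalibrationResult(
        n_bins=n_bins,
        bin_membership=membership,
        bin_sizes=sizes,
        mean_predicted=mean_pred,
        observed_incidence=inc,
        incidence_ci_low=ci_lo,
        incidence_ci_high=ci_hi,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=r_squared,
        intercept_pvalue=float(fit.pvalues[0]),
        slope_pvalue=float(fit.pvalues[1]),
    )


@dataclass
class MedianSplitResult:
    """Event incidence above vs at-or-below the median dose, with Fisher p."""

    median_dose: float
    n_low: int
    n_high: int
    incidence_low: float
    incidence_high: float
    table: np.ndarray  # [[events_low, nonevents_low], [events_high, nonevents_high]]
    p_value: float

    def to_dict(self) -> dict:
        return {
            "median_dose": self.median_dose,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "incidence_low": self.incidence_low,
            "incidence_high": self.incidence_high,
            "table": self.table.tolist(),
            "p_value": self.p_value,
        }


def median_split_comparison(doses, events) -> MedianSplitResult:
    """Compare event incidence between dose groups split at the median.

    Records with dose exactly equal to the median go to the low group.  The
    p-value is the conventional two-sided Fisher exact test (sum of table
    probabilities not exceeding that of the observed table).
    """
    d = np.asarray(doses, dtype=float)
    o = np.asarray(events, dtype=int)
    if d.size < 2:
        raise ValueError("need at least 2 records for a median split")
    med = float(np.median(d))
    low = d <= med
    if low.all() or not low.any():
        raise ValueError("degenerate split: all doses on one side of the median")
    k_low, n_low = int(o[low].sum()), int(low.sum())
    k_high, n_high = int(o[~low].sum()), int((~low).sum())
    table = np.array([[k_low, n_low - k_low], [k_high, n_high - k_high]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return MedianSplitResult(
        median_dose=med,
        n_low=n_low,
        n_high=n_high,
        incidence_low=k_low / n_low,
        incidence_high=k_high / n_high,
        table=table,
        p_value=float(p),
    )


def correlation_matrix(frame: pd.DataFrame, variables=None):
    """Pairwise Spearman rank correlations (mid-rank ties) with p-values.

    Binary variables must already be encoded 0/1.  A constant variable has
    undefined rank correlation: its entries are reported as NaN, not zero.
    Returns ``(rho, p)`` as symmetric DataFrames with unit diagonal.
    """
    if variables is None:
        variables = [c for c in frame.columns
                     if pd.api.types.is_numeric_dtype(frame[c])]
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=variables, columns=variables)
    np.fill_diagonal(pval.values, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            pair = frame[[variables[i], variables[j]]].dropna()
            if len(pair) < 3:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r, p = stats.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    for v in variables:
        if frame[v].nunique(dropna=True) < 2:
            rho.loc[v, v] = np.nan
            pval.loc[v, v] = np.nan
    return rho, pval


def dose_parameter_table(dvh) -> dict:
    """Per-decile dose parameters D10%..D90%, D95% and mean dose for one DVH."""
    return dvh.dose_metrics(percents=(10, 20, 30, 40, 50, 60, 70, 80, 90, 95))
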