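"""Model/results interface for auditing the hippocampal NTCP model on a cohort.

:class:`HippocampalNTCP` wraps a cohort table together with a Lyman
parameterization and change norms; its :meth:`~HippocampalNTCP.fit` runs the
whole audit — NTCP prediction, reliable-change event scoring (when AVLT-dr
score pairs rather than an event flag are supplied), Brier scoring, binned
calibration with the recalibration regression, and the median-dose-split
incidence comparison — and returns an :class:`NTCPAuditResults` carrying the
scored cohort, the performance metrics and a ``summary()`` table.

The "fit" here estimates the recalibration line (observed incidence on
predicted risk); the dose-response parameters themselves are fixed inputs
being audited, not refitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (CalibrationResult, MedianSplitResult, brier_score,
                         calibration, correlation_matrix,
                         median_split_comparison)
from .fixtures import table2_cohort
from .lyman import GONDI_2013, LymanParameters, ntcp, predict_cohort
from .neurocog import ChangeNorms
from .cohort import SCORE_COLUMNS, read_cohort, score_events
from .simulate import SimulationConfig, generate_cohort

__all__ = ["HippocampalNTCP", "NTCPAuditResults"]


class HippocampalNTCP:
    """The Lyman probit NTCP model applied to a cohort for validation.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Must contain ``age_years`` and ``d40_eqd2`` (EQD2 Gy to 40% of the
        bilateral hippocampus), plus either a boolean ``event`` column or
        the AVLT-dr score pair ``avlt_dr_baseline``/``avlt_dr_followup``.
    params : LymanParameters
        Dose-response parameters under audit (default: the published
        hippocampal TD50 = 14.88 EQD2 Gy, m = 0.54).
    norms : ChangeNorms
        Normative test-retest regression used to score events from raw
        scores.
    """

    def __init__(self, cohort: pd.DataFrame,
                 params: LymanParameters = GONDI_2013,
                 norms: ChangeNorms = ChangeNorms()):
        if "d40_eqd2" not in cohort.columns:
            raise ValueError("cohort must have a d40_eqd2 column")
        has_event = "event" in cohort.columns and not cohort["event"].isna().all()
        has_scores = all(c in cohort.columns for c in SCORE_COLUMNS)
        if not (has_event or has_scores):
            raise ValueError(
                "cohort needs an event column or AVLT-dr baseline/followup scores"
            )
        self.cohort = cohort.reset_index(drop=True)
        self.params = params
        self.norms = norms

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "HippocampalNTCP":
        return cls(frame, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HippocampalNTCP":
        return cls(read_cohort(path), **kwargs)

    @classmethod
    def from_published_cohort(cls, events_variant: str = "as_printed",
                              **kwargs) -> "HippocampalNTCP":
        """The 29-patient printed validation cohort."""
        return cls(table2_cohort(events_variant), **kwargs)

    @classmethod
    def from_simulation(cls, config: SimulationConfig = SimulationConfig(),
                        **kwargs) -> "HippocampalNTCP":
        """A synthetic cohort drawn under the generator's study conditions."""
        sim = generate_cohort(config)
        model = cls(sim.records, **kwargs)
        model.simulated = sim
        return model

    # -- prediction ------------------------------------------------------

    def predict(self, d40):
        """Raw NTCP at one dose or an array of doses (EQD2 Gy)."""
        if np.isscalar(d40):
            return ntcp(float(d40), self.params).ntcp
        return np.array([ntcp(float(d), self.params).ntcp for d in np.asarray(d40)])

    # -- the audit -------------------------------------------------------

    def fit(self, n_bins: int = 3, cap: float | None = None) -> "NTCPAuditResults":
        """Score the cohort and estimate the calibration of the model on it."""
        frame = self.cohort.copy()
        predictions, errors = predict_cohort(frame["d40_eqd2"], self.params)
        frame["t_value"] = [p.t_value if p else np.nan for p in predictions]
        frame["ntcp"] = [p.ntcp if p else np.nan for p in predictions]
        frame["ntcp_display"] = [p.display if p else "" for p in predictions]
        if "event" not in frame.columns or frame["event"].isna().all():
            frame = score_events(frame, self.norms)
        complete = frame.dropna(subset=["ntcp", "event"])
        pred = complete["ntcp"].to_numpy(dtype=float)
        events = complete["event"].to_numpy(dtype=bool)
        result = NTCPAuditResults(
            model=self,
            frame=frame,
            prediction_errors=errors,
            brier=brier_score(pred, events),
            brier_capped=(brier_score(pred, events, cap=cap)
                          if cap is not None else None),
            cap=cap,
            calibration=calibration(pred, events, n_bins=n_bins),
            median_split=median_split_comparison(
                complete["d40_eqd2"].to_numpy(dtype=float), events),
        )
        return result


class NTCPAuditResults:
    """Results of one cohort audit; see :meth:`summary`.

    Attributes
    ----------
    frame : pandas.DataFrame
        The cohort with appended ``t_value``, ``ntcp``, ``ntcp_display`` and
        (when scored from raw AVLT-dr pairs) ``expected_change``, ``z``,
        ``event`` columns.
    brier, brier_capped : float
        Mean squared forecast error, on raw probabilities and (optionally)
        with forecasts truncated at ``cap``.
    calibration : CalibrationResult
    median_split : MedianSplitResult
    """

    def __init__(self, model: HippocampalNTCP, frame: pd.DataFrame,
                 prediction_errors, brier: float, brier_capped,
                 cap, calibration: CalibrationResult,
                 median_split: MedianSplitResult):
        self.model = model
        self.frame = frame
        self.prediction_errors = prediction_errors
        self.brier = brier
        self.brier_capped = brier_capped
        self.cap = cap
        self.calibration = calibration
        self.median_split = median_split

    # -- derived quantities ---------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].fillna(False).astype(bool).sum())

    @property
    def n_high_risk(self) -> int:
        """Patients whose raw predicted NTCP exceeds 0.99."""
        return int((self.frame["ntcp"] > 0.99).sum())

    @property
    def event_rate(self) -> float:
        return self.n_events / self.n_patients

    @property
    def brier_no_skill(self) -> float:
        """Brier score of the constant forecast at the event rate."""
        p = self.event_rate
        return p * (1.0 - p)

    def correlations(self, variables=None):
        """Spearman correlation matrix over cohort columns (rho, p)."""
        frame = self.frame.copy()
        frame["event"] = frame["event"].astype(float)
        if variables is None:
            skip = {"t_value", "ntcp"}
            variables = [c for c in frame.columns
                         if pd.api.types.is_numeric_dtype(frame[c])
                         and c not in skip]
        return correlation_matrix(frame, variables)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Human-readable audit summary in a statsmodels-like layout."""
        p = self.model.params
        cal = self.calibration
        ms = self.median_split
        lines = [
            "                 Hippocampal NTCP model audit",
            "=" * 64,
            f"No. patients:        {self.n_patients:>6}     "
            f"Events observed:      {self.n_events:>5}",
            f"TD50 (EQD2 Gy):      {p.td50:>6.2f}     "
            f"Slope m:              {p.m:>5.2f}",
            f"Predicted NTCP>0.99: {self.n_high_risk:>6}     "
            f"Event rate:           {self.event_rate:>5.1%}",
            "-" * 64,
            f"Brier score (raw forecasts):       {self.brier:8.4f}",
        ]
        if self.brier_capped is not None:
            lines.append(
                f"Brier score (forecasts capped {self.cap}): {self.brier_capped:8.4f}"
            )
        lines += [
            f"Brier score, no-skill reference:   {self.brier_no_skill:8.4f}",
            "-" * 64,
            f"Calibration ({cal.n_bins} equal-size bins of ascending predicted risk)",
            "  bin   n    mean predicted   observed incidence   95% CI",
        ]
        for b in range(cal.n_bins):
            lines.append(
                f"  {b + 1:>3} {cal.bin_sizes[b]:>4}   {cal.mean_predicted[b]:>11.3f}"
                f"      {cal.observed_incidence[b]:>10.3f}"
                f"        [{cal.incidence_ci_low[b]:.3f}, {cal.incidence_ci_high[b]:.3f}]"
            )
        lines += [
            f"  recalibration: intercept {cal.intercept:+.3f} (p={cal.intercept_pvalue:.2g}), "
            f"slope {cal.slope:.3f} (p={cal.slope_pvalue:.2g}), r^2 {cal.r_squared:.3f}",
            "-" * 64,
            f"Median D40% split at {ms.median_dose:.1f} EQD2 Gy: "
            f"incidence {ms.incidence_low:.1%} (n={ms.n_low}) vs "
            f"{ms.incidence_high:.1%} (n={ms.n_high}), Fisher p = {ms.p_value:.2f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Calibration plot: per-bin observed incidence (Wilson 95% error
        bars) against mean predicted risk, with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        cal = self.calibration
        yerr = np.vstack([
            cal.observed_incidence - cal.incidence_ci_low,
            cal.incidence_ci_high - cal.observed_incidence,
        ])
        ax.errorbar(cal.mean_predicted, cal.observed_incidence, yerr=yerr,
                    fmt="o", capsize=4, label="bins")
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
        xs = np.linspace(0, 1, 50)
        ax.plot(xs, cal.intercept + cal.slope * xs, "C1-", lw=1,
                label=f"recalibration (slope {cal.slope:.2f})")
        ax.set_xlabel("Predicted NTCP")
        ax.set_ylabel("Observed incidence")
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
        ax.legend(loc="upper left", fontsize=8)
        return ax

    def to_report(self) -> dict:
        """JSON-serializable report of all audit quantities (raw precision)."""
        return {
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "n_high_risk": self.n_high_risk,
            "event_rate": self.event_rate,
            "brier": self.brier,
            "brier_capped": self.brier_capped,
            "cap": self.cap,
            "brier_no_skill": self.brier_no_skill,
            "calibration": self.calibration.to_dict(),
            "median_split": self.median_split.to_dict(),
            "parameters": {"td50": self.model.params.td50, "m": self.model.params.m},
        }
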