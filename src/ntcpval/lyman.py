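"""The Lyman probit NTCP model for hippocampal dose and memory impairment.

NTCP(D) = Phi(t) with t = (D - TD50) / (m * TD50), where D is the EQD2 dose
to 40% of the bilateral hippocampus (D40%), TD50 the dose with 50%
complication probability and m the dimensionless slope.  The shipped default
parameters (TD50 = 14.88 EQD2 Gy, m = 0.54) are the published hippocampal
values for memory impairment at 18 months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["LymanParameters", "NtcpPrediction", "GONDI_2013", "ntcp",
           "inverse_ntcp", "predict_cohort", "format_probability"]


@dataclass(frozen=True)
class LymanParameters:
    """Parameters (TD50, m) of the probit dose-response."""

    td50: float = 14.88
    m: float = 0.54

    def __post_init__(self) -> None:
        if not (self.td50 > 0):
            raise ValueError(f"td50 must be positive, got {self.td50}")
        if not (self.m > 0):
            raise ValueError(f"m must be positive, got {self.m}")


#: Published hippocampal parameterization (memory impairment at 18 months).
GONDI_2013 = LymanParameters(td50=14.88, m=0.54)


def format_probability(p: float) -> str:
    """Two-decimal display string; probabilities above 0.99 render as '>0.99'.

    Rounding is round-half-even on the shortest decimal representation of the
    double, which is deterministic across platforms.
    """
    if p > 0.99:
        return ">0.99"
    return f"{p:.2f}"


@dataclass(frozen=True)
class NtcpPrediction:
    """One NTCP evaluation: dose in, probit deviate and probability out.

    ``ntcp`` is the raw (uncapped) probability; ``display`` applies the
    2-decimal / '>0.99' presentation rule.  Raw values are never truncated
    internally — capping is a scoring-time option, not a model property.
    """

    d40: float
    t_value: float
    ntcp: float
    display: str


def ntcp(d40: float, params: LymanParameters = GONDI_2013) -> NtcpPrediction:
    """Probability of memory impairment at bilateral-hippocampus D40% (EQD2 Gy).

    Uses the error-function form of the standard normal CDF
    (``scipy.special.ndtr``), accurate to well below 1e-12 absolute.
    """
    if d40 < 0:
        raise ValueError(f"dose must be non-negative, got {d40}")
    t = (d40 - params.td50) / (params.m * params.td50)
    p = float(ndtr(t))
    return NtcpPrediction(d40=float(d40), t_value=float(t), ntcp=p,
                          display=format_probability(p))


def inverse_ntcp(p: float, params: LymanParameters = GONDI_2013) -> float:
    """Dose at which the model predicts complication probability ``p``."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"probability must be in (0, 1), got {p}")
    return float(params.td50 * (1.0 + params.m * ndtri(p)))


def predict_cohort(d40_values, params: LymanParameters = GONDI_2013):
    """Vector NTCP prediction over a cohort's D40% values.

    Returns ``(predictions, errors)``: ``predictions[i]`` is an
    :class:`NtcpPrediction` or ``None`` where the dose was missing/invalid,
    and ``errors`` lists ``(index, message)`` pairs for those records.  A
    partially failing cohort still yields every valid prediction.
    """
    predictions: list[NtcpPrediction | None] = []
    errors: list[tuple[int, str]] = []
    for i, d in enumerate(d40_values):
        try:
            d = float(d)
            if np.isnan(d):
                raise ValueError("missing D40% value")
            predictions.append(ntcp(d, params))
        except (TypeError, ValueError) as exc:
            predictions.append(None)
            errors.append((i, str(exc)))
    return predictions, errors
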