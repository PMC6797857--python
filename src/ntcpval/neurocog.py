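"""Reliable-change scoring of AVLT delayed-recall test-retest performance.

The AVLT delayed recall (AVLT-dr) asks a subject to recall a 15-word list
after 20 minutes; scores are integers 0-15.  Because practice effects and
ageing shift retest scores even without any insult, an observed change is
judged against a normative regression-based expectation

    E = intercept + age_slope * (age - age_center)

and standardized with the normative residual SD:

    Z = (O - E) / residual_sd

where O is the observed change (retest minus baseline).  A neurocognitive
event is declared when Z < -1.5 (strict).  The default coefficients
(1.025, -0.035 per year, centred at 62.5 years, residual SD 2.362) are the
published healthy-ageing test-retest norms for this test condition.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ChangeNorms", "AssessmentPair", "expected_change", "z_score",
           "is_event", "score_assessment"]


@dataclass(frozen=True)
class ChangeNorms:
    """Normative test-retest change regression and event threshold."""

    intercept: float = 1.025       # expected change at the centering age, points
    age_slope: float = -0.035      # points per year
    age_center: float = 62.5       # years
    residual_sd: float = 2.362     # points
    z_threshold: float = -1.5

    def __post_init__(self) -> None:
        if not (self.residual_sd > 0):
            raise ValueError(f"residual_sd must be positive, got {self.residual_sd}")


@dataclass(frozen=True)
class AssessmentPair:
    """A baseline/retest AVLT-dr pair for one subject."""

    age_years: float
    baseline_score: int
    retest_score: int

    def __post_init__(self) -> None:
        for name in ("baseline_score", "retest_score"):
            s = getattr(self, name)
            if s != int(s):
                raise ValueError(f"{name} must be an integer word count, got {s}")
            if not (0 <= s <= 15):
                raise ValueError(f"{name} must be within [0, 15], got {s}")

    @property
    def observed_change(self) -> int:
        return int(self.retest_score) - int(self.baseline_score)


def expected_change(age_years: float, norms: ChangeNorms = ChangeNorms()) -> float:
    """Normative expected test-retest change at a given age (adult norms only)."""
    if age_years < 18:
        raise ValueError(f"adult norms require age >= 18, got {age_years}")
    return norms.intercept + norms.age_slope * (age_years - norms.age_center)


def z_score(observed_change: float, age_years: float,
            norms: ChangeNorms = ChangeNorms()) -> float:
    """Reliable-change Z of an observed change score against the age norm."""
    return (observed_change - expected_change(age_years, norms)) / norms.residual_sd


def is_event(z: float, norms: ChangeNorms = ChangeNorms()) -> bool:
    """True iff Z falls strictly below the event threshold (default -1.5)."""
    return z < norms.z_threshold


def score_assessment(pair: AssessmentPair, norms: ChangeNorms = ChangeNorms()):
    """Score one assessment pair: returns (expected_change, z, event)."""
    e = expected_change(pair.age_years, norms)
    z = (pair.observed_change - e) / norms.residual_sd
    return e, z, is_event(z, norms)
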