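"""Synthetic cohorts of partial-brain-irradiated patients.

The generator emulates the statistical structure the validation pipeline
assumes so every stage is testable without patient data:

* ages ~ N(43, 10^2) years, clipped to [18, 80] (the study population's
  median age is 43);
* left/right hippocampal cumulative DVHs with sigmoidal (logistic) shape on
  a 0.1 Gy grid up to 1.15x the 28 x 1.8 Gy = 50.4 Gy prescription, with
  per-structure midpoint ~ U(5, 52) Gy, steepness ~ U(1, 8) Gy and absolute
  volume ~ U(2, 5) cc per side;
* events drawn Bernoulli(NTCP(D40%)) under a configurable true
  dose-response (defaults = the published parameters), with bilateral
  compositing, EQD2 conversion and D40% extraction routed through the same
  dvh code the analysis uses;
* AVLT-dr score pairs constructed so the reliable-change Z reproduces the
  drawn event label before integer rounding: events get
  Z = -1.5 - |N(0, 0.7)|, non-events Z ~ N(0,1) truncated to >= -1.5, and
  observed change = round(E(age) + 2.362 Z) clipped so scores stay in
  [0, 15]; baselines ~ round(N(9, 2.5)) clipped to [2, 15].

One pseudo-random stream per cohort, seeded once; draws are ordered per
patient, so a cohort is byte-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import DoseVolumeHistogram, FractionationScheme, combine_bilateral, to_eqd2
from .lyman import GONDI_2013, LymanParameters, ntcp
from .neurocog import ChangeNorms, expected_change

__all__ = ["SimulationConfig", "SimulatedCohort", "generate_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort; defaults mirror the trial arm."""

    n_patients: int = 29
    seed: int = 0
    age_mean: float = 43.0
    age_sd: float = 10.0
    age_min: float = 18.0
    age_max: float = 80.0
    n_fractions: int = 28
    dose_per_fraction: float = 1.8
    alpha_beta: float = 2.0
    dvh_midpoint_range: tuple[float, float] = (5.0, 52.0)   # Gy
    dvh_steepness_range: tuple[float, float] = (1.0, 8.0)   # Gy
    volume_range_cc: tuple[float, float] = (2.0, 5.0)       # per side
    true_dose_response: LymanParameters = GONDI_2013
    event_z_sd: float = 0.7
    baseline_mean: float = 9.0
    baseline_sd: float = 2.5
    baseline_range: tuple[int, int] = (2, 15)
    dose_grid_step: float = 0.1
    dose_max_factor: float = 1.15
    norms: ChangeNorms = field(default_factory=ChangeNorms)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("age_sd", "event_z_sd", "baseline_sd", "dose_grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def scheme(self) -> FractionationScheme:
        return FractionationScheme(self.n_fractions, self.dose_per_fraction,
                                   self.alpha_beta)

    @property
    def prescription_gy(self) -> float:
        return self.n_fractions * self.dose_per_fraction


@dataclass
class SimulatedCohort:
    """Records plus the per-patient DVHs they were derived from."""

    records: pd.DataFrame
    dvhs: dict[str, dict[str, DoseVolumeHistogram]]  # patient_id -> structure -> DVH
    config: SimulationConfig


def _logistic_dvh(grid: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    """Truncated-logistic cumulative curve, renormalised so f(0) = 1."""
    s = 1.0 / (1.0 + np.exp((grid - midpoint) / steepness))
    return s / s[0]


def generate_cohort(config: SimulationConfig = SimulationConfig()) -> SimulatedCohort:
    """Draw a cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    grid = np.arange(
        0.0,
        config.dose_max_factor * config.prescription_gy + config.dose_grid_step / 2,
        config.dose_grid_step,
    )
    rows = []
    dvhs: dict[str, dict[str, DoseVolumeHistogram]] = {}
    lobes = ("frontal", "temporal", "parietal", "multifocal", "other")
    for i in range(config.n_patients):
        pid = f"S{i + 1:04d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            config.age_min, config.age_max))
        per_side = {}
        for side in ("left", "right"):
            mid = rng.uniform(*config.dvh_midpoint_range)
            steep = rng.uniform(*config.dvh_steepness_range)
            vol = rng.uniform(*config.volume_range_cc)
            per_side[side] = DoseVolumeHistogram(
                f"hippocampus_{side}", grid, _logistic_dvh(grid, mid, steep), vol
            )
        bilateral = combine_bilateral(per_side["left"], per_side["right"],
                                      structure="hippocampus_bilateral")
        bilateral_eqd2 = to_eqd2(bilateral, config.scheme)
        d40 = bilateral_eqd2.dose_at_volume(40.0)
        p_event = ntcp(d40, config.true_dose_response).ntcp
        event = bool(rng.uniform() < p_event)
        if event:
            z = -1.5 - abs(rng.normal(0.0, config.event_z_sd))
        else:
            z = float(stats.truncnorm.rvs(-1.5, np.inf, random_state=rng))
        e_change = expected_change(age, config.norms)
        baseline = int(np.clip(round(rng.normal(config.baseline_mean,
                                                config.baseline_sd)),
                               *config.baseline_range))
        change = round(e_change + config.norms.residual_sd * z)
        followup = int(np.clip(baseline + change, 0, 15))
        # exchangeable-noise covariates (no real anatomical meaning)
        laterality = rng.choice(("left", "right", "both"), p=(0.55, 0.35, 0.10))
        rows.append({
            "patient_id": pid,
            "age_years": round(age, 1),
            "d40_eqd2": d40,
            "avlt_dr_baseline": baseline,
            "avlt_dr_followup": followup,
            "event": event,
            "p_event_true": p_event,
            "z_true": z,
            "mean_dose_eqd2": bilateral_eqd2.mean_dose(),
            "volume_cc": bilateral.volume_cc,
            "laterality": laterality,
            "lobe": lobes[int(rng.integers(len(lobes)))],
            "aed_count": int(rng.integers(0, 3)),
        })
        dvhs[pid] = {
            "left": per_side["left"],
            "right": per_side["right"],
            "bilateral_eqd2": bilateral_eqd2,
        }
    return SimulatedCohort(records=pd.DataFrame(rows), dvhs=dvhs, config=config)
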