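"""Cumulative dose-volume histograms: representation, algebra, and dose metrics.

A cumulative DVH gives, for each dose level D, the fraction of a structure's
volume receiving *at least* D.  All DVHs here use fraction-of-structure units
(volume_fraction in [0, 1]); absolute volumes in cc are carried alongside so
that bilateral structures can be composited by volume weighting.

Dose can be on the ``physical`` scale (as planned/delivered) or on the
``eqd2`` scale (equivalent dose in 2 Gy fractions under the linear-quadratic
model).  :func:`to_eqd2` converts bin-by-bin with the per-bin dose per
fraction d = D / n_fractions:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

with alpha/beta = 2 Gy by default (late CNS effects).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DVHError",
    "ScaleError",
    "DoseVolumeHistogram",
    "FractionationScheme",
    "combine_bilateral",
    "to_eqd2",
    "read_dvh_csv",
    "write_dvh_csv",
]

PHYSICAL = "physical"
EQD2 = "eqd2"


class DVHError(ValueError):
    """Invalid DVH data."""


class ScaleError(DVHError):
    """Operation applied on the wrong dose scale (physical vs EQD2)."""


@dataclass(frozen=True)
class FractionationScheme:
    """A fractionation prescription used for EQD2 conversion.

    Parameters
    ----------
    n_fractions : int
        Number of delivered fractions (>= 1).
    dose_per_fraction : float
        Prescribed dose per fraction in Gy.  Informational only: the EQD2
        conversion uses the per-bin dose per fraction D / n_fractions, not
        the prescription.
    alpha_beta : float
        Linear-quadratic alpha/beta ratio in Gy; default 2 Gy (late CNS).
    """

    n_fractions: int
    dose_per_fraction: float = 1.8
    alpha_beta: float = 2.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise DVHError(f"n_fractions must be >= 1, got {self.n_fractions}")
        if self.alpha_beta <= 0:
            raise DVHError(f"alpha_beta must be positive, got {self.alpha_beta}")


@dataclass
class DoseVolumeHistogram:
    """Cumulative dose->volume-fraction curve for a single structure.

    Invariants (validated on construction): ``dose_gy`` starts at 0 and is
    strictly increasing; ``volume_fraction`` starts at 1.0, lies in [0, 1]
    and is non-increasing; ``volume_cc`` is positive.
    """

    structure: str
    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    volume_cc: float
    dose_scale: str = PHYSICAL

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        d, v = self.dose_gy, self.volume_fraction
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size < 1:
            raise DVHError(
                f"{self.structure}: dose and volume arrays must be 1-D of equal length"
            )
        if d[0] != 0.0:
            raise DVHError(f"{self.structure}: dose grid must start at 0, got {d[0]}")
        diffs = np.diff(d)
        if np.any(diffs == 0):
            raise DVHError(f"{self.structure}: duplicate dose grid values")
        if np.any(diffs < 0):
            raise DVHError(f"{self.structure}: dose grid must be strictly increasing")
        if abs(v[0] - 1.0) > 1e-12:
            raise DVHError(f"{self.structure}: volume_fraction[0] must be 1.0, got {v[0]}")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise DVHError(f"{self.structure}: volume fractions outside [0, 1]")
        if np.any(np.diff(v) > 1e-12):
            raise DVHError(f"{self.structure}: volume_fraction must be non-increasing")
        if not (self.volume_cc > 0):
            raise DVHError(f"{self.structure}: volume_cc must be positive")
        if self.dose_scale not in (PHYSICAL, EQD2):
            raise DVHError(f"unknown dose scale {self.dose_scale!r}")

    # -- queries ---------------------------------------------------------

    def fraction_at_dose(self, dose):
        """Cumulative volume fraction receiving >= ``dose`` (linear interp, 0 beyond grid)."""
        return np.interp(dose, self.dose_gy, self.volume_fraction, left=1.0, right=0.0)

    def dose_at_volume(self, x_percent: float) -> float:
        """Dose received by ``x_percent`` % of the structure volume (Dx%).

        Linear interpolation between the bracketing grid points; if the
        target fraction lies below the curve's final value, the last grid
        dose is returned (no extrapolation beyond delivered dose).
        """
        if not (0.0 < x_percent < 100.0):
            raise DVHError(f"x_percent must be in (0, 100), got {x_percent}")
        f = x_percent / 100.0
        v, d = self.volume_fraction, self.dose_gy
        if f >= v[0]:
            return float(d[0])
        if f < v[-1]:
            return float(d[-1])
        # first index where v[i] <= f (v is non-increasing)
        i = int(np.searchsorted(-v, -f, side="left"))
        if v[i] == f:
            return float(d[i])
        lo, hi = i - 1, i  # v[lo] > f > v[hi]
        w = (v[lo] - f) / (v[lo] - v[hi])
        return float(d[lo] + w * (d[hi] - d[lo]))

    def mean_dose(self) -> float:
        """Mass-weighted mean dose from the differential of the cumulative curve.

        Each bin's differential mass sits at the bin midpoint; any residual
        mass beyond the last grid point is assigned the last grid dose.
        """
        d, v = self.dose_gy, self.volume_fraction
        masses = -np.diff(v)
        mids = 0.5 * (d[:-1] + d[1:])
        return float(np.sum(masses * mids) + v[-1] * d[-1])

    def dose_metrics(self, percents=(10, 20, 30, 40, 50, 60, 70, 80, 90, 95)) -> dict:
        """Dx% for the requested percentages plus the mean dose."""
        out = {f"D{p:g}%": self.dose_at_volume(p) for p in percents}
        out["mean"] = self.mean_dose()
        return out


def combine_bilateral(
    left: DoseVolumeHistogram,
    right: DoseVolumeHistogram,
    structure: str | None = None,
) -> DoseVolumeHistogram:
    """Volume-weighted composite DVH of two structures on the union dose grid.

    At each dose D the composite fraction is
    (V_L f_L(D) + V_R f_R(D)) / (V_L + V_R), with each cumulative curve
    linearly interpolated between its grid points and 0 beyond the last.
    """
    if left.dose_scale != right.dose_scale:
        raise ScaleError(
            f"dose scale mismatch: {left.dose_scale} vs {right.dose_scale}"
        )
    grid = np.union1d(left.dose_gy, right.dose_gy)
    # a curve ending above zero has an atom of volume at its last dose; add a
    # breakpoint just past it so the union-grid interpolation keeps the jump
    eps = 1e-9 * max(float(grid[-1]), 1.0)
    extra = [dvh.dose_gy[-1] + eps for dvh in (left, right)
             if dvh.volume_fraction[-1] > 0 and dvh.dose_gy[-1] < grid[-1]]
    if extra:
        grid = np.union1d(grid, extra)
    vl, vr = left.volume_cc, right.volume_cc
    frac = (vl * left.fraction_at_dose(grid) + vr * right.fraction_at_dose(grid)) / (vl + vr)
    if structure is None:
        structure = f"{left.structure}+{right.structure}"
    return DoseVolumeHistogram(structure, grid, frac, vl + vr, left.dose_scale)


def to_eqd2(dvh: DoseVolumeHistogram, scheme: FractionationScheme) -> DoseVolumeHistogram:
    """Convert a physical-dose DVH to EQD2 bin-by-bin.

    Each bin dose D is mapped to D (D/n + a/b) / (2 + a/b) where n is the
    number of fractions; volume fractions are unchanged.  The map is strictly
    increasing in D for a/b > 0, so the grid stays valid.
    """
    if dvh.dose_scale != PHYSICAL:
        raise ScaleError(f"to_eqd2 requires physical dose, got {dvh.dose_scale}")
    d = dvh.dose_gy
    ab = scheme.alpha_beta
    eqd2 = d * (d / scheme.n_fractions + ab) / (2.0 + ab)
    return replace(dvh, dose_gy=eqd2, volume_fraction=dvh.volume_fraction.copy(),
                   dose_scale=EQD2)


# -- CSV interchange -----------------------------------------------------
#
# Dialect: one file per plan, header `structure,dose_gy,volume_fraction,volume_cc`
# with dose ascending per structure and volume_cc constant per structure.

def read_dvh_csv(path, dose_scale: str = PHYSICAL,
                 volume_cc: float | None = None) -> dict[str, DoseVolumeHistogram]:
    """Read per-structure cumulative DVHs from a CSV file.

    ``volume_cc`` overrides/supplies absolute volumes when the file lacks a
    ``volume_cc`` column (applied to every structure).
    """
    rows: dict[str, list[tuple[float, float, float | None]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"structure", "dose_gy", "volume_fraction"} <= set(
            reader.fieldnames
        ):
            raise DVHError(
                f"{path}: header must contain structure,dose_gy,volume_fraction"
            )
        has_vol = "volume_cc" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            try:
                dose = float(row["dose_gy"])
                frac = float(row["volume_fraction"])
                vol = float(row["volume_cc"]) if has_vol and row["volume_cc"] else None
            except ValueError as exc:
                raise DVHError(f"{path}: malformed number at line {lineno}: {exc}") from exc
            rows.setdefault(row["structure"], []).append((dose, frac, vol))
    out = {}
    for name, triples in rows.items():
        doses = np.array([t[0] for t in triples])
        fracs = np.array([t[1] for t in triples])
        vols = {t[2] for t in triples if t[2] is not None}
        if len(vols) > 1:
            raise DVHError(f"{path}: volume_cc not constant for structure {name!r}")
        vol = vols.pop() if vols else volume_cc
        if vol is None:
            raise DVHError(
                f"{path}: no volume_cc for structure {name!r} and no override given"
            )
        # absolute-volume DVHs are normalised on read
        if fracs[0] > 1.0 + 1e-12:
            fracs = fracs / fracs[0]
        out[name] = DoseVolumeHistogram(name, doses, fracs, vol, dose_scale)
    return out


def write_dvh_csv(path, dvhs) -> None:
    """Write DVHs (mapping or iterable) in the same CSV dialect read_dvh_csv reads."""
    if isinstance(dvhs, dict):
        dvhs = dvhs.values()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure", "dose_gy", "volume_fraction", "volume_cc"])
        for dvh in dvhs:
            for d, v in zip(dvh.dose_gy, dvh.volume_fraction):
                writer.writerow([dvh.structure, repr(float(d)), repr(float(v)),
                                 repr(float(dvh.volume_cc))])
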