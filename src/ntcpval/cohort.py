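"""Cohort table reading/validation and the end-to-end audit pipeline.

Cohort CSV dialect::

    patient_id,age_years,d40_eqd2,avlt_dr_baseline,avlt_dr_followup,event[,covariates...]

``event`` accepts Yes/No/1/0/true/false (case-insensitive); empty cells are
missing values; unknown columns are preserved as covariates.  Validation
errors name the offending row and column.
"""

from __future__ import annotations

import hashlib
import os
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np
import pandas as pd

from .dvh import DVHError, FractionationScheme, combine_bilateral, read_dvh_csv, to_eqd2
from .lyman import GONDI_2013, LymanParameters, predict_cohort
from .neurocog import ChangeNorms, expected_change, is_event
from .evaluation import brier_score, calibration, median_split_comparison

__all__ = ["CohortValidationError", "read_cohort", "write_cohort",
           "score_events", "run_pipeline"]

_TRUE = {"yes", "y", "1", "true"}
_FALSE = {"no", "n", "0", "false"}

SCORE_COLUMNS = ("avlt_dr_baseline", "avlt_dr_followup")


class CohortValidationError(ValueError):
    """Cohort file failed validation; message cites row and column."""


def _parse_event(value, row: int):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip().lower()
    if text == "" or text == "nan":
        return np.nan
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CohortValidationError(
        f"row {row}, column event: unrecognised value {value!r}"
    )


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Returns a DataFrame with typed columns; ``event`` becomes a nullable
    boolean, scores nullable integers.  Row numbers in error messages count
    the header as line 1, matching what an editor shows.
    """
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if "patient_id" not in frame.columns or "age_years" not in frame.columns:
        missing = {"patient_id", "age_years"} - set(frame.columns)
        raise CohortValidationError(f"{path}: missing required columns {sorted(missing)}")
    dup = frame["patient_id"][frame["patient_id"].duplicated()]
    if not dup.empty:
        raise CohortValidationError(
            f"{path}: duplicate patient_id {dup.iloc[0]!r} at row {dup.index[0] + 2}"
        )
    out = frame.copy()
    for col in ("age_years", "d40_eqd2"):
        if col not in out.columns:
            continue
        parsed = []
        for idx, raw in out[col].items():
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(raw))
            except ValueError:
                raise CohortValidationError(
                    f"{path}: row {idx + 2}, column {col}: malformed number {raw!r}"
                ) from None
        out[col] = parsed
    for col in SCORE_COLUMNS:
        if col not in out.columns:
            continue
        parsed = []
        for idx, raw in out[col].items():
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                parsed.append(pd.NA)
                continue
            try:
                value = float(raw)
            except ValueError:
                raise CohortValidationError(
                    f"{path}: row {idx + 2}, column {col}: malformed number {raw!r}"
                ) from None
            if value != int(value):
                raise CohortValidationError(
                    f"{path}: row {idx + 2}, column {col}: score must be an integer "
                    f"word count, got {raw!r}"
                )
            if not (0 <= value <= 15):
                raise CohortValidationError(
                    f"{path}: row {idx + 2}, column {col}: score {raw!r} outside [0, 15]"
                )
            parsed.append(int(value))
        out[col] = pd.array(parsed, dtype="Int64")
    if "event" in out.columns:
        out["event"] = pd.array(
            [_parse_event(v, i + 2) for i, v in out["event"].items()],
            dtype="boolean",
        )
    # any remaining (covariate) columns: try numeric, else leave as text
    handled = {"patient_id", "age_years", "d40_eqd2", "event", *SCORE_COLUMNS}
    for col in out.columns:
        if col not in handled:
            try:
                out[col] = pd.to_numeric(out[col])
            except (ValueError, TypeError):
                pass
    return out


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort table; events serialize as Yes/No, missing as empty."""
    out = frame.copy()
    if "event" in out.columns:
        out["event"] = out["event"].map(
            lambda v: "" if pd.isna(v) else ("Yes" if v else "No")
        )
    out.to_csv(path, index=False)


def score_events(frame: pd.DataFrame, norms: ChangeNorms = ChangeNorms()) -> pd.DataFrame:
    """Append expected_change, z and event columns from AVLT-dr score pairs."""
    for col in SCORE_COLUMNS:
        if col not in frame.columns:
            raise CohortValidationError(
                f"event scoring needs columns {SCORE_COLUMNS}; missing {col!r}"
            )
    out = frame.copy()
    expected = np.array([expected_change(a, norms) for a in out["age_years"]])
    change = (out["avlt_dr_followup"].astype(float)
              - out["avlt_dr_baseline"].astype(float)).to_numpy()
    z = (change - expected) / norms.residual_sd
    out["expected_change"] = expected
    out["z"] = z
    out["event"] = pd.array([is_event(v, norms) for v in z], dtype="boolean")
    return out


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _tool_version() -> str:
    try:
        return _pkg_version("ntcpval")
    except PackageNotFoundError:
        return "unknown"


def compute_d40_from_dvhs(frame: pd.DataFrame, dvh_dir,
                          scheme: FractionationScheme,
                          tolerance_gy: float = 0.1):
    """Fill/check the d40_eqd2 column from per-patient DVH CSV files.

    Each patient's file ``<patient_id>.csv`` holds either left+right
    structures (composited by volume) or a single pre-composited structure,
    on the physical dose scale.  Returns (frame, warnings).
    """
    warnings: list[str] = []
    d40s = []
    for _, row in frame.iterrows():
        pid = row["patient_id"]
        path = os.path.join(dvh_dir, f"{pid}.csv")
        structures = read_dvh_csv(path)
        if len(structures) == 1:
            (dvh,) = structures.values()
        else:
            sides = sorted(structures)
            if len(structures) != 2:
                raise DVHError(
                    f"{path}: expected 1 or 2 structures, found {sorted(structures)}"
                )
            dvh = combine_bilateral(structures[sides[0]], structures[sides[1]],
                                    structure="bilateral")
        d40 = to_eqd2(dvh, scheme).dose_at_volume(40.0)
        existing = row.get("d40_eqd2", np.nan)
        if not pd.isna(existing) and abs(float(existing) - d40) > tolerance_gy:
            warnings.append(
                f"{pid}: d40_eqd2 column {existing:.2f} Gy disagrees with DVH-derived "
                f"{d40:.2f} Gy by more than {tolerance_gy} Gy"
            )
        d40s.append(d40)
    out = frame.copy()
    out["d40_eqd2"] = d40s
    return out, warnings


def run_pipeline(cohort_path, dvh_dir=None,
                 params: LymanParameters = GONDI_2013,
                 norms: ChangeNorms = ChangeNorms(),
                 scheme: FractionationScheme | None = None,
                 n_bins: int = 3, cap: float | None = None) -> dict:
    """Run the full audit: (DVH -> EQD2 -> D40%) -> NTCP -> events -> evaluation.

    Event scoring from AVLT-dr pairs is skipped when an event column is
    supplied.  The report carries stage provenance, parameter values, tool
    version and input hashes; per-record prediction failures are listed and
    flagged rather than aborting the run.
    """
    report: dict = {
        "provenance": {
            "tool": "ntcpval",
            "version": _tool_version(),
            "cohort_file": str(cohort_path),
            "cohort_sha256": _file_sha256(cohort_path),
            "parameters": {"td50": params.td50, "m": params.m,
                           "n_bins": n_bins, "cap": cap},
            "norms": vars(norms).copy() if hasattr(norms, "__dict__") else {
                f: getattr(norms, f) for f in
                ("intercept", "age_slope", "age_center", "residual_sd", "z_threshold")},
        },
        "stages": [],
        "warnings": [],
    }
    frame = read_cohort(cohort_path)
    report["stages"].append("read_cohort")

    if dvh_dir is not None:
        if scheme is None:
            scheme = FractionationScheme(n_fractions=28)
        frame, warnings = compute_d40_from_dvhs(frame, dvh_dir, scheme)
        report["warnings"].extend(warnings)
        report["stages"].append("dvh_to_d40")
    if "d40_eqd2" not in frame.columns:
        raise CohortValidationError(
            "cohort has no d40_eqd2 column and no DVH directory was given"
        )

    predictions, errors = predict_cohort(frame["d40_eqd2"], params)
    frame["t_value"] = [p.t_value if p else np.nan for p in predictions]
    frame["ntcp"] = [p.ntcp if p else np.nan for p in predictions]
    frame["ntcp_display"] = [p.display if p else "" for p in predictions]
    report["stages"].append("predict_ntcp")
    report["record_errors"] = [
        {"patient_id": frame["patient_id"].iloc[i], "error": msg} for i, msg in errors
    ]

    if "event" not in frame.columns or frame["event"].isna().all():
        if not all(c in frame.columns for c in SCORE_COLUMNS):
            missing = [c for c in ("event", *SCORE_COLUMNS) if c not in frame.columns]
            raise CohortValidationError(
                f"cohort supplies neither an event column nor AVLT-dr scores; "
                f"missing columns {missing}"
            )
        frame = score_events(frame, norms)
        report["stages"].append("score_events")

    complete = frame.dropna(subset=["ntcp", "event"])
    pred = complete["ntcp"].to_numpy(dtype=float)
    events = complete["event"].to_numpy(dtype=bool)
    report["n_patients"] = int(len(frame))
    report["n_evaluated"] = int(len(complete))
    report["n_events"] = int(events.sum())
    report["n_high_risk"] = int((pred > 0.99).sum())
    report["brier"] = brier_score(pred, events)
    if cap is not None:
        report["brier_capped"] = brier_score(pred, events, cap=cap)
    report["calibration"] = calibration(pred, events, n_bins=n_bins).to_dict()
    report["median_split"] = median_split_comparison(
        complete["d40_eqd2"].to_numpy(dtype=float), events
    ).to_dict()
    report["stages"].append("evaluate")
    report["cohort"] = frame
    return report
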