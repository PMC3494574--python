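"""Domain model for daily COPD diary data.

Patients score four respiratory symptoms every morning, each on its own
ordinal scale (shortness of breath 0-4, cough 0-3, sputum production 0-3,
nocturnal awakening due to respiratory symptoms 0-4), record up to three
morning peak-expiratory-flow (PEF) attempts in l/min, and note rescue
salbutamol use in puffs per day.  Exacerbation episodes carry an onset day,
an end day and a severity class (moderate = oral corticosteroid course,
severe = hospital admission).  Baseline patient descriptors include the
Clinical COPD Questionnaire (CCQ): ten items on a 0-6 Likert scale whose
overall score is the mean of all ten items, with symptom, functional and
mental domain means.

Days are 0-based integers counted from randomization; there is no calendar
arithmetic anywhere in the package.  Missing values are empty CSV cells and
``NaN`` in memory, never numeric sentinels.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SYMPTOM_SCALES",
    "TOTAL_SYMPTOM_MAX",
    "DIARY_COLUMNS",
    "EPISODE_COLUMNS",
    "PATIENT_COLUMNS",
    "DEFAULT_CCQ_DOMAINS",
    "CCQResult",
    "ValidationError",
    "daily_pef",
    "total_symptom_score",
    "proper_day",
    "ccq_scores",
    "validate_diary",
    "validate_episodes",
    "validate_patients",
    "read_diary_csv",
    "write_diary_csv",
    "read_episodes_csv",
    "write_episodes_csv",
    "read_patients_csv",
    "write_patients_csv",
    "add_derived_columns",
]

#: maximum ordinal value per symptom item (minimum is always 0)
SYMPTOM_SCALES: Mapping[str, int] = {
    "dyspnea": 4,
    "cough": 3,
    "sputum": 3,
    "nocturnal": 4,
}

#: highest possible total symptom score (sum of the four scale maxima)
TOTAL_SYMPTOM_MAX: int = sum(SYMPTOM_SCALES.values())

DIARY_COLUMNS = [
    "patient_id",
    "day",
    "dyspnea",
    "cough",
    "sputum",
    "nocturnal",
    "pef1",
    "pef2",
    "pef3",
    "salbutamol",
]
EPISODE_COLUMNS = ["patient_id", "onset_day", "end_day", "severity"]
PATIENT_COLUMNS = (
    ["patient_id", "age", "sex", "current_smoker", "pack_years", "fev1_pct_pred"]
    + [f"ccq{i}" for i in range(1, 11)]
    + ["arm", "followup_days"]
)

SEVERITIES = ("moderate", "severe")
SEXES = ("male", "female")
ARMS = ("salmeterol", "salmeterol_fluticasone")

#: standard CCQ item-to-domain mapping (1-based item numbers):
#: four symptom items, two mental items, four functional items.
DEFAULT_CCQ_DOMAINS: Mapping[str, tuple[int, ...]] = {
    "symptom": (1, 2, 5, 6),
    "mental": (3, 4),
    "functional": (7, 8, 9, 10),
}


class ValidationError(ValueError):
    """Raised when a record or table violates the diary data contract."""


@dataclasses.dataclass(frozen=True)
class CCQResult:
    """CCQ summary: overall mean plus the three domain means, all in [0, 6]."""

    total: float
    symptom_domain: float
    functional_domain: float
    mental_domain: float
    complete: bool = True


# ---------------------------------------------------------------------------
# elementary scoring
# ---------------------------------------------------------------------------

def daily_pef(pef_attempts: Sequence[float]) -> float:
    """Best of up to three morning PEF attempts (l/min); NaN if none present.

    The daily analysis value is the highest of the recorded attempts.
    Negative or non-finite attempts are rejected.
    """
    present = []
    for v in pef_attempts:
        if v is None:
            continue
        v = float(v)
        if np.isnan(v):
            continue
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"invalid PEF attempt: {v!r}")
        present.append(v)
    if not present:
        return float("nan")
    return max(present)


def total_symptom_score(dyspnea, cough, sputum, nocturnal) -> float:
    """Sum of the four symptom items (0-14); NaN if any item is missing.

    Accepts scalars or aligned numpy/pandas arrays.
    """
    arrs = [np.asarray(x, dtype=float) for x in (dyspnea, cough, sputum, nocturnal)]
    total = arrs[0] + arrs[1] + arrs[2] + arrs[3]
    return total if total.ndim else float(total)


def proper_day(dyspnea, cough, sputum, nocturnal):
    """True where all four symptom items are present.

    A "properly scored" diary day only requires the symptom items; missing
    PEF or salbutamol does not disqualify the day.
    """
    arrs = [np.asarray(x, dtype=float) for x in (dyspnea, cough, sputum, nocturnal)]
    ok = ~(np.isnan(arrs[0]) | np.isnan(arrs[1]) | np.isnan(arrs[2]) | np.isnan(arrs[3]))
    return ok if ok.ndim else bool(ok)


def ccq_scores(
    ccq_items: Sequence[float],
    domains: Mapping[str, tuple[int, ...]] = DEFAULT_CCQ_DOMAINS,
) -> CCQResult:
    """Score the ten CCQ items: overall mean and the three domain means.

    ``domains`` maps domain name to 1-based item numbers and must partition
    items 1..10.  Items out of [0, 6] raise; a missing item yields an
    incomplete result (NaN total/domains where affected).
    """
    items = np.asarray(list(ccq_items), dtype=float)
    if items.shape != (10,):
        raise ValidationError(f"expected 10 CCQ items, got {items.shape}")
    covered = sorted(i for idx in domains.values() for i in idx)
    if covered != list(range(1, 11)):
        raise ValidationError("CCQ domain map must partition items 1..10")
    present = ~np.isnan(items)
    if np.any((items[present] < 0) | (items[present] > 6)):
        raise ValidationError("CCQ items must lie in [0, 6]")
    complete = bool(present.all())

    def domain_mean(name: str) -> float:
        idx = np.array(domains[name]) - 1
        vals = items[idx]
        return float(np.mean(vals)) if not np.isnan(vals).any() else float("nan")

    total = float(np.mean(items)) if complete else float("nan")
    return CCQResult(
        total=total,
        symptom_domain=domain_mean("symptom"),
        functional_domain=domain_mean("functional"),
        mental_domain=domain_mean("mental"),
        complete=complete,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns {missing}")


def _check_scale(df: pd.DataFrame, col: str, lo: float, hi: float, what: str) -> None:
    vals = df[col]
    bad = vals.notna() & ((vals < lo) | (vals > hi))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{what} row {row}: {col}={vals.iloc[row]!r} outside [{lo}, {hi}]"
        )


def validate_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format diary panel; returns a normalized copy.

    Checks column presence, ordinal scales, non-negative finite PEF and
    salbutamol, and uniqueness of (patient_id, day).
    """
    _require_columns(diary, DIARY_COLUMNS, "diary")
    out = diary.loc[:, DIARY_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["day"] = out["day"].astype(int)
    for col in SYMPTOM_SCALES:
        out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        _check_scale(out, col, 0, SYMPTOM_SCALES[col], "diary")
        frac = out[col].dropna() % 1
        if (frac != 0).any():
            raise ValidationError(f"diary column {col} must be whole-valued ordinals")
    for col in ("pef1", "pef2", "pef3", "salbutamol"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        vals = out[col]
        bad = vals.notna() & (~np.isfinite(vals) | (vals < 0))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"diary row {row}: {col}={vals.iloc[row]!r} must be finite and >= 0"
            )
    dup = out.duplicated(subset=["patient_id", "day"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"diary row {row}: duplicate patient-day "
            f"({out['patient_id'].iloc[row]}, {out['day'].iloc[row]})"
        )
    return out.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def validate_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Validate the exacerbation-episode table (onset/end days, severity)."""
    _require_columns(episodes, EPISODE_COLUMNS, "episodes")
    out = episodes.loc[:, EPISODE_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["onset_day"] = out["onset_day"].astype(int)
    out["end_day"] = out["end_day"].astype(int)
    out["severity"] = out["severity"].astype(str)
    bad = ~out["severity"].isin(SEVERITIES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"episodes row {row}: severity {out['severity'].iloc[row]!r} "
            f"not in {SEVERITIES}"
        )
    if (out["end_day"] < out["onset_day"]).any():
        row = int(np.flatnonzero((out["end_day"] < out["onset_day"]).to_numpy())[0])
        raise ValidationError(f"episodes row {row}: end_day < onset_day")
    out = out.sort_values(["patient_id", "onset_day"], kind="stable").reset_index(drop=True)
    # episodes of one patient must not overlap
    prev_end = out.groupby("patient_id")["end_day"].shift(1)
    overlap = prev_end.notna() & (out["onset_day"] <= prev_end)
    if overlap.any():
        row = int(np.flatnonzero(overlap.to_numpy())[0])
        raise ValidationError(
            f"episodes row {row}: overlapping episodes for patient "
            f"{out['patient_id'].iloc[row]}"
        )
    return out


def validate_patients(patients: pd.DataFrame) -> pd.DataFrame:
    """Validate the baseline patient table (demographics, CCQ items, arm)."""
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    out = patients.loc[:, PATIENT_COLUMNS].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    if out["patient_id"].duplicated().any():
        raise ValidationError("patients table has duplicate patient_id")
    for col, allowed in (("sex", SEXES), ("arm", ARMS)):
        out[col] = out[col].astype(str)
        bad = ~out[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"patients row {row}: {col}={out[col].iloc[row]!r} not in {allowed}"
            )
    out["current_smoker"] = out["current_smoker"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
         "true": True, "false": False, "1": True, "0": False}
    )
    if out["current_smoker"].isna().any():
        raise ValidationError("patients: current_smoker must be boolean")
    out["current_smoker"] = out["current_smoker"].astype(bool)
    for col in ("age", "pack_years", "fev1_pct_pred"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
    if (out["pack_years"] < 0).any():
        raise ValidationError("patients: pack_years must be >= 0")
    for i in range(1, 11):
        col = f"ccq{i}"
        out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        _check_scale(out, col, 0, 6, "patients")
    out["followup_days"] = out["followup_days"].astype(int)
    if (out["followup_days"] < 1).any():
        raise ValidationError("patients: followup_days must be >= 1")
    return out.reset_index(drop=True)


def add_derived_columns(diary: pd.DataFrame) -> pd.DataFrame:
    """Append ``pef`` (best of three attempts), ``total`` and ``proper`` columns."""
    out = diary.copy()
    out["pef"] = out[["pef1", "pef2", "pef3"]].max(axis=1)
    out["total"] = total_symptom_score(
        out["dyspnea"], out["cough"], out["sputum"], out["nocturnal"]
    )
    out["proper"] = proper_day(
        out["dyspnea"], out["cough"], out["sputum"], out["nocturnal"]
    )
    return out


# ---------------------------------------------------------------------------
# CSV I/O (UTF-8, header required, "." decimal separator, empty cell = missing)
# ---------------------------------------------------------------------------

def _read_csv(path: str | os.PathLike | io.IOBase, what: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"could not parse {what} CSV: {exc}") from exc


def read_diary_csv(path) -> pd.DataFrame:
    """Read and validate a diary CSV (columns per the documented dialect)."""
    return validate_diary(_read_csv(path, "diary"))


def write_diary_csv(diary: pd.DataFrame, path) -> None:
    """Write a validated diary panel; round-trips bit-for-bit on valid data."""
    out = validate_diary(diary).copy()
    for col in SYMPTOM_SCALES:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def read_episodes_csv(path) -> pd.DataFrame:
    return validate_episodes(_read_csv(path, "episodes"))


def write_episodes_csv(episodes: pd.DataFrame, path) -> None:
    validate_episodes(episodes).to_csv(path, index=False)


def read_patients_csv(path) -> pd.DataFrame:
    return validate_patients(_read_csv(path, "patients"))


def write_patients_csv(patients: pd.DataFrame, path) -> None:
    validate_patients(patients).to_csv(path, index=False)
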