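"""Day-level ROC evaluation of window-score predictors.

The unit of analysis is the patient-day: case scores are the window scores
on first-onset days, control scores the scores on every other at-risk
patient-day.  The AUC is the tie-corrected rank (Mann-Whitney) statistic

    AUC = [#(case > control) + 0.5 * #(case = control)] / (n_cases * n_controls),

identical to the trapezoidal area under the empirical ROC curve, and
interpretable as the probability that a randomly chosen onset day scores
higher than a randomly chosen non-onset day (ties counted half).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diary_model import ValidationError

__all__ = ["RocResult", "day_level_labels", "auc", "roc_curve", "auc_bootstrap_ci"]


@dataclasses.dataclass
class RocResult:
    """Empirical ROC curve with its AUC.

    ``thresholds`` descend from +inf to -inf; point ``i`` classifies
    score >= thresholds[i] as positive, so the curve runs monotonically
    from (0, 0) to (1, 1).  ``auc`` is the trapezoidal area, equal to the
    rank-statistic AUC up to floating-point tolerance.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity,
             "fpr": self.fpr}
        )


def day_level_labels(
    table: pd.DataFrame,
    controls: str = "all_days",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a counting-process table into case and control scores.

    Cases are the event rows (one per exacerbating patient at first onset).
    With ``controls="all_days"`` (default) the controls are every other
    at-risk patient-day row; ``controls="one_per_patient"`` samples a single
    non-event day per patient instead (``seed`` fixes the draw), removing
    the within-patient dependence at the cost of discarding data.
    """
    if controls not in ("all_days", "one_per_patient"):
        raise ValidationError(f"unknown control sampling {controls!r}")
    scores = table["score"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int).astype(bool)
    cases = scores[event]
    if controls == "all_days":
        controls_arr = scores[~event]
    else:
        non_event = table.loc[~event, ["patient_id", "score"]]
        rng = np.random.default_rng(seed)
        picked = non_event.groupby("patient_id")["score"].apply(
            lambda s: s.iloc[rng.integers(len(s))]
        )
        controls_arr = picked.to_numpy(dtype=float)
    controls = controls_arr
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError(
            f"need at least one case and one control "
            f"(got {len(cases)} cases, {len(controls)} controls)"
        )
    return cases, controls


def auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Tie-corrected rank AUC of case vs control scores."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("cases and controls must be non-empty")
    # wins + half-ties via binary search against the sorted controls
    sorted_controls = np.sort(controls)
    below = np.searchsorted(sorted_controls, cases, side="left")
    below_or_equal = np.searchsorted(sorted_controls, cases, side="right")
    wins = below.sum(dtype=float)
    ties = (below_or_equal - below).sum(dtype=float)
    return float((wins + 0.5 * ties) / (len(cases) * len(controls)))


def roc_curve(cases: np.ndarray, controls: np.ndarray) -> RocResult:
    """Empirical ROC curve over all distinct observed scores.

    Thresholds are the distinct scores plus +/- infinity sentinels;
    sensitivity is the fraction of cases at or above each threshold, the
    false-positive rate the corresponding fraction of controls.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("cases and controls must be non-empty")
    distinct = np.unique(np.concatenate([cases, controls]))
    thresholds = np.concatenate([[np.inf], distinct[::-1], [-np.inf]])
    sorted_cases = np.sort(cases)
    sorted_controls = np.sort(controls)
    sens = 1.0 - np.searchsorted(sorted_cases, thresholds, side="left") / len(cases)
    fpr = 1.0 - np.searchsorted(sorted_controls, thresholds, side="left") / len(controls)
    area = float(np.trapezoid(sens, fpr))
    return RocResult(
        thresholds=thresholds, sensitivity=sens, fpr=fpr, auc=area,
        n_cases=len(cases), n_controls=len(controls),
    )


def auc_bootstrap_ci(
    table: pd.DataFrame,
    n_boot: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Patient-level bootstrap percentile CI for the day-level AUC.

    Patients, not days, are resampled, because the day rows of one patient
    are dependent.  Resamples without both a case and a control are skipped.
    """
    rng = np.random.default_rng(seed)
    patients = table["patient_id"].unique()
    groups = {pid: grp for pid, grp in table.groupby("patient_id")}
    stats = []
    for _ in range(n_boot):
        sample = rng.choice(patients, size=len(patients), replace=True)
        boot = pd.concat([groups[pid] for pid in sample], ignore_index=True)
        scores = boot["score"].to_numpy(dtype=float)
        event = boot["event"].to_numpy(bool)
        if event.any() and (~event).any():
            stats.append(auc(scores[event], scores[~event]))
    if not stats:
        raise ValidationError("no bootstrap resample had both cases and controls")
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
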