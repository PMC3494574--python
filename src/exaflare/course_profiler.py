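"""Onset-aligned profiling of the symptom course around exacerbations.

The profiling analysis aligns each eligible first exacerbation at relative
day 0 and follows every diary signal from 28 days before to 56 days after
onset.  Eligibility mirrors the trial analysis: a patient must have
properly scored (all four symptom items present) at least 50% of the diary
days both in the 4 pre-onset weeks and in the 8 post-onset weeks, and must
not have a new exacerbation within 8 weeks after the onset (such episodes
are "treatment failures" and are excluded).

Weekly summaries compare each post-onset week (week 1 = relative days
0..6, ..., week 8 = days 49..55) against the stable-phase baseline week,
week -4 (days -28..-22), with a paired test on patient-level weekly means.
The recovery week of a signal is the first week from which all later weeks
are no longer significantly worse than week -4 (elevated symptoms or
salbutamol, depressed PEF); a signal still significantly worse in week 8
has not recovered within the observation window.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diary_model import ValidationError, add_derived_columns

__all__ = [
    "REL_WINDOW",
    "PRE_DAYS",
    "POST_DAYS",
    "WEEK_DAYS",
    "PROFILE_SIGNALS",
    "AlignedCourse",
    "eligible_first_episodes",
    "align_course",
    "weekly_summary",
    "recovery_week",
    "recovery_rank",
    "compare_episodes",
]

#: relative-day span of an aligned course (inclusive)
REL_WINDOW = (-28, 56)
#: pre-onset eligibility window (relative days, inclusive)
PRE_DAYS = (-28, -1)
#: post-onset eligibility window (relative days, inclusive)
POST_DAYS = (0, 55)
#: comparison periods for first/second/severe episode contrasts
COMPARE_PRE = (-28, 0)
COMPARE_POST = (1, 56)

#: week label -> relative days; the 8 post-onset weeks partition days 0..55
WEEK_DAYS: Mapping[int, range] = {
    -4: range(-28, -21),
    **{k: range(7 * (k - 1), 7 * k) for k in range(1, 9)},
}
BASELINE_WEEK = -4

PROFILE_SIGNALS = ("dyspnea", "cough", "sputum", "nocturnal", "total", "pef", "salbutamol")

#: sign of a clinically *worse* change relative to baseline
WORSE_SIGN: Mapping[str, float] = {
    "dyspnea": 1.0, "cough": 1.0, "sputum": 1.0, "nocturnal": 1.0,
    "total": 1.0, "salbutamol": 1.0, "pef": -1.0,
}


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def eligible_first_episodes(diary: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Classify each patient's first episode as eligible or excluded.

    Returns one row per patient with an episode: the first episode's onset,
    end and severity, ``eligible`` flag and ``reason`` for exclusion
    (``out_of_window`` when the onset lies outside the patient's diary
    coverage, ``treatment_failure`` when a new onset occurs within relative
    days 1..56, ``incomplete_diary`` when either the 4-week pre-onset or
    8-week post-onset window has under 50% properly scored days).
    """
    d = add_derived_columns(diary)
    proper = d[d["proper"]].groupby("patient_id")["day"].apply(set)
    span = d.groupby("patient_id")["day"].agg(["min", "max"])

    rows = []
    for pid, eps in episodes.groupby("patient_id"):
        eps = eps.sort_values("onset_day")
        first = eps.iloc[0]
        onset = int(first["onset_day"])
        rec = {
            "patient_id": pid,
            "onset_day": onset,
            "end_day": int(first["end_day"]),
            "severity": first["severity"],
            "eligible": False,
            "reason": None,
        }
        if pid not in span.index or not (
            span.loc[pid, "min"] <= onset <= span.loc[pid, "max"]
        ):
            rec["reason"] = "out_of_window"
        elif ((eps["onset_day"].iloc[1:] - onset).between(1, 56)).any():
            rec["reason"] = "treatment_failure"
        else:
            days = proper.get(pid, set())
            pre_n = sum(1 for r in range(onset + PRE_DAYS[0], onset + PRE_DAYS[1] + 1) if r in days)
            post_n = sum(1 for r in range(onset + POST_DAYS[0], onset + POST_DAYS[1] + 1) if r in days)
            pre_total = PRE_DAYS[1] - PRE_DAYS[0] + 1
            post_total = POST_DAYS[1] - POST_DAYS[0] + 1
            if pre_n / pre_total < 0.5 or post_n / post_total < 0.5:
                rec["reason"] = "incomplete_diary"
            else:
                rec["eligible"] = True
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["patient_id", "onset_day", "end_day", "severity", "eligible", "reason"],
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AlignedCourse:
    """Signals of eligible episodes on the relative-day grid -28..+56.

    ``data`` maps each signal to a (patients x relative days) frame; rows
    are patient ids, columns the full integer grid, NaN where the diary day
    is missing or (for symptom signals) not properly scored.
    """

    data: dict[str, pd.DataFrame]
    onsets: pd.Series

    @property
    def signals(self) -> list[str]:
        return list(self.data)

    @property
    def n_patients(self) -> int:
        return len(self.onsets)

    def mean(self, signal: str) -> pd.Series:
        return self.data[signal].mean(axis=0)

    def sem(self, signal: str) -> pd.Series:
        frame = self.data[signal]
        return frame.std(axis=0, ddof=1) / np.sqrt(frame.notna().sum(axis=0))

    def weekly_patient_means(self, signal: str, min_days: int = 4) -> pd.DataFrame:
        """Patient-level weekly means; NaN when under ``min_days`` proper days."""
        frame = self.data[signal]
        out = {}
        for week, days in WEEK_DAYS.items():
            block = frame.loc[:, list(days)]
            means = block.mean(axis=1)
            means[block.notna().sum(axis=1) < min_days] = np.nan
            out[week] = means
        return pd.DataFrame(out)

    def period_patient_means(self, signal: str, period: tuple[int, int]) -> pd.Series:
        """Patient-level mean over an inclusive relative-day period."""
        frame = self.data[signal]
        return frame.loc[:, list(range(period[0], period[1] + 1))].mean(axis=1)


def align_course(
    diary: pd.DataFrame,
    onsets: pd.Series | Mapping[str, int],
    signals: Sequence[str] = PROFILE_SIGNALS,
) -> AlignedCourse:
    """Align each patient's diary at their episode onset (relative day 0).

    ``onsets`` maps patient_id to onset day (e.g. the eligible rows of
    :func:`eligible_first_episodes`).  Missing diary days stay missing;
    symptom signals (including ``total``) are restricted to properly scored
    days.
    """
    onsets = pd.Series(dict(onsets), name="onset_day").astype(int)
    if len(onsets) == 0:
        raise ValidationError("no eligible episodes to align")
    d = add_derived_columns(diary)
    d = d[d["patient_id"].isin(onsets.index)].copy()
    d["rel_day"] = d["day"] - d["patient_id"].map(onsets)
    d = d[(d["rel_day"] >= REL_WINDOW[0]) & (d["rel_day"] <= REL_WINDOW[1])]

    grid = list(range(REL_WINDOW[0], REL_WINDOW[1] + 1))
    data = {}
    for sig in signals:
        if sig not in d.columns:
            raise ValidationError(f"unknown signal {sig!r}")
        sub = d
        if sig in ("dyspnea", "cough", "sputum", "nocturnal", "total"):
            sub = d[d["proper"]]
        wide = sub.pivot(index="patient_id", columns="rel_day", values=sig)
        data[sig] = wide.reindex(index=onsets.index, columns=grid)
    return AlignedCourse(data=data, onsets=onsets)


# ---------------------------------------------------------------------------
# weekly contrasts vs the baseline week
# ---------------------------------------------------------------------------

def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided paired p-value; 1.0 for identical pairs, NaN under n < 2."""
    if len(a) < 2:
        return float("nan")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    if test == "t":
        p = stats.ttest_rel(a, b).pvalue
    elif test == "wilcoxon":
        p = stats.wilcoxon(a, b, zero_method="wilcox").pvalue
    else:
        raise ValidationError(f"unknown paired test {test!r}")
    return float(p) if np.isfinite(p) else 1.0


def weekly_summary(
    aligned: AlignedCourse,
    signals: Sequence[str] | None = None,
    test: str = "t",
    alpha: float = 0.05,
    min_days: int = 4,
) -> pd.DataFrame:
    """Weekly means, SEMs and paired contrasts against week -4.

    One row per (signal, week) for week -4 and post-onset weeks 1..8:
    group mean and SEM over patients contributing that week, the number of
    patients paired with week -4, the two-sided paired p-value (NaN when
    fewer than two pairs) and its alpha-level flag, and the paired mean
    difference week minus baseline.
    """
    signals = list(signals) if signals is not None else aligned.signals
    rows = []
    for sig in signals:
        weekly = aligned.weekly_patient_means(sig, min_days=min_days)
        base = weekly[BASELINE_WEEK]
        for week in WEEK_DAYS:
            col = weekly[week]
            n_week = int(col.notna().sum())
            mean = float(col.mean()) if n_week else float("nan")
            sem = float(col.std(ddof=1) / np.sqrt(n_week)) if n_week > 1 else float("nan")
            if week == BASELINE_WEEK:
                rows.append(
                    {"signal": sig, "week": week, "mean": mean, "sem": sem,
                     "n": n_week, "n_pairs": n_week, "mean_diff": 0.0,
                     "p": float("nan"), "significant": False}
                )
                continue
            paired = weekly[[week, BASELINE_WEEK]].dropna()
            n_pairs = len(paired)
            diff = (
                float((paired[week] - paired[BASELINE_WEEK]).mean())
                if n_pairs else float("nan")
            )
            p = _paired_p(
                paired[week].to_numpy(), paired[BASELINE_WEEK].to_numpy(), test
            )
            rows.append(
                {"signal": sig, "week": week, "mean": mean, "sem": sem,
                 "n": n_week, "n_pairs": n_pairs, "mean_diff": diff,
                 "p": p, "significant": bool(np.isfinite(p) and p < alpha)}
            )
    return pd.DataFrame(rows)


def recovery_week(
    summary: pd.DataFrame,
    signal: str,
    alpha: float = 0.05,
    require_worsening: bool = True,
) -> int | None:
    """First week from which the signal stays back at baseline, or None.

    Returns the smallest week ``w`` in 1..8 such that none of the weeks
    ``w..8`` differs significantly from week -4 in the clinically worse
    direction (higher symptoms/salbutamol, lower PEF; set
    ``require_worsening=False`` to block on any two-sided significance).
    ``None`` means not recovered by week 8.  A week with an undefined
    p-value (fewer than two paired patients) makes every ``w`` at or below
    it ineligible.
    """
    sub = summary[summary["signal"] == signal].set_index("week")
    missing = [w for w in range(1, 9) if w not in sub.index]
    if missing:
        raise ValidationError(f"summary lacks weeks {missing} for {signal!r}")
    sign = WORSE_SIGN.get(signal, 1.0)
    blocking = {}
    for w in range(1, 9):
        p, diff = sub.loc[w, "p"], sub.loc[w, "mean_diff"]
        if not np.isfinite(p):
            blocking[w] = None  # undefined: week cannot certify recovery
            continue
        sig_flag = p < alpha
        if require_worsening:
            sig_flag = sig_flag and (sign * diff > 0)
        blocking[w] = bool(sig_flag)
    for w in range(1, 9):
        tail = [blocking[j] for j in range(w, 9)]
        if any(b is None for b in tail):
            continue
        if not any(tail):
            return w
    return None


def recovery_rank(week: int | None) -> int:
    """Orderable recovery index: the week itself, or 9 for not recovered."""
    return 9 if week is None else int(week)


# ---------------------------------------------------------------------------
# first / second / severe episode comparisons
# ---------------------------------------------------------------------------

def compare_episodes(
    aligned_first: AlignedCourse,
    aligned_second: AlignedCourse | None = None,
    aligned_severe: AlignedCourse | None = None,
    signals: Sequence[str] | None = None,
    test: str = "t",
) -> pd.DataFrame:
    """Contrast episode classes over the pre (-28..0) and post (1..56) periods.

    Per signal: patient-level period means per class; a paired test of
    first vs second episodes over patients contributing both (pre and post
    periods); and Welch's two-sample test of severe vs first-moderate
    pre-period means.  The severe post-onset period is not compared
    (hospitalized patients rarely complete diaries after a severe onset).
    """
    signals = list(signals) if signals is not None else aligned_first.signals
    rows = []
    for sig in signals:
        row: dict = {"signal": sig}
        first_pre = aligned_first.period_patient_means(sig, COMPARE_PRE)
        first_post = aligned_first.period_patient_means(sig, COMPARE_POST)
        row["first_pre_mean"] = float(first_pre.mean())
        row["first_post_mean"] = float(first_post.mean())
        row["n_first"] = int(first_pre.notna().sum())

        if aligned_second is not None:
            second_pre = aligned_second.period_patient_means(sig, COMPARE_PRE)
            second_post = aligned_second.period_patient_means(sig, COMPARE_POST)
            row["second_pre_mean"] = float(second_pre.mean())
            row["second_post_mean"] = float(second_post.mean())
            for label, a, b in (
                ("pre", first_pre, second_pre),
                ("post", first_post, second_post),
            ):
                both = pd.concat({"f": a, "s": b}, axis=1).dropna()
                row[f"n_pairs_{label}"] = len(both)
                row[f"p_first_vs_second_{label}"] = _paired_p(
                    both["f"].to_numpy(), both["s"].to_numpy(), test
                )

        if aligned_severe is not None:
            severe_pre = aligned_severe.period_patient_means(sig, COMPARE_PRE).dropna()
            row["severe_pre_mean"] = float(severe_pre.mean())
            row["n_severe"] = len(severe_pre)
            mod = first_pre.dropna()
            if len(severe_pre) >= 2 and len(mod) >= 2:
                row["p_severe_vs_moderate_pre"] = float(
                    stats.ttest_ind(
                        severe_pre.to_numpy(), mod.to_numpy(), equal_var=False
                    ).pvalue
                )
            else:
                row["p_severe_vs_moderate_pre"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
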