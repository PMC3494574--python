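"""Day-level exacerbation prediction from a moving two-week window.

The predictor for day ``t`` is the difference between two moving weekly
averages of a diary signal: the mean over days ``t-7 .. t-1`` minus the mean
over days ``t-14 .. t-8``.  The window slides one day at a time, so every
follow-up day of every patient carries an up-to-date "recent change" score
that uses only strictly earlier diary entries.  For example, a patient whose
mean total symptom score is 10 points over days 101-107 and 13 points over
days 108-114 scores +3 at day 115.

These day-level scores feed a proportional-hazards model with the score as
a time-dependent covariate: each patient-day at risk (no prior exacerbation,
inside follow-up, score defined) becomes one row of a counting-process
table, the day of the first exacerbation onset is the event row, and the
partial likelihood is maximized over the day-wise risk sets.  The same table
supplies the Table-3-style analysis of relative risks by change bin and the
reference band (mean +/- 2 SD of the non-event scores per follow-up day).

Only data up to the first exacerbation are used: a patient leaves the risk
set at the first onset or at the end of follow-up, whichever comes first.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diary_model import ValidationError, add_derived_columns

__all__ = [
    "WindowConfig",
    "HazardFit",
    "window_scores_matrix",
    "window_score_series",
    "window_scores_panel",
    "build_counting_process",
    "fit_td_cox",
    "rr_by_change_bin",
    "reference_band",
    "DEFAULT_CHANGE_BINS",
]

#: Table-3 change bins on the total-symptom window score:
#: (-inf, 1) reference, [1, 2), [2, 3), [3, inf)
DEFAULT_CHANGE_BINS: tuple[float, ...] = (1.0, 2.0, 3.0)

#: signals for which clinical deterioration lowers the raw value
NEGATIVE_SIGNALS = frozenset({"pef"})


@dataclasses.dataclass(frozen=True)
class WindowConfig:
    """Configuration of the moving-window change score.

    block_length:       days per averaging block (two consecutive blocks).
    min_days_per_block: minimum proper diary days for a block mean to be
                        defined; blocks with fewer days yield an undefined
                        score, days inside a block are never imputed.
    signal:             diary variable the score is computed on ("total",
                        one of the four symptoms, "pef" or "salbutamol").
    orient_deteriorate_positive: negate the score for signals where
                        deterioration lowers the value (PEF), so that a
                        positive score always means worsening.
    """

    block_length: int = 7
    min_days_per_block: int = 4
    signal: str = "total"
    orient_deteriorate_positive: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_days_per_block <= self.block_length:
            raise ValidationError(
                "need 1 <= min_days_per_block <= block_length, got "
                f"{self.min_days_per_block} / {self.block_length}"
            )

    @property
    def sign(self) -> float:
        if self.orient_deteriorate_positive and self.signal in NEGATIVE_SIGNALS:
            return -1.0
        return 1.0


def window_scores_matrix(
    values: np.ndarray, block_length: int = 7, min_days: int = 4
) -> np.ndarray:
    """Window change scores for a (patients, days) value matrix.

    ``values[:, d]`` is the signal on day ``d`` (NaN where missing); the
    returned matrix has the same shape, with column ``t`` holding the score
    attributed to day ``t``: mean over days ``t-B .. t-1`` minus mean over
    days ``t-2B .. t-B-1`` (B = block_length), NaN whenever either block has
    fewer than ``min_days`` non-missing days or does not fit before day 0.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        return window_scores_matrix(vals[None, :], block_length, min_days)[0]
    n, t_max = vals.shape
    filled = np.where(np.isnan(vals), 0.0, vals)
    present = (~np.isnan(vals)).astype(float)
    zero = np.zeros((n, 1))
    csum = np.concatenate([zero, np.cumsum(filled, axis=1)], axis=1)
    ccnt = np.concatenate([zero, np.cumsum(present, axis=1)], axis=1)

    scores = np.full((n, t_max), np.nan)
    b = block_length
    t = np.arange(2 * b, t_max)
    if t.size == 0:
        return scores
    with np.errstate(invalid="ignore", divide="ignore"):
        recent_sum = csum[:, t] - csum[:, t - b]
        recent_cnt = ccnt[:, t] - ccnt[:, t - b]
        earlier_sum = csum[:, t - b] - csum[:, t - 2 * b]
        earlier_cnt = ccnt[:, t - b] - ccnt[:, t - 2 * b]
        score = recent_sum / recent_cnt - earlier_sum / earlier_cnt
    defined = (recent_cnt >= min_days) & (earlier_cnt >= min_days)
    scores[:, t] = np.where(defined, score, np.nan)
    return scores


def window_score_series(series: pd.Series, config: WindowConfig | None = None) -> pd.Series:
    """Window change score for one patient's daily signal series.

    ``series`` is indexed by integer study day (gaps and NaN allowed).  The
    result is indexed by every day from the first diary day up to one day
    past the last, NaN where the score is undefined.  The score at day ``t``
    uses only days strictly before ``t``.
    """
    config = config or WindowConfig()
    if len(series) == 0:
        return pd.Series(dtype=float)
    days = series.index.to_numpy()
    if np.any(days != days.astype(int)):
        raise ValidationError("series index must be integer days")
    lo, hi = int(days.min()), int(days.max())
    full = np.arange(lo, hi + 2)  # one extra day: score for the day after the diary ends
    vals = np.full(full.shape, np.nan)
    vals[series.index.to_numpy() - lo] = series.to_numpy(dtype=float)
    scores = window_scores_matrix(vals, config.block_length, config.min_days_per_block)
    return pd.Series(config.sign * scores, index=full, name="score")


def window_scores_panel(diary: pd.DataFrame, config: WindowConfig | None = None) -> pd.DataFrame:
    """Window scores for every patient of a diary panel.

    Returns a long table (patient_id, day, score) with one row per
    patient-day where the score is defined.  Symptom signals use proper
    days only (all four items present); "pef" uses the best-of-three daily
    value and is sign-flipped when the config orients deterioration
    positive.
    """
    config = config or WindowConfig()
    d = add_derived_columns(diary)
    if config.signal not in d.columns:
        raise ValidationError(f"unknown signal {config.signal!r}")
    if config.signal in ("total", "dyspnea", "cough", "sputum", "nocturnal"):
        d = d[d["proper"]]
    wide = d.pivot(index="patient_id", columns="day", values=config.signal)
    lo, hi = int(wide.columns.min()), int(wide.columns.max())
    wide = wide.reindex(columns=range(lo, hi + 2))
    scores = window_scores_matrix(
        wide.to_numpy(dtype=float), config.block_length, config.min_days_per_block
    )
    out = pd.DataFrame(
        config.sign * scores, index=wide.index, columns=wide.columns
    ).stack().rename("score").reset_index()
    out.columns = ["patient_id", "day", "score"]
    out["day"] = out["day"].astype(int)
    return out.sort_values(["patient_id", "day"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# counting-process construction
# ---------------------------------------------------------------------------

def build_counting_process(
    diary: pd.DataFrame,
    episodes: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    config: WindowConfig | None = None,
    followup: pd.Series | None = None,
) -> pd.DataFrame:
    """Day-level risk-set rows up to each patient's first exacerbation.

    One row per patient-day with a defined window score while the patient is
    at risk: no prior onset and day < follow-up end.  ``event`` is 1 on the
    first-onset day (when its score is defined); the patient contributes no
    rows after the first onset.  ``followup`` optionally maps patient_id to
    follow-up length in days; by default follow-up runs one day past each
    patient's last diary entry.

    Patients whose first onset precedes the earliest definable score (or
    falls on an undefined-score day) contribute no event row; they are
    listed in the result's ``attrs["events_dropped"]``.
    """
    config = config or WindowConfig()
    if scores is None:
        scores = window_scores_panel(diary, config)
    scores = scores.dropna(subset=["score"]).copy()

    first_onset = episodes.groupby("patient_id")["onset_day"].min()
    if followup is None:
        followup = diary.groupby("patient_id")["day"].max() + 1
    followup = followup.reindex(scores["patient_id"].unique())

    end = followup.copy()
    onset_aligned = first_onset.reindex(end.index)
    has_onset = onset_aligned.notna()
    # at risk through the onset day itself; otherwise through followup - 1
    end[has_onset] = np.minimum(onset_aligned[has_onset] + 1, end[has_onset])

    scores["_end"] = scores["patient_id"].map(end)
    table = scores[scores["day"] < scores["_end"]].drop(columns="_end").copy()
    table["event"] = (
        table["patient_id"].map(first_onset).eq(table["day"]).astype(int)
    )

    dropped = sorted(
        set(first_onset.index)
        - set(table.loc[table["event"] == 1, "patient_id"])
    )
    if dropped:
        warnings.warn(
            f"{len(dropped)} patient(s) had a first onset without a defined "
            "window score; they contribute no event row",
            stacklevel=2,
        )
    table = table.reset_index(drop=True)
    table.attrs["events_dropped"] = dropped
    return table


# ---------------------------------------------------------------------------
# time-dependent Cox fit
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HazardFit:
    """Result of a proportional-hazards fit on the counting-process table.

    ``beta`` is on the log relative-risk scale; ``rr`` = exp(beta) with a
    Wald 95% CI from the inverse observed information.  For binned fits the
    arrays carry one entry per non-reference bin and ``labels`` names them;
    the reference bin has RR identically 1 and is not listed.
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    n_rows: int
    ties: str
    converged: bool
    identifiable: bool

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        z = stats.norm.ppf(0.975)
        return np.exp(
            np.column_stack([self.beta - z * self.se, self.beta + z * self.se])
        )

    @property
    def zscores(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zscores))

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "rr": self.rr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.zscores,
                "p": self.pvalues,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _partial_loglik_parts(beta, x, day_codes, event, n_days, ties):
    """Breslow/Efron log partial likelihood, gradient and information.

    Risk sets are day-wise: every row sharing a day code is in that day's
    risk set.  Only days with at least one event contribute.
    """
    eta = x @ beta
    w = np.exp(eta)
    p = x.shape[1]

    # per-day aggregates over the full risk set
    s0 = np.bincount(day_codes, weights=w, minlength=n_days)
    s1 = np.empty((n_days, p))
    s2 = np.empty((n_days, p, p))
    for j in range(p):
        s1[:, j] = np.bincount(day_codes, weights=w * x[:, j], minlength=n_days)
        for k in range(j, p):
            s2[:, j, k] = s2[:, k, j] = np.bincount(
                day_codes, weights=w * x[:, j] * x[:, k], minlength=n_days
            )

    ev = event.astype(bool)
    d = np.bincount(day_codes[ev], minlength=n_days).astype(float)
    sum_x_ev = np.zeros((n_days, p))
    for j in range(p):
        sum_x_ev[:, j] = np.bincount(day_codes[ev], weights=x[ev, j], minlength=n_days)

    has = d > 0
    ll = float((sum_x_ev[has] @ beta).sum())
    grad = sum_x_ev[has].sum(axis=0)
    info = np.zeros((p, p))

    if ties == "breslow":
        ll -= float((d[has] * np.log(s0[has])).sum())
        mean = s1[has] / s0[has, None]
        grad -= (d[has, None] * mean).sum(axis=0)
        cov = s2[has] / s0[has, None, None] - mean[:, :, None] * mean[:, None, :]
        info += (d[has, None, None] * cov).sum(axis=0)
    elif ties == "efron":
        ev_w = np.bincount(day_codes[ev], weights=w[ev], minlength=n_days)
        ev_s1 = np.zeros((n_days, p))
        ev_s2 = np.zeros((n_days, p, p))
        for j in range(p):
            ev_s1[:, j] = np.bincount(
                day_codes[ev], weights=(w * x[:, j])[ev], minlength=n_days
            )
            for k in range(j, p):
                ev_s2[:, j, k] = ev_s2[:, k, j] = np.bincount(
                    day_codes[ev], weights=(w * x[:, j] * x[:, k])[ev], minlength=n_days
                )
        for t in np.flatnonzero(has):
            dt = int(d[t])
            for r in range(dt):
                f = r / dt
                denom = s0[t] - f * ev_w[t]
                num1 = s1[t] - f * ev_s1[t]
                num2 = s2[t] - f * ev_s2[t]
                ll -= np.log(denom)
                mean = num1 / denom
                grad -= mean
                info += num2 / denom - np.outer(mean, mean)
    else:  # pragma: no cover
        raise ValidationError(f"unknown tie method {ties!r}")
    return ll, grad, info


def fit_td_cox(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("score",),
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> HazardFit:
    """Fit the time-dependent Cox model by Newton-Raphson.

    ``table`` is a counting-process table with columns ``day``, ``event``
    and the covariates.  The risk set at day ``t`` consists of all rows with
    that day.  Ties are handled by the Breslow (default) or Efron method;
    standard errors come from the inverse observed information at the
    maximum.  A model whose covariates do not vary inside any risk set is
    flagged non-identifiable and returned at beta = 0.
    """
    covariates = list(covariates)
    x = table[covariates].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("covariates contain NaN")
    event = table["event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValidationError("no event rows: cannot fit the hazard model")
    day_codes, _ = pd.factorize(table["day"], sort=True)
    n_days = int(day_codes.max()) + 1
    p = x.shape[1]

    beta = np.zeros(p)
    ll0, grad0, info0 = _partial_loglik_parts(beta, x, day_codes, event, n_days, ties)
    # identifiability: covariates must vary within at least one event-day risk set
    if np.linalg.matrix_rank(info0, tol=1e-12) < p:
        se = np.full(p, np.nan)
        return HazardFit(
            names=covariates, beta=beta, se=se, loglik=ll0, loglik_null=ll0,
            n_events=n_events, n_rows=len(table), ties=ties,
            converged=True, identifiable=False,
        )

    ll, grad, info = ll0, grad0, info0
    converged = False
    for _ in range(max_iter):
        step = np.linalg.solve(info, grad)
        # step-halving to keep the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _partial_loglik_parts(
                cand, x, day_codes, event, n_days, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            converged = True
            break
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return HazardFit(
        names=covariates, beta=beta, se=se, loglik=ll, loglik_null=ll0,
        n_events=n_events, n_rows=len(table), ties=ties,
        converged=converged, identifiable=True,
    )


def rr_by_change_bin(
    table: pd.DataFrame,
    bins: Sequence[float] = DEFAULT_CHANGE_BINS,
    ties: str = "breslow",
) -> HazardFit:
    """Relative risk per change bin versus the reference bin.

    Scores are cut at the given ascending edges into ``len(bins) + 1``
    half-open bins; the lowest bin (scores below the first edge) is the
    reference with RR = 1.  Empty non-reference bins are dropped from the
    fit with a warning and reported as NaN.
    """
    edges = list(bins)
    if sorted(edges) != edges:
        raise ValidationError("bin edges must be ascending")
    full_edges = [-np.inf] + edges + [np.inf]
    labels = []
    for lo, hi in zip(full_edges[1:-1], full_edges[2:]):
        labels.append(f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}")

    aug = table.copy()
    cols = []
    kept_labels = []
    score = aug["score"].to_numpy(dtype=float)
    for (lo, hi), lab in zip(zip(full_edges[1:-1], full_edges[2:]), labels):
        ind = ((score >= lo) & (score < hi)).astype(float)
        col = f"bin[{lab}]"
        if ind.sum() == 0:
            warnings.warn(f"change bin {lab} is empty; RR undefined", stacklevel=2)
            continue
        aug[col] = ind
        cols.append(col)
        kept_labels.append(lab)
    fit = fit_td_cox(aug, covariates=cols, ties=ties)

    # re-expand to the full label set with NaN for empty bins
    beta = np.full(len(labels), np.nan)
    se = np.full(len(labels), np.nan)
    for lab, b, s in zip(kept_labels, fit.beta, fit.se):
        i = labels.index(lab)
        beta[i], se[i] = b, s
    return HazardFit(
        names=[f"bin[{lab}]" for lab in labels], beta=beta, se=se,
        loglik=fit.loglik, loglik_null=fit.loglik_null, n_events=fit.n_events,
        n_rows=fit.n_rows, ties=ties, converged=fit.converged,
        identifiable=fit.identifiable,
    )


def reference_band(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day-wise non-event reference band and the event-day scores.

    For every follow-up day, the mean and SD of the defined scores among
    rows without an event that day define the band mean +/- 2 SD (undefined
    when fewer than two non-event scores exist).  Event-day scores are
    returned separately for overlay.
    """
    non_event = table[table["event"] == 0]
    grp = non_event.groupby("day")["score"]
    band = grp.agg(n="count", mean="mean", sd="std")
    band.loc[band["n"] < 2, ["mean", "sd"]] = np.nan
    band["lower"] = band["mean"] - 2 * band["sd"]
    band["upper"] = band["mean"] + 2 * band["sd"]
    events = table.loc[table["event"] == 1, ["patient_id", "day", "score"]].reset_index(
        drop=True
    )
    return band.reset_index(), events
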