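"""Synthetic diary-cohort generator.

Emulates the statistical structure of a COPD exacerbation diary study: each
patient has a latent baseline per signal (four ordinal symptoms, salbutamol
puffs/day, morning PEF), daily Gaussian noise, and exacerbation episodes
that superimpose a stereotyped "bump" on the latent course — a linear rise
starting two weeks before onset, a sharper rise over the final week, a peak
at the onset day, and a decay back to baseline over a signal-specific
number of weeks (defaults: cough and sputum 4, salbutamol 6, dyspnea 7,
nocturnal 8, PEF 2; the PEF bump is a dip).  Latent values are discretized
by rounding and clamping to each ordinal scale.

Two modes:

* ``shape`` — every patient receives scheduled episodes with the fixed
  course above; used to verify onset-aligned profiling (weekly contrasts,
  recovery weeks, first/second/severe comparisons).
* ``hazard`` — episode onsets are caused by recent symptom change: each
  at-risk day's onset probability is ``1 - exp(-h0 * exp(beta_true * s_t))``
  where ``s_t`` is the patient's moving two-week-window change score of the
  observed total symptom score (0 while undefined).  Because the generator
  scores exactly what the analysis scores, the time-dependent Cox fit is
  estimating a true, known log relative risk.

Missingness is whole-day and completely at random.  Identical
``(params, seed)`` always reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd

from .diary_model import (
    SYMPTOM_SCALES,
    ValidationError,
    validate_diary,
    validate_episodes,
    validate_patients,
)
from .window_predictor import window_scores_matrix

__all__ = [
    "SIGNALS",
    "EpisodeShape",
    "CohortParams",
    "SimulatedCohort",
    "bump_profile",
    "simulate_cohort",
    "truth_recovery_report",
]

SIGNALS = ("dyspnea", "cough", "sputum", "nocturnal", "salbutamol", "pef")
ORDINAL_SIGNALS = ("dyspnea", "cough", "sputum", "nocturnal")


def _default_amplitudes() -> dict[str, float]:
    # latent units added in the onset week; the PEF amplitude is a decrement in l/min
    return {
        "dyspnea": 1.0,
        "cough": 1.0,
        "sputum": 1.0,
        "nocturnal": 1.0,
        "salbutamol": 1.0,
        "pef": 20.0,
    }


def _default_recovery_weeks() -> dict[str, int]:
    return {
        "dyspnea": 7,
        "cough": 4,
        "sputum": 4,
        "nocturnal": 8,
        "salbutamol": 6,
        "pef": 2,
    }


def _default_baseline_mean() -> dict[str, float]:
    return {
        "dyspnea": 1.5,
        "cough": 1.1,
        "sputum": 1.1,
        "nocturnal": 0.3,
        "salbutamol": 1.5,
        "pef": 279.0,
    }


def _default_baseline_sd() -> dict[str, float]:
    return {
        "dyspnea": 0.8,
        "cough": 0.7,
        "sputum": 0.7,
        "nocturnal": 0.5,
        "salbutamol": 1.0,
        "pef": 45.0,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "dyspnea": 0.7,
        "cough": 0.7,
        "sputum": 0.7,
        "nocturnal": 0.6,
        "salbutamol": 0.8,
        "pef": 15.0,
    }


def _default_severe_pre_amplitude() -> dict[str, float]:
    # additional latent elevation (PEF: depression) before a severe onset
    return {
        "dyspnea": 1.0,
        "cough": 1.0,
        "sputum": 1.0,
        "nocturnal": 1.0,
        "salbutamol": 1.0,
        "pef": 10.0,
    }


@dataclasses.dataclass
class EpisodeShape:
    """Stereotyped latent episode course.

    ramp_start_day:  days before onset at which symptoms begin rising.
    sharp_rise_day:  days before onset at which the rise accelerates.
    sharp_rise_frac: fraction of the peak reached when the sharp rise starts.
    peak_amplitude:  latent units added at the onset-day peak, per signal
                     (PEF amplitude is applied as a decrement).
    recovery_weeks:  per signal, the week in which the mean course is back
                     at baseline; the bump decays to exactly zero at the
                     start of that week (day ``7 * (recovery_weeks - 1)``).
    """

    ramp_start_day: int = 14
    sharp_rise_day: int = 7
    sharp_rise_frac: float = 1.0 / 3.0
    peak_amplitude: dict[str, float] = dataclasses.field(default_factory=_default_amplitudes)
    recovery_weeks: dict[str, int] = dataclasses.field(default_factory=_default_recovery_weeks)

    def __post_init__(self) -> None:
        if not self.ramp_start_day >= self.sharp_rise_day >= 1:
            raise ValidationError("need ramp_start_day >= sharp_rise_day >= 1")
        if any(a < 0 for a in self.peak_amplitude.values()):
            raise ValidationError("peak amplitudes must be >= 0")
        if any(w < 1 for w in self.recovery_weeks.values()):
            raise ValidationError("recovery_weeks must be >= 1")


def bump_profile(rel_days, shape: EpisodeShape, recovery_weeks: int) -> np.ndarray:
    """Fraction of the peak amplitude at each day relative to onset (day 0).

    Zero before ``-ramp_start_day``; linear rise to ``sharp_rise_frac`` at
    ``-sharp_rise_day``; steeper linear rise to 1 at day 0; square-root
    decay reaching exactly zero at day ``7 * (recovery_weeks - 1)`` so the
    course is flat from the configured recovery week onward.
    """
    d = np.asarray(rel_days, dtype=float)
    f = np.zeros_like(d)
    ramp, sharp, frac = shape.ramp_start_day, shape.sharp_rise_day, shape.sharp_rise_frac
    pre1 = (d >= -ramp) & (d < -sharp)
    if ramp > sharp:
        f[pre1] = frac * (d[pre1] + ramp) / (ramp - sharp)
    pre2 = (d >= -sharp) & (d <= 0)
    f[pre2] = frac + (1.0 - frac) * (d[pre2] + sharp) / sharp
    decay_len = 7 * (recovery_weeks - 1)
    if decay_len > 0:
        post = (d > 0) & (d < decay_len)
        f[post] = np.sqrt(1.0 - d[post] / decay_len)
    return f


@dataclasses.dataclass
class CohortParams:
    """Study conditions for one simulated cohort.

    Baseline means reflect the stable-phase weekly averages of a moderate
    to severe COPD trial population (symptom scores around 1.1-1.5, near
    zero for nocturnal awakening, PEF ~279 l/min, ~1.5 salbutamol puffs per
    day).  In hazard mode, ``h0`` is the daily baseline onset hazard
    (default 0.004/day, about 1.5 exacerbations per patient-year) and
    ``beta_true`` the log relative risk per point of window score.
    Episode durations are log-normal with a 10-day median for moderate
    episodes and a 1.62-fold longer severe median (matching 18.6 vs 11.5
    day geometric means).
    """

    n_patients: int = 150
    followup_days: int = 365
    mode: str = "shape"
    shape: EpisodeShape = dataclasses.field(default_factory=EpisodeShape)
    baseline_mean: dict[str, float] = dataclasses.field(default_factory=_default_baseline_mean)
    baseline_sd: dict[str, float] = dataclasses.field(default_factory=_default_baseline_sd)
    noise_sd: dict[str, float] = dataclasses.field(default_factory=_default_noise_sd)
    missing_prob: float = 0.05
    noise_ar: float = 0.5
    amp_jitter_sd: float = 0.1

    # shape mode: scheduled episodes
    episodes_per_patient: int = 1
    first_onset_range: tuple[int, int] = (42, 84)
    episode_gap_days: int = 150
    severe_pre_amplitude: dict[str, float] = dataclasses.field(
        default_factory=_default_severe_pre_amplitude
    )

    # hazard mode: onsets caused by recent symptom change
    h0: float = 0.004
    beta_true: float = 0.5
    refractory_days: int = 56
    block_refractory: bool = True
    max_episodes: int = 1

    # episode severity / duration
    severity_prob: float = 0.09
    duration_median_days: float = 10.0
    duration_sigma_log: float = 0.55
    duration_patient_sd: float = 0.3
    severe_duration_multiplier: float = 1.62

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.mode not in ("shape", "hazard"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        for name in ("missing_prob", "severity_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValidationError("noise_ar must be in [0, 1)")
        if self.h0 <= 0:
            raise ValidationError("h0 must be > 0")
        if self.followup_days < 1:
            raise ValidationError("followup_days must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortParams":
        d = dict(d)
        shape_d = d.pop("shape", None)
        params = cls(**d) if shape_d is None else cls(shape=EpisodeShape(**shape_d), **d)
        return params


@dataclasses.dataclass
class SimulatedCohort:
    diary: pd.DataFrame
    episodes: pd.DataFrame
    patients: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _ar1_noise(rng, rho: float, sd: float, n: int, t_max: int) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` and lag-1 correlation ``rho``."""
    innov = rng.standard_normal((n, t_max))
    if rho == 0.0:
        return sd * innov
    x = np.empty((n, t_max))
    x[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, t_max):
        x[:, t] = rho * x[:, t - 1] + scale * innov[:, t]
    return sd * x


def _observed_ordinals(latent: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Round-and-clamp latent symptom values onto their ordinal scales."""
    obs = {}
    for sig in ORDINAL_SIGNALS:
        obs[sig] = np.clip(np.round(latent[sig]), 0, SYMPTOM_SCALES[sig])
    return obs


def _masked_total(observed: dict[str, np.ndarray], missing: np.ndarray) -> np.ndarray:
    total = sum(observed[sig] for sig in ORDINAL_SIGNALS)
    return np.where(missing, np.nan, total)


def _draw_durations(
    rng, severe: np.ndarray, p: CohortParams, patient_log_re: np.ndarray
) -> np.ndarray:
    """Log-normal episode durations with a patient-level random intercept."""
    mu = (
        np.log(p.duration_median_days)
        + np.where(severe, np.log(p.severe_duration_multiplier), 0.0)
        + patient_log_re
    )
    dur = np.exp(rng.normal(mu, p.duration_sigma_log))
    return np.clip(np.round(dur), 2, 119).astype(int)


def _add_episode_bumps(
    latent: dict[str, np.ndarray],
    episodes: list[dict],
    amp_mult: np.ndarray,
    p: CohortParams,
    post_only: bool = False,
) -> None:
    """Superimpose each episode's bump on the latent course, in place.

    With ``post_only`` (hazard mode) the bump is applied from the onset day
    onward only: the pre-onset rise must stay out of the latent course
    there, because the day-by-day onset draws have already conditioned on
    the diary as observed — a retroactive prodrome would decouple the
    realized onset hazard from the window score the analysis computes.  In
    hazard mode the pre-onset symptom rise emerges endogenously instead
    (onsets preferentially follow chance upward drifts).
    """
    t_days = np.arange(p.followup_days)
    for ep in episodes:
        i = ep["index"]
        rel = t_days - ep["onset_day"]
        for sig in SIGNALS:
            prof = bump_profile(rel, p.shape, p.shape.recovery_weeks[sig])
            amp = amp_mult[i] * p.shape.peak_amplitude[sig]
            if ep["severity"] == "severe" and not post_only:
                pre = (rel >= -p.shape.ramp_start_day) & (rel <= 0)
                extra = np.where(pre, p.severe_pre_amplitude[sig], 0.0)
            else:
                extra = 0.0
            delta = amp * prof + extra * (prof > 0)
            if post_only:
                delta = np.where(rel >= 0, delta, 0.0)
            if sig == "pef":
                latent[sig][i] -= delta
            else:
                latent[sig][i] += delta


def _simulate_patients(rng, p: CohortParams, ids: list[str]) -> pd.DataFrame:
    n = p.n_patients
    age = np.round(rng.normal(63.5, 7.8, n), 1)
    sex = np.where(rng.random(n) < 0.74, "male", "female")
    smoker = rng.random(n) < 0.37
    pack_years = np.round(np.clip(rng.normal(36.0, 18.0, n), 0, None), 1)
    fev1 = np.round(np.clip(rng.normal(47.8, 13.4, n), 15, 90), 1)
    ccq_domain_means = {"symptom": 2.2, "mental": 0.5, "functional": 1.7}
    item_domain = ["symptom", "symptom", "mental", "mental", "symptom", "symptom",
                   "functional", "functional", "functional", "functional"]
    ccq = {
        f"ccq{i + 1}": np.clip(
            np.round(rng.normal(ccq_domain_means[item_domain[i]], 1.0, n)), 0, 6
        )
        for i in range(10)
    }
    arm = np.where(rng.random(n) < 0.5, "salmeterol", "salmeterol_fluticasone")
    return pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "sex": sex,
            "current_smoker": smoker,
            "pack_years": pack_years,
            "fev1_pct_pred": fev1,
            **ccq,
            "arm": arm,
            "followup_days": p.followup_days,
        }
    )


def simulate_cohort(params: CohortParams, seed: int) -> SimulatedCohort:
    """Generate a diary panel, episode table, patient table and truth record.

    Reproducible: identical ``(params, seed)`` give identical outputs.  The
    truth record stores the generator parameters, per-patient baselines and
    amplitude multipliers, and the per-episode ground truth, and is JSON
    serializable.
    """
    p = params
    rng = np.random.default_rng(seed)
    n, t_max = p.n_patients, p.followup_days
    ids = [f"P{i + 1:04d}" for i in range(n)]

    patients = _simulate_patients(rng, p, ids)

    baselines = {
        sig: p.baseline_mean[sig] + p.baseline_sd[sig] * rng.standard_normal(n)
        for sig in SIGNALS
    }
    baselines["pef"] = np.clip(baselines["pef"], 60.0, None)
    # daily noise is a stationary AR(1): symptom series persist from day to
    # day, which is what gives the two-week change score a realistic spread
    latent = {
        sig: baselines[sig][:, None]
        + _ar1_noise(rng, p.noise_ar, p.noise_sd[sig], n, t_max)
        for sig in SIGNALS
    }
    missing = rng.random((n, t_max)) < p.missing_prob

    episodes: list[dict] = []
    amp_mult = np.exp(rng.normal(0.0, p.amp_jitter_sd, n))
    dur_log_re = rng.normal(0.0, p.duration_patient_sd, n)

    if p.mode == "shape":
        lo, hi = p.first_onset_range
        onsets = [rng.integers(lo, hi + 1, n)]
        for _ in range(p.episodes_per_patient - 1):
            onsets.append(onsets[-1] + p.episode_gap_days + rng.integers(-14, 15, n))
        for k in range(p.episodes_per_patient):
            severe = rng.random(n) < p.severity_prob
            dur = _draw_durations(rng, severe, p, dur_log_re)
            for i in range(n):
                if onsets[k][i] > t_max - 1:
                    continue
                end = min(onsets[k][i] + dur[i] - 1, t_max - 1)
                if k + 1 < p.episodes_per_patient:
                    end = min(end, onsets[k + 1][i] - 1)  # never overlap the next episode
                episodes.append(
                    {
                        "index": i,
                        "patient_id": ids[i],
                        "onset_day": int(onsets[k][i]),
                        "end_day": int(end),
                        "severity": "severe" if severe[i] else "moderate",
                    }
                )
        _add_episode_bumps(latent, episodes, amp_mult, p)
    else:  # hazard mode
        at_risk_from = np.zeros(n, dtype=int)
        done = np.zeros(n, dtype=bool)
        n_eps = np.zeros(n, dtype=int)
        for _ in range(p.max_episodes):
            observed = _observed_ordinals(latent)
            total = _masked_total(observed, missing)
            scores = window_scores_matrix(total)
            s = np.where(np.isnan(scores), 0.0, scores)
            prob = 1.0 - np.exp(-p.h0 * np.exp(p.beta_true * s))
            u = rng.random((n, t_max))
            hit = u < prob
            day_idx = np.arange(t_max)[None, :]
            hit &= day_idx >= at_risk_from[:, None]
            hit &= ~done[:, None]
            any_hit = hit.any(axis=1)
            onset = np.where(any_hit, hit.argmax(axis=1), -1)
            severe = rng.random(n) < p.severity_prob
            dur = _draw_durations(rng, severe, p, dur_log_re)
            new_eps = []
            for i in range(n):
                if not any_hit[i]:
                    done[i] = True
                    continue
                ep = {
                    "index": i,
                    "patient_id": ids[i],
                    "onset_day": int(onset[i]),
                    "end_day": int(min(onset[i] + dur[i] - 1, t_max - 1)),
                    "severity": "severe" if severe[i] else "moderate",
                }
                new_eps.append(ep)
                n_eps[i] += 1
                blocked_until = ep["end_day"] + 1
                if p.block_refractory:
                    blocked_until = max(blocked_until, onset[i] + p.refractory_days + 1)
                at_risk_from[i] = blocked_until
                if n_eps[i] >= p.max_episodes or blocked_until >= t_max:
                    done[i] = True
            if not new_eps:
                break
            episodes.extend(new_eps)
            _add_episode_bumps(latent, new_eps, amp_mult, p, post_only=True)

    # observed diary
    observed = _observed_ordinals(latent)
    salb = np.clip(np.round(latent["salbutamol"]), 0, 30)
    pef_attempts = (
        latent["pef"][:, :, None] + rng.normal(0.0, 8.0, (n, t_max, 3))
    )
    pef_attempts = np.clip(pef_attempts, 30.0, None)

    keep = ~missing
    pid_col = np.repeat(np.array(ids, dtype=object), t_max).reshape(n, t_max)
    diary = pd.DataFrame(
        {
            "patient_id": pid_col[keep],
            "day": np.tile(np.arange(t_max), (n, 1))[keep],
            "dyspnea": observed["dyspnea"][keep],
            "cough": observed["cough"][keep],
            "sputum": observed["sputum"][keep],
            "nocturnal": observed["nocturnal"][keep],
            "pef1": np.round(pef_attempts[:, :, 0][keep], 1),
            "pef2": np.round(pef_attempts[:, :, 1][keep], 1),
            "pef3": np.round(pef_attempts[:, :, 2][keep], 1),
            "salbutamol": salb[keep],
        }
    )
    episodes_df = pd.DataFrame(
        [
            {k: ep[k] for k in ("patient_id", "onset_day", "end_day", "severity")}
            for ep in episodes
        ],
        columns=["patient_id", "onset_day", "end_day", "severity"],
    )
    if len(episodes_df):
        episodes_df = episodes_df.sort_values(
            ["patient_id", "onset_day"]
        ).reset_index(drop=True)

    truth = {
        "seed": int(seed),
        "mode": p.mode,
        "parameters": {
            "beta_true": p.beta_true,
            "h0": p.h0,
            "duration_median_days": p.duration_median_days,
            "duration_patient_sd": p.duration_patient_sd,
            "severe_duration_multiplier": p.severe_duration_multiplier,
            **{f"recovery_weeks.{s}": p.shape.recovery_weeks[s] for s in SIGNALS},
            **{f"peak_amplitude.{s}": p.shape.peak_amplitude[s] for s in SIGNALS},
        },
        "patients": {
            ids[i]: {
                "amp_multiplier": float(amp_mult[i]),
                **{f"baseline.{s}": float(baselines[s][i]) for s in SIGNALS},
            }
            for i in range(n)
        },
        "episodes": [
            {k: ep[k] for k in ("patient_id", "onset_day", "end_day", "severity")}
            for ep in episodes
        ],
    }
    json.dumps(truth)  # guarantee serializability

    return SimulatedCohort(
        diary=validate_diary(diary),
        episodes=validate_episodes(episodes_df),
        patients=validate_patients(patients),
        truth=truth,
    )


def truth_recovery_report(truth: dict, estimates: pd.DataFrame) -> pd.DataFrame:
    """Compare downstream estimates against the generator's ground truth.

    ``estimates`` needs columns ``parameter`` and ``estimate``; optional
    ``ci_low``/``ci_high`` enable the coverage flag.  Parameters must exist
    in ``truth["parameters"]``.
    """
    required = {"parameter", "estimate"}
    if not required.issubset(estimates.columns):
        raise ValidationError(f"estimates table needs columns {sorted(required)}")
    true_vals = truth["parameters"]
    rows = []
    for _, r in estimates.iterrows():
        name = r["parameter"]
        if name not in true_vals:
            raise ValidationError(f"unknown truth parameter {name!r}")
        t = float(true_vals[name])
        est = float(r["estimate"])
        row = {"parameter": name, "truth": t, "estimate": est, "bias": est - t}
        if "ci_low" in estimates.columns and "ci_high" in estimates.columns:
            lo, hi = float(r["ci_low"]), float(r["ci_high"])
            row["ci_low"], row["ci_high"] = lo, hi
            row["covered"] = bool(lo <= t <= hi)
        rows.append(row)
    return pd.DataFrame(rows)
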