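"""Exacerbation-rate and episode-duration models.

Two standard longitudinal-trial analyses around the diary machinery:

* a Poisson regression of each patient's exacerbation count on baseline
  covariates with a log person-years offset, so coefficients are log annual
  rate ratios (the intercept-only fitted rate is exactly total events /
  total person-years);
* a linear mixed model on log-transformed episode durations with a patient
  random intercept (patients contribute several episodes), severity and
  baseline covariates as fixed effects.  Effects are reported on the
  multiplicative scale; covariates with a conventional step (pack-years)
  are additionally reported per step, e.g. exp(5 b) per 5 pack-years.

Model fitting is delegated to statsmodels (GLM with Poisson family,
MixedLM); this module owns the design construction, the CCQ handling and
the result contracts.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diary_model import DEFAULT_CCQ_DOMAINS, ValidationError

__all__ = [
    "RateModelFit",
    "DurationModelFit",
    "episode_exposure",
    "fit_rate_model",
    "fit_duration_model",
    "DEFAULT_RATE_COVARIATES",
    "DEFAULT_DURATION_COVARIATES",
]

DEFAULT_RATE_COVARIATES = ("fev1_pct_pred", "age", "sex", "current_smoker", "ccq")
DEFAULT_DURATION_COVARIATES = (
    "sex", "age", "current_smoker", "pack_years", "arm", "fev1_pct_pred"
)

DAYS_PER_YEAR = 365.25


@dataclasses.dataclass
class RateModelFit:
    """Poisson rate-model result on the annual-rate scale.

    ``table`` holds one row per model term: coefficient (log rate ratio),
    SE, rate ratio with Wald 95% CI and p-value.  ``pearson_dispersion`` is
    the Pearson chi-square over residual degrees of freedom (values well
    above 1 indicate overdispersion relative to the Poisson assumption).
    """

    table: pd.DataFrame
    deviance: float
    pearson_dispersion: float
    n_patients: int
    total_events: int
    total_person_years: float
    converged: bool
    selected_ccq_domain: str | None = None

    @property
    def fitted_annual_rate(self) -> float:
        """Intercept-implied annual rate (events per person-year)."""
        return float(np.exp(self.table.loc["intercept", "coef"]))


@dataclasses.dataclass
class DurationModelFit:
    """Mixed-model result for log episode durations.

    ``table`` lists fixed effects with multiplicative duration ratios;
    ``random_intercept_var`` is the between-patient variance on the log
    scale (0 when every patient contributes a single episode and the model
    degenerates to OLS).  Geometric means are empirical per severity class.
    """

    table: pd.DataFrame
    random_intercept_var: float
    geometric_mean_moderate: float
    geometric_mean_severe: float
    severity_ratio: float
    severity_ratio_ci: tuple[float, float]
    pack_years_step_ratio: float
    n_episodes: int
    n_patients: int
    converged: bool
    method: str


def episode_exposure(
    episodes: pd.DataFrame, patients: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Per-patient episode counts and person-years of follow-up."""
    counts = (
        episodes.groupby("patient_id").size()
        .reindex(patients["patient_id"], fill_value=0)
        .astype(int)
    )
    years = pd.Series(
        patients["followup_days"].to_numpy(dtype=float) / DAYS_PER_YEAR,
        index=patients["patient_id"],
    )
    return counts, years


def _covariate_columns(
    patients: pd.DataFrame, name: str, ccq: str
) -> dict[str, np.ndarray]:
    """Expand a covariate name into design columns."""
    if name == "sex":
        return {"sex_female": (patients["sex"] == "female").to_numpy(float)}
    if name == "current_smoker":
        return {"current_smoker": patients["current_smoker"].to_numpy(float)}
    if name == "arm":
        return {
            "arm_salmeterol": (patients["arm"] == "salmeterol").to_numpy(float)
        }
    if name == "ccq":
        items = patients[[f"ccq{i}" for i in range(1, 11)]].to_numpy(float)
        if ccq == "total":
            return {"ccq_total": items.mean(axis=1)}
        if ccq == "domains":
            return {
                f"ccq_{dom}": items[:, np.array(idx) - 1].mean(axis=1)
                for dom, idx in DEFAULT_CCQ_DOMAINS.items()
            }
        raise ValidationError(f"ccq must be 'total' or 'domains', got {ccq!r}")
    if name in patients.columns:
        return {name: patients[name].to_numpy(float)}
    raise ValidationError(f"unknown covariate {name!r}")


def _wald_table(names, coef, se) -> pd.DataFrame:
    from scipy import stats as sps

    z = sps.norm.ppf(0.975)
    with np.errstate(invalid="ignore", divide="ignore"):
        zval = coef / se
    return pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "ratio": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p": 2 * sps.norm.sf(np.abs(zval)),
        },
        index=pd.Index(names, name="term"),
    )


def fit_rate_model(
    patients: pd.DataFrame,
    event_counts: pd.Series | np.ndarray,
    exposure_years: pd.Series | np.ndarray,
    covariates: Sequence[str] = DEFAULT_RATE_COVARIATES,
    ccq: str = "total",
) -> RateModelFit:
    """Poisson regression of exacerbation counts with person-year offset.

    ``event_counts`` and ``exposure_years`` align with the patient table
    (by patient_id when given as Series).  ``ccq="total"`` enters the CCQ
    overall score; ``ccq="domains"`` fits the three domain means jointly
    and retains the smallest-p domain in a refit, reporting which domain
    survived.
    """
    counts = np.asarray(
        event_counts.reindex(patients["patient_id"])
        if isinstance(event_counts, pd.Series) else event_counts,
        dtype=float,
    )
    years = np.asarray(
        exposure_years.reindex(patients["patient_id"])
        if isinstance(exposure_years, pd.Series) else exposure_years,
        dtype=float,
    )
    if np.any(counts < 0) or np.any(~np.isfinite(counts)):
        raise ValidationError("event counts must be finite and >= 0")
    if np.any(years <= 0) or np.any(~np.isfinite(years)):
        raise ValidationError("exposure must be finite and > 0")

    def build_design(cov_list, ccq_mode):
        cols: dict[str, np.ndarray] = {}
        for name in cov_list:
            cols.update(_covariate_columns(patients, name, ccq_mode))
        x = pd.DataFrame({"intercept": np.ones(len(patients)), **cols})
        return x

    def glm_fit(x):
        model = sm.GLM(
            counts, x.to_numpy(), family=sm.families.Poisson(),
            offset=np.log(years),
        )
        return model.fit(maxiter=200, tol=1e-10)

    selected_domain = None
    x = build_design(covariates, ccq)
    res = glm_fit(x)
    if ccq == "domains" and "ccq" in covariates:
        # retain only the most significant domain, then refit
        dom_cols = [c for c in x.columns if c.startswith("ccq_")]
        pvals = pd.Series(res.pvalues, index=x.columns)[dom_cols]
        keep = pvals.idxmin()
        selected_domain = keep.removeprefix("ccq_")
        x = x.drop(columns=[c for c in dom_cols if c != keep])
        res = glm_fit(x)

    table = _wald_table(list(x.columns), np.asarray(res.params), np.asarray(res.bse))
    df_resid = max(len(patients) - x.shape[1], 1)
    return RateModelFit(
        table=table,
        deviance=float(res.deviance),
        pearson_dispersion=float(res.pearson_chi2) / df_resid,
        n_patients=len(patients),
        total_events=int(counts.sum()),
        total_person_years=float(years.sum()),
        converged=bool(res.converged),
        selected_ccq_domain=selected_domain,
    )


def fit_duration_model(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_DURATION_COVARIATES,
    pack_years_step: float = 5.0,
) -> DurationModelFit:
    """Mixed model for log episode duration with a patient random intercept.

    Durations are ``end_day - onset_day + 1`` (>= 1 by validation).  When
    no patient contributes more than one episode the random intercept is
    unidentifiable: the model falls back to OLS with the variance fixed at
    zero (with a warning).
    """
    if len(episodes) == 0:
        raise ValidationError("need at least one episode")
    df = episodes.merge(patients, on="patient_id", how="left", validate="m:1")
    if df[["age"]].isna().any().any():
        raise ValidationError("episodes reference patients missing from the table")
    duration = (df["end_day"] - df["onset_day"] + 1).to_numpy(float)
    y = np.log(duration)

    cols: dict[str, np.ndarray] = {"severe": (df["severity"] == "severe").to_numpy(float)}
    for name in covariates:
        cols.update(_covariate_columns(df, name, "total"))
    x = pd.DataFrame({"intercept": np.ones(len(df)), **cols})

    multi = (df.groupby("patient_id").size() > 1).any()
    method = "mixedlm"
    converged = True
    if multi:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = sm.MixedLM(y, x.to_numpy(), groups=df["patient_id"].to_numpy())
                mres = md.fit(reml=True, maxiter=200)
                coef = np.asarray(mres.fe_params)
                se = np.asarray(mres.bse_fe)
                re_var = float(np.asarray(mres.cov_re).ravel()[0])
                converged = bool(mres.converged)
            except Exception:
                multi = False
    if not multi:
        warnings.warn(
            "single episode per patient (or mixed fit failed): random-intercept "
            "variance fixed to 0, fitting OLS on log durations",
            stacklevel=2,
        )
        method = "ols"
        ores = sm.OLS(y, x.to_numpy()).fit()
        coef, se, re_var = np.asarray(ores.params), np.asarray(ores.bse), 0.0

    table = _wald_table(list(x.columns), coef, se)
    sev_row = table.loc["severe"]
    moderate = duration[df["severity"] == "moderate"]
    severe = duration[df["severity"] == "severe"]
    geo = lambda v: float(np.exp(np.mean(np.log(v)))) if len(v) else float("nan")
    py_ratio = (
        float(np.exp(pack_years_step * table.loc["pack_years", "coef"]))
        if "pack_years" in table.index else float("nan")
    )
    return DurationModelFit(
        table=table,
        random_intercept_var=re_var,
        geometric_mean_moderate=geo(moderate),
        geometric_mean_severe=geo(severe),
        severity_ratio=float(sev_row["ratio"]),
        severity_ratio_ci=(float(sev_row["ci_low"]), float(sev_row["ci_high"])),
        pack_years_step_ratio=py_ratio,
        n_episodes=len(df),
        n_patients=df["patient_id"].nunique(),
        converged=converged,
        method=method,
    )
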