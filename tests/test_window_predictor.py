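"""Window score, counting process and time-dependent Cox fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import exaflare as ex
from exaflare.diary_model import ValidationError
from exaflare.window_predictor import WindowConfig

from conftest import complete_diary


def brute_force_score(series: pd.Series, t: int, block: int = 7, min_days: int = 4):
    """Recompute both block means from scratch for one day.

    The full two-week window must lie inside the diary coverage (days
    before the first diary day are outside follow-up, not merely missing);
    within coverage, each block mean uses the available proper days,
    requiring at least ``min_days`` of them.
    """
    if t - 2 * block < series.index.min():
        return np.nan

    def block_mean(days):
        vals = [series[d] for d in days if d in series.index and np.isfinite(series[d])]
        return (np.mean(vals), len(vals)) if vals else (np.nan, 0)

    recent, n_r = block_mean(range(t - block, t))
    earlier, n_e = block_mean(range(t - 2 * block, t - block))
    if n_r < min_days or n_e < min_days:
        return np.nan
    return recent - earlier


class TestWindowScore:
    def test_worked_example_plus_three_at_day_115(self):
        series = pd.Series([10.0] * 7 + [13.0] * 7, index=range(101, 115))
        scores = ex.window_score_series(series)
        assert scores.loc[115] == pytest.approx(3.0)

    def test_constant_series_scores_zero(self):
        series = pd.Series(2.0, index=range(0, 60))
        scores = ex.window_score_series(series)
        defined = scores.dropna()
        assert len(defined) > 0
        assert (defined == 0.0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_gappy_series(self, seed):
        rng = np.random.default_rng(seed)
        days = np.sort(rng.choice(np.arange(60), size=45, replace=False))
        vals = rng.integers(0, 15, size=45).astype(float)
        vals[rng.random(45) < 0.15] = np.nan
        series = pd.Series(vals, index=days)
        scores = ex.window_score_series(series)
        for t in scores.index:
            expected = brute_force_score(series, int(t))
            got = scores.loc[t]
            assert (np.isnan(got) and np.isnan(expected)) or got == pytest.approx(expected)

    def test_no_lookahead(self):
        """Changing diary data at days >= t never changes score(t)."""
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 14, 60).astype(float)
        a = pd.Series(vals, index=range(60))
        b = a.copy()
        b.iloc[40:] = rng.integers(0, 14, 20).astype(float)
        sa, sb = ex.window_score_series(a), ex.window_score_series(b)
        pd.testing.assert_series_equal(sa.loc[:40], sb.loc[:40])

    def test_time_origin_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 14, 60).astype(float)
        base = pd.Series(vals, index=range(60))
        shifted = pd.Series(vals, index=range(1000, 1060))
        s0 = ex.window_score_series(base)
        s1 = ex.window_score_series(shifted)
        np.testing.assert_array_equal(s0.to_numpy(), s1.to_numpy())
        assert (s1.index == s0.index + 1000).all()

    def test_min_days_per_block(self):
        # recent block (days 7..13) with 3 proper days -> undefined; 4 -> defined
        earlier = {d: 1.0 for d in range(0, 7)}  # earlier block complete
        for days, expect_defined in (((7, 8, 13), False), ((7, 8, 9, 13), True)):
            series = pd.Series({**earlier, **{d: 2.0 for d in days}})
            score = ex.window_score_series(series).loc[14]
            if expect_defined:
                assert score == pytest.approx(1.0)
            else:
                assert np.isnan(score)

    def test_pef_orientation_flips_sign(self):
        series = pd.Series([300.0] * 7 + [280.0] * 7, index=range(14))
        raw = ex.window_score_series(series, WindowConfig(signal="pef",
                                                          orient_deteriorate_positive=False))
        oriented = ex.window_score_series(series, WindowConfig(signal="pef"))
        assert raw.loc[14] == pytest.approx(-20.0)
        assert oriented.loc[14] == pytest.approx(20.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            WindowConfig(block_length=7, min_days_per_block=8)


class TestCountingProcess:
    def test_onset_day_is_last_row_with_event(self):
        diary = complete_diary("a", range(0, 365))
        eps = pd.DataFrame(
            {"patient_id": ["a"], "onset_day": [40], "end_day": [50],
             "severity": ["moderate"]}
        )
        table = ex.build_counting_process(diary, eps)
        assert table["day"].max() == 40
        assert table.loc[table["day"] == 40, "event"].item() == 1
        assert table["event"].sum() == 1

    def test_no_episode_rows_span_defined_days(self):
        # diary days 1..99, follow-up 100: defined scores on days 15..99
        diary = complete_diary("a", range(1, 100))
        eps = pd.DataFrame(columns=["patient_id", "onset_day", "end_day", "severity"])
        followup = pd.Series({"a": 100})
        table = ex.build_counting_process(diary, eps, followup=followup)
        assert table["day"].tolist() == list(range(15, 100))
        assert (table["event"] == 0).all()

    def test_early_onset_contributes_no_event_row(self):
        diary = complete_diary("a", range(0, 200))
        eps = pd.DataFrame(
            {"patient_id": ["a"], "onset_day": [10], "end_day": [20],
             "severity": ["moderate"]}
        )
        with pytest.warns(UserWarning, match="no event row"):
            table = ex.build_counting_process(diary, eps)
        assert table["event"].sum() == 0
        assert table.attrs["events_dropped"] == ["a"]

    def test_event_conservation_on_synthetic_cohort(self, hazard_cohort, counting_table):
        first = hazard_cohort.episodes.groupby("patient_id")["onset_day"].min()
        dropped = set(counting_table.attrs["events_dropped"])
        expected = len(first) - len(dropped)
        assert counting_table["event"].sum() == expected
        # at most one event row per patient, none after the first onset
        per_patient = counting_table.groupby("patient_id")["event"].sum()
        assert per_patient.le(1).all()
        last_day = counting_table.groupby("patient_id")["day"].max()
        for pid, onset in first.items():
            if pid in last_day.index and pid not in dropped:
                assert last_day[pid] == onset


class TestTimeDependentCox:
    @staticmethod
    def small_table():
        """Three patients, two informative event days (finite, nontrivial MLE)."""
        rows = [
            ("a", 4, 1.0, 1), ("b", 4, 0.0, 0), ("c", 4, 0.5, 0),
            ("b", 8, 0.7, 0), ("c", 8, 0.2, 1),
        ]
        return pd.DataFrame(rows, columns=["patient_id", "day", "score", "event"])

    def test_matches_direct_partial_likelihood_maximization(self):
        table = self.small_table()

        def neg_loglik(beta):
            t1 = beta * 1.0 - np.log(np.exp(beta * 1.0) + np.exp(0.0) + np.exp(0.5 * beta))
            t2 = beta * 0.2 - np.log(np.exp(0.7 * beta) + np.exp(0.2 * beta))
            return -(t1 + t2)

        direct = optimize.minimize_scalar(neg_loglik, bounds=(-10, 10), method="bounded",
                                          options={"xatol": 1e-12})
        fit = ex.fit_td_cox(table)
        assert fit.beta[0] == pytest.approx(direct.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-direct.fun, abs=1e-9)

    def test_tied_two_patient_score_equation_root_is_zero(self):
        # two events on one day with scores 1 and 0: Breslow MLE is exactly 0
        rows = [("a", 5, 1.0, 1), ("b", 5, 0.0, 1)]
        table = pd.DataFrame(rows, columns=["patient_id", "day", "score", "event"])
        fit = ex.fit_td_cox(table)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)

    def test_constant_scores_flagged_non_identifiable(self):
        rows = [("a", 4, 1.0, 1), ("b", 4, 1.0, 0), ("b", 8, 1.0, 1)]
        table = pd.DataFrame(rows, columns=["patient_id", "day", "score", "event"])
        fit = ex.fit_td_cox(table)
        assert not fit.identifiable
        assert fit.beta[0] == 0.0
        assert np.isnan(fit.se[0])

    def test_no_events_rejected(self):
        rows = [("a", 4, 1.0, 0), ("b", 4, 0.0, 0)]
        table = pd.DataFrame(rows, columns=["patient_id", "day", "score", "event"])
        with pytest.raises(ValidationError):
            ex.fit_td_cox(table)

    def test_loglik_at_maximum_not_below_null(self, counting_table):
        fit = ex.fit_td_cox(counting_table)
        assert fit.converged
        assert fit.loglik >= fit.loglik_null

    def test_agrees_with_lifelines_under_efron_ties(self, counting_table):
        lifelines = pytest.importorskip("lifelines")
        fit = ex.fit_td_cox(counting_table, ties="efron")
        df = counting_table.copy()
        df["start"] = df["day"] - 0.5
        df["stop"] = df["day"].astype(float)
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df[["patient_id", "start", "stop", "score", "event"]],
                id_col="patient_id", start_col="start", stop_col="stop",
                event_col="event")
        assert fit.beta[0] == pytest.approx(ctv.params_["score"], abs=1e-6)
        assert fit.se[0] == pytest.approx(ctv.standard_errors_["score"], abs=1e-6)

    def test_breslow_and_efron_close_with_light_ties(self, counting_table):
        b = ex.fit_td_cox(counting_table, ties="breslow")
        e = ex.fit_td_cox(counting_table, ties="efron")
        assert b.beta[0] == pytest.approx(e.beta[0], rel=0.05)

    def test_time_shift_leaves_fit_unchanged(self, hazard_cohort, counting_table):
        import warnings

        diary = hazard_cohort.diary.copy()
        diary["day"] += 500
        eps = hazard_cohort.episodes.copy()
        eps[["onset_day", "end_day"]] += 500
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shifted = ex.build_counting_process(diary, eps)
        fit0 = ex.fit_td_cox(counting_table)
        fit1 = ex.fit_td_cox(shifted)
        assert fit1.beta[0] == pytest.approx(fit0.beta[0], abs=1e-10)


class TestChangeBins:
    def test_default_bins_and_labels(self, counting_table):
        fit = ex.rr_by_change_bin(counting_table)
        assert fit.names == ["bin[1-2]", "bin[2-3]", "bin[>3]"]
        assert ex.DEFAULT_CHANGE_BINS == (1.0, 2.0, 3.0)

    def test_two_bin_fit_equals_binary_covariate_fit(self, counting_table):
        binned = ex.rr_by_change_bin(counting_table, bins=(1.0,))
        manual = counting_table.copy()
        manual["above"] = (manual["score"] >= 1.0).astype(float)
        direct = ex.fit_td_cox(manual, covariates=("above",))
        assert binned.beta[0] == pytest.approx(direct.beta[0], abs=1e-8)
        assert binned.se[0] == pytest.approx(direct.se[0], abs=1e-8)

    def test_empty_bin_reported_nan(self, counting_table):
        capped = counting_table.copy()
        capped["score"] = capped["score"].clip(upper=2.5)
        with pytest.warns(UserWarning, match="empty"):
            fit = ex.rr_by_change_bin(capped)
        assert np.isnan(fit.rr[-1])
        assert np.isfinite(fit.rr[:-1]).all()

    def test_bin_rrs_nondecreasing_under_positive_effect(self):
        """With a monotone true effect, estimated bin RRs order correctly."""
        import warnings

        ok = 0
        n_rep = 100
        for r in range(n_rep):
            params = ex.CohortParams(
                mode="hazard", n_patients=500, followup_days=365, beta_true=1.0
            )
            cohort = ex.simulate_cohort(params, seed=3000 + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = ex.build_counting_process(cohort.diary, cohort.episodes)
            fit = ex.rr_by_change_bin(table)
            rr = np.concatenate([[1.0], fit.rr])
            rr = rr[np.isfinite(rr)]
            ok += int(np.all(np.diff(rr) >= 0))
        assert ok / n_rep >= 0.90


class TestReferenceBand:
    def test_constant_scores_collapse_band(self):
        rows = [("a", d, 1.5, 0) for d in range(20, 25)] + \
               [("b", d, 1.5, 0) for d in range(20, 25)]
        table = pd.DataFrame(rows, columns=["patient_id", "day", "score", "event"])
        band, events = ex.reference_band(table)
        assert (band["lower"] == 1.5).all()
        assert (band["upper"] == 1.5).all()
        assert events.empty

    def test_single_patient_day_band_undefined(self):
        rows = [("a", 20, 1.0, 0), ("a", 21, 1.0, 0), ("b", 21, 2.0, 0)]
        table = pd.DataFrame(rows, columns=["patient_id", "day", "score", "event"])
        band, _ = ex.reference_band(table)
        day20 = band.set_index("day").loc[20]
        assert np.isnan(day20["lower"])

    def test_gaussian_scores_give_95pct_coverage(self):
        rng = np.random.default_rng(8)
        n = 10_000
        days = np.repeat(np.arange(100), n // 100)
        scores = rng.standard_normal(n)
        table = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n)], "day": days,
             "score": scores, "event": 0}
        )
        band, _ = ex.reference_band(table)
        merged = table.merge(band, on="day")
        inside = ((merged["score"] >= merged["lower"])
                  & (merged["score"] <= merged["upper"])).mean()
        se = np.sqrt(0.954 * 0.046 / n)
        assert abs(inside - 0.954) < 4 * se
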