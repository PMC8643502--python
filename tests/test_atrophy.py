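import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from diaschisis import atrophy
from diaschisis.atrophy import (
    ReferenceFit,
    bonferroni_level,
    call_atrophic_areas,
    fit_all_reference_areas,
    fit_reference_model,
    prediction_band,
    reference_area_change_tests,
    sweep_pi_levels,
    zscore_standardize,
)

from conftest import make_volume_table


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class TestZScores:
    def test_known_baselines(self, tiny_area_table):
        """Baselines {8,10,12} ml: mean 10, sample SD 2, so 8 ml is z=-1 and
        a follow-up of 6 ml is z=-2, i.e. z_change=-1."""
        z = zscore_standardize(tiny_area_table)
        s0 = z[(z.subject_id == "s0")].sort_values("time_months")
        assert s0["z"].to_numpy() == pytest.approx([-1.0, -2.0])
        assert s0["z_change"].to_numpy() == pytest.approx([0.0, -1.0])

    def test_baseline_mean_zero_sd_one(self, default_zscores):
        base = default_zscores[default_zscores.time_months == 0]
        stats = base.groupby("area_label")["z"].agg(["mean", "std"])
        assert np.allclose(stats["mean"], 0.0, atol=1e-9)
        assert np.allclose(stats["std"], 1.0, atol=1e-9)

    def test_zero_baseline_variance_rejected(self, tiny_area_table):
        flat = tiny_area_table.copy()
        flat.loc[flat.time_months == 0, "volume_ml"] = 10.0
        with pytest.raises(ValueError, match="zero baseline variance"):
            zscore_standardize(flat)

    def test_missing_baseline_rejected(self, tiny_area_table):
        broken = tiny_area_table[
            ~((tiny_area_table.subject_id == "s1") & (tiny_area_table.time_months == 0))
        ]
        with pytest.raises(ValueError, match="baseline"):
            zscore_standardize(broken)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_standardization_invariant_random_tables(self, seed):
        """Property: per-area baseline z-scores have mean 0 and SD 1."""
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(rng.integers(3, 8)):
            sub = f"s{i}"
            v0 = rng.uniform(5, 15)
            rows.append((sub, f"{sub}_L", "target", "frontal", "A", 0.0, v0))
            rows.append((sub, f"{sub}_L", "target", "frontal", "A", 3.0,
                         v0 + rng.normal()))
        table = make_volume_table(rows)
        if table[table.time_months == 0]["volume_ml"].nunique() == 1:
            return
        z = zscore_standardize(table)
        base = z[z.time_months == 0]["z"]
        assert base.mean() == pytest.approx(0.0, abs=1e-9)
        assert base.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# reference model
# ---------------------------------------------------------------------------

def _zchange_frame(subjects, times, values):
    return pd.DataFrame(
        {"subject_id": subjects, "time_months": times, "z_change": values}
    )


class TestReferenceModel:
    def test_single_observation_exact_interpolation(self):
        fit = fit_reference_model(_zchange_frame(["a"], [2.0], [-0.4]), "A")
        assert fit.beta == pytest.approx(-0.2)
        assert fit.sigma_b == 0.0 and fit.sigma_e == 0.0
        assert fit.degenerate

    def test_noise_free_data_recovers_slope_with_zero_variances(self):
        t = np.array([1.0, 2.0, 3.0, 1.5, 4.0, 6.0])
        fit = fit_reference_model(
            _zchange_frame(["a", "a", "b", "b", "c", "c"], t, -0.1 * t), "A"
        )
        assert fit.beta == pytest.approx(-0.1, abs=1e-12)
        assert fit.sigma_b == 0.0 and fit.sigma_e == 0.0
        assert not fit.degenerate

    def test_no_followups_rejected(self):
        with pytest.raises(ValueError, match="no follow-up"):
            fit_reference_model(_zchange_frame(["a"], [0.0], [0.0]), "A")

    def test_matches_closed_form_wls_when_single_followup(self):
        """Balanced single follow-up: the mixed fit equals the closed-form
        no-intercept least-squares slope (variance ratio unidentifiable,
        resolved to zero)."""
        rng = np.random.default_rng(7)
        n = 30
        t = np.full(n, 4.0)
        y = -0.05 * t + rng.normal(0, 0.3, n)
        fit = fit_reference_model(
            _zchange_frame([f"s{i}" for i in range(n)], t, y), "A"
        )
        beta_wls = float(t @ y / (t @ t))
        assert fit.beta == pytest.approx(beta_wls, abs=1e-6)
        assert fit.sigma_b == pytest.approx(0.0, abs=1e-8)

    def test_against_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM (ML) on the same
        no-intercept random-slope model; our profiled optimum must be at
        least as good in log-likelihood and agree on the parameters."""
        rng = np.random.default_rng(21)
        n_sub, beta, sb, se = 80, -0.05, 0.05, 0.2
        rows = []
        for i in range(n_sub):
            b = rng.normal(0, sb)
            for t in rng.uniform(1, 10, rng.integers(2, 4)):
                rows.append((f"s{i}", t, (beta + b) * t + rng.normal(0, se)))
        df = pd.DataFrame(rows, columns=["subject_id", "time_months", "z_change"])
        fit = fit_reference_model(df, "A")

        exog = df["time_months"].to_numpy()[:, None]
        m = sm.MixedLM(
            df["z_change"].to_numpy(), exog, groups=df["subject_id"], exog_re=exog
        )
        res = m.fit(reml=False)
        assert fit.beta == pytest.approx(float(res.fe_params[0]), abs=2e-3)
        sigma_b_sm = math.sqrt(float(np.asarray(res.cov_re)[0, 0]))
        sigma_e_sm = math.sqrt(res.scale)
        assert fit.sigma_b == pytest.approx(sigma_b_sm, abs=0.01)
        assert fit.sigma_e == pytest.approx(sigma_e_sm, abs=0.01)

        # our likelihood at the optimum is not beaten by the oracle's
        groups = [np.flatnonzero(df.subject_id == f"s{i}") for i in range(n_sub)]
        gamma_sm = (sigma_b_sm / sigma_e_sm) ** 2
        ll_sm = atrophy._profile_loglik(
            gamma_sm, df.z_change.to_numpy(), exog, exog[:, 0], groups
        )
        gamma_own = (fit.sigma_b / fit.sigma_e) ** 2
        ll_own = atrophy._profile_loglik(
            gamma_own, df.z_change.to_numpy(), exog, exog[:, 0], groups
        )
        assert ll_own >= ll_sm - 1e-6

    def test_simulation_recovery_unbiased(self):
        """beta, sigma_b, sigma_e recovered without bias (30 replicates,
        mean within 3 MC SEs of truth)."""
        truth = dict(beta=-0.05, sb=0.02, se=0.1)
        est = []
        rng = np.random.default_rng(5)
        for _ in range(30):
            rows = []
            for i in range(200):
                b = rng.normal(0, truth["sb"])
                for t in rng.uniform(1, 12, rng.integers(1, 4)):
                    rows.append(
                        (f"s{i}", t, (truth["beta"] + b) * t + rng.normal(0, truth["se"]))
                    )
            df = pd.DataFrame(rows, columns=["subject_id", "time_months", "z_change"])
            f = fit_reference_model(df, "A")
            est.append((f.beta, f.sigma_b, f.sigma_e))
        est = np.array(est)
        for k, target in enumerate([truth["beta"], truth["sb"], truth["se"]]):
            mc_se = est[:, k].std(ddof=1) / math.sqrt(len(est))
            assert abs(est[:, k].mean() - target) < 3 * mc_se + 1e-4


# ---------------------------------------------------------------------------
# Bonferroni and bands
# ---------------------------------------------------------------------------

class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,coverage,threshold",
        [
            (0.05, 36, 0.9986111111111111, 0.05 / 36),
            (0.05, 20, 0.9975, 0.0025),
            (0.05, 1, 0.95, 0.05),
        ],
    )
    def test_known_values(self, alpha, m, coverage, threshold):
        cov, thr = bonferroni_level(alpha, m)
        assert cov == pytest.approx(coverage, abs=1e-12)
        assert thr == pytest.approx(threshold, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_level(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_level(1.5, 10)


def _plain_fit(beta=0.0, se_beta=0.0, sigma_b=0.0, sigma_e=1.0, subjects=()):
    return ReferenceFit(
        "A", beta, se_beta, sigma_b, sigma_e,
        {s: 0.0 for s in subjects}, {s: sigma_b**2 for s in subjects},
        n_obs=10, n_subjects=max(len(subjects), 1),
        quantile_family="normal",
    )


class TestPredictionBand:
    def test_collapses_without_variance(self):
        fit = _plain_fit(beta=-0.1, sigma_e=0.0)
        band = prediction_band(fit, 5.0, 0.95)
        assert band.lower == band.center == band.upper == pytest.approx(-0.5)

    def test_normal_quantile_limits(self):
        band = prediction_band(_plain_fit(), 1.0, 0.95)
        assert band.upper == pytest.approx(1.959964, abs=1e-5)
        assert band.lower == pytest.approx(-1.959964, abs=1e-5)

    def test_t_quantile_wider_than_normal(self):
        fit = _plain_fit()
        fit.quantile_family = "t"
        fit.df_resid = 19.0
        t_band = prediction_band(fit, 1.0, 0.95)
        assert t_band.upper > 1.959964

    def test_conditional_equals_marginal_when_no_random_slope(self):
        fit = _plain_fit(beta=-0.05, sigma_b=0.0, sigma_e=0.3, subjects=["a"])
        for t in (1.0, 4.0, 9.0):
            marg = prediction_band(fit, t, 0.99, mode="marginal")
            cond = prediction_band(fit, t, 0.99, mode="conditional", subject_id="a")
            assert marg.lower == pytest.approx(cond.lower)
            assert marg.upper == pytest.approx(cond.upper)

    def test_conditional_requires_subject(self):
        with pytest.raises(ValueError, match="subject"):
            prediction_band(_plain_fit(), 1.0, 0.95, mode="conditional")

    @settings(deadline=None, max_examples=40)
    @given(
        level=st.floats(min_value=0.5, max_value=0.999),
        t1=st.floats(min_value=0.1, max_value=20.0),
        dt=st.floats(min_value=0.01, max_value=10.0),
    )
    def test_band_width_monotone(self, level, t1, dt):
        """Width grows with coverage level and with time when sigma_e > 0."""
        fit = _plain_fit(beta=-0.02, se_beta=0.01, sigma_b=0.05, sigma_e=0.2)
        b1 = prediction_band(fit, t1, level)
        b2 = prediction_band(fit, t1 + dt, level)
        assert (b2.upper - b2.lower) >= (b1.upper - b1.lower)
        higher = prediction_band(fit, t1, level + (1 - level) / 2)
        assert (higher.upper - higher.lower) > (b1.upper - b1.lower)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _two_dataset_table(change_a, change_b):
    """Two unilateral datasets, one area, known z-changes at t=2."""
    rows = []
    for i, (sub, last) in enumerate([("s0", change_a), ("s1", change_b)]):
        for role in ("target", "reference"):
            v0 = 10.0 + 2.0 * i
            rows.append((sub, f"{sub}_L", role, "frontal", "G_front_sup", 0.0, v0))
            dv = last if role == "target" else 0.0
            rows.append((sub, f"{sub}_L", role, "frontal", "G_front_sup", 2.0, v0 + dv))
    return make_volume_table(rows)


class TestCalling:
    def test_strictly_beneath_rule(self):
        """Observed change exactly on the lower limit is not atrophic;
        any amount beneath it is."""
        from scipy import stats as sps

        fits = {"G_front_sup": _plain_fit(beta=0.0, sigma_e=0.5, subjects=["s0", "s1"])}
        z = zscore_standardize(_two_dataset_table(-1.0, 0.0))
        lower = -float(sps.norm.ppf(0.975)) * 0.5
        table = z.copy()
        for value, expect in [(lower, False), (lower - 0.01, True)]:
            table.loc[
                (table.role == "target") & (table.time_months > 0), "z_change"
            ] = value
            calls = call_atrophic_areas(table, fits, 0.95)
            assert bool(calls.calls.is_atrophic.all()) is expect

    def test_missing_homologous_fit_rejected(self, default_zscores):
        with pytest.raises(ValueError, match="no homologous reference fit"):
            call_atrophic_areas(default_zscores, {}, 0.95)

    def test_bilateral_datasets_use_marginal_mode(self, default_zscores):
        fits = fit_all_reference_areas(default_zscores)
        calls = call_atrophic_areas(default_zscores, fits, 0.9986)
        modes = calls.calls.groupby("dataset_id")["mode"].first()
        ref_ids = set(
            default_zscores[default_zscores.role == "reference"]["dataset_id"]
        )
        for ds, mode in modes.items():
            assert mode == ("conditional" if ds in ref_ids else "marginal")

    def test_recovers_injected_areas(self):
        """Strong injected atrophy (-4 z) is flagged exactly; clean areas
        are (almost) never flagged."""
        from diaschisis import CohortConfig, generate_cohort

        hits = trials = fp = 0
        for seed in range(5):
            cfg = CohortConfig(seed=100 + seed, atrophy_effect=-4.0)
            data = generate_cohort(cfg)
            z = zscore_standardize(data.volumes)
            fits = fit_all_reference_areas(z)
            level, _ = bonferroni_level(0.05, 36)
            calls = call_atrophic_areas(z, fits, level)
            truth = {k: set(v) for k, v in
                     data.ground_truth.atrophic_area_labels.items()}
            flagged = {
                d: set(g[g.is_atrophic].area_label)
                for d, g in calls.calls.groupby("dataset_id")
            }
            for d in truth:
                trials += 1
                hits += truth[d] <= flagged[d]
                fp += len(flagged[d] - truth[d])
        assert hits / trials >= 0.95
        assert fp / trials < 0.5

    def test_sweep_counts_monotone_in_level(self, default_zscores):
        fits = fit_all_reference_areas(default_zscores)
        sweep = sweep_pi_levels(default_zscores, fits, m=36)
        assert set(sweep) == {0.95, 0.90, 0.80, 0.70, 0.60, 0.50}
        counts = {lvl: cs.n_atrophic for lvl, cs in sweep.items()}
        levels = sorted(counts)
        for lo, hi in zip(levels, levels[1:]):
            assert (counts[lo] >= counts[hi]).all()

    def test_single_level_sweep_matches_direct_call(self, default_zscores):
        fits = fit_all_reference_areas(default_zscores)
        level, _ = bonferroni_level(0.05, 36)
        direct = call_atrophic_areas(
            default_zscores, fits, level, level_nominal=0.95, m=36
        )
        swept = sweep_pi_levels(default_zscores, fits, m=36, alpha_levels=[0.95])
        pd.testing.assert_frame_equal(direct.calls, swept[0.95].calls)


# ---------------------------------------------------------------------------
# reference-area change tests
# ---------------------------------------------------------------------------

class TestReferenceChangeTests:
    def test_strong_common_slope_all_significant(self):
        rng = np.random.default_rng(3)
        rows = []
        for area in ("A", "B"):
            for i in range(50):
                t = float(rng.uniform(2, 10))
                v0 = 10 + rng.normal()
                rows.append((f"s{i}", f"s{i}_L", "reference", "frontal", area, 0.0, v0))
                rows.append(
                    (f"s{i}", f"s{i}_L", "reference", "frontal", area, t,
                     v0 + (-0.5 * t + rng.normal(0, 0.05)))
                )
            # a second follow-up for a few subjects to identify the variances
            for i in range(3):
                rows.append(
                    (f"s{i}", f"s{i}_L", "reference", "frontal", area, 12.0,
                     rows[-1][-1]))
        z = zscore_standardize(make_volume_table(rows))
        res = reference_area_change_tests(z, alpha=0.05)
        assert (res["p_slope"] < 0.05 / 50).all()

    def test_single_followup_per_subject_is_degenerate(self):
        rows = []
        for i in range(10):
            rows.append((f"s{i}", f"s{i}_L", "reference", "frontal", "A", 0.0,
                         10 + 0.1 * i))
            rows.append((f"s{i}", f"s{i}_L", "reference", "frontal", "A", 3.0,
                         10 + 0.1 * i - 0.2))
        z = zscore_standardize(make_volume_table(rows))
        res = reference_area_change_tests(z)
        assert res["degenerate"].all()
        assert res["p_slope"].isna().all()

    def test_null_false_positive_rate_controlled(self):
        """No real slope, Bonferroni threshold: significant areas are rare."""
        from diaschisis import CohortConfig, generate_cohort

        n_sig = 0
        n_areas = 0
        for seed in range(8):
            cfg = CohortConfig(seed=500 + seed, atrophic_area_fraction=0.0,
                               reference_slope=0.0)
            data = generate_cohort(cfg)
            z = zscore_standardize(data.volumes)
            res = reference_area_change_tests(z, alpha=0.05)
            valid = res[~res.degenerate]
            n_sig += int(valid["slope_significant"].sum())
            n_areas += len(valid)
        # expected ~alpha/m per area; allow generous slack at small n
        assert n_sig <= max(3, 0.01 * n_areas)
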