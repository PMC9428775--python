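"""Mixed-model path estimation, mediator gating and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actimediate.mediation import (
    AnalysisSpec,
    PathEstimate,
    RankDeficientError,
    bootstrap_indirect,
    fit_a_path,
    fit_lmm,
    fit_outcome_model,
    fit_total_effect,
    gate_mediators,
)
from actimediate.synthetic import TrialConfig, simulate_analysis_table

from helpers import exact_mediation_data as _exact_mediation_data


def _flat_data(seed, n_sch=12, per=12, arm_effect=2.0, noise=3.0):
    """Clustered layout with truly zero between-school variance."""
    rng = np.random.default_rng(seed)
    n = n_sch * per
    df = pd.DataFrame(
        {
            "school_id": np.repeat([f"S{k}" for k in range(n_sch)], per),
            "arm": np.repeat(np.arange(n_sch) % 2, per),
            "x": rng.normal(0, 1, n),
        }
    )
    df["y"] = arm_effect * df["arm"] + 0.5 * df["x"] + rng.normal(0, noise, n)
    return df


class TestFitLmm:
    def test_boundary_variance_falls_back_to_ols(self):
        # seed chosen so the REML school-variance estimate hits zero
        for seed in range(20):
            df = _flat_data(seed)
            fits = fit_lmm(df, "y", ["arm", "x"], cluster="school_id")
            if not fits["arm"].converged:
                break
        else:
            pytest.fail("no boundary fit found in 20 seeds")
        ols = sm.OLS(df["y"], sm.add_constant(df[["arm", "x"]])).fit()
        assert fits["arm"].coefficient == pytest.approx(ols.params["arm"], abs=1e-6)
        assert fits["arm"].cluster_var_estimate == 0.0

    def test_outcome_constant_across_arms_gives_zero_effect(self):
        df = _flat_data(1)
        df["y"] = 0.5 * df["x"] + 3.0  # no arm term, no noise
        fits = fit_lmm(df, "y", ["arm", "x"], cluster="school_id")
        assert fits["arm"].coefficient == pytest.approx(0.0, abs=1e-8)

    def test_recovers_arm_effect_across_simulated_trials(self):
        # 100 clustered replicates with true effect 2.0 and school sd > 0
        estimates = []
        for k in range(100):
            rng = np.random.default_rng(5000 + k)
            n_sch, per = 18, 12
            u = rng.normal(0, 3.0, n_sch)
            df = pd.DataFrame(
                {
                    "school_id": np.repeat(np.arange(n_sch), per),
                    "arm": np.repeat(np.arange(n_sch) % 2, per),
                }
            )
            df["y"] = 2.0 * df["arm"] + u[df["school_id"]] + rng.normal(0, 4.0, len(df))
            fits = fit_lmm(df, "y", ["arm"], cluster="school_id")
            estimates.append(fits["arm"].coefficient)
        est = np.asarray(estimates)
        mcse = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 2.0) < 3 * mcse

    def test_rank_deficiency_names_collinear_columns(self):
        df = _flat_data(2)
        df["x2"] = 2 * df["x"]
        with pytest.raises(RankDeficientError, match="x"):
            fit_lmm(df, "y", ["arm", "x", "x2"], cluster="school_id")

    def test_requires_two_clusters(self):
        df = _flat_data(3)
        df["school_id"] = "S0"
        with pytest.raises(ValueError, match="2 clusters"):
            fit_lmm(df, "y", ["arm", "x"], cluster="school_id")


class TestPathModels:
    def test_noise_free_estimates_equal_generating_values(self):
        df = _exact_mediation_data()
        spec = AnalysisSpec(seed=0)
        a = fit_a_path(df, "barriers", spec)
        b, c_prime = fit_outcome_model(df, "barriers", "sedentary", spec)
        assert a.coefficient == pytest.approx(2.0, abs=1e-7)
        assert b.coefficient == pytest.approx(0.5, abs=1e-7)
        assert c_prime.coefficient == pytest.approx(10.0, abs=1e-7)

    def test_no_mediation_limit_b_zero_c_equals_c_prime(self):
        df = _exact_mediation_data(b=0.0)
        spec = AnalysisSpec(seed=0)
        b, c_prime = fit_outcome_model(df, "barriers", "sedentary", spec)
        c = fit_total_effect(df, "barriers", "sedentary", spec)
        assert b.coefficient == pytest.approx(0.0, abs=1e-7)
        assert c.coefficient == pytest.approx(c_prime.coefficient, abs=1e-6)

    def test_ols_identity_c_minus_c_prime_equals_ab(self, analysis_table):
        table, _ = analysis_table
        spec = AnalysisSpec(cluster_var=None, a_path_wear="wear_t2", seed=0)
        a = fit_a_path(table, "barriers", spec, extra_covariates=("sedentary_t0",))
        b, c_prime = fit_outcome_model(table, "barriers", "sedentary", spec)
        c = fit_total_effect(table, "barriers", "sedentary", spec)
        assert c.coefficient - c_prime.coefficient == pytest.approx(
            a.coefficient * b.coefficient, abs=1e-8
        )

    def test_flipping_arm_coding_negates_a_c_cprime_not_b(self, analysis_table):
        table, _ = analysis_table
        spec = AnalysisSpec(seed=0)
        flipped = table.assign(arm=1 - table["arm"])
        for fn in (fit_a_path,):
            orig = fn(table, "barriers", spec)
            flip = fn(flipped, "barriers", spec)
            assert flip.coefficient == pytest.approx(-orig.coefficient, abs=1e-6)
        b0, cp0 = fit_outcome_model(table, "barriers", "sedentary", spec)
        b1, cp1 = fit_outcome_model(flipped, "barriers", "sedentary", spec)
        assert cp1.coefficient == pytest.approx(-cp0.coefficient, abs=1e-6)
        assert b1.coefficient == pytest.approx(b0.coefficient, abs=1e-6)
        c0 = fit_total_effect(table, "barriers", "sedentary", spec)
        c1 = fit_total_effect(flipped, "barriers", "sedentary", spec)
        assert c1.coefficient == pytest.approx(-c0.coefficient, abs=1e-6)

    def test_school_level_permutation_null_centers_a_at_zero(self):
        cfg = TrialConfig(a_true={}, seed=9)
        table, _ = simulate_analysis_table(cfg)
        spec = AnalysisSpec(cluster_var=None, seed=0)
        rng = np.random.default_rng(0)
        schools = table["school_id"].unique()
        coefs = []
        for _ in range(60):
            arm_map = dict(zip(schools, rng.permutation(np.arange(len(schools)) % 2)))
            permuted = table.assign(arm=table["school_id"].map(arm_map))
            coefs.append(fit_a_path(permuted, "barriers", spec).coefficient)
        coefs = np.asarray(coefs)
        assert abs(coefs.mean()) < 3 * coefs.std(ddof=1) / np.sqrt(len(coefs))


def _estimate(p):
    return PathEstimate("a", 1.0, 0.5, 0.0, 2.0, p, 100, True, 0.0)


class TestGate:
    def test_exactly_one_mediator_clears_nominal_alpha(self):
        ps = {"m%d" % i: _estimate(p) for i, p in enumerate([0.03, 0.76, 0.99, 0.14, 0.48, 0.23, 0.67])}
        assert gate_mediators(ps, AnalysisSpec(alpha=0.05)) == ["m0"]

    def test_all_half_yields_empty(self):
        ps = {"m%d" % i: _estimate(0.5) for i in range(7)}
        assert gate_mediators(ps, AnalysisSpec(alpha=0.05)) == []

    def test_degenerate_alpha_one_passes_everything(self):
        ps = {"m%d" % i: _estimate(0.5) for i in range(7)}
        assert len(gate_mediators(ps, AnalysisSpec(alpha=0.999999))) == 7


class TestBootstrap:
    def test_point_estimate_is_product_of_full_sample_fits(self, analysis_table):
        table, _ = analysis_table
        spec = AnalysisSpec(n_boot=5, seed=1)
        r = bootstrap_indirect(table, "barriers", "sedentary", spec)
        assert r.ab_point == r.a.coefficient * r.b.coefficient
        assert r.ab_ci_low <= r.ab_ci_high

    def test_identical_seed_identical_ci(self, analysis_table):
        table, _ = analysis_table
        spec = AnalysisSpec(n_boot=30, seed=11)
        r1 = bootstrap_indirect(table, "barriers", "sedentary", spec)
        r2 = bootstrap_indirect(table, "barriers", "sedentary", spec)
        assert (r1.ab_ci_low, r1.ab_ci_high) == (r2.ab_ci_low, r2.ab_ci_high)
        assert r1.n_boot_used == spec.n_boot

    def test_degenerate_variances_give_zero_width_ci(self):
        df = _exact_mediation_data()
        spec = AnalysisSpec(n_boot=40, seed=2)
        r = bootstrap_indirect(df, "barriers", "sedentary", spec)
        assert r.ab_point == pytest.approx(1.0, abs=1e-8)
        assert r.ab_ci_high - r.ab_ci_low == pytest.approx(0.0, abs=1e-8)
        assert r.n_boot_failed == 0

    def test_participant_unit_resampling(self, analysis_table):
        table, _ = analysis_table
        spec = AnalysisSpec(n_boot=20, seed=3, bootstrap_unit="participant")
        r = bootstrap_indirect(table, "barriers", "sedentary", spec)
        assert r.n_boot_used == 20

    def test_null_indirect_effect_coverage(self):
        """With a_true=0 the percentile CI should rarely exclude zero."""
        n_trials, n_boot = 80, 100
        spec = AnalysisSpec(
            cluster_var=None, n_boot=n_boot, seed=0, bootstrap_unit="participant"
        )
        exclusions = 0
        for k in range(n_trials):
            cfg = TrialConfig(
                n_schools_per_arm=5,
                participants_per_school=8,
                a_true={},
                b_true={("barriers", "sedentary"): 0.8},
                seed=40_000 + k,
            )
            table, _ = simulate_analysis_table(cfg)
            r = bootstrap_indirect(table, "barriers", "sedentary", spec)
            if r.ab_ci_low > 0 or r.ab_ci_high < 0:
                exclusions += 1
        # nominal 5%; percentile intervals on n=80 run a little anticonservative
        assert exclusions / n_trials <= 0.15


class TestProfiledRemlCrossCheck:
    def test_attains_statsmodels_reml_optimum(self):
        """The profiled-REML fit reaches a criterion value at least as good
        as statsmodels MixedLM on the same data, with matching fixed
        effects (MixedLM's general-purpose optimizer is the independent
        reference; its own stopping rule leaves a little slack)."""
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLMParams

        from actimediate.mediation import _profile_reml

        rng = np.random.default_rng(0)
        for _ in range(8):
            n_sch, per = 18, 15
            u = rng.normal(0, 2.0, n_sch)
            df = pd.DataFrame(
                {
                    "school_id": np.repeat(np.arange(n_sch), per),
                    "arm": np.repeat(np.arange(n_sch) % 2, per),
                    "x": rng.normal(0, 1, n_sch * per),
                }
            )
            df["y"] = (
                1.5 * df["arm"] + 0.8 * df["x"] + u[df["school_id"]]
                + rng.normal(0, 3, len(df))
            )
            X = sm.add_constant(df[["arm", "x"]])
            X.columns = ["Intercept", "arm", "x"]
            gi = pd.factorize(df["school_id"])[0]
            beta, _, var_u, sig_e2, boundary = _profile_reml(
                df["y"].to_numpy(), X.to_numpy(), gi
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(df["y"], X, groups=df["school_id"])
                ref = model.fit(reml=True)

            def reml_ll(ratio):
                params = MixedLMParams.from_components(
                    fe_params=None, cov_re=np.array([[max(ratio, 1e-12)]])
                )
                return model.loglike(params, profile_fe=True)

            ratio_mine = var_u / sig_e2 if not boundary else 0.0
            ratio_ref = float(ref.cov_re.iloc[0, 0]) / ref.scale
            assert reml_ll(ratio_mine) >= reml_ll(ratio_ref) - 1e-6
            assert beta[1] == pytest.approx(float(ref.params["arm"]), abs=1e-4)
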