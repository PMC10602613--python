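import math

import pytest

import episeries as ep
from episeries.exceptions import (
    DegenerateVarianceError,
    NotConvergedError,
    NotNestedError,
    OptimizationFailureError,
)

from conftest import MID_BACKGROUNDS, pair_table
from test_model import shifted

F = ep.ModelFamily


class TestLRT:
    def test_fit_against_itself_gives_zero_stat_unit_p(self, additive_table, additive_design):
        add = ep.fit_model(additive_table, additive_design, F.ADDITIVE)
        r = ep.likelihood_ratio_test(add, add)
        assert r.stat == 0.0 and r.p == 1.0 and r.df == 0

    def test_stat_df_and_p_definition(self, sigmoid_table, sigmoid_design):
        small = ep.fit_model(sigmoid_table, sigmoid_design, F.ADDITIVE)
        big = ep.fit_model(sigmoid_table, sigmoid_design, F.IDIOSYNCRATIC)
        r = ep.likelihood_ratio_test(small, big)
        assert r.stat == pytest.approx(2 * (big.llf - small.llf))
        assert r.df == big.df_model - small.df_model
        from scipy.stats import chi2

        assert r.p == pytest.approx(chi2.sf(r.stat, r.df))
        assert r.nesting == "strict"

    def test_sigmoid_comparisons_flagged_approximate(self, sigmoid_table, sigmoid_design):
        small = ep.fit_model(sigmoid_table, sigmoid_design, F.PROPORTIONAL, n_starts=8, seed=1)
        big = ep.fit_model(sigmoid_table, sigmoid_design, F.SIGMOID, n_starts=8, seed=1)
        assert ep.likelihood_ratio_test(small, big).nesting == "approximate"

    def test_non_nested_pair_refused_by_name(self, additive_table, additive_design):
        c = ep.fit_model(additive_table, additive_design, F.CONSTANT)
        p = ep.fit_model(additive_table, additive_design, F.PROPORTIONAL, n_starts=4, seed=0)
        with pytest.raises(NotNestedError, match="constant"):
            ep.likelihood_ratio_test(c, p)

    def test_different_data_refused(self, additive_table, additive_design):
        a = ep.fit_model(additive_table, additive_design, F.ADDITIVE)
        b = ep.fit_model(shifted(additive_table, 0.1), additive_design, F.IDIOSYNCRATIC)
        with pytest.raises(ValueError, match="identical data"):
            ep.likelihood_ratio_test(a, b)

    def test_negative_stat_beyond_tol_is_an_optimizer_failure(self, additive_table, additive_design):
        a = ep.fit_model(additive_table, additive_design, F.ADDITIVE)
        bad = ep.fit_model(additive_table, additive_design, F.IDIOSYNCRATIC)
        bad.rss = bad.rss * 4.0  # corrupt the big fit
        with pytest.raises(OptimizationFailureError):
            ep.likelihood_ratio_test(a, bad)

    def test_lrt_invariant_to_translation_and_relabeling(self, additive_table, additive_design):
        def stat(table, design):
            s = ep.fit_model(table, design, F.ADDITIVE)
            b = ep.fit_model(table, design, F.IDIOSYNCRATIC)
            return ep.likelihood_ratio_test(s, b).stat

        s0 = stat(additive_table, additive_design)
        moved = shifted(additive_table, 1.23)
        assert stat(moved, additive_design) == pytest.approx(s0, abs=1e-8)
        relabeled = additive_table.df.copy()
        relabeled["clv3_allele"] = relabeled["clv3_allele"].map(
            lambda a: {"b1": "zz9"}.get(a, a)
        )
        t2 = ep.PhenotypeTable(relabeled)
        assert stat(t2, ep.ExperimentDesign.from_table(t2, "wus")) == pytest.approx(s0, abs=1e-8)

    def test_power_against_one_strong_idiosyncratic_background(self):
        # one background deviating by 0.3 from an otherwise additive effect
        reject = 0
        for rep in range(20):
            focal = {l: 0.25 for l, _ in MID_BACKGROUNDS}
            focal["b4"] = 0.55
            sd = ep.SimDesign(
                backgrounds=MID_BACKGROUNDS, true_family="idiosyncratic", focal_params=focal,
                n_plants=2, n_fruits=50, residual_sd=0.2, seed=1000 + rep,
            )
            table, _ = ep.simulate_experiment(sd)
            design = ep.ExperimentDesign.from_table(table, "wus")
            r = ep.likelihood_ratio_test(
                ep.fit_model(table, design, F.ADDITIVE),
                ep.fit_model(table, design, F.IDIOSYNCRATIC),
            )
            reject += r.p < 1e-4
        assert reject >= 19  # >= 95% of replicates


class TestBootstrap:
    def test_bootstrap_p_reproducible_and_valid(self, additive_table, additive_design):
        kw = dict(B=99, seed=5, n_starts=4)
        r1 = ep.bootstrap_lrt(additive_table, additive_design, F.ADDITIVE, F.CONSTANT, **kw)
        r2 = ep.bootstrap_lrt(additive_table, additive_design, F.ADDITIVE, F.CONSTANT, **kw)
        assert r1.bootstrap_p == r2.bootstrap_p
        assert 0 < r1.bootstrap_p <= 1

    def test_zero_observed_stat_gives_p_one(self):
        # zero-noise additive data: every family ties, stat is exactly 0
        sd = ep.SimDesign(
            backgrounds=MID_BACKGROUNDS[:3], true_family="additive", focal_params={"delta": 0.2},
            n_plants=1, n_fruits=5, residual_sd=0.0, seed=0,
        )
        table, _ = ep.simulate_experiment(sd)
        design = ep.ExperimentDesign.from_table(table, "wus")
        r = ep.bootstrap_lrt(table, design, F.ADDITIVE, F.CONSTANT, B=99, seed=1)
        assert r.stat == 0.0 and r.bootstrap_p == 1.0

    def test_rejects_too_few_replicates(self, additive_table, additive_design):
        with pytest.raises(ValueError):
            ep.bootstrap_lrt(additive_table, additive_design, F.ADDITIVE, F.CONSTANT, B=10)

    def test_bootstrap_agrees_with_chisq_for_strictly_nested_pair(self, additive_table, additive_design):
        # B large enough that Monte-Carlo error (~sqrt(p(1-p)/B)) is well
        # inside the 0.05 agreement band
        r = ep.bootstrap_lrt(additive_table, additive_design, F.ADDITIVE, F.CONSTANT, B=999, seed=3, n_starts=2)
        assert abs(r.bootstrap_p - r.p) < 0.05


class TestScan:
    def test_zero_noise_additive_scan_all_stats_zero(self):
        sd = ep.SimDesign(
            backgrounds=MID_BACKGROUNDS, true_family="additive", focal_params={"delta": 0.2},
            n_plants=1, n_fruits=5, residual_sd=0.0, seed=0,
        )
        table, _ = ep.simulate_experiment(sd)
        design = ep.ExperimentDesign.from_table(table, "wus")
        sr = ep.nested_model_scan(table, design, n_starts=6, seed=0)
        assert all(r.stat == pytest.approx(0.0, abs=1e-6) for r in sr.lrts)

    def test_sigmoid_truth_scan_selects_sigmoid(self, sigmoid_table, sigmoid_design):
        sr = ep.nested_model_scan(sigmoid_table, sigmoid_design, n_starts=16, seed=2)
        assert sr.lrt(F.CONSTANT, F.SIGMOID).p < 1e-3
        assert sr.lrt(F.ADDITIVE, F.SIGMOID).p < 1e-3
        # and the saturated model offers no real improvement over the truth
        assert sr.lrt(F.SIGMOID, F.IDIOSYNCRATIC).p > 1e-4

    def test_scan_report_structure(self, sigmoid_table, sigmoid_design):
        sr = ep.nested_model_scan(sigmoid_table, sigmoid_design, n_starts=8, seed=2)
        d = sr.to_dict()
        assert set(d["fits"]) == {f.value for f in F}
        assert len(d["lrts"]) == 9
        txt = sr.summary()
        assert "sigmoid" in txt and "AIC" in txt
        aic = sr.aic_table()
        assert list(aic.columns) == ["family", "loglik", "n_mean_params", "aic", "converged"]

    def test_scan_bootstrap_attaches_to_approximate_pairs(self, additive_table, additive_design):
        sr = ep.nested_model_scan(additive_table, additive_design, n_starts=4, seed=0, bootstrap_B=99)
        for r in sr.lrts:
            if r.nesting == "approximate":
                assert r.bootstrap_p is not None
            else:
                assert r.bootstrap_p is None


class TestPairwiseEffects:
    def test_identical_samples_give_zero_delta(self):
        t = pair_table([4, 5, 6, 4], [4, 5, 6, 4])
        d = ep.ExperimentDesign.from_table(t, "wus")
        effects = {e.background: e for e in ep.pairwise_effects(t, d)}
        assert effects["fas"].delta_log == pytest.approx(0.0, abs=1e-12)

    def test_doubling_counts_gives_log2_and_100_percent(self):
        t = pair_table([4] * 6, [8] * 6)
        d = ep.ExperimentDesign.from_table(t, "wus")
        e = {x.background: x for x in ep.pairwise_effects(t, d)}["fas"]
        assert e.delta_log == pytest.approx(math.log(2), abs=1e-12)
        assert e.percent_change == pytest.approx(100.0)
        assert e.se == pytest.approx(0.0, abs=1e-12)

    def test_log_scale_percent_option(self):
        t = pair_table([4] * 6, [8] * 6)
        d = ep.ExperimentDesign.from_table(t, "wus")
        e = {x.background: x for x in ep.pairwise_effects(t, d, log_scale_percent=True)}["fas"]
        assert e.percent_change == pytest.approx(100.0)

    def test_se_combines_genotype_ses_in_quadrature(self, additive_table, additive_design):
        summaries = {s.genotype_id: s for s in additive_table.summarize()}
        for e in ep.pairwise_effects(additive_table, additive_design):
            s0, s1 = summaries[e.genotype_background], summaries[e.genotype_mutant]
            assert e.se == pytest.approx(math.hypot(s0.se_log, s1.se_log), abs=1e-12)
            assert e.delta_log == pytest.approx(s1.mean_log - s0.mean_log, abs=1e-12)

    def test_deltas_equal_saturated_fitted_mean_differences(self, sigmoid_table, sigmoid_design):
        res = ep.fit_model(sigmoid_table, sigmoid_design, F.IDIOSYNCRATIC)
        fm = res.fitted_means
        for e in ep.pairwise_effects(sigmoid_table, sigmoid_design):
            assert e.delta_log == pytest.approx(
                fm[e.genotype_mutant] - fm[e.genotype_background], abs=1e-10
            )

    def test_missing_partner_omitted_with_warning(self, additive_table):
        df = additive_table.df
        keep = ~((df.clv3_allele == "b2") & (df.wus == "lc"))
        with pytest.warns(UserWarning):
            t = ep.PhenotypeTable(df[keep].copy())
            d = ep.ExperimentDesign.from_table(t, "wus")
        with pytest.warns(UserWarning, match="missing cell"):
            effects = ep.pairwise_effects(t, d)
        assert "b2" not in {e.background for e in effects}


class TestVarianceDecomposition:
    def test_saturated_and_additive_limits_exact(self, sigmoid_table, sigmoid_design):
        vi = ep.epistatic_variance_fraction(sigmoid_table, sigmoid_design, F.IDIOSYNCRATIC)
        va = ep.epistatic_variance_fraction(sigmoid_table, sigmoid_design, F.ADDITIVE)
        assert vi.fraction == 1.0
        assert va.fraction == 0.0

    def test_fraction_in_unit_interval_and_ordered(self, sigmoid_table, sigmoid_design):
        v = ep.epistatic_variance_fraction(sigmoid_table, sigmoid_design, F.SIGMOID, n_starts=16, seed=1)
        assert v.rss_idiosyncratic <= v.rss_model <= v.rss_additive
        assert 0.0 <= v.fraction <= 1.0
        assert v.percent == pytest.approx(100 * v.fraction)

    def test_fraction_invariant_under_count_rescaling(self, sigmoid_table, sigmoid_design):
        v0 = ep.epistatic_variance_fraction(sigmoid_table, sigmoid_design, F.CONSTANT)
        v1 = ep.epistatic_variance_fraction(shifted(sigmoid_table, math.log(2)), sigmoid_design, F.CONSTANT)
        assert v1.fraction == pytest.approx(v0.fraction, abs=1e-8)

    def test_no_epistatic_variance_raises(self):
        sd = ep.SimDesign(
            backgrounds=MID_BACKGROUNDS[:3], true_family="additive", focal_params={"delta": 0.2},
            n_plants=1, n_fruits=5, residual_sd=0.0, seed=0,
        )
        table, _ = ep.simulate_experiment(sd)
        design = ep.ExperimentDesign.from_table(table, "wus")
        with pytest.raises(DegenerateVarianceError):
            ep.epistatic_variance_fraction(table, design, F.CONSTANT)

    def test_genotype_level_option(self, sigmoid_table, sigmoid_design):
        v = ep.epistatic_variance_fraction(sigmoid_table, sigmoid_design, F.SIGMOID, n_starts=16, seed=1, level="genotype")
        assert 0.0 <= v.fraction <= 1.0 and v.level == "genotype"


class TestSigmoidPrediction:
    def test_midpoint_and_asymptote(self, sigmoid_table, sigmoid_design):
        res = ep.fit_model(sigmoid_table, sigmoid_design, F.SIGMOID, n_starts=16, seed=2)
        A = ep.predict_saturated_effect(res)
        x0 = res.params.focal["x0"]
        assert ep.predict_effect_at(res, x0) == pytest.approx(A / 2)
        assert ep.predict_effect_at(res, x0 + 100) == pytest.approx(A, rel=1e-6)

    def test_predicted_effect_tracks_generator_truth(self, sigmoid_sim, sigmoid_design):
        table, truth = sigmoid_sim
        res = ep.fit_model(table, sigmoid_design, F.SIGMOID, n_starts=16, seed=2)
        strongest = max(truth.params.beta, key=truth.params.beta.get)
        pred = ep.predict_effect_at(res, truth.params.beta[strongest])
        # within 3 SE of the generator's true effect (SE ~ sigma*sqrt(2/n))
        se = 0.2 * math.sqrt(2 / 150)
        assert abs(pred - truth.effects[strongest]) < 3 * se

    def test_requires_converged_sigmoid(self, sigmoid_table, sigmoid_design):
        res = ep.fit_model(sigmoid_table, sigmoid_design, F.ADDITIVE)
        with pytest.raises(NotNestedError):
            ep.predict_saturated_effect(res)
        sig = ep.fit_model(sigmoid_table, sigmoid_design, F.SIGMOID, n_starts=8, seed=1)
        sig.converged = False
        with pytest.raises(NotConvergedError):
            ep.predict_saturated_effect(sig)
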