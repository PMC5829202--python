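"""Gibbs-sampled mixed models, moment oracle and repeatability ratios."""

import numpy as np
import pandas as pd
import pytest

from shoalkit.repeatability import (
    ModelError,
    ModelSpec,
    PosteriorDraws,
    cis_overlap,
    compare_levels,
    compute_repeatability,
    fit_lmm_mcmc,
    moment_estimator,
)
from shoalkit.synthetic import LMMGenConfig, generate_lmm_data

SPEC_FULL = ModelSpec("value", fixed=("context",), individual="individual_id")
SPEC_GROUP = ModelSpec("value", fixed=("context",))

FAST = dict(chains=2, iters=2000, burnin=400, thin=4)


@pytest.fixture(scope="module")
def balanced_fit():
    """One shared fit of balanced data with known components (1, 0.5, 1)."""
    table, truth = generate_lmm_data(
        LMMGenConfig(n_groups=50, n_per_group=5, n_obs=4, seed=42)
    )
    draws = fit_lmm_mcmc(table, SPEC_FULL, seed=1, **FAST)
    return table, truth, draws


class TestRepeatabilityRatio:
    @pytest.mark.parametrize(
        "vg,vi,ve,rg,ri",
        [
            (0.85, 0.00, 0.87, 0.49, 0.00),
            (0.75, 0.67, 2.12, 0.21, 0.19),
            (1.70e-3, None, 4.18e-3, 0.29, None),
            (2.32e-4, None, 5.78e-4, 0.29, None),
        ],
    )
    def test_point_component_ratios(self, vg, vi, ve, rg, ri):
        res = compute_repeatability(v_group=vg, v_id=vi, v_res=ve)
        assert round(res.r_group, 2) == rg
        if ri is not None:
            assert round(res.r_id, 2) == ri

    def test_boundary_behaviour(self):
        assert compute_repeatability(v_group=0.0, v_id=3.0, v_res=1.0).r_group == 0.0
        near_one = compute_repeatability(v_group=1.0, v_id=0.0, v_res=1e-9)
        assert near_one.r_group == pytest.approx(1.0, abs=1e-6)

    def test_negative_variance_draw_is_a_contract_violation(self):
        with pytest.raises(RuntimeError, match="negative"):
            compute_repeatability(v_group=-0.1, v_res=1.0)

    def test_scale_invariance_of_ratio(self, rng):
        vg, ve = rng.gamma(2.0, size=200), rng.gamma(2.0, size=200)
        draws = PosteriorDraws(
            beta=np.zeros((1, 200, 1)), beta_names=["(intercept)"],
            v_group=vg[None, :], v_res=ve[None, :],
        )
        scaled = PosteriorDraws(
            beta=np.zeros((1, 200, 1)), beta_names=["(intercept)"],
            v_group=9.0 * vg[None, :], v_res=9.0 * ve[None, :],
        )
        a, b = compute_repeatability(draws), compute_repeatability(scaled)
        np.testing.assert_allclose(a.draws_r_group, b.draws_r_group)


class TestMomentEstimator:
    def test_recovers_truth_on_large_balanced_data(self):
        table, truth = generate_lmm_data(
            LMMGenConfig(n_groups=200, n_per_group=5, n_obs=6, seed=7)
        )
        est = moment_estimator(table, SPEC_FULL)
        assert est.v_group == pytest.approx(truth["v_group"], rel=0.3)
        assert est.v_id == pytest.approx(truth["v_id"], rel=0.3)
        assert est.v_res == pytest.approx(truth["v_res"], rel=0.1)

    def test_component_scaling_under_response_rescale(self):
        table, _ = generate_lmm_data(LMMGenConfig(n_groups=30, seed=3))
        est = moment_estimator(table, SPEC_FULL)
        scaled = table.assign(value=table["value"] * 3.0)
        est3 = moment_estimator(scaled, SPEC_FULL)
        assert est3.v_group == pytest.approx(9.0 * est.v_group)
        assert est3.v_res == pytest.approx(9.0 * est.v_res)

    def test_zero_within_group_spread_gives_zero_residual(self):
        table = pd.DataFrame(
            {
                "value": np.repeat([1.0, 2.0, 5.0], 4),
                "group_id": np.repeat(["a", "b", "c"], 4),
            }
        )
        est = moment_estimator(table, ModelSpec("value"))
        assert est.v_res == 0.0
        assert est.v_group > 0.0

    def test_single_observation_per_individual_is_confounded(self):
        table = pd.DataFrame(
            {
                "value": np.arange(12.0),
                "group_id": np.repeat(["a", "b", "c"], 4),
                "individual_id": [f"i{k}" for k in range(12)],
            }
        )
        est = moment_estimator(table, ModelSpec("value", individual="individual_id"))
        assert est.confounded
        assert np.isnan(est.v_id)


class TestGibbsSampler:
    def test_posterior_means_recover_truth_within_sampling_error(self, balanced_fit):
        # a variance estimated from q effects has SE ~ v * sqrt(2/q); assert
        # recovery within 3 SE of the generating values for this design
        _, truth, draws = balanced_fit
        checks = [
            ("v_group", truth["v_group"], 50),
            ("v_id", truth["v_id"], 250),
            ("v_res", truth["v_res"], 1000),
        ]
        for comp, v_true, q in checks:
            se = v_true * np.sqrt(2.0 / q)
            assert abs(draws.flat(comp).mean() - v_true) < 3 * se, comp
        assert all(r < 1.1 for r in draws.rhat.values())

    def test_agrees_with_moment_oracle(self, balanced_fit):
        table, _, draws = balanced_fit
        mom = moment_estimator(table, SPEC_FULL)
        assert draws.flat("v_group").mean() == pytest.approx(mom.v_group, rel=0.15)
        assert draws.flat("v_id").mean() == pytest.approx(mom.v_id, rel=0.15)
        assert draws.flat("v_res").mean() == pytest.approx(mom.v_res, rel=0.15)

    def test_agrees_with_reml_cross_check(self, balanced_fit):
        # independent route: statsmodels MixedLM with a nested variance component
        import statsmodels.formula.api as smf

        table, _, draws = balanced_fit
        md = smf.mixedlm(
            "value ~ C(context)", table, groups="group_id",
            re_formula="1", vc_formula={"individual_id": "0 + C(individual_id)"},
        ).fit(reml=True)
        v_group_reml = float(md.cov_re.iloc[0, 0])
        v_id_reml = float(md.vcomp[0])
        v_res_reml = float(md.scale)
        assert draws.flat("v_group").mean() == pytest.approx(v_group_reml, rel=0.2)
        assert draws.flat("v_id").mean() == pytest.approx(v_id_reml, rel=0.2)
        assert draws.flat("v_res").mean() == pytest.approx(v_res_reml, rel=0.1)

    def test_no_group_signal_concentrates_near_zero(self):
        table, _ = generate_lmm_data(
            LMMGenConfig(n_groups=40, n_per_group=1, n_obs=10,
                         v_group=0.0, v_id=0.0, v_res=1.0, seed=11)
        )
        draws = fit_lmm_mcmc(table, SPEC_GROUP, seed=2, **FAST)
        res = compute_repeatability(draws)
        assert res.r_group < 0.1
        assert not res.significant_group

    def test_intercept_only_reduces_to_mean_estimation(self, rng):
        y = rng.normal(3.0, 1.0, 200)
        table = pd.DataFrame({"value": y})
        draws = fit_lmm_mcmc(
            table, ModelSpec("value", group=None), seed=3, chains=1,
            iters=1500, burnin=300, thin=3,
        )
        beta = draws.flat("beta")[:, 0]
        assert beta.mean() == pytest.approx(y.mean(), abs=3 * y.std() / np.sqrt(200))

    def test_different_seeds_agree_within_monte_carlo_error(self):
        table, _ = generate_lmm_data(LMMGenConfig(n_groups=30, seed=5))
        a = fit_lmm_mcmc(table, SPEC_FULL, seed=101, **FAST)
        b = fit_lmm_mcmc(table, SPEC_FULL, seed=202, **FAST)
        for comp in ("v_group", "v_id", "v_res"):
            x, y = a.flat(comp), b.flat(comp)
            se = np.hypot(x.std(), y.std()) / np.sqrt(50)  # generous ESS floor
            assert abs(x.mean() - y.mean()) < 4 * se

    def test_input_validation(self):
        bad = pd.DataFrame(
            {
                "value": [1.0, 2.0, 3.0, 4.0],
                "group_id": ["a", "a", "b", "b"],
                "individual_id": ["i1", "i1", "i1", "i2"],  # i1 in two groups
            }
        )
        with pytest.raises(ModelError, match="more than one group"):
            fit_lmm_mcmc(bad, ModelSpec("value", individual="individual_id"),
                         chains=1, iters=10, burnin=0, thin=1)

    def test_too_few_observations_per_group(self):
        table = pd.DataFrame({"value": [1.0, 2.0, 3.0], "group_id": ["a", "a", "b"]})
        with pytest.raises(ModelError, match="fewer than 2"):
            fit_lmm_mcmc(table, ModelSpec("value"), chains=1, iters=10,
                         burnin=0, thin=1)


class TestCompareLevels:
    def test_interval_overlap_rules(self):
        assert not cis_overlap((1.0, 2.0), (3.0, 4.0))
        assert cis_overlap((1.0, 3.0), (2.0, 4.0))

    def test_large_injected_context_effect_is_detected(self):
        table, _ = generate_lmm_data(
            LMMGenConfig(n_groups=20, n_per_group=1, n_obs=4,
                         context_effects=(0.0, 8.0, 0.0, 0.0),
                         v_group=0.2, v_id=0.0, v_res=0.5, seed=9)
        )
        draws = fit_lmm_mcmc(table, SPEC_GROUP, seed=4, **FAST)
        c = compare_levels(draws, "context", "c1", "c2")
        assert c.significantly_different
        c_same = compare_levels(draws, "context", "c1", "c3")
        assert not c_same.significantly_different

    def test_unknown_level_is_an_error(self):
        table, _ = generate_lmm_data(LMMGenConfig(n_groups=10, seed=1))
        draws = fit_lmm_mcmc(table, SPEC_GROUP, seed=5, chains=1, iters=200,
                             burnin=50, thin=2)
        with pytest.raises(ModelError, match="unknown level"):
            compare_levels(draws, "context", "c1", "nope")
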