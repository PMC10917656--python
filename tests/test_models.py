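"""Rescorla-Wagner variants: RPE generation, grid fitting, CV comparison."""

import numpy as np
import pytest
from scipy import stats

import distrl
from distrl.models import (
    MODEL_ORDER,
    MODELS,
    DeltaGrid,
    _contiguous_folds,
    parameter_grid,
    rpe_sequence,
    scaled_regressor,
)
from distrl.neurons import NeuronGroundTruth, NeuronRecord

from conftest import single_cue_trials


def truth(**kw):
    base = dict(tau=0.75, s_true=0.8, alpha_plus=0.6, alpha_minus=0.2, noise_sd=0.0)
    base.update(kw)
    return NeuronGroundTruth(**base)


class TestRpeSequence:
    def test_single_step_updates(self):
        d, v = rpe_sequence(single_cue_trials([1.0]), 0.2, 0.1, v_init=0.5)
        assert d[0] == pytest.approx(0.5) and v[0] == pytest.approx(0.5)
        d, v = rpe_sequence(single_cue_trials([1.0, 0.0]), 0.2, 0.1, v_init=0.5)
        assert v[1] == pytest.approx(0.6)  # V after positive update
        assert d[1] == pytest.approx(-0.6)
        d, v = rpe_sequence(single_cue_trials([0.0, 0.0]), 0.2, 0.1, v_init=0.5)
        assert d[0] == pytest.approx(-0.5) and v[1] == pytest.approx(0.45)

    def test_symmetric_reduces_to_classic_recursion(self, dynamic_trials):
        d_asym, v_asym = rpe_sequence(dynamic_trials, 0.3, 0.3)
        # classic single-rate recursion computed independently per cue
        cue = dynamic_trials.cue_id.to_numpy()
        r = dynamic_trials.delivered_reward.to_numpy()
        values = {c: 0.5 for c in np.unique(cue)}
        expected = np.empty(r.size)
        for t in range(r.size):
            expected[t] = r[t] - values[cue[t]]
            values[cue[t]] += 0.3 * expected[t]
        assert np.allclose(d_asym, expected)

    def test_values_update_only_for_the_chosen_cue(self, dynamic_trials):
        _, v = rpe_sequence(dynamic_trials, 0.5, 0.5)
        cue = dynamic_trials.cue_id.to_numpy()
        # a cue's pre-update value is unchanged between its encounters
        for c in np.unique(cue):
            idx = np.flatnonzero(cue == c)
            r = dynamic_trials.delivered_reward.to_numpy()[idx]
            vc = v[idx]
            for k in range(1, idx.size):
                d_prev = r[k - 1] - vc[k - 1]
                assert vc[k] == pytest.approx(vc[k - 1] + 0.5 * d_prev)


class TestScaledRegressor:
    @pytest.mark.parametrize(
        "delta, s, expected",
        [(0.5, 0.8, 0.4), (-0.5, 0.8, -0.1), (0.5, 0.5, 0.25), (0.0, 0.9, 0.0)],
    )
    def test_values(self, delta, s, expected):
        assert scaled_regressor(np.array([delta]), s)[0] == pytest.approx(expected)

    def test_symmetric_is_half_delta(self):
        d = np.linspace(-1, 1, 11)
        assert np.allclose(scaled_regressor(d, 0.5), 0.5 * d)

    def test_zero_delta_routed_to_negative_branch(self):
        # delta <= 0 uses the (1-S) branch; at delta = 0 both give 0,
        # but the sign convention matters for event labelling elsewhere
        assert scaled_regressor(np.array([0.0]), 1.0)[0] == 0.0


class TestGrid:
    def test_coarse_grid_candidates(self):
        assert np.allclose(parameter_grid(0.5), [0.0, 0.5, 1.0])
        assert parameter_grid(0.025).size == 41

    def test_grid_step_must_divide_one(self):
        with pytest.raises(ValueError):
            parameter_grid(0.3)

    def test_noiseless_on_grid_recovery_is_exact(self, dynamic_trials):
        g = truth()
        n = distrl.simulate_neuron_dynamic(dynamic_trials, g, seed=0)
        p = distrl.fit_grid(n, dynamic_trials, "ALAS")
        assert p.alpha_plus == pytest.approx(0.6)
        assert p.alpha_minus == pytest.approx(0.2)
        assert p.s == pytest.approx(0.8)
        assert p.train_r2 == pytest.approx(1.0)

    def test_symmetric_model_enforces_constraints(self, dynamic_trials):
        g = truth()
        n = distrl.simulate_neuron_dynamic(dynamic_trials, g, seed=0)
        p = distrl.fit_grid(n, dynamic_trials, "SLSS")
        assert p.alpha_plus == p.alpha_minus
        assert p.s == 0.5

    def test_nesting_invariant_exact(self, dynamic_trials, coupled_dynamic_population):
        dg = DeltaGrid(dynamic_trials)
        for n in coupled_dynamic_population[:8]:
            r2 = {
                m: distrl.fit_grid(n, dynamic_trials, m, delta_grid=dg).train_r2
                for m in MODEL_ORDER
            }
            assert r2["ALAS"] >= r2["SLAS"] >= r2["SLSS"]
            assert r2["ALAS"] >= r2["ALSS"] >= r2["SLSS"]

    def test_all_one_sign_delta_never_selects_degenerate_regressor(self):
        # all rewards high: every delta > 0, so S = 0 zeroes the regressor
        trials = single_cue_trials(np.ones(60))
        rng = np.random.default_rng(1)
        n = NeuronRecord("a", "s", feedback_rate=rng.normal(size=60))
        p = distrl.fit_grid(n, trials, "ALAS")
        assert np.isfinite(p.train_r2)
        x = scaled_regressor(rpe_sequence(trials, p.alpha_plus, p.alpha_minus)[0], p.s)
        assert x.std() > 0


class TestCrossvalidation:
    def test_noiseless_neuron_scores_near_one(self, dynamic_trials):
        n = distrl.simulate_neuron_dynamic(dynamic_trials, truth(), seed=0)
        fit = distrl.crossvalidate(n, dynamic_trials, "ALAS")
        assert fit.mean_test_r2 > 0.999
        assert fit.per_fold_test_r2.size == 10

    def test_pure_noise_neuron_scores_near_zero(self, dynamic_trials):
        rng = np.random.default_rng(2)
        n = NeuronRecord("a", "s", feedback_rate=rng.normal(size=len(dynamic_trials)))
        fit = distrl.crossvalidate(n, dynamic_trials, "ALAS")
        assert fit.mean_test_r2 < 0.08

    def test_population_batched_matches_per_neuron(self, dynamic_trials, coupled_dynamic_population):
        pop = coupled_dynamic_population[:4]
        batched = distrl.crossvalidate_population(pop, dynamic_trials, ["ALAS"])
        for n, f_b in zip(pop, batched["ALAS"]):
            f_s = distrl.crossvalidate(n, dynamic_trials, "ALAS")
            assert np.allclose(f_s.per_fold_test_r2, f_b.per_fold_test_r2)
            assert f_s.best_params.alpha_plus == f_b.best_params.alpha_plus
            assert f_s.best_params.s == f_b.best_params.s

    def test_refit_choice_preserves_model_ranking(self, dynamic_trials, coupled_dynamic_population):
        pop = coupled_dynamic_population[:10]
        means = {}
        for refit in (True, False):
            fits = distrl.crossvalidate_population(
                pop, dynamic_trials, MODEL_ORDER, refit_linear=refit
            )
            means[refit] = [
                np.mean([f.mean_test_r2 for f in fits[m]]) for m in MODEL_ORDER
            ]
        assert stats.spearmanr(means[True], means[False]).statistic > 0.7

    def test_fold_count_adapts_with_warning(self):
        with pytest.warns(UserWarning):
            folds = _contiguous_folds(60, 10, min_fold_size=10)
        assert len(folds) == 6
        with pytest.raises(ValueError):
            _contiguous_folds(3, 2, min_fold_size=10)


class TestComparison:
    def test_identical_fits_give_t_zero_p_one(self, dynamic_trials, coupled_dynamic_population):
        fits = distrl.crossvalidate_population(
            coupled_dynamic_population[:5], dynamic_trials, ["ALAS"]
        )
        dup = {"A": fits["ALAS"], "B": fits["ALAS"]}
        row = distrl.compare_models(dup).iloc[0]
        assert row.t == 0.0 and row.p == 1.0 and row.mean_diff == 0.0

    def test_mismatched_neuron_sets_rejected(self, dynamic_trials, coupled_dynamic_population):
        fits = distrl.crossvalidate_population(
            coupled_dynamic_population[:4], dynamic_trials, ["ALAS", "SLSS"]
        )
        fits["SLSS"] = fits["SLSS"][:3]
        with pytest.raises(ValueError):
            distrl.compare_models(fits)


class TestParameterAnalyses:
    def test_noiseless_population_has_perfect_consistency(self, dynamic_trials):
        pop = [
            distrl.simulate_neuron_dynamic(
                dynamic_trials,
                truth(tau=t, s_true=t, alpha_plus=0.5 * t, alpha_minus=0.5 * (1 - t)),
                seed=i,
                neuron_id=f"n{i}",
            )
            for i, t in enumerate(np.linspace(0.25, 0.75, 8))
        ]
        res = distrl.parameter_consistency(pop, dynamic_trials)
        assert res["learning_asymmetry"][0] > 0.95
        assert res["scaling"][0] > 0.95

    def test_noise_population_has_null_consistency(self, dynamic_trials):
        rng = np.random.default_rng(3)
        pop = [
            NeuronRecord(f"x{i}", "s", feedback_rate=rng.normal(size=len(dynamic_trials)))
            for i in range(20)
        ]
        res = distrl.parameter_consistency(pop, dynamic_trials)
        assert abs(res["learning_asymmetry"][0]) < 0.45

    def test_coupled_population_links_scaling_to_learning(self, dynamic_trials, coupled_dynamic_population):
        res = distrl.scaling_learning_correlation(
            coupled_dynamic_population, dynamic_trials
        )
        assert res["mean_r"] > 0.4
        assert res["geometric_mean_p"] < 0.05

    def test_uncoupled_population_shows_no_link(self, dynamic_trials):
        pop = distrl.make_population(
            dynamic_trials, 20, seed=30, coupled=False, noise_sd=1.25,
            negative_fraction=0.0,
        )
        res = distrl.scaling_learning_correlation(pop, dynamic_trials)
        assert abs(res["mean_r"]) < 0.4
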