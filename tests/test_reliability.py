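"""Split-half reliability, generalization, topography and subject controls."""

import numpy as np
import pytest
from scipy import stats

import distrl
from distrl.neurons import NeuronGroundTruth, NeuronRecord
from distrl.pipeline import make_reversal_estimator, static_strata
from distrl.reliability import normalized_ap, stratified_half_masks


def value_population(trials, n=40, noise_sd=2.5, seed=0):
    rng = np.random.default_rng(seed)
    pop = []
    for i, tau in enumerate(rng.uniform(0.2, 0.8, size=n)):
        g = NeuronGroundTruth(
            tau=tau, s_true=tau, alpha_plus=0.3, alpha_minus=0.3, noise_sd=noise_sd
        )
        pop.append(
            distrl.simulate_neuron_static(
                trials, g, seed=int(rng.integers(2**31)), neuron_id=f"n{i}"
            )
        )
    return pop


def noise_population(n_trials, n=40, seed=0):
    rng = np.random.default_rng(seed)
    return [
        NeuronRecord(f"x{i}", "s", feedback_rate=rng.normal(size=n_trials),
                     choice_rate=rng.normal(size=n_trials))
        for i in range(n)
    ]


class TestSplitHalf:
    def test_stratified_halves_cover_all_strata(self):
        rng = np.random.default_rng(1)
        strata = np.repeat(np.arange(6), 20)
        h1, h2 = stratified_half_masks(strata, rng)
        assert not np.any(h1 & h2) and np.all(h1 | h2)
        for s in range(6):
            assert h1[strata == s].sum() == 10

    def test_deterministic_estimator_gives_perfect_reliability(self, static_trials):
        pop = value_population(static_trials, n=20)
        taus = {n.neuron_id: float(n.ground_truth.tau) for n in pop}
        res = distrl.split_half_consistency(
            lambda n, mask: taus[n.neuron_id], pop, n_partitions=20, seed=2
        )
        assert np.all(res.per_partition_r >= 1 - 1e-12)
        assert res.bootstrap_p == 0.0

    def test_reliable_population_summaries_are_significant(self, static_trials):
        pop = value_population(static_trials, n=30, noise_sd=2.5, seed=3)
        res = distrl.split_half_consistency(
            make_reversal_estimator(static_trials),
            pop,
            n_partitions=50,
            seed=4,
            strata_fn=static_strata(static_trials),
        )
        assert res.mean_r > 0.5
        assert res.geometric_mean_p < 0.01
        assert res.bootstrap_p < 0.05

    def test_null_population_is_not_significant(self, static_trials):
        # a fixed noise dataset still couples the two halves through the
        # full-data value, so mean_r fluctuates dataset-to-dataset; only
        # the significance summaries are expected to stay null
        pop = noise_population(len(static_trials), n=40, seed=5)
        est = lambda n, mask: float(n.feedback_rate[mask].mean())
        res = distrl.split_half_consistency(est, pop, n_partitions=200, seed=6)
        assert abs(res.mean_r) < 0.3
        assert res.geometric_mean_p > 0.05
        assert res.bootstrap_p > 0.05

    def test_noise_estimator_gives_calibrated_null(self, static_trials):
        # an estimator returning fresh noise makes the two half-estimates
        # exactly independent, the strict null of the machinery
        pop = noise_population(len(static_trials), n=40, seed=5)
        rng = np.random.default_rng(55)
        est = lambda n, mask: float(rng.normal())
        res = distrl.split_half_consistency(est, pop, n_partitions=300, seed=7)
        assert abs(res.mean_r) < 0.05
        assert res.geometric_mean_p > 0.05
        assert abs((res.per_partition_p < 0.05).mean() - 0.05) < 0.03

    def test_summary_invariants_hold(self, static_trials):
        pop = noise_population(len(static_trials), n=10, seed=7)
        est = lambda n, mask: float(n.feedback_rate[mask].mean())
        res = distrl.split_half_consistency(est, pop, n_partitions=30, seed=8)
        assert res.geometric_mean_p == pytest.approx(
            np.exp(np.log(res.per_partition_p).mean())
        )
        assert res.bootstrap_p == pytest.approx((res.per_partition_r <= 0).mean())

    def test_mostly_undefined_estimator_raises(self, static_trials):
        pop = noise_population(len(static_trials), n=10, seed=9)
        res_fn = lambda n, mask: None if n.neuron_id != "x0" else 1.0
        with pytest.raises(ValueError):
            distrl.split_half_consistency(res_fn, pop, n_partitions=5, seed=10)


class TestStimulusSetGeneralization:
    def test_value_tuned_neurons_generalize(self, static_trials_98):
        pop = value_population(static_trials_98, n=40, noise_sd=2.5, seed=11)
        r, p, n = distrl.stimulus_set_generalization(
            pop, static_trials_98, make_reversal_estimator(static_trials_98)
        )
        assert r > 0.3 and p < 0.05

    def test_set_specific_tuning_does_not_generalize(self, static_trials_98):
        # tuning to stimulus identity: an independent random level profile
        # per (set, level) cell, so set-1 and set-2 estimates share nothing
        rng = np.random.default_rng(12)
        t = static_trials_98
        lv = t["chosen_value_level"].to_numpy()
        ss = t["stimulus_set"].to_numpy()
        pop = []
        for i in range(40):
            means = {(s, l): rng.normal() for s in (1, 2) for l in range(0, 5)}
            rate = np.array([means[(s, l)] for s, l in zip(ss, lv)])
            pop.append(
                NeuronRecord(
                    f"n{i}", "s",
                    feedback_rate=rate,
                    choice_rate=rate + rng.normal(0, 0.1, len(t)),
                )
            )
        r, p, n = distrl.stimulus_set_generalization(
            pop, t, make_reversal_estimator(t)
        )
        assert abs(r) < 0.35 and p > 0.01

    def test_identical_sets_give_perfect_correlation(self, static_trials):
        # duplicate every trial once per set label: the two masks select
        # identical data, so the estimates match exactly
        import pandas as pd

        t1 = static_trials.copy()
        t1["stimulus_set"] = 1
        t2 = static_trials.copy()
        t2["stimulus_set"] = 2
        doubled = pd.concat([t1, t2], ignore_index=True)
        pop = []
        for i, n in enumerate(value_population(static_trials, n=10, noise_sd=1.0, seed=13)):
            pop.append(
                NeuronRecord(
                    n.neuron_id, "s",
                    choice_rate=np.concatenate([n.choice_rate, n.choice_rate]),
                    feedback_rate=np.concatenate([n.feedback_rate, n.feedback_rate]),
                )
            )
        r, p, _ = distrl.stimulus_set_generalization(
            pop, doubled, make_reversal_estimator(doubled)
        )
        assert r == pytest.approx(1.0)


class TestTopography:
    def test_min_max_normalization_within_subject(self):
        pop = [
            NeuronRecord(f"n{i}", "s1", feedback_rate=np.zeros(4), ap_mm=ap)
            for i, ap in enumerate([30.0, 33.0, 36.0])
        ]
        norm = normalized_ap(pop)
        assert [norm[f"n{i}"] for i in range(3)] == [0.0, 0.5, 1.0]

    def test_constant_ap_subject_excluded(self):
        pop = [
            NeuronRecord("a", "s1", feedback_rate=np.zeros(4), ap_mm=30.0),
            NeuronRecord("b", "s1", feedback_rate=np.zeros(4), ap_mm=30.0),
        ]
        assert normalized_ap(pop) == {}

    def test_positive_gradient_detected(self, static_trials):
        pop = distrl.make_population(
            static_trials, 60, seed=14, topography_slope=0.7, noise_sd=1.0
        )
        optimism = {n.neuron_id: n.ground_truth.tau for n in pop}
        r, p, _ = distrl.topography_correlation(pop, optimism)
        assert r > 0.3 and p < 0.05

    def test_null_gradient_not_detected(self, static_trials):
        rs = []
        for seed in range(5):
            pop = distrl.make_population(
                static_trials, 60, seed=20 + seed, topography_slope=0.0
            )
            optimism = {n.neuron_id: n.ground_truth.tau for n in pop}
            r, _, _ = distrl.topography_correlation(pop, optimism)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15


class TestSubjectCovariateGLM:
    def test_within_subject_effect_survives_subject_offsets(self):
        rng = np.random.default_rng(15)
        subj = np.repeat(["a", "b"], 30)
        x = rng.normal(size=60)
        y = 2.0 * x + np.where(subj == "a", 5.0, -5.0) + rng.normal(0, 0.5, 60)
        t, p = distrl.subject_covariate_glm(y, x, subj)
        assert p < 0.001 and t > 0

    def test_pure_subject_effect_gives_null_predictor(self):
        rng = np.random.default_rng(16)
        subj = np.repeat(["a", "b"], 30)
        x = rng.normal(size=60)
        y = np.where(subj == "a", 5.0, -5.0) + rng.normal(0, 0.5, 60)
        t, p = distrl.subject_covariate_glm(y, x, subj)
        assert abs(t) < 2.5

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            distrl.subject_covariate_glm(
                np.ones(10), np.arange(10.0), np.repeat(["a"], 10)
            )
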