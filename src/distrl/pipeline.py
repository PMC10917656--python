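"""End-to-end synthetic analysis runs.

``run_static_analysis`` regenerates the full static-task analysis chain on
a simulated population — RPE screening, sign alignment, reversal-point and
asymmetric-scaling estimation, split-half consistency, stimulus-set
generalization, the scaling-predicts-reversal correlation (with a
subject-covariate control), and the anterior-posterior topography test —
plus ground-truth recovery diagnostics only a simulation can provide.

``run_dynamic_analysis`` does the same for the learning task: RPE-proxy
screening, cross-validated comparison of the four Rescorla-Wagner
variants, fitted-parameter consistency, the learning-scaling coupling
test, and the RPE sign-transition analysis.

Both return a plain ``dict`` report (JSON-serialisable) and optionally
write it, with the intermediate tables, to ``config.output_dir``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from . import io as dio
from .config import RunConfig
from .models import (
    MODEL_ORDER,
    compare_models,
    crossvalidate_population,
    fits_table,
    parameter_consistency,
    rpe_sequence,
    scaling_learning_correlation,
)
from .neurons import make_population, population_truth_table
from .optimism import (
    asymmetric_scaling,
    estimate_optimism,
    estimates_table,
    neuron_optimism,
    reversal_point,
)
from .reliability import (
    split_half_consistency,
    stimulus_set_generalization,
    subject_covariate_glm,
    topography_correlation,
)
from .screening import (
    align_sign,
    screen_bayer_glimcher,
    screen_ledger,
    screen_opposite_sign,
    screen_rpe_regressor,
)
from .tasks import generate_dynamic_task, generate_static_task
from .transitions import (
    correlate_with_model_asymmetry,
    label_sign_transitions,
    transition_slopes,
)

log = logging.getLogger("distrl.pipeline")


def make_reversal_estimator(trials):
    """Per-neuron reversal-point statistic on a trial mask (None if no crossing)."""
    levels = trials["chosen_value_level"].to_numpy()
    valid = levels >= 1

    def estimator(neuron, mask):
        m = np.asarray(mask, dtype=bool) & valid
        if m.sum() < 8 or np.unique(levels[m]).size < 2:
            return None
        rp, _ = reversal_point(neuron.choice_rate, levels, m)
        return rp

    return estimator


def make_scaling_estimator(trials, min_trials: int = 5):
    """Per-neuron asymmetric-scaling statistic on a trial mask."""
    levels = trials["chosen_value_level"].to_numpy()
    p = trials["chosen_probability"].to_numpy()
    rew = trials["rewarded"].to_numpy()
    valid = levels >= 1

    def estimator(neuron, mask):
        m = np.asarray(mask, dtype=bool) & valid
        try:
            _, _, sa, _ = asymmetric_scaling(
                neuron.feedback_rate[m], p[m], rew[m], min_trials=min_trials
            )
        except ValueError:
            return None
        return sa

    return estimator


def static_strata(trials):
    """Stratum labels (value level x reward outcome) for balanced halves."""
    lab = (
        trials["chosen_value_level"].to_numpy() * 2 + trials["rewarded"].to_numpy()
    )

    def strata_fn(neuron):
        return lab

    return strata_fn


def run_static_analysis(config: RunConfig) -> dict:
    """Full static-task analysis on a freshly simulated population."""
    an = config.analysis
    trials = generate_static_task(
        config.task.n_trials, config.task.accuracy, seed=config.stage_seed("task")
    )
    pop = config.population
    neurons = make_population(
        trials,
        pop.n_neurons,
        seed=config.stage_seed("population"),
        tau_range=pop.tau_range,
        alpha_total_range=pop.alpha_total_range,
        coupled=pop.coupled,
        topography_slope=pop.topography_slope,
        distractor_fraction=pop.distractor_fraction,
        negative_fraction=pop.negative_fraction,
        gain=pop.gain,
        baseline=pop.baseline,
        noise_sd=pop.noise_sd,
        n_subjects=pop.n_subjects,
    )
    screens = [screen_opposite_sign(n, trials, an.alpha) for n in neurons]
    ledger = screen_ledger(screens)
    passed = [
        align_sign(n, s) for n, s in zip(neurons, screens) if s.passed
    ]
    for n, s in zip(neurons, screens):
        if not s.passed:
            log.info("excluded %s: %s", n.neuron_id, s.reason or "screen failed")
    report: dict = {
        "kind": "static",
        "master_seed": config.master_seed,
        "n_neurons_simulated": len(neurons),
        "n_neurons_passed": len(passed),
    }
    tables = {"screens": ledger, "ground_truth": population_truth_table(neurons)}
    if len(passed) < 3:
        report["status"] = "empty"
        if config.output_dir:
            dio.write_report(config.output_dir, report, tables)
        return report
    report["status"] = "ok"

    estimates = [estimate_optimism(n, trials) for n in passed]
    composite = neuron_optimism(estimates)
    tables["optimism"] = estimates_table(estimates)

    rev_est = make_reversal_estimator(trials)
    sca_est = make_scaling_estimator(trials)
    strata_fn = static_strata(trials)
    seed_c = config.stage_seed("consistency")
    report["reversal_consistency"] = split_half_consistency(
        rev_est, passed, an.n_partitions, seed=seed_c, strata_fn=strata_fn
    ).to_dict()
    report["scaling_consistency"] = split_half_consistency(
        sca_est, passed, an.n_partitions, seed=seed_c + 1, strata_fn=strata_fn
    ).to_dict()

    r, p, n_used = stimulus_set_generalization(passed, trials, rev_est)
    report["stimulus_set_generalization"] = {"r": r, "p": p, "n": n_used}

    both = [
        e for e in estimates
        if e.reversal_point is not None and e.scaling_asymmetry is not None
    ]
    rp_vals = np.array([e.reversal_point for e in both])
    sa_vals = np.array([e.scaling_asymmetry for e in both])
    r_sr, p_sr = stats.pearsonr(sa_vals, rp_vals)
    report["scaling_reversal_correlation"] = {
        "r": float(r_sr), "p": float(p_sr), "n": len(both)
    }
    subj = {n.neuron_id: n.subject_id for n in passed}
    ids = [e.neuron_id for e in both]
    if len(set(subj[i] for i in ids)) >= 2:
        t_g, p_g = subject_covariate_glm(
            rp_vals, sa_vals, np.array([subj[i] for i in ids])
        )
        report["scaling_reversal_subject_glm"] = {"t": t_g, "p": p_g}

    r_t, p_t, n_t = topography_correlation(passed, composite)
    report["topography"] = {"r": r_t, "p": p_t, "n": n_t}

    # ground-truth recovery diagnostics (simulation only)
    truth = {n.neuron_id: n.ground_truth for n in passed if n.ground_truth}
    rec = [
        (e.reversal_point, e.scaling_asymmetry, truth[e.neuron_id].tau,
         truth[e.neuron_id].s_true)
        for e in both
        if e.neuron_id in truth and truth[e.neuron_id].kind == "rpe"
    ]
    if len(rec) >= 3:
        rp_a, sa_a, tau_a, s_a = map(np.array, zip(*rec))
        report["recovery"] = {
            "spearman_reversal_vs_tau": float(stats.spearmanr(rp_a, tau_a).statistic),
            "spearman_scaling_vs_s": float(stats.spearmanr(sa_a, s_a).statistic),
            "n": len(rec),
        }
    if config.output_dir:
        dio.write_report(config.output_dir, report, tables)
    return report


def run_dynamic_analysis(config: RunConfig, include_bayer_glimcher: bool = True) -> dict:
    """Full dynamic-task (learning) analysis on a simulated population."""
    an = config.analysis
    trials = generate_dynamic_task(
        config.task.n_trials, seed=config.stage_seed("task"), n_cues=config.task.n_cues
    )
    pop = config.population
    neurons = make_population(
        trials,
        pop.n_neurons,
        seed=config.stage_seed("population"),
        tau_range=pop.tau_range,
        alpha_total_range=pop.alpha_total_range,
        coupled=pop.coupled,
        topography_slope=pop.topography_slope,
        distractor_fraction=pop.distractor_fraction,
        negative_fraction=pop.negative_fraction,
        gain=pop.gain,
        baseline=pop.baseline,
        noise_sd=pop.noise_sd,
        n_subjects=pop.n_subjects,
        v_init=an.v_init,
    )
    # screening proxy: RPEs from a canonical symmetric Rescorla-Wagner run
    # on the realised choice/reward sequence (alpha = 0.5)
    proxy_delta, _ = rpe_sequence(trials, 0.5, 0.5, v_init=an.v_init)
    screens = [screen_rpe_regressor(n, proxy_delta, an.alpha) for n in neurons]
    ledger = screen_ledger(screens)
    if include_bayer_glimcher:
        bg = [screen_bayer_glimcher(n, trials, an.alpha) for n in neurons]
        ledger = screen_ledger(screens + bg)
    passed = [align_sign(n, s) for n, s in zip(neurons, screens) if s.passed]
    report: dict = {
        "kind": "dynamic",
        "master_seed": config.master_seed,
        "n_neurons_simulated": len(neurons),
        "n_neurons_passed": len(passed),
    }
    tables = {"screens": ledger, "ground_truth": population_truth_table(neurons)}
    if len(passed) < 3:
        report["status"] = "empty"
        if config.output_dir:
            dio.write_report(config.output_dir, report, tables)
        return report
    report["status"] = "ok"

    fits = crossvalidate_population(
        passed,
        trials,
        MODEL_ORDER,
        n_folds=an.n_folds,
        refit_linear=an.refit_linear,
        grid_step=an.grid_step,
        v_init=an.v_init,
    )
    comparison = compare_models(fits)
    tables["model_fits"] = fits_table(fits)
    tables["model_comparison"] = comparison
    report["model_comparison"] = comparison.to_dict(orient="records")
    report["mean_test_r2"] = {
        m: float(np.mean([f.mean_test_r2 for f in fl])) for m, fl in fits.items()
    }
    report["parameter_consistency"] = {
        k: v
        for k, v in parameter_consistency(
            passed, trials, "ALAS", an.grid_step, an.v_init
        ).items()
        if k != "excluded"
    }
    report["scaling_learning_correlation"] = scaling_learning_correlation(
        passed, trials, "ALAS", an.grid_step, an.v_init
    )

    # transition analysis with each neuron's best model by held-out R^2
    by_id = {m: {f.neuron_id: f for f in fl} for m, fl in fits.items()}
    profiles = []
    for n in passed:
        best_m = max(MODEL_ORDER, key=lambda m: by_id[m][n.neuron_id].mean_test_r2)
        bp = by_id[best_m][n.neuron_id].best_params
        delta, _ = rpe_sequence(trials, bp.alpha_plus, bp.alpha_minus, an.v_init)
        prof = transition_slopes(n, label_sign_transitions(delta), trials)
        if prof is not None:
            profiles.append(prof)
    if len(profiles) >= 3:
        r_tr, p_tr, n_tr = correlate_with_model_asymmetry(profiles, fits["ALAS"])
        report["transition_asymmetry_correlation"] = {"r": r_tr, "p": p_tr, "n": n_tr}

    truth = {n.neuron_id: n.ground_truth for n in passed if n.ground_truth}
    rec = [
        (f.learning_asymmetry, f.best_params.s,
         truth[f.neuron_id].learning_asymmetry, truth[f.neuron_id].s_true)
        for f in fits["ALAS"]
        if f.neuron_id in truth
        and truth[f.neuron_id].kind == "rpe"
        and f.learning_asymmetry is not None
    ]
    if len(rec) >= 3:
        la_f, s_f, la_t, s_t = map(np.array, zip(*rec))
        report["recovery"] = {
            "spearman_learning_asymmetry": float(stats.spearmanr(la_f, la_t).statistic),
            "spearman_scaling": float(stats.spearmanr(s_f, s_t).statistic),
            "n": len(rec),
        }
    if config.output_dir:
        dio.write_report(config.output_dir, report, tables)
    return report
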