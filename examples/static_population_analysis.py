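"""Full static-task population analysis on synthetic ground truth.

Simulates a 40-neuron population with a known anterior-posterior optimism
gradient, screens for RPE coding, and runs the reliability, generalization
and topography statistics.
"""

import distrl

config = distrl.RunConfig(
    master_seed=3,
    task=distrl.TaskConfig(kind="static", n_trials=600),
    population=distrl.PopulationConfig(
        n_neurons=40, noise_sd=2.0, topography_slope=0.6
    ),
    analysis=distrl.AnalysisConfig(n_partitions=100),
)
rep = distrl.run_static_analysis(config)

print(f"neurons passing the RPE screen: {rep['n_neurons_passed']}/{rep['n_neurons_simulated']}")
rc = rep["reversal_consistency"]
print(f"reversal split-half: mean r = {rc['mean_r']:.2f}, geometric mean p = {rc['geometric_mean_p']:.2e}")
sg = rep["stimulus_set_generalization"]
print(f"across stimulus sets: r = {sg['r']:.2f}, p = {sg['p']:.2e}")
sr = rep["scaling_reversal_correlation"]
print(f"scaling asymmetry predicts reversal point: r = {sr['r']:.2f}, p = {sr['p']:.2e}")
tp = rep["topography"]
print(f"anterior-posterior topography: r = {tp['r']:.2f}, p = {tp['p']:.3f}")
print(f"recovery of simulated tau (rank corr): {rep['recovery']['spearman_reversal_vs_tau']:.2f}")
print("Consistent split-half and cross-set correlations show the optimism")
print("diversity is a stable property of each unit, not estimation noise.")
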