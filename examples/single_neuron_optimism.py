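"""Estimate one simulated neuron's optimism: reversal point and scaling.

Builds a static probabilistic-cue session, simulates an optimistic RPE
neuron (target expectile tau = 0.7), and recovers its optimism from the
firing rates alone.
"""

import distrl
from distrl.neurons import NeuronGroundTruth

trials = distrl.generate_static_task(n_trials=2000, accuracy=0.98, seed=1)
truth = NeuronGroundTruth(
    tau=0.7, s_true=0.7, alpha_plus=0.35, alpha_minus=0.15,
    gain=5.0, baseline=10.0, noise_sd=1.5,
)
neuron = distrl.simulate_neuron_static(trials, truth, seed=2)

est = distrl.estimate_optimism(neuron, trials)
print(f"reversal point     : {est.reversal_point:.3f}   (2.5 = neutral; >2.5 optimistic)")
print(f"quadratic concavity: {est.quadratic_beta2:.3f}   (>0 = convex, optimistic)")
print(f"scaling asymmetry  : {est.scaling_asymmetry:.3f}   (beta+/(beta+ + beta-); true S = {truth.s_true})")
print("An optimistic unit responds above its mean rate only for the highest")
print("cue values and weighs positive RPEs more than negative ones.")
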