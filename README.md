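# distrl

Detecting signatures of **distributional reinforcement learning** in
single-neuron firing rates.

Classic reinforcement learning assumes every value-coding neuron tracks the
*mean* of the reward distribution. Distributional RL instead predicts a
population of units that each learn a different **expectile** of that
distribution: a unit that weighs positive reward prediction errors (RPEs,
δ = r − V) more than negative ones converges to a value above the mean
(an "optimist"), and vice versa. `distrl` implements the full analysis
chain used to test these predictions in cortical recordings — and, because
such recordings are not publicly available, pairs it with a synthetic-data
generator that emulates the two task designs and neuron populations with
known ground truth, so every estimator is validated end to end against the
parameters that generated the data.

The package is aimed at computational/systems neuroscientists analysing
trial-resolved firing rates, and at methodologists who want a tested
reference implementation of these estimators.

## What it computes

For each neuron (after RPE-coding screens and sign alignment):

- **Reversal point** — the interpolated cue value at which the z-scored
  choice-epoch response crosses zero; 2.5 is neutral on four value levels
  coded 1–4, above is optimistic.
- **Quadratic concavity** — β₂ from FR = β₀ + β₁R + β₂R², an alternative
  index of the same nonlinearity.
- **Asymmetric scaling** — β⁺/(β⁺+β⁻), from regressions of the feedback
  response on cued probability run separately on rewarded (positive-RPE)
  and unrewarded (negative-RPE) trials.
- **Asymmetric learning** — α⁺/(α⁺+α⁻) from a grid-search fit
  (0.025 steps) of four nested Rescorla–Wagner read-out models
  (SLSS/SLAS/ALSS/ALAS: symmetric/asymmetric learning × scaling, with the
  single-parameter scaled regressor x = δ·S for δ>0, δ·(1−S) for δ≤0),
  compared by tenfold cross-validated held-out R².

Population statistics: split-half consistency over many random partitions
(mean r, geometric-mean p, bootstrap p), stimulus-set generalization,
anterior–posterior topography with within-subject normalized coordinates,
subject-covariate controls, RPE sign-transition dynamics, and a
brute-force expectile oracle tying α⁺/α⁻ asymmetry to expectile codes.

## Worked example

```bash
python examples/single_neuron_optimism.py
```

simulates an optimistic RPE neuron (target expectile τ = 0.7) on a
2,000-trial probabilistic-cue session and recovers its optimism from the
rates alone:

```
reversal point     : 2.874   (2.5 = neutral; >2.5 optimistic)
quadratic concavity: 0.978   (>0 = convex, optimistic)
scaling asymmetry  : 0.741   (beta+/(beta+ + beta-); true S = 0.7)
```

The reversal point sits above the neutral 2.5 and the scaling asymmetry
recovers the generative S ≈ 0.7: both measures agree that this unit's
value prediction sits high in the reward distribution. The other examples
(`static_population_analysis.py`, `dynamic_model_comparison.py`,
`expectile_convergence.py`) run the population-level analyses; on a
coupled population the fully distributional ALAS model wins the
cross-validated comparison and the fitted asymmetries are consistent
across independent data halves.

```python
import distrl

config = distrl.RunConfig(master_seed=3)
report = distrl.run_static_analysis(config)   # or run_dynamic_analysis
```

Reports are plain dicts (JSON-serialisable); with `config.output_dir` set,
all intermediate tables (screens, estimates, fits, ground truth) are
written as CSV alongside `report.json`.

## Layout

- `src/distrl/tasks.py`, `neurons.py` — task simulators and neuron
  populations with ground truth
- `src/distrl/screening.py` — RPE-coding inclusion screens, sign alignment
- `src/distrl/optimism.py` — reversal point, quadratic index, scaling
  asymmetry, composite optimism
- `src/distrl/reliability.py` — split-half consistency, generalization,
  topography, subject controls
- `src/distrl/models.py` — the four RW variants, grid fitting, CV
  comparison, parameter analyses
- `src/distrl/transitions.py` — firing dynamics around RPE sign switches
- `src/distrl/expectiles.py` — expectile oracle and convergence checks
- `src/distrl/pipeline.py`, `config.py`, `io.py` — end-to-end runs,
  validated configs, CSV/JSON serialization

See `docs/methods.md` for the models, conventions and design decisions.
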