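"""Simulated neuron populations with known distributional-RL ground truth.

Each simulated unit is a reward-prediction-error (RPE) neuron whose
window-averaged firing rate is an affine read-out of an asymmetrically
scaled RPE:

    rate = baseline + coding_sign * gain * asym(delta; S) + noise

where ``asym`` weights positive and negative RPEs differently (the scaling
asymmetry S), and — in the dynamic task — the value entering delta = r - V
is itself updated with separate learning rates alpha+ / alpha- (the
learning asymmetry). When generation is "coupled", a unit's target
expectile tau, its scaling asymmetry and its learning-rate ratio all agree:
tau = S = alpha+/(alpha+ + alpha-), the configuration distributional RL
predicts. Distractor units (value-insensitive, or violating the RPE sign
signature) can be mixed in to exercise the selectivity screens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .expectiles import expectile_oracle
from .tasks import is_static


@dataclass
class NeuronGroundTruth:
    """Generative parameters of one simulated unit.

    ``tau`` is the target expectile position in (0,1); ``s_true`` the
    asymmetric scaling; ``alpha_plus``/``alpha_minus`` the learning rates;
    ``gain`` (rate units per unit scaled RPE) and ``baseline`` (rate units)
    the affine read-out; ``coding_sign`` +1/-1; ``noise_sd`` the Gaussian
    rate noise s.d.; ``ap_mm`` the anterior-posterior coordinate;
    ``kind`` is 'rpe' for genuine RPE coders, or 'noise' / 'same_sign'
    for distractors.
    """

    tau: float
    s_true: float
    alpha_plus: float
    alpha_minus: float
    gain: float = 5.0
    baseline: float = 10.0
    coding_sign: int = 1
    noise_sd: float = 2.5
    ap_mm: float = 33.0
    kind: str = "rpe"

    def __post_init__(self):
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0,1), got {self.tau}")
        if not 0.0 <= self.s_true <= 1.0:
            raise ValueError(f"s_true must be in [0,1], got {self.s_true}")
        for name in ("alpha_plus", "alpha_minus"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {a}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.coding_sign not in (1, -1):
            raise ValueError("coding_sign must be +1 or -1")

    @property
    def learning_asymmetry(self) -> float:
        return self.alpha_plus / (self.alpha_plus + self.alpha_minus)


@dataclass
class NeuronRecord:
    """Per-trial epoch rates and metadata for one unit.

    ``choice_rate`` is present only for static-task sessions (the dynamic
    task's analyses use the feedback epoch alone).
    """

    neuron_id: str
    subject_id: str
    feedback_rate: np.ndarray
    choice_rate: np.ndarray | None = None
    region: str = "ACC"
    ap_mm: float = 33.0
    ground_truth: NeuronGroundTruth | None = None
    sign_aligned: bool = False

    def __post_init__(self):
        self.feedback_rate = np.asarray(self.feedback_rate, dtype=float)
        if not np.all(np.isfinite(self.feedback_rate)):
            raise ValueError("feedback_rate contains non-finite values")
        if self.choice_rate is not None:
            self.choice_rate = np.asarray(self.choice_rate, dtype=float)
            if self.choice_rate.shape != self.feedback_rate.shape:
                raise ValueError("choice_rate and feedback_rate lengths differ")
            if not np.all(np.isfinite(self.choice_rate)):
                raise ValueError("choice_rate contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.feedback_rate.size


def asym_scale(delta: np.ndarray, s: float) -> np.ndarray:
    """Asymmetric RPE scaling 2*S*delta (delta>0) / 2*(1-S)*delta (delta<=0).

    The factor 2 makes S=0.5 the identity, so symmetric units are exactly
    linear; any common positive factor is absorbed by the read-out gain.
    """
    delta = np.asarray(delta, dtype=float)
    return np.where(delta > 0, 2.0 * s * delta, 2.0 * (1.0 - s) * delta)


def simulate_neuron_static(
    trials: pd.DataFrame,
    truth: NeuronGroundTruth,
    seed: int | None = None,
    neuron_id: str = "n0",
    subject_id: str = "s0",
) -> NeuronRecord:
    """Simulate choice- and feedback-epoch rates on a static session.

    Choice epoch: the unit responds to the chosen value v (1-4 analysis
    coding) relative to its own value prediction, the tau-expectile V_tau of
    the session's chosen-value distribution — optimistic units (tau > 0.5)
    sit above the mean, so their response stays negative for all but the
    highest values. Feedback epoch: the RPE is r - p with r the Bernoulli
    outcome and p the cued probability. Both epochs pass the deviation
    through the unit's asymmetric scaling and affine read-out.

    Distractor kinds: 'noise' units ignore the task entirely; 'same_sign'
    units code the chosen value with the *same* sign at choice and feedback
    (violating the RPE signature the screens require).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rng = np.random.default_rng(seed)
    v = trials["chosen_value_level"].to_numpy(float)
    p = trials["chosen_probability"].to_numpy(float)
    r = trials["rewarded"].to_numpy(float)
    n = len(trials)
    noise_c = rng.normal(0.0, truth.noise_sd, size=n)
    noise_f = rng.normal(0.0, truth.noise_sd, size=n)
    if truth.kind == "noise":
        choice_sig = np.zeros(n)
        feedback_sig = np.zeros(n)
    elif truth.kind == "same_sign":
        vc = v - v.mean()
        choice_sig = vc
        feedback_sig = vc
    else:
        v_tau = expectile_oracle(v, truth.tau)
        choice_sig = asym_scale(v - v_tau, truth.s_true)
        feedback_sig = asym_scale(r - p, truth.s_true)
    k = truth.coding_sign * truth.gain
    return NeuronRecord(
        neuron_id=neuron_id,
        subject_id=subject_id,
        choice_rate=truth.baseline + k * choice_sig + noise_c,
        feedback_rate=truth.baseline + k * feedback_sig + noise_f,
        ap_mm=truth.ap_mm,
        ground_truth=truth,
    )


def simulate_neuron_dynamic(
    trials: pd.DataFrame,
    truth: NeuronGroundTruth,
    v_init: float = 0.5,
    seed: int | None = None,
    neuron_id: str = "n0",
    subject_id: str = "s0",
) -> NeuronRecord:
    """Simulate feedback-epoch rates on a dynamic (learning) session.

    Per-cue values start at ``v_init`` and are updated on each encounter
    with alpha+ for positive and alpha- for non-positive RPEs
    (delta = r - V, computed before the update). The rate read-out passes
    delta through the same ``asym_scale`` convention as the static
    generator (2*S / 2*(1-S), identity at S=0.5), so ``gain`` means "rate
    change per unit RPE of a symmetric unit" in both tasks; the factor 2
    relative to the fitted single-S read-out is absorbed by the fitted
    slope and affects no estimator.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if not 0.0 <= v_init <= 1.0:
        raise ValueError(f"v_init must be in [0,1], got {v_init}")
    rng = np.random.default_rng(seed)
    cue = trials["cue_id"].to_numpy(int)
    r = trials["delivered_reward"].to_numpy(float)
    n = len(trials)
    values = {c: float(v_init) for c in np.unique(cue)}
    delta = np.empty(n)
    for t in range(n):
        c = cue[t]
        d = r[t] - values[c]
        values[c] += (truth.alpha_plus if d > 0 else truth.alpha_minus) * d
        delta[t] = d
    if truth.kind == "noise":
        sig = np.zeros(n)
    elif truth.kind == "same_sign":
        # responds to reward itself on this and the previous trial (no RPE)
        sig = r + np.concatenate([[r[0]], r[:-1]])
    else:
        sig = asym_scale(delta, truth.s_true)
    rate = truth.baseline + truth.coding_sign * truth.gain * sig
    rate = rate + rng.normal(0.0, truth.noise_sd, size=n)
    return NeuronRecord(
        neuron_id=neuron_id,
        subject_id=subject_id,
        feedback_rate=rate,
        ap_mm=truth.ap_mm,
        ground_truth=truth,
    )


def make_population(
    task: pd.DataFrame,
    n_neurons: int,
    seed: int | None = None,
    tau_range: tuple[float, float] = (0.2, 0.8),
    alpha_total_range: tuple[float, float] = (0.2, 0.8),
    coupled: bool = True,
    topography_slope: float = 0.0,
    distractor_fraction: float = 0.0,
    negative_fraction: float = 0.5,
    gain: float = 5.0,
    baseline: float = 10.0,
    noise_sd: float = 2.5,
    n_subjects: int = 2,
    v_init: float = 0.5,
) -> list[NeuronRecord]:
    """Assemble a simulated population on one session's trial table.

    Per-neuron tau is drawn Uniform(tau_range); with ``coupled=True`` the
    scaling asymmetry and learning-rate ratio both equal tau
    (S = alpha+/(alpha+ + alpha-) = tau, with alpha+ + alpha- drawn
    Uniform(alpha_total_range)), the arrangement distributional RL
    predicts; uncoupled populations draw S independently of the alphas.
    ``topography_slope`` in [-1,1] is the target correlation between tau
    and the anterior-posterior coordinate. ``distractor_fraction`` of the
    units are non-RPE distractors (half task-insensitive, half same-sign
    coders); ``negative_fraction`` of units carry coding_sign -1.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if not -1.0 <= topography_slope <= 1.0:
        raise ValueError("topography_slope must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    static = is_static(task)
    neurons: list[NeuronRecord] = []
    taus = rng.uniform(*tau_range, size=n_neurons)
    totals = rng.uniform(*alpha_total_range, size=n_neurons)
    # AP coordinate: mix the tau rank signal with independent noise so that
    # corr(ap, tau) targets topography_slope; span ~30-38 mm per subject.
    z_tau = (taus - taus.mean()) / (taus.std() + 1e-12)
    mix = topography_slope * z_tau + np.sqrt(1 - topography_slope**2) * rng.normal(size=n_neurons)
    ap = 34.0 + 2.5 * mix
    n_distract = int(round(distractor_fraction * n_neurons))
    kinds = np.array(["rpe"] * n_neurons, dtype=object)
    if n_distract:
        idx = rng.choice(n_neurons, size=n_distract, replace=False)
        half = n_distract // 2
        kinds[idx[:half]] = "same_sign"
        kinds[idx[half:]] = "noise"
    signs = np.where(rng.random(n_neurons) < negative_fraction, -1, 1)
    subjects = rng.integers(0, n_subjects, size=n_neurons)
    for i in range(n_neurons):
        tau = float(taus[i])
        a_tot = float(totals[i])
        if coupled:
            s = tau
            a_plus, a_minus = a_tot * tau, a_tot * (1.0 - tau)
        else:
            s = float(rng.uniform(*tau_range))
            a_plus, a_minus = a_tot * tau, a_tot * (1.0 - tau)
        truth = NeuronGroundTruth(
            tau=tau,
            s_true=s,
            alpha_plus=a_plus,
            alpha_minus=a_minus,
            gain=gain,
            baseline=baseline,
            coding_sign=int(signs[i]),
            noise_sd=noise_sd,
            ap_mm=float(ap[i]),
            kind=str(kinds[i]),
        )
        child_seed = int(rng.integers(0, 2**31 - 1))
        kwargs = dict(
            neuron_id=f"n{i:04d}",
            subject_id=f"subj{subjects[i]}",
            seed=child_seed,
        )
        if static:
            neurons.append(simulate_neuron_static(task, truth, **kwargs))
        else:
            neurons.append(simulate_neuron_dynamic(task, truth, v_init=v_init, **kwargs))
    return neurons


def population_truth_table(neurons: list[NeuronRecord]) -> pd.DataFrame:
    """Ground-truth parameters of a simulated population as a DataFrame."""
    rows = []
    for n in neurons:
        t = n.ground_truth
        if t is None:
            continue
        rows.append(
            {
                "neuron_id": n.neuron_id,
                "subject_id": n.subject_id,
                "ap_mm": n.ap_mm,
                "tau": t.tau,
                "s_true": t.s_true,
                "alpha_plus": t.alpha_plus,
                "alpha_minus": t.alpha_minus,
                "learning_asymmetry": t.learning_asymmetry,
                "coding_sign": t.coding_sign,
                "kind": t.kind,
            }
        )
    return pd.DataFrame(rows)


def flip_record(neuron: NeuronRecord) -> NeuronRecord:
    """Return a copy with rates reflected about their means (sign flip)."""
    fb = 2.0 * neuron.feedback_rate.mean() - neuron.feedback_rate
    ch = None
    if neuron.choice_rate is not None:
        ch = 2.0 * neuron.choice_rate.mean() - neuron.choice_rate
    return replace(neuron, feedback_rate=fb, choice_rate=ch)
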