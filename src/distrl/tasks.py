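"""Synthetic task generators.

Two session dialects are supported:

* a *static* probabilistic-cue task: on each trial two cues of neighbouring
  reward probability are offered, the subject almost always takes the higher
  one, and reward is Bernoulli in the cued probability; and
* a *dynamic* reversal-learning task: four cues each carry one of three
  reward levels, and a cue's level is redrawn every five to nine encounters
  of that cue, forcing continual value learning.

Sessions are returned as :class:`pandas.DataFrame` objects (one row per
trial) so downstream estimators can use ordinary column arithmetic; the
column contracts are given in each generator's docstring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: reward probability attached to each static-task value level
LEVEL_PROBABILITIES = {1: 0.1, 2: 0.3, 3: 0.5, 4: 0.7, 5: 0.9}

#: the four adjacent-level cue pairs offered in the static task
STATIC_PAIRS = [(1, 2), (2, 3), (3, 4), (4, 5)]

#: numeric coding of the dynamic task's three reinforcement levels
DYNAMIC_REWARD_LEVELS = np.array([0.0, 0.5, 1.0])

STATIC_COLUMNS = [
    "trial_index",
    "pair_low_level",
    "pair_high_level",
    "chosen_level",
    "chosen_value_level",
    "chosen_probability",
    "stimulus_set",
    "rewarded",
]

DYNAMIC_COLUMNS = [
    "trial_index",
    "cue_id",
    "reward_level",
    "block_id",
    "delivered_reward",
]


def generate_static_task(
    n_trials: int, accuracy: float = 0.98, seed: int | None = None
) -> pd.DataFrame:
    """Simulate a static probabilistic-cue session.

    Parameters
    ----------
    n_trials
        Number of trials (>= 1).
    accuracy
        Probability of choosing the higher-valued cue of the offered pair.
        The default reflects near-ceiling performance.
    seed
        Seed for the trial-level randomness.

    Returns
    -------
    pandas.DataFrame
        Columns: ``trial_index``; ``pair_low_level``/``pair_high_level``
        (adjacent levels in 1..5, mapping to probabilities 0.1..0.9);
        ``chosen_level``; ``chosen_value_level`` (the 1-4 analysis coding of
        the chosen value, i.e. ``chosen_level - 1``; 0 marks the rarely
        chosen 0.1 option and is masked out of value analyses);
        ``chosen_probability``; ``stimulus_set`` (1 or 2, two stimuli per
        value level); ``rewarded`` (Bernoulli in the chosen probability).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if not np.isfinite(accuracy) or not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be a finite value in [0, 1], got {accuracy}")
    rng = np.random.default_rng(seed)
    pair_idx = rng.integers(0, len(STATIC_PAIRS), size=n_trials)
    pairs = np.asarray(STATIC_PAIRS)[pair_idx]
    take_higher = rng.random(n_trials) < accuracy
    chosen = np.where(take_higher, pairs[:, 1], pairs[:, 0])
    probs = np.array([LEVEL_PROBABILITIES[lv] for lv in range(1, 6)])[chosen - 1]
    rewarded = (rng.random(n_trials) < probs).astype(int)
    stim_set = rng.integers(1, 3, size=n_trials)
    return pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "pair_low_level": pairs[:, 0],
            "pair_high_level": pairs[:, 1],
            "chosen_level": chosen,
            "chosen_value_level": chosen - 1,
            "chosen_probability": probs,
            "stimulus_set": stim_set,
            "rewarded": rewarded,
        }
    )


def generate_dynamic_task(
    n_trials: int,
    seed: int | None = None,
    n_cues: int = 4,
    block_length_range: tuple[int, int] = (5, 9),
    choice_policy: str = "uniform",
    softmax_temperature: float = 0.2,
    value_alpha: float = 0.5,
) -> pd.DataFrame:
    """Simulate a dynamic reversal-learning session.

    Each cue carries one of three reward levels (0, 0.5, 1). A cue's level
    is constant within a block of 5-9 *encounters of that cue* and is then
    redrawn uniformly over the three levels (it may stay the same). The cue
    sampled on each trial is drawn uniformly by default; a softmax policy
    over running value estimates (learning rate ``value_alpha``) is
    available for sensitivity checks, since the analyses condition on the
    realised choice/reward sequence.

    Returns a DataFrame with columns ``trial_index``, ``cue_id`` (1-based
    chosen cue), ``reward_level`` (numeric level of the chosen cue),
    ``block_id`` (per-cue block counter) and ``delivered_reward``
    (== ``reward_level``).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    lo, hi = block_length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid block_length_range {block_length_range}")
    if choice_policy not in ("uniform", "softmax"):
        raise ValueError(f"unknown choice_policy {choice_policy!r}")
    rng = np.random.default_rng(seed)

    level = rng.integers(0, 3, size=n_cues)
    remaining = rng.integers(lo, hi + 1, size=n_cues)
    block = np.zeros(n_cues, dtype=int)
    values = np.full(n_cues, 0.5)

    cue_col = np.empty(n_trials, dtype=int)
    lvl_col = np.empty(n_trials)
    blk_col = np.empty(n_trials, dtype=int)
    for t in range(n_trials):
        if choice_policy == "uniform":
            c = rng.integers(0, n_cues)
        else:
            logits = values / softmax_temperature
            p = np.exp(logits - logits.max())
            p /= p.sum()
            c = rng.choice(n_cues, p=p)
        r = DYNAMIC_REWARD_LEVELS[level[c]]
        cue_col[t] = c + 1
        lvl_col[t] = r
        blk_col[t] = block[c]
        values[c] += value_alpha * (r - values[c])
        remaining[c] -= 1
        if remaining[c] == 0:
            level[c] = rng.integers(0, 3)
            remaining[c] = rng.integers(lo, hi + 1)
            block[c] += 1
    return pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "cue_id": cue_col,
            "reward_level": lvl_col,
            "block_id": blk_col,
            "delivered_reward": lvl_col,
        }
    )


def is_static(trials: pd.DataFrame) -> bool:
    """True if the trial table is in the static-task dialect."""
    return "chosen_probability" in trials.columns


def static_rpes(trials: pd.DataFrame) -> np.ndarray:
    """Feedback-epoch reward prediction errors for a static session.

    The expectation against which the outcome is compared is the cued
    probability itself (the cue fully specifies the gamble), so
    delta = r - p with r in {0, 1}: e.g. a rewarded trial at p = 0.9 yields
    delta = 0.1 and at p = 0.3 yields delta = 0.7.
    """
    return trials["rewarded"].to_numpy(float) - trials["chosen_probability"].to_numpy(float)
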