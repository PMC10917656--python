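"""Firing-rate dynamics around RPE sign transitions.

A model-guided, largely model-free check of asymmetric learning: using the
best-fitting model's RPE trace, find the trials on which the RPE sign
switches, and compare the change in firing between the first trial of the
switch and the next encounter of the same cue. A unit that learns faster
from positive RPEs raises its value sharply after the first positive
surprise, so its positive RPE — and hence its rate — decays steeply on the
next encounter, while its response after a first negative RPE barely
moves; pessimistic units show the mirror pattern. The signed contrast of
the two decay slopes therefore tracks the learning asymmetry
alpha+/(alpha+ + alpha-).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TransitionProfile:
    neuron_id: str
    mean_rate_first_pos: float
    mean_rate_next_pos: float
    mean_rate_first_neg: float
    mean_rate_next_neg: float
    slope_pos: float
    slope_neg: float
    slope_asymmetry: float
    n_pos_events: int
    n_neg_events: int


def label_sign_transitions(delta_sequence: np.ndarray) -> list[tuple[int, str]]:
    """Trials at which the RPE sign switches.

    Signs follow the delta <= 0 convention (zero counts as negative). An
    event ``(t, 'pos')`` marks a switch into positive RPE at trial t;
    ``(t, 'neg')`` a switch into non-positive RPE. A constant-sign
    sequence yields an empty list.
    """
    d = np.asarray(delta_sequence, dtype=float)
    pos = d > 0
    events = []
    for t in range(1, d.size):
        if pos[t] != pos[t - 1]:
            events.append((t, "pos" if pos[t] else "neg"))
    return events


def transition_slopes(
    neuron,
    events: list[tuple[int, str]],
    trials: pd.DataFrame,
    min_events: int = 5,
) -> TransitionProfile | None:
    """Mean z-scored rate at each switch trial and the next same-cue trial.

    The "next" trial is the next encounter of the *same cue*, because value
    updates are cue-specific and only that encounter reflects the update
    triggered by the switch. slope = rate(next) - rate(first), per switch
    direction; slope_asymmetry = (-slope_pos) - slope_neg, so larger values
    mean faster decay of positive RPEs, i.e. more optimistic learning.
    Returns None when either direction has fewer than ``min_events`` usable
    events (switch trials with a later same-cue trial).
    """
    rate = np.asarray(neuron.feedback_rate, dtype=float)
    sd = rate.std()
    z = (rate - rate.mean()) / (sd if sd > 0 else 1.0)
    cue = trials["cue_id"].to_numpy()
    next_same = np.full(cue.size, -1)
    last_seen: dict = {}
    for t in range(cue.size - 1, -1, -1):
        next_same[t] = last_seen.get(cue[t], -1)
        last_seen[cue[t]] = t
    first = {"pos": [], "neg": []}
    nxt = {"pos": [], "neg": []}
    for t, direction in events:
        t2 = next_same[t]
        if t2 < 0:
            continue
        first[direction].append(z[t])
        nxt[direction].append(z[t2])
    if len(first["pos"]) < min_events or len(first["neg"]) < min_events:
        return None
    mfp, mnp = float(np.mean(first["pos"])), float(np.mean(nxt["pos"]))
    mfn, mnn = float(np.mean(first["neg"])), float(np.mean(nxt["neg"]))
    slope_pos = mnp - mfp
    slope_neg = mnn - mfn
    return TransitionProfile(
        neuron_id=neuron.neuron_id,
        mean_rate_first_pos=mfp,
        mean_rate_next_pos=mnp,
        mean_rate_first_neg=mfn,
        mean_rate_next_neg=mnn,
        slope_pos=slope_pos,
        slope_neg=slope_neg,
        slope_asymmetry=(-slope_pos) - slope_neg,
        n_pos_events=len(first["pos"]),
        n_neg_events=len(first["neg"]),
    )


def correlate_with_model_asymmetry(
    profiles: list[TransitionProfile],
    fits: list,
) -> tuple[float, float, int]:
    """Pearson r between slope asymmetry and fitted learning asymmetry.

    ``fits`` are per-neuron :class:`~distrl.models.ModelFit` objects of the
    best-fitting (asymmetric-learning) model; matching is by neuron_id.
    """
    asym = {
        f.neuron_id: f.learning_asymmetry
        for f in fits
        if f.learning_asymmetry is not None
    }
    pairs = [
        (p.slope_asymmetry, asym[p.neuron_id])
        for p in profiles
        if p is not None and p.neuron_id in asym
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 overlapping neurons")
    x, y = np.array(pairs).T
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(pairs)
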