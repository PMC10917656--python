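"""Neuron-inclusion screens and sign alignment.

Only units that carry a reward-prediction-error signal should enter the
distributional analyses. Three screens are provided:

* ``screen_opposite_sign`` — static task: value-selective at choice, and
  value-selective at feedback with the opposite sign (the RPE signature:
  a unit that fires more for higher cued value must fire *less* at feedback
  after high-value cues, because the prediction error there is smaller),
  with the rewarded- and unrewarded-trial feedback slopes agreeing in sign.
* ``screen_rpe_regressor`` — dynamic task: firing rate linearly related to
  a model-derived RPE sequence.
* ``screen_bayer_glimcher`` — a stricter dynamic-task criterion: current-
  and previous-trial reward both significant with opposite signs.

``align_sign`` flips negatively coding units about their mean rate so the
population shares a positive coding convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .neurons import NeuronRecord, flip_record


def _sign(x: float) -> int:
    return int(np.sign(x))


@dataclass
class ScreenResult:
    neuron_id: str
    passed: bool
    criterion: str
    choice_slope_sign: int = 0
    feedback_slope_sign: int = 0
    p_values: dict = field(default_factory=dict)
    reason: str = ""


def _slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and its two-sided p for y ~ x."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def screen_opposite_sign(
    neuron: NeuronRecord,
    trials: pd.DataFrame,
    alpha: float = 0.05,
    min_trials: int = 10,
) -> ScreenResult:
    """Static-task RPE screen.

    Passes iff (i) choice-window rate regresses on the chosen value level
    with p < alpha; (ii) feedback-window rate regresses on value with
    p < alpha separately on rewarded and on unrewarded trials, both slopes
    sharing one sign; and (iii) that feedback sign is opposite to the
    choice sign. Trials on which the rarely chosen lowest-probability
    option was taken are excluded (value coding 1-4).
    """
    if neuron.choice_rate is None:
        raise ValueError("opposite-sign screen requires a choice-epoch rate")
    mask = trials["chosen_value_level"].to_numpy() >= 1
    v = trials["chosen_value_level"].to_numpy(float)[mask]
    rewarded = trials["rewarded"].to_numpy(bool)[mask]
    ch = neuron.choice_rate[mask]
    fb = neuron.feedback_rate[mask]
    n_rew, n_unrew = int(rewarded.sum()), int((~rewarded).sum())
    if min(len(v), n_rew, n_unrew) < min_trials:
        return ScreenResult(
            neuron.neuron_id, False, "opposite_sign",
            reason=f"insufficient trials (rewarded={n_rew}, unrewarded={n_unrew})",
        )
    s_ch, p_ch = _slope_test(v, ch)
    s_fr, p_fr = _slope_test(v[rewarded], fb[rewarded])
    s_fu, p_fu = _slope_test(v[~rewarded], fb[~rewarded])
    pvals = {"choice": p_ch, "feedback_rewarded": p_fr, "feedback_unrewarded": p_fu}
    passed = (
        p_ch < alpha
        and p_fr < alpha
        and p_fu < alpha
        and _sign(s_fr) == _sign(s_fu) != 0
        and _sign(s_fr) == -_sign(s_ch)
    )
    return ScreenResult(
        neuron.neuron_id,
        bool(passed),
        "opposite_sign",
        choice_slope_sign=_sign(s_ch),
        feedback_slope_sign=_sign(s_fr),
        p_values=pvals,
    )


def screen_rpe_regressor(
    neuron: NeuronRecord,
    rpe_sequence: np.ndarray,
    alpha: float = 0.05,
) -> ScreenResult:
    """Dynamic-task screen: rate ~ RPE linear regression at p < alpha."""
    rpe = np.asarray(rpe_sequence, dtype=float)
    if rpe.shape != neuron.feedback_rate.shape:
        raise ValueError("rpe_sequence length must match the rate series")
    if np.ptp(rpe) == 0:
        raise ValueError("constant RPE sequence: screen undefined")
    slope, p = _slope_test(rpe, neuron.feedback_rate)
    return ScreenResult(
        neuron.neuron_id,
        bool(p < alpha),
        "rpe_regressor",
        feedback_slope_sign=_sign(slope),
        choice_slope_sign=_sign(slope),
        p_values={"rpe": p},
    )


def screen_bayer_glimcher(
    neuron: NeuronRecord,
    trials: pd.DataFrame,
    alpha: float = 0.05,
) -> ScreenResult:
    """Strict dynamic-task RPE screen.

    Fits rate(t) = b0 + b1*Rew(t) + b2*Rew(t-1) over trials 2..T and passes
    iff b1 and b2 are each significant at alpha with opposite signs — the
    defining property of a prediction-error signal, which rises with the
    current outcome and falls with the recent expectation.
    """
    r = trials["delivered_reward"].to_numpy(float)
    if r.size < 3 or np.ptp(r) == 0:
        return ScreenResult(
            neuron.neuron_id, False, "bayer_glimcher", reason="degenerate reward sequence"
        )
    y = neuron.feedback_rate[1:]
    X = np.column_stack([np.ones(r.size - 1), r[1:], r[:-1]])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        return ScreenResult(
            neuron.neuron_id, False, "bayer_glimcher", reason="collinear design"
        )
    resid = y - X @ beta
    dof = y.size - 3
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    passed = (
        pvals[1] < alpha and pvals[2] < alpha and _sign(beta[1]) == -_sign(beta[2]) != 0
    )
    return ScreenResult(
        neuron.neuron_id,
        bool(passed),
        "bayer_glimcher",
        feedback_slope_sign=_sign(beta[1]),
        choice_slope_sign=_sign(beta[1]),
        p_values={"reward_t": float(pvals[1]), "reward_tm1": float(pvals[2])},
    )


def align_sign(neuron: NeuronRecord, screen: ScreenResult) -> NeuronRecord:
    """Return the record in the canonical positive-coding convention.

    The reference sign is the choice-epoch slope (static screen) or the
    RPE slope (dynamic screens). Negative coders are reflected about their
    mean rate, which preserves every mean-level statistic and makes the
    flip an exact involution; records already aligned (or positive) are
    returned unchanged, so the operation is idempotent.
    """
    sign = screen.choice_slope_sign
    if sign == 0:
        raise ValueError("cannot align a neuron with undefined slope sign")
    if neuron.sign_aligned:
        return neuron
    out = neuron if sign > 0 else flip_record(neuron)
    return replace(out, sign_aligned=True)


def screen_ledger(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabulate screen outcomes (one row per neuron) for export."""
    rows = []
    for r in results:
        row = {
            "neuron_id": r.neuron_id,
            "criterion": r.criterion,
            "passed": r.passed,
            "choice_slope_sign": r.choice_slope_sign,
            "feedback_slope_sign": r.feedback_slope_sign,
            "reason": r.reason,
        }
        for k, v in r.p_values.items():
            row[f"p_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
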