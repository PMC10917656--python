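"""Per-neuron optimism statistics.

Three per-neuron measures of where a unit's value prediction sits within
the reward distribution:

* the **reversal point** — the interpolated value level at which the
  z-scored choice response crosses zero from below; a neutral unit on four
  equiprobable levels 1-4 reverses at 2.5, optimists above, pessimists
  below;
* the **quadratic concavity** beta2 from rate ~ level + level^2, an
  alternative index of the same nonlinearity;
* the **asymmetric scaling** beta+/(beta+ + beta-) measured at feedback,
  from the separate regressions of rate on cued probability on rewarded
  (positive-RPE) and unrewarded (negative-RPE) trials.

``neuron_optimism`` combines reversal point and scaling asymmetry into a
single per-neuron composite (mean of the two z-scored measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OptimismEstimate:
    neuron_id: str
    reversal_point: float | None = None
    quadratic_beta2: float | None = None
    beta_plus: float | None = None
    beta_minus: float | None = None
    scaling_asymmetry: float | None = None
    neuron_optimism: float | None = None
    flags: set = field(default_factory=set)


def reversal_point(
    choice_rates: np.ndarray,
    chosen_levels: np.ndarray,
    trial_mask: np.ndarray | None = None,
) -> tuple[float | None, set]:
    """Interpolated zero crossing of the z-scored per-level response.

    Rates are z-scored across the masked trials, averaged per value level,
    and the levels scanned in increasing order for the first adjacent pair
    whose means change sign from negative to non-negative; the reversal is
    the linear interpolation of zero within that pair. Returns
    ``(value, flags)`` where flags may contain ``no_crossing`` (monotone
    positive/negative profile, value None) or ``multiple_crossings``
    (non-monotone profile; the first crossing is reported).
    """
    rates = np.asarray(choice_rates, dtype=float)
    levels = np.asarray(chosen_levels)
    if trial_mask is not None:
        rates, levels = rates[trial_mask], levels[trial_mask]
    if rates.size == 0:
        raise ValueError("empty trial mask")
    uniq = np.unique(levels)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct value levels")
    sd = rates.std()
    if sd == 0:
        sd = 1.0
    z = (rates - rates.mean()) / sd
    means = np.array([z[levels == lv].mean() for lv in uniq])
    flags: set = set()
    crossings = [
        i for i in range(uniq.size - 1) if means[i] < 0 and means[i + 1] >= 0
    ]
    if not crossings:
        flags.add("no_crossing")
        return None, flags
    if len(crossings) > 1:
        flags.add("multiple_crossings")
    i = crossings[0]
    lo, hi = float(uniq[i]), float(uniq[i + 1])
    frac = -means[i] / (means[i + 1] - means[i])
    return lo + frac * (hi - lo), flags


def quadratic_optimism(
    choice_rates: np.ndarray, chosen_levels: np.ndarray
) -> float:
    """Quadratic coefficient of rate ~ level + level^2 (OLS).

    Convex profiles (responding mostly to the top of the value range, i.e.
    optimistic) give positive beta2 under a positive coding convention.
    """
    rates = np.asarray(choice_rates, dtype=float)
    levels = np.asarray(chosen_levels, dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need >= 3 distinct value levels for a quadratic fit")
    X = np.column_stack([np.ones_like(levels), levels, levels**2])
    beta, _, rank, _ = np.linalg.lstsq(X, rates, rcond=None)
    if rank < 3:
        raise ValueError("collinear design in quadratic fit")
    return float(beta[2])


def asymmetric_scaling(
    feedback_rates: np.ndarray,
    chosen_probability: np.ndarray,
    rewarded: np.ndarray,
    min_trials: int = 10,
    beta_tol_frac: float = 1e-6,
) -> tuple[float, float, float | None, set]:
    """Feedback-epoch RPE scaling asymmetry beta+/(beta+ + beta-).

    For a sign-aligned RPE unit the positive RPE on a rewarded trial is
    1 - p and the negative RPE on an unrewarded trial is -p, both
    *decreasing* in the cued probability p; the raw slopes of rate on p are
    therefore negative, and their negations estimate the positive scaling
    factors beta+ and beta-. If either beta is negative beyond a tolerance
    (a non-RPE response profile) or the denominator is non-positive, the
    ratio is undefined and the ``unstable_ratio`` flag is set.

    Returns ``(beta_plus, beta_minus, scaling_asymmetry_or_None, flags)``.
    """
    rates = np.asarray(feedback_rates, dtype=float)
    p = np.asarray(chosen_probability, dtype=float)
    rew = np.asarray(rewarded, dtype=bool)
    if rew.sum() < min_trials or (~rew).sum() < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials in each reward condition "
            f"(got {int(rew.sum())} rewarded, {int((~rew).sum())} unrewarded)"
        )
    slope_r = stats.linregress(p[rew], rates[rew]).slope
    slope_u = stats.linregress(p[~rew], rates[~rew]).slope
    beta_plus, beta_minus = -float(slope_r), -float(slope_u)
    flags: set = set()
    tol = beta_tol_frac * max(rates.std(), 1e-12)
    if beta_plus < -tol or beta_minus < -tol or beta_plus + beta_minus <= 0:
        flags.add("unstable_ratio")
        return beta_plus, beta_minus, None, flags
    return beta_plus, beta_minus, beta_plus / (beta_plus + beta_minus), flags


def estimate_optimism(
    neuron, trials: pd.DataFrame, trial_mask: np.ndarray | None = None
) -> OptimismEstimate:
    """All per-neuron optimism measures for one sign-aligned static record."""
    level = trials["chosen_value_level"].to_numpy()
    valid = level >= 1
    if trial_mask is not None:
        valid = valid & np.asarray(trial_mask, dtype=bool)
    rp, flags = reversal_point(neuron.choice_rate, level, valid)
    est = OptimismEstimate(neuron_id=neuron.neuron_id, reversal_point=rp, flags=flags)
    try:
        est.quadratic_beta2 = quadratic_optimism(
            neuron.choice_rate[valid], level[valid].astype(float)
        )
    except ValueError:
        est.flags.add("quadratic_undefined")
    try:
        bp, bm, sa, sflags = asymmetric_scaling(
            neuron.feedback_rate[valid],
            trials["chosen_probability"].to_numpy()[valid],
            trials["rewarded"].to_numpy()[valid],
        )
        est.beta_plus, est.beta_minus, est.scaling_asymmetry = bp, bm, sa
        est.flags |= sflags
    except ValueError:
        est.flags.add("scaling_undefined")
    return est


def neuron_optimism(estimates: list[OptimismEstimate]) -> dict[str, float]:
    """Composite optimism: mean of z-scored reversal point and asymmetry.

    Neurons missing either measure are excluded; the z-scores are taken
    across the included neurons. Returns ``{neuron_id: composite}`` and
    writes the value back onto each included estimate.
    """
    usable = [
        e
        for e in estimates
        if e.reversal_point is not None and e.scaling_asymmetry is not None
    ]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 neurons with both measures, got {len(usable)}")
    rp = np.array([e.reversal_point for e in usable])
    sa = np.array([e.scaling_asymmetry for e in usable])

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    comp = 0.5 * (_z(rp) + _z(sa))
    out = {}
    for e, c in zip(usable, comp):
        e.neuron_optimism = float(c)
        out[e.neuron_id] = float(c)
    return out


def estimates_table(estimates: list[OptimismEstimate]) -> pd.DataFrame:
    """Per-neuron optimism estimates as a DataFrame for export."""
    return pd.DataFrame(
        [
            {
                "neuron_id": e.neuron_id,
                "reversal_point": e.reversal_point,
                "quadratic_beta2": e.quadratic_beta2,
                "beta_plus": e.beta_plus,
                "beta_minus": e.beta_minus,
                "scaling_asymmetry": e.scaling_asymmetry,
                "neuron_optimism": e.neuron_optimism,
                "flags": ";".join(sorted(e.flags)),
            }
            for e in estimates
        ]
    )
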