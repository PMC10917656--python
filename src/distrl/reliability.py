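"""Population-level reliability and generalization statistics.

Diversity of a per-neuron statistic (reversal point, scaling asymmetry,
...) is only meaningful if it is *consistent*: the value estimated in one
random half of each neuron's trials must predict the value estimated in
the other half, across neurons. ``split_half_consistency`` repeats that
random partition many times and summarises the per-partition correlations
by their mean r, the geometric mean of the p-values, and a bootstrap
summary p (the fraction of partitions whose correlation is non-positive).

Also here: generalization of reversal points across the two stimulus sets,
the anterior-posterior topography correlation, and an OLS control that
re-tests a neuron-level relationship with subject identity regressed out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConsistencyResult:
    n_partitions: int
    per_partition_r: np.ndarray
    per_partition_p: np.ndarray
    mean_r: float
    geometric_mean_p: float
    bootstrap_p: float
    seed: int | None = None
    n_neurons_used: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_partitions": self.n_partitions,
            "mean_r": self.mean_r,
            "geometric_mean_p": self.geometric_mean_p,
            "bootstrap_p": self.bootstrap_p,
            "mean_neurons_used": self.n_neurons_used,
        }


def _correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson"):
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def stratified_half_masks(
    strata: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split of trial indices, balanced within each stratum.

    Within every stratum (e.g. value level x reward outcome) the trials are
    shuffled and alternately assigned, so both halves retain all strata and
    every per-level / per-condition estimator stays defined.
    """
    n = strata.size
    h1 = np.zeros(n, dtype=bool)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        k = idx.size // 2
        if idx.size % 2 == 1 and rng.random() < 0.5:
            k += 1
        h1[idx[:k]] = True
    return h1, ~h1


def split_half_consistency(
    estimator,
    neurons: list,
    n_partitions: int = 1000,
    seed: int | None = None,
    strata_fn=None,
    method: str = "pearson",
    max_undefined_frac: float = 0.5,
    min_neurons: int = 3,
) -> ConsistencyResult:
    """Split-half reliability of a per-neuron statistic.

    Parameters
    ----------
    estimator
        Callable ``estimator(neuron, trial_mask) -> float or None``
        evaluating the statistic on a trial subset (None = undefined).
    neurons
        Population of records sharing one session's trial count.
    n_partitions
        Number of independent random half-splits (the partitioning is
        re-drawn per neuron within each partition).
    strata_fn
        Optional ``strata_fn(neuron) -> array`` of per-trial stratum labels
        used to balance the halves; default: a single stratum.
    max_undefined_frac
        If on average more than this fraction of neurons yield an undefined
        estimate, the population is unusable and an error is raised.

    Returns a :class:`ConsistencyResult`; ``bootstrap_p`` is the fraction
    of partitions with r <= 0 (resolution 1/n_partitions).
    """
    rng = np.random.default_rng(seed)
    rs, ps, used = [], [], []
    n_undef = 0
    for _ in range(n_partitions):
        a_vals, b_vals = [], []
        for neuron in neurons:
            strata = (
                strata_fn(neuron)
                if strata_fn is not None
                else np.zeros(neuron.n_trials, dtype=int)
            )
            h1, h2 = stratified_half_masks(np.asarray(strata), rng)
            va, vb = estimator(neuron, h1), estimator(neuron, h2)
            if va is None or vb is None:
                n_undef += 1
                continue
            a_vals.append(va)
            b_vals.append(vb)
        if len(a_vals) < min_neurons:
            raise ValueError(
                f"fewer than {min_neurons} neurons with defined estimates in a partition"
            )
        r, p = _correlate(np.array(a_vals), np.array(b_vals), method)
        rs.append(r)
        ps.append(p)
        used.append(len(a_vals))
    undef_frac = n_undef / (n_partitions * len(neurons))
    if undef_frac > max_undefined_frac:
        raise ValueError(
            f"estimator undefined for {undef_frac:.0%} of neuron-halves "
            f"(limit {max_undefined_frac:.0%})"
        )
    rs, ps = np.array(rs), np.array(ps)
    return ConsistencyResult(
        n_partitions=n_partitions,
        per_partition_r=rs,
        per_partition_p=ps,
        mean_r=float(rs.mean()),
        # p = 0 (perfect correlation) is floored so the geometric mean stays defined
        geometric_mean_p=float(np.exp(np.log(np.maximum(ps, 1e-300)).mean())),
        bootstrap_p=float((rs <= 0).mean()),
        seed=seed,
        n_neurons_used=float(np.mean(used)),
    )


def stimulus_set_generalization(
    neurons: list,
    trials: pd.DataFrame,
    estimator,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Across-neuron correlation of a statistic estimated per stimulus set.

    Each value level is denoted by two distinct stimuli; a unit tuned to
    *value* (not stimulus identity) should give matching estimates on the
    set-1-only and set-2-only trials. Neurons with an undefined estimate in
    either set are excluded. Returns (r, p, n_used).
    """
    set_lbl = trials["stimulus_set"].to_numpy()
    m1, m2 = set_lbl == 1, set_lbl == 2
    a_vals, b_vals = [], []
    for neuron in neurons:
        va, vb = estimator(neuron, m1), estimator(neuron, m2)
        if va is None or vb is None:
            continue
        a_vals.append(va)
        b_vals.append(vb)
    if len(a_vals) < 3:
        raise ValueError("fewer than 3 neurons defined in both stimulus sets")
    r, p = _correlate(np.array(a_vals), np.array(b_vals), method)
    return r, p, len(a_vals)


def normalized_ap(neurons: list) -> dict[str, float]:
    """Min-max normalise anterior-posterior coordinates within subject.

    Maps each subject's AP range onto [0, 1] so that "most anterior within
    this subject's sampled region" is comparable across subjects. Subjects
    with a constant AP are dropped (normalisation undefined).
    """
    by_subject: dict[str, list] = {}
    for n in neurons:
        by_subject.setdefault(n.subject_id, []).append(n)
    out: dict[str, float] = {}
    for subj, group in by_subject.items():
        ap = np.array([n.ap_mm for n in group])
        span = ap.max() - ap.min()
        if span == 0:
            continue
        for n, a in zip(group, ap):
            out[n.neuron_id] = float((a - ap.min()) / span)
    return out


def topography_correlation(
    neurons: list, optimism: dict[str, float], method: str = "pearson"
) -> tuple[float, float, int]:
    """Correlation of within-subject-normalised AP with neuron optimism."""
    ap = normalized_ap(neurons)
    ids = [n.neuron_id for n in neurons if n.neuron_id in ap and n.neuron_id in optimism]
    if len(ids) < 3:
        raise ValueError("fewer than 3 neurons with AP and optimism defined")
    x = np.array([ap[i] for i in ids])
    y = np.array([optimism[i] for i in ids])
    r, p = _correlate(x, y, method)
    return r, p, len(ids)


def subject_covariate_glm(
    response: np.ndarray, predictor: np.ndarray, subject: np.ndarray
) -> tuple[float, float]:
    """t and two-sided p of the predictor with subject regressed out.

    OLS of response on the predictor plus subject indicator columns;
    guards a neuron-level correlation against between-subject offsets.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    subj = np.asarray(subject)
    levels = np.unique(subj)
    if levels.size < 2:
        raise ValueError("need >= 2 subjects for the subject-covariate control")
    if all(np.ptp(x[subj == s]) == 0 for s in levels):
        raise ValueError("predictor constant within every subject")
    dummies = np.column_stack([(subj == s).astype(float) for s in levels[1:]])
    X = sm.add_constant(np.column_stack([x, dummies]))
    fit = sm.OLS(y, X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])
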