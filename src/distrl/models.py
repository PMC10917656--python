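"""Rescorla-Wagner model variants, grid fitting and cross-validated comparison.

Four nested models of a unit's feedback-epoch firing are compared, crossing
symmetric/asymmetric *learning* with symmetric/asymmetric *scaling*:

    SLSS  classic RL: one learning rate, linear RPE read-out
    SLAS  one learning rate, asymmetrically scaled read-out
    ALSS  separate alpha+/alpha- value updates, linear read-out
    ALAS  fully distributional: both asymmetries

Value dynamics: per-cue V <- V + alpha+ * delta (delta > 0) or
V <- V + alpha- * delta (delta <= 0), delta = r - V computed before the
update. Read-out: FR = beta0 + beta1 * x with the single-parameter scaled
regressor x = delta*S (delta > 0) or delta*(1-S) (delta <= 0); with
beta+ = S and beta- = 1-S the implied scaling-asymmetry ratio
beta+/(beta+ + beta-) equals S itself, which keeps the searched parameter
inside [0, 1].

Fitting is a grid search over (alpha+, alpha-, S) in 0.025 steps with
beta0/beta1 estimated by least squares at every grid point; model
comparison uses tenfold cross-validation on held-out R^2. Because the
training R^2 at a grid point equals the squared correlation between the
scaled regressor and the rate, and the regressor is *linear in S* for
fixed learning rates, the whole R^2 surface is evaluated in closed form
from five moment statistics, vectorised over the alpha grid; the flat
C-order argmax over the lexicographically ordered grid realises the
smallest-(alpha+, alpha-, S) tie-break deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ModelSpec:
    name: str
    asymmetric_learning: bool
    asymmetric_scaling: bool


MODELS = {
    "SLSS": ModelSpec("SLSS", False, False),
    "SLAS": ModelSpec("SLAS", False, True),
    "ALSS": ModelSpec("ALSS", True, False),
    "ALAS": ModelSpec("ALAS", True, True),
}

MODEL_ORDER = ["SLSS", "SLAS", "ALSS", "ALAS"]


@dataclass
class ModelParams:
    alpha_plus: float
    alpha_minus: float
    s: float
    beta0: float = 0.0
    beta1: float = 0.0
    train_r2: float | None = None

    @property
    def learning_asymmetry(self) -> float | None:
        tot = self.alpha_plus + self.alpha_minus
        return self.alpha_plus / tot if tot > 0 else None


@dataclass
class ModelFit:
    neuron_id: str
    model: ModelSpec
    best_params: ModelParams
    per_fold_test_r2: np.ndarray
    mean_test_r2: float

    @property
    def learning_asymmetry(self) -> float | None:
        return self.best_params.learning_asymmetry


def parameter_grid(grid_step: float = 0.025) -> np.ndarray:
    """Grid {0, grid_step, ..., 1}; grid_step must divide 1."""
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step {grid_step} does not divide 1")
    return np.linspace(0.0, 1.0, n + 1)


def rpe_sequence(
    trials: pd.DataFrame,
    alpha_plus: float,
    alpha_minus: float,
    v_init: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (delta, V) from the asymmetric update over one session.

    V is the chosen cue's value *before* the update on that trial;
    delta = r - V; the update applies alpha+ for delta > 0 and alpha- for
    delta <= 0 (symmetric models simply pass the same value for both).
    """
    if not 0.0 <= v_init <= 1.0:
        raise ValueError(f"v_init must be in [0,1], got {v_init}")
    cue = trials["cue_id"].to_numpy(int)
    r = trials["delivered_reward"].to_numpy(float)
    values = {c: float(v_init) for c in np.unique(cue)}
    delta = np.empty(r.size)
    vtrace = np.empty(r.size)
    for t in range(r.size):
        c = cue[t]
        v = values[c]
        d = r[t] - v
        vtrace[t] = v
        delta[t] = d
        values[c] = v + (alpha_plus if d > 0 else alpha_minus) * d
    return delta, vtrace


def scaled_regressor(delta: np.ndarray, s: float) -> np.ndarray:
    """x = delta*S for positive RPEs, delta*(1-S) for non-positive ones."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"S must be in [0,1], got {s}")
    delta = np.asarray(delta, dtype=float)
    return np.where(delta > 0, delta * s, delta * (1.0 - s))


class DeltaGrid:
    """Precomputed RPE sequences for every (alpha+, alpha-) grid pair.

    The RPE trace depends only on the learning rates and the session's
    choice/reward sequence — not on the neuron, the scaling S, or the CV
    fold — so it is computed once per session for the full lexicographic
    (alpha+, alpha-) grid and shared by every fit. ``dpos``/``dneg`` hold
    the positive- and non-positive-RPE components (K x T), whose
    S-weighted sum is the scaled regressor.
    """

    def __init__(self, trials: pd.DataFrame, grid_step: float = 0.025, v_init: float = 0.5):
        self.grid_step = grid_step
        self.v_init = v_init
        self.alphas = parameter_grid(grid_step)
        g = self.alphas.size
        ap = np.repeat(self.alphas, g)
        am = np.tile(self.alphas, g)
        self.pairs = np.column_stack([ap, am])  # lexicographic (alpha+, alpha-)
        self.sym_rows = np.flatnonzero(ap == am)
        cue = trials["cue_id"].to_numpy(int)
        r = trials["delivered_reward"].to_numpy(float)
        cues = np.unique(cue)
        cue_index = {c: i for i, c in enumerate(cues)}
        K, T = ap.size, r.size
        V = np.full((K, cues.size), v_init)
        delta = np.empty((K, T))
        for t in range(T):
            ci = cue_index[cue[t]]
            d = r[t] - V[:, ci]
            V[:, ci] += np.where(d > 0, ap, am) * d
            delta[:, t] = d
        self.delta = delta
        self.dpos = np.where(delta > 0, delta, 0.0)
        self.dneg = delta - self.dpos
        self.n_trials = T


def _fold_moments(dg: DeltaGrid, train: np.ndarray):
    """Center the grid regressor components on the training trials."""
    dp = dg.dpos[:, train]
    dn = dg.dneg[:, train]
    dpc = dp - dp.mean(axis=1, keepdims=True)
    dnc = dn - dn.mean(axis=1, keepdims=True)
    Spp = np.einsum("kt,kt->k", dpc, dpc)
    Snn = np.einsum("kt,kt->k", dnc, dnc)
    Spn = np.einsum("kt,kt->k", dpc, dnc)
    return dpc, dnc, Spp, Snn, Spn


def _r2_surface(Sxy_p, Sxy_n, Spp, Snn, Spn, Syy, s_grid):
    """Training R^2 over the (alpha-pair, S) grid, closed form.

    x(S) = S*dpos + (1-S)*dneg, so cov(x,y) and var(x) are polynomial in S
    and R^2 = cov^2 / (var * var(y)). Degenerate regressors (zero variance)
    get -inf so they are never selected.
    """
    s = s_grid[None, :]
    cov = Sxy_p[:, None] * s + Sxy_n[:, None] * (1.0 - s)
    var = (
        Spp[:, None] * s**2
        + 2.0 * Spn[:, None] * s * (1.0 - s)
        + Snn[:, None] * (1.0 - s) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / (var * Syy)
    r2[~np.isfinite(r2)] = -np.inf
    r2[var <= 1e-300] = -np.inf
    return r2


def _model_rows_sgrid(dg: DeltaGrid, model: ModelSpec):
    rows = (
        np.arange(dg.pairs.shape[0]) if model.asymmetric_learning else dg.sym_rows
    )
    s_grid = dg.alphas if model.asymmetric_scaling else np.array([0.5])
    return rows, s_grid


def _ols_betas(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    vx = x - x.mean()
    denom = vx @ vx
    if denom <= 0:
        return float(y.mean()), 0.0
    b1 = (vx @ (y - y.mean())) / denom
    b0 = y.mean() - b1 * x.mean()
    return float(b0), float(b1)


def fit_grid(
    neuron,
    trials: pd.DataFrame,
    model: ModelSpec | str,
    training_trials: np.ndarray | None = None,
    grid_step: float = 0.025,
    v_init: float = 0.5,
    delta_grid: DeltaGrid | None = None,
) -> ModelParams:
    """Best (alpha+, alpha-, S) for one neuron by exhaustive grid search.

    RPEs are always propagated over the *full* session; beta0/beta1 and the
    R^2 ranking use the training trials only. Symmetry constraints restrict
    the grid (alpha+ = alpha- and/or S = 0.5). Ties in training R^2 resolve
    to the lexicographically smallest (alpha+, alpha-, S).
    """
    if isinstance(model, str):
        model = MODELS[model]
    dg = delta_grid or DeltaGrid(trials, grid_step, v_init)
    y = np.asarray(neuron.feedback_rate, dtype=float)
    train = (
        np.ones(dg.n_trials, dtype=bool)
        if training_trials is None
        else np.asarray(training_trials)
    )
    if train.dtype != bool:
        mask = np.zeros(dg.n_trials, dtype=bool)
        mask[train] = True
        train = mask
    if not train.any():
        raise ValueError("empty training set")
    rows, s_grid = _model_rows_sgrid(dg, model)
    dpc, dnc, Spp, Snn, Spn = _fold_moments(dg, train)
    yc = y[train] - y[train].mean()
    Syy = yc @ yc
    Sxy_p = dpc @ yc
    Sxy_n = dnc @ yc
    r2 = _r2_surface(
        Sxy_p[rows], Sxy_n[rows], Spp[rows], Snn[rows], Spn[rows], Syy, s_grid
    )
    flat = int(np.argmax(r2))
    ri, si = divmod(flat, s_grid.size)
    row = rows[ri]
    ap, am = dg.pairs[row]
    s = float(s_grid[si])
    if not model.asymmetric_learning:
        ap = am = float(ap)
    x = scaled_regressor(dg.delta[row], s)
    b0, b1 = _ols_betas(x[train], y[train])
    return ModelParams(
        alpha_plus=float(ap),
        alpha_minus=float(am),
        s=s,
        beta0=b0,
        beta1=b1,
        train_r2=float(r2.flat[flat]),
    )


def _contiguous_folds(n_trials: int, n_folds: int, min_fold_size: int = 10) -> list[np.ndarray]:
    """Contiguous trial blocks; fold count adapts downward for short sessions."""
    if n_trials // n_folds < min_fold_size:
        adjusted = max(2, n_trials // min_fold_size)
        if adjusted < n_folds:
            warnings.warn(
                f"session of {n_trials} trials too short for {n_folds} folds; using {adjusted}"
            )
            n_folds = adjusted
    if n_trials // n_folds < 2:
        raise ValueError(f"{n_trials} trials cannot support {n_folds} folds")
    return np.array_split(np.arange(n_trials), n_folds)


def _test_r2(x_test: np.ndarray, y_test: np.ndarray, refit_linear: bool, b0: float, b1: float) -> float:
    yv = y_test - y_test.mean()
    Syy = yv @ yv
    if Syy <= 0:
        return 0.0
    if refit_linear:
        xv = x_test - x_test.mean()
        Sxx = xv @ xv
        if Sxx <= 0:
            return 0.0
        return float((xv @ yv) ** 2 / (Sxx * Syy))
    resid = y_test - (b0 + b1 * x_test)
    return float(1.0 - resid @ resid / Syy)


def crossvalidate(
    neuron,
    trials: pd.DataFrame,
    model: ModelSpec | str,
    n_folds: int = 10,
    refit_linear: bool = True,
    grid_step: float = 0.025,
    v_init: float = 0.5,
    seed: int | None = None,
    fold_scheme: str = "contiguous",
    delta_grid: DeltaGrid | None = None,
) -> ModelFit:
    """Held-out R^2 of one model for one neuron, tenfold cross-validation.

    Folds are contiguous trial blocks by default (the RPE regressor depends
    on trial history, so temporal order is preserved); ``fold_scheme=
    'interleaved'`` shuffles trials into folds for sensitivity analysis.
    Per fold the nonlinear parameters are grid-fitted on the training
    trials, RPEs regenerated over the full session with them, and R^2
    evaluated on the held-out trials — with beta0/beta1 refitted there
    (``refit_linear=True``, isolating the comparison to the asymmetry
    structure) or carried over from training. ``best_params`` of the
    returned fit come from a final full-session grid fit.
    """
    if isinstance(model, str):
        model = MODELS[model]
    dg = delta_grid or DeltaGrid(trials, grid_step, v_init)
    y = np.asarray(neuron.feedback_rate, dtype=float)
    folds = _contiguous_folds(dg.n_trials, n_folds)
    if fold_scheme == "interleaved":
        perm = np.random.default_rng(seed).permutation(dg.n_trials)
        folds = [perm[f] for f in folds]
    elif fold_scheme != "contiguous":
        raise ValueError(f"unknown fold_scheme {fold_scheme!r}")
    fold_r2 = []
    for test_idx in folds:
        train = np.ones(dg.n_trials, dtype=bool)
        train[test_idx] = False
        params = fit_grid(
            neuron, trials, model, training_trials=train, delta_grid=dg
        )
        row = _pair_row(dg, params.alpha_plus, params.alpha_minus)
        x = scaled_regressor(dg.delta[row], params.s)
        fold_r2.append(
            _test_r2(x[test_idx], y[test_idx], refit_linear, params.beta0, params.beta1)
        )
    fold_r2 = np.array(fold_r2)
    best = fit_grid(neuron, trials, model, delta_grid=dg)
    return ModelFit(
        neuron_id=getattr(neuron, "neuron_id", "n?"),
        model=model,
        best_params=best,
        per_fold_test_r2=fold_r2,
        mean_test_r2=float(fold_r2.mean()),
    )


def _pair_row(dg: DeltaGrid, ap: float, am: float) -> int:
    g = dg.alphas.size
    i = int(round(ap / dg.grid_step))
    j = int(round(am / dg.grid_step))
    return i * g + j


def crossvalidate_population(
    neurons: list,
    trials: pd.DataFrame,
    models: list[str] | None = None,
    n_folds: int = 10,
    refit_linear: bool = True,
    grid_step: float = 0.025,
    v_init: float = 0.5,
) -> dict[str, list[ModelFit]]:
    """Cross-validated fits of several models for a whole population.

    Equivalent to calling :func:`crossvalidate` per neuron and model, but
    the per-fold centered grid moments (which do not depend on the neuron)
    are computed once and shared, which is what makes full-grid tenfold CV
    of a population cheap.
    """
    model_names = models or MODEL_ORDER
    specs = [MODELS[m] if isinstance(m, str) else m for m in model_names]
    dg = DeltaGrid(trials, grid_step, v_init)
    Y = np.column_stack([np.asarray(n.feedback_rate, float) for n in neurons])
    folds = _contiguous_folds(dg.n_trials, n_folds)
    n_neurons = Y.shape[1]
    fold_r2 = {m.name: np.empty((len(folds), n_neurons)) for m in specs}
    masks = []
    for test_idx in folds:
        train = np.ones(dg.n_trials, dtype=bool)
        train[test_idx] = False
        masks.append((train, test_idx))
    # final full-data fits reuse the same machinery with an all-true mask
    all_mask = (np.ones(dg.n_trials, dtype=bool), np.array([], dtype=int))
    best_params = {m.name: [None] * n_neurons for m in specs}
    for fi, (train, test_idx) in enumerate([*masks, all_mask]):
        dpc, dnc, Spp, Snn, Spn = _fold_moments(dg, train)
        Yt = Y[train]
        Yc = Yt - Yt.mean(axis=0, keepdims=True)
        Syy = np.einsum("tn,tn->n", Yc, Yc)
        SxyP = dpc @ Yc  # (K, N)
        SxyN = dnc @ Yc
        final = fi == len(masks)
        for spec in specs:
            rows, s_grid = _model_rows_sgrid(dg, spec)
            for ni in range(n_neurons):
                r2 = _r2_surface(
                    SxyP[rows, ni],
                    SxyN[rows, ni],
                    Spp[rows],
                    Snn[rows],
                    Spn[rows],
                    Syy[ni],
                    s_grid,
                )
                flat = int(np.argmax(r2))
                ri, si = divmod(flat, s_grid.size)
                row = rows[ri]
                ap, am = dg.pairs[row]
                s = float(s_grid[si])
                x = scaled_regressor(dg.delta[row], s)
                b0, b1 = _ols_betas(x[train], Y[train, ni])
                if final:
                    best_params[spec.name][ni] = ModelParams(
                        float(ap), float(am), s, b0, b1, float(r2.flat[flat])
                    )
                else:
                    fold_r2[spec.name][fi, ni] = _test_r2(
                        x[test_idx], Y[test_idx, ni], refit_linear, b0, b1
                    )
    out: dict[str, list[ModelFit]] = {}
    for spec in specs:
        fits = []
        for ni, neuron in enumerate(neurons):
            r2s = fold_r2[spec.name][:, ni]
            fits.append(
                ModelFit(
                    neuron_id=neuron.neuron_id,
                    model=spec,
                    best_params=best_params[spec.name][ni],
                    per_fold_test_r2=r2s.copy(),
                    mean_test_r2=float(r2s.mean()),
                )
            )
        out[spec.name] = fits
    return out


def compare_models(fits: dict[str, list[ModelFit]]) -> pd.DataFrame:
    """Pairwise paired-t comparison of mean held-out R^2 across neurons.

    One row per ordered model pair (m1 better listed first in MODEL_ORDER
    convention): mean per-neuron difference m1 - m2, its s.e.m., and the
    paired two-sided t-test over neurons.
    """
    names = list(fits)
    ids = {m: [f.neuron_id for f in fits[m]] for m in names}
    base = ids[names[0]]
    for m in names[1:]:
        if ids[m] != base:
            raise ValueError("model fits cover different neuron sets")
    r2 = {m: np.array([f.mean_test_r2 for f in fits[m]]) for m in names}
    rows = []
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            d = r2[m1] - r2[m2]
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(r2[m1], r2[m2])
            rows.append(
                {
                    "model_a": m1,
                    "model_b": m2,
                    "mean_diff": float(d.mean()),
                    "sem_diff": float(d.std(ddof=1) / np.sqrt(d.size)),
                    "t": float(t),
                    "p": float(p),
                    "n_neurons": d.size,
                }
            )
    return pd.DataFrame(rows)


def _half_fits(
    neurons: list,
    trials: pd.DataFrame,
    model: ModelSpec | str = "ALAS",
    grid_step: float = 0.025,
    v_init: float = 0.5,
):
    """Full grid fits (no CV) on the two contiguous session halves."""
    if isinstance(model, str):
        model = MODELS[model]
    dg = DeltaGrid(trials, grid_step, v_init)
    half = dg.n_trials // 2
    m1 = np.zeros(dg.n_trials, dtype=bool)
    m1[:half] = True
    rows = []
    for neuron in neurons:
        p1 = fit_grid(neuron, trials, model, training_trials=m1, delta_grid=dg)
        p2 = fit_grid(neuron, trials, model, training_trials=~m1, delta_grid=dg)
        rows.append((neuron.neuron_id, p1, p2))
    return rows


def parameter_consistency(
    neurons: list,
    trials: pd.DataFrame,
    model: ModelSpec | str = "ALAS",
    grid_step: float = 0.025,
    v_init: float = 0.5,
) -> dict:
    """Split-half consistency of the fitted asymmetry parameters.

    The session is split into two contiguous halves, the model grid-fitted
    independently in each, and the across-neuron Pearson correlation of
    the learning asymmetry alpha+/(alpha+ + alpha-) (and separately of S)
    between halves returned. Neurons whose learning asymmetry is undefined
    in either half (alpha+ + alpha- = 0) are excluded.
    """
    halves = _half_fits(neurons, trials, model, grid_step, v_init)
    la1, la2, s1, s2 = [], [], [], []
    excluded = []
    for nid, p1, p2 in halves:
        if p1.learning_asymmetry is None or p2.learning_asymmetry is None:
            excluded.append(nid)
            continue
        la1.append(p1.learning_asymmetry)
        la2.append(p2.learning_asymmetry)
        s1.append(p1.s)
        s2.append(p2.s)
    if len(la1) < 3:
        raise ValueError("fewer than 3 neurons with defined asymmetry in both halves")
    r_la, p_la = stats.pearsonr(la1, la2)
    r_s, p_s = stats.pearsonr(s1, s2)
    return {
        "learning_asymmetry": (float(r_la), float(p_la)),
        "scaling": (float(r_s), float(p_s)),
        "n_neurons": len(la1),
        "excluded": excluded,
    }


def scaling_learning_correlation(
    neurons: list,
    trials: pd.DataFrame,
    model: ModelSpec | str = "ALAS",
    grid_step: float = 0.025,
    v_init: float = 0.5,
) -> dict:
    """Cross-partition correlation between learning and scaling asymmetry.

    Learning asymmetry fitted in one contiguous half is correlated with S
    fitted in the *other* half (both directions, so the two estimates never
    share trials), and the two correlations are summarised by their mean r
    and the geometric mean of their p-values.
    """
    halves = _half_fits(neurons, trials, model, grid_step, v_init)
    la1, la2, s1, s2 = [], [], [], []
    for _, p1, p2 in halves:
        if p1.learning_asymmetry is None or p2.learning_asymmetry is None:
            continue
        la1.append(p1.learning_asymmetry)
        la2.append(p2.learning_asymmetry)
        s1.append(p1.s)
        s2.append(p2.s)
    if len(la1) < 3:
        raise ValueError("fewer than 3 usable neurons")
    r_a, p_a = stats.pearsonr(la1, s2)
    r_b, p_b = stats.pearsonr(la2, s1)
    return {
        "r_forward": float(r_a),
        "p_forward": float(p_a),
        "r_reverse": float(r_b),
        "p_reverse": float(p_b),
        "mean_r": float((r_a + r_b) / 2.0),
        "geometric_mean_p": float(np.exp((np.log(p_a) + np.log(p_b)) / 2.0)),
        "n_neurons": len(la1),
    }


def fits_table(fits: dict[str, list[ModelFit]]) -> pd.DataFrame:
    """One row per neuron x model, for CSV export."""
    rows = []
    for mname, flist in fits.items():
        for f in flist:
            p = f.best_params
            rows.append(
                {
                    "neuron_id": f.neuron_id,
                    "model": mname,
                    "alpha_plus": p.alpha_plus,
                    "alpha_minus": p.alpha_minus,
                    "s": p.s,
                    "beta0": p.beta0,
                    "beta1": p.beta1,
                    "train_r2": p.train_r2,
                    "mean_test_r2": f.mean_test_r2,
                    "learning_asymmetry": f.learning_asymmetry,
                }
            )
    return pd.DataFrame(rows)
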