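"""Expectile oracle and asymmetric-update convergence checks.

The tau-expectile of a distribution X is the unique root e of

    tau * E[(X - e)_+] = (1 - tau) * E[(e - X)_+],

the asymmetric-least-squares analogue of a quantile; tau = 0.5 gives the
mean. Its relevance here: a value updated with separate learning rates for
positive and negative prediction errors (alpha+ / alpha-) fluctuates around
the tau-expectile of the reward distribution with
tau = alpha+ / (alpha+ + alpha-). This module provides a brute-force,
bisection-based oracle used throughout the test-suite as the independent
ground truth for that correspondence.
"""

from __future__ import annotations

import numpy as np


def expectile_oracle(samples, tau: float, tol: float = 1e-10) -> float:
    """tau-expectile of an empirical sample by bisection.

    The estimating function
    g(e) = tau*E[(X-e)_+] - (1-tau)*E[(e-X)_+] is continuous and strictly
    decreasing in e, positive at min(X) and negative at max(X), so plain
    bisection over the sample range converges to the unique root.

    Parameters
    ----------
    samples : array-like
        Draws from (or the support of a weighted representation of) X.
    tau : float
        Asymmetry level, strictly inside (0, 1).
    tol : float
        Absolute bracket width at which bisection stops.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly inside (0, 1), got {tau}")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # degenerate distribution: every expectile is that point
        return lo

    def g(e: float) -> float:
        d = x - e
        return tau * d[d > 0].sum() - (1.0 - tau) * (-d[d < 0]).sum()

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def two_point_expectile(p: float, tau: float, low: float = 0.0, high: float = 1.0) -> float:
    """Closed-form tau-expectile of a two-point distribution.

    For X = high w.p. p and low w.p. 1-p on {0, 1} the root of the
    estimating equation is e = tau*p / (tau*p + (1-tau)*(1-p)); the general
    two-point case rescales that weight onto [low, high].
    """
    w = tau * p / (tau * p + (1.0 - tau) * (1.0 - p))
    return low + w * (high - low)


def asymmetric_update_trace(
    alpha_plus: float,
    alpha_minus: float,
    reward_stream,
    v_init: float = 0.5,
) -> np.ndarray:
    """Value trace of the asymmetric Rescorla-Wagner update on a stream.

    V <- V + alpha+ * delta if delta > 0 else V + alpha- * delta, with
    delta = r - V. Returns V *after* each update (length of the stream).
    """
    r = np.asarray(reward_stream, dtype=float)
    v = float(v_init)
    out = np.empty(r.size)
    for t in range(r.size):
        d = r[t] - v
        v += (alpha_plus if d > 0 else alpha_minus) * d
        out[t] = v
    return out


def converged_value(
    alpha_plus: float,
    alpha_minus: float,
    reward_stream,
    burn_in: int,
) -> float:
    """Long-run value of the asymmetric update, time-averaged after burn-in.

    With small learning rates the stationary process fluctuates tightly
    around the tau-expectile of the stream's distribution,
    tau = alpha+/(alpha+ + alpha-); time-averaging (rather than taking the
    final value) removes the residual fluctuation.
    """
    r = np.asarray(reward_stream, dtype=float)
    if burn_in >= r.size:
        raise ValueError(f"burn_in ({burn_in}) must be < stream length ({r.size})")
    trace = asymmetric_update_trace(alpha_plus, alpha_minus, r)
    return float(trace[burn_in:].mean())
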