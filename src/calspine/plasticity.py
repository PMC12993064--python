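"""Calcium-threshold synaptic weight dynamics.

The weight w of the spine at segment x follows

    dw/dt = (1 - w) * gamma_p * H[C_s - theta_p] - w * gamma_d * H[C_s - theta_d]

with strict Heavisides (H(0) = 0) and 0 < theta_d < theta_p, so that calcium
above theta_p engages both terms (net potentiation toward the fixed point
gamma_p / (gamma_p + gamma_d) whenever that exceeds w), calcium in
(theta_d, theta_p] gives pure exponential depression, and calcium at or below
theta_d leaves the weight untouched.

Within one solver step the spine calcium is treated as constant, which makes
the weight ODE linear with constant coefficients; ``update_weights`` applies
its exact one-step solution rather than an explicit Euler step, so weights
follow the piecewise-exponential closed form to machine precision and can
never leave [0, 1].
"""

from __future__ import annotations

import numpy as np

from .model_core import ModelParameters


class ConfigurationError(ValueError):
    """Solver/plasticity configuration violates a stability contract."""


def _heaviside_strict(x: np.ndarray) -> np.ndarray:
    # H(0) = 0: plasticity requires strict threshold exceedance.
    return (np.asarray(x) > 0).astype(float)


def weight_derivative(w, C_s, params: ModelParameters):
    """dw/dt (1/s) for weight(s) ``w`` at spine calcium ``C_s`` (uM)."""
    w = np.asarray(w, dtype=float)
    C_s = np.asarray(C_s, dtype=float)
    pot = _heaviside_strict(C_s - params.theta_p)
    dep = _heaviside_strict(C_s - params.theta_d)
    return (1.0 - w) * params.gamma_p * pot - w * params.gamma_d * dep


def update_weights(weights, C_s, dt: float, params: ModelParameters) -> np.ndarray:
    """Advance weights by one step of duration ``dt`` at constant ``C_s``.

    Exact exponential update: with a = gamma_p * H[C_s - theta_p] and
    r = a + gamma_d * H[C_s - theta_d], the step maps w to
    a/r + (w - a/r) * exp(-r dt) (identity where r = 0).  The result stays in
    [0, 1] by construction; the final clip only removes roundoff.
    """
    if not dt > 0:
        raise ConfigurationError("dt must be positive")
    if dt * (params.gamma_p + params.gamma_d) >= 1.0:
        raise ConfigurationError(
            "dt * (gamma_p + gamma_d) must be < 1 "
            f"(got {dt * (params.gamma_p + params.gamma_d):.3g})")
    w = np.asarray(weights, dtype=float)
    C_s = np.broadcast_to(np.asarray(C_s, dtype=float), w.shape)
    a = params.gamma_p * _heaviside_strict(C_s - params.theta_p)
    r = a + params.gamma_d * _heaviside_strict(C_s - params.theta_d)
    decay = np.exp(-r * dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_inf = np.where(r > 0, a / np.where(r > 0, r, 1.0), 0.0)
    w_new = np.where(r > 0, w_inf + (w - w_inf) * decay, w)
    return np.clip(w_new, 0.0, 1.0)


def piecewise_constant_solution(w0: float,
                                levels: np.ndarray,
                                durations: np.ndarray,
                                params: ModelParameters) -> float:
    """Closed-form final weight for a piecewise-constant calcium trace.

    Concatenates the exact exponential solution over each (level, duration)
    segment.  This is the analytic reference the per-step update must match.
    """
    w = float(w0)
    for c, tau in zip(levels, durations):
        a = params.gamma_p if c > params.theta_p else 0.0
        r = a + (params.gamma_d if c > params.theta_d else 0.0)
        if r > 0:
            w_inf = a / r
            w = w_inf + (w - w_inf) * np.exp(-r * tau)
    return w
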