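"""Single-step integration schemes.

Three schemes act on one neuron between conductance recalibrations:

* Heun's method (explicit trapezoid RK2), ``rk2_step``;
* the ETD2RK exponential integrator, ``etd2_step``, which freezes the linear
  coefficients c_z at the step start, propagates the linear part exactly and
  quadratures the nonlinear remainder with the phi-functions;
* the adaptive selector, ``select_scheme``: ETD2 inside a neuron's post-spike
  stiff period, RK2 (the c -> 0 reduction of ETD2RK) elsewhere.

Heun is exactly the c -> 0 limit of the ETD2RK formulas, which makes the two
branches of the adaptive method mutually consistent; the generic steppers here
are an independent pure-Python implementation used to cross-check the compiled
network loop.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParams, gating_rates, steady_state

PHI_SERIES_THRESHOLD = 1e-4


def phi1(x):
    """(e^x - 1)/x, series-evaluated near 0; phi1(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < PHI_SERIES_THRESHOLD
    xs = np.where(small, 0.0, x)
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        direct = np.expm1(xs) / np.where(small, 1.0, xs)
    series = 1.0 + x * (1 / 2 + x * (1 / 6 + x * (1 / 24 + x * (1 / 120 + x / 720))))
    out = np.where(small, series, direct)
    return float(out) if out.ndim == 0 else out


def phi2(x):
    """(e^x - 1 - x)/x^2, series-evaluated near 0; phi2(0) = 1/2."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < PHI_SERIES_THRESHOLD
    xs = np.where(small, 1.0, x)
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        direct = (np.expm1(xs) - xs) / (xs * xs)
    series = 0.5 + x * (1 / 6 + x * (1 / 24 + x * (1 / 120 + x * (1 / 720 + x / 5040))))
    out = np.where(small, series, direct)
    return float(out) if out.ndim == 0 else out


def heun_step(f, t, y, dt):
    """One explicit-trapezoid (Heun) step: predictor y + dt f, corrector
    averages the slopes at both ends."""
    y = np.asarray(y, dtype=float)
    f0 = np.asarray(f(t, y), dtype=float)
    pred = y + dt * f0
    f1 = np.asarray(f(t + dt, pred), dtype=float)
    return y + 0.5 * dt * (f0 + f1)


def etd2rk_step(f, t, y, dt, c):
    """One ETD2RK step for dy/dt = f(t, y) with frozen linear coefficients c.

    The nonlinear remainder is F(t, y) = f(t, y) - c*y.  Predictor
    ``a = y e^{c dt} + F0 dt phi1(c dt)``; corrector adds
    ``(F(t+dt, a) - F0) dt phi2(c dt)``.  With c = 0 this is Heun's method.
    """
    y = np.asarray(y, dtype=float)
    c = np.broadcast_to(np.asarray(c, dtype=float), y.shape)
    x = c * dt
    e = np.exp(x)
    p1 = phi1(x)
    p2 = phi2(x)
    F0 = np.asarray(f(t, y), dtype=float) - c * y
    a = y * e + F0 * dt * p1
    F1 = np.asarray(f(t + dt, a), dtype=float) - c * a
    return a + (F1 - F0) * dt * p2


def select_scheme(stiff_until: float, t_k: float) -> str:
    """Scheme for the step starting at t_k: 'etd2' while inside the stiff
    period (t_k < stiff_until), 'rk2' otherwise."""
    return "etd2" if t_k < stiff_until else "rk2"


# -- single-neuron wrappers -------------------------------------------------

def _pack(state, kind):
    if kind == "rtm":
        return np.array([state.V, state.h, state.n])
    return np.array([state.V, state.m, state.h, state.n])


def _neuron_f(params: ModelParams, synapse_params, conductance_at):
    """Full right-hand side as a function of (t, packed state); conductance_at
    must supply the spike-free (G_E, G_I) at any stage time."""
    from .model import NeuronState, hh_rhs

    kind = params.model_kind

    def f(t, y):
        gE, gI = conductance_at(t)
        if kind == "rtm":
            st = NeuronState(V=y[0], m=0.0, h=y[1], n=y[2])
        else:
            st = NeuronState(V=y[0], m=y[1], h=y[2], n=y[3])
        return np.array(hh_rhs(st, gE, gI, params, synapse_params))

    return f


def _linear_coeffs(state, params: ModelParams) -> np.ndarray:
    """Frozen per-step linear rates c_z from the step-start state:
    c_V from the instantaneous ionic conductance, c_z = -(alpha_z + beta_z)."""
    kind = params.model_kind
    m = steady_state(state.V, "m", kind) if kind == "rtm" else state.m
    cV = (-params.G_Na * m ** 3 * state.h
          - params.G_K * state.n ** 4 - params.G_L) / params.C
    cs = [cV]
    gates = ("h", "n") if kind == "rtm" else ("m", "h", "n")
    for g in gates:
        a, b = gating_rates(state.V, g, kind)
        cs.append(-(a + b))
    return np.array(cs)


def _unpack(y, state, params):
    from .model import NeuronState

    if params.model_kind == "rtm":
        V = float(y[0])
        return NeuronState(V=V, m=steady_state(V, "m", "rtm"),
                           h=float(y[1]), n=float(y[2]))
    return NeuronState(V=float(y[0]), m=float(y[1]), h=float(y[2]), n=float(y[3]))


def rk2_step(state, t_k: float, dt: float, conductance_at,
             params: ModelParams, synapse_params):
    """Advance one neuron from t_k to t_k+dt with Heun's method."""
    f = _neuron_f(params, synapse_params, conductance_at)
    y = etd2rk_step(f, t_k, _pack(state, params.model_kind), dt, 0.0)
    return _unpack(y, state, params)


def etd2_step(state, t_k: float, dt: float, conductance_at,
              params: ModelParams, synapse_params):
    """Advance one neuron from t_k to t_k+dt with the ETD2RK scheme."""
    f = _neuron_f(params, synapse_params, conductance_at)
    c = _linear_coeffs(state, params)
    y = etd2rk_step(f, t_k, _pack(state, params.model_kind), dt, c)
    return _unpack(y, state, params)
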