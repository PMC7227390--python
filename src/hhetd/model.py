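"""Single-neuron conductance-based models.

Two model kinds are supported:

* ``"hh"`` — the classical four-variable Hodgkin-Huxley neuron with state
  (V, m, h, n): sodium, potassium and leak currents, gating variables with
  voltage-dependent opening (alpha) and closing (beta) rates.
* ``"rtm"`` — the reduced Traub-Miles neuron, identical in structure except
  that sodium activation is instantaneous, m = alpha_m(V)/(alpha_m(V)+beta_m(V)),
  so the dynamical state is (V, h, n).

Units throughout the package: mV, ms, mS/cm^2, uF/cm^2, uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import _kernels

_MODEL_CODES = {"hh": _kernels.HH, "rtm": _kernels.RTM}

#: voltages (mV) where a gating-rate numerator and 1 - exp(...) vanish together
SINGULAR_VOLTAGES = {"hh": (-40.0, -55.0), "rtm": (-54.0, -27.0, -52.0)}


def _model_code(model_kind: str) -> int:
    try:
        return _MODEL_CODES[model_kind]
    except KeyError:
        raise ValueError(f"unknown model_kind {model_kind!r}; expected 'hh' or 'rtm'")


@dataclass(frozen=True)
class ModelParams:
    """Membrane parameters of a conductance-based neuron.

    Attributes
    ----------
    C : membrane capacitance (uF/cm^2)
    V_Na, V_K, V_L : reversal potentials (mV)
    G_Na, G_K, G_L : maximal conductances (mS/cm^2)
    V_th : firing threshold used for spike detection (mV)
    model_kind : "hh" or "rtm"
    """

    C: float = 1.0
    V_Na: float = 50.0
    V_K: float = -77.0
    V_L: float = -54.387
    G_Na: float = 120.0
    G_K: float = 36.0
    G_L: float = 0.3
    V_th: float = -50.0
    model_kind: str = "hh"

    def __post_init__(self):
        _model_code(self.model_kind)
        if self.C <= 0:
            raise ValueError("membrane capacitance C must be positive")
        if min(self.G_Na, self.G_K, self.G_L) < 0:
            raise ValueError("maximal conductances must be non-negative")
        if not (self.V_K < self.V_th < self.V_Na):
            raise ValueError("require V_K < V_th < V_Na")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.V_Na, self.V_K, self.V_L,
                         self.G_Na, self.G_K, self.G_L, self.V_th])


def hh_default() -> ModelParams:
    """Standard Hodgkin-Huxley parameter set."""
    return ModelParams()


def rtm_default() -> ModelParams:
    """Reduced Traub-Miles parameter set (note the higher threshold, 0 mV)."""
    return ModelParams(V_Na=50.0, V_K=-100.0, V_L=-67.0,
                       G_Na=100.0, G_K=80.0, G_L=0.1,
                       V_th=0.0, model_kind="rtm")


PRESETS = {"HH-default": hh_default, "RTM-default": rtm_default}


@dataclass
class NeuronState:
    """Instantaneous state (V in mV; m, h, n dimensionless).

    For the RTM model m is not dynamical: it is carried for convenience as the
    instantaneous steady value at the current voltage.
    """

    V: float
    m: float
    h: float
    n: float


_GATE_INDEX = {"m": 0, "h": 1, "n": 2}


def gating_rates(V: float, gate: str, model_kind: str = "hh") -> tuple[float, float]:
    """Opening/closing rates (alpha, beta) in ms^-1 for one gate at voltage V.

    Removable singularities of the x/(1-exp(-x)) form are evaluated by a
    guarded series expansion, so the result is finite and continuous at the
    grid-aligned voltages where numerator and denominator vanish together.
    """
    if not np.isfinite(V):
        raise ValueError("membrane potential must be finite")
    code = _model_code(model_kind)
    r = _kernels.rates(float(V), code)
    try:
        g = _GATE_INDEX[gate]
    except KeyError:
        raise ValueError(f"unknown gate {gate!r}; expected 'm', 'h' or 'n'")
    return r[2 * g], r[2 * g + 1]


def steady_state(V: float, gate: str, model_kind: str = "hh") -> float:
    """Voltage-clamp steady value alpha/(alpha+beta) of a gating variable."""
    a, b = gating_rates(V, gate, model_kind)
    return a / (a + b)


def hh_rhs(state: NeuronState, G_E: float, G_I: float,
           params: ModelParams, synapse_params) -> tuple:
    """Time derivatives of the neuron state at fixed synaptic conductances.

    Returns (dV/dt, dm/dt, dh/dt, dn/dt) for the HH model and
    (dV/dt, dh/dt, dn/dt) for RTM (m replaced by its instantaneous value).
    """
    if G_E < 0 or G_I < 0:
        raise ValueError("synaptic conductances must be non-negative")
    kind = params.model_kind
    am, bm = gating_rates(state.V, "m", kind)
    ah, bh = gating_rates(state.V, "h", kind)
    an, bn = gating_rates(state.V, "n", kind)
    m = am / (am + bm) if kind == "rtm" else state.m
    dV = _kernels.dvdt(state.V, m, state.h, state.n, G_E, G_I,
                       params.C, params.V_Na, params.V_K, params.V_L,
                       params.G_Na, params.G_K, params.G_L,
                       synapse_params.V_GE, synapse_params.V_GI)
    dh = (1.0 - state.h) * ah - state.h * bh
    dn = (1.0 - state.n) * an - state.n * bn
    if kind == "rtm":
        return dV, dh, dn
    dm = (1.0 - state.m) * am - state.m * bm
    return dV, dm, dh, dn


def resting_state(params: ModelParams | None = None,
                  bracket: tuple[float, float] = (-80.0, -50.0)) -> NeuronState:
    """Fixed point of the autonomous (zero-input) single-neuron system.

    Solves for the voltage at which the ionic current vanishes with every gate
    at its steady value; the returned state has all derivatives ~ 0.
    """
    p = params or hh_default()
    kind = p.model_kind

    def current(V):
        m = steady_state(V, "m", kind)
        h = steady_state(V, "h", kind)
        n = steady_state(V, "n", kind)
        return (-(V - p.V_Na) * p.G_Na * m ** 3 * h
                - (V - p.V_K) * p.G_K * n ** 4
                - (V - p.V_L) * p.G_L)

    V0 = brentq(current, bracket[0], bracket[1], xtol=1e-13, rtol=1e-15)
    return NeuronState(V=V0, m=steady_state(V0, "m", kind),
                       h=steady_state(V0, "h", kind),
                       n=steady_state(V0, "n", kind))


def initial_state(n: int, params: ModelParams, v0: float = -65.0,
                  v0_jitter: float = 0.0, rng: np.random.Generator | None = None):
    """Per-neuron initial arrays (V, m, h, n): V = v0 (optionally jittered
    uniformly in [-v0_jitter/2, v0_jitter/2]), gates at steady state."""
    kind = params.model_kind
    V = np.full(n, float(v0))
    if v0_jitter > 0:
        if rng is None:
            raise ValueError("v0_jitter > 0 requires an rng")
        V += rng.uniform(-v0_jitter / 2.0, v0_jitter / 2.0, size=n)
    m = np.array([steady_state(v, "m", kind) for v in V])
    h = np.array([steady_state(v, "h", kind) for v in V])
    n_ = np.array([steady_state(v, "n", kind) for v in V])
    return V, m, h, n_


def with_threshold(params: ModelParams, V_th: float) -> ModelParams:
    return replace(params, V_th=V_th)
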