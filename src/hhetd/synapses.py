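"""Double-exponential synaptic conductance dynamics and feedforward drive.

Each neuron carries one conductance pair per receptor type Q in {E, I}:

    dG/dt = -G/sigma_r + H
    dH/dt = -H/sigma_d + sum_spikes strength * delta(t - spike_time)

whose spike response is the double-exponential kernel
``kernel(sigma_d, sigma_r, t)``.  Between spikes the pair decays exactly
(`decay_step`); spikes falling inside a step are folded in at the step end
with their exact kernel contribution (`recalibrate`), which is what keeps the
overall scheme second-order despite the pulse coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic reversal potentials (mV) and kernel time constants (ms)."""

    V_GE: float = 0.0
    V_GI: float = -80.0
    sigma_r_E: float = 0.5
    sigma_d_E: float = 3.0
    sigma_r_I: float = 0.5
    sigma_d_I: float = 7.0

    def __post_init__(self):
        if not (0 < self.sigma_r_E < self.sigma_d_E):
            raise ValueError("require 0 < sigma_r_E < sigma_d_E")
        if not (0 < self.sigma_r_I < self.sigma_d_I):
            raise ValueError("require 0 < sigma_r_I < sigma_d_I")

    def tau(self, receptor: str) -> tuple[float, float]:
        """(sigma_d, sigma_r) for receptor 'E' or 'I'."""
        if receptor == "E":
            return self.sigma_d_E, self.sigma_r_E
        if receptor == "I":
            return self.sigma_d_I, self.sigma_r_I
        raise ValueError(f"unknown receptor {receptor!r}")


def kernel(sigma_d: float, sigma_r: float, t):
    """Spike-induced conductance kernel.

    ``sigma_d * sigma_r / (sigma_d - sigma_r) * (e^{-t/sigma_d} - e^{-t/sigma_r})``
    for t > 0, zero for t <= 0.  Vectorized over t.
    """
    if not (0 < sigma_r < sigma_d):
        raise ValueError("require 0 < sigma_r < sigma_d")
    t = np.asarray(t, dtype=float)
    pref = sigma_d * sigma_r / (sigma_d - sigma_r)
    with np.errstate(over="ignore"):
        val = pref * (np.exp(-t / sigma_d) - np.exp(-t / sigma_r))
    out = np.where(t > 0, val, 0.0)
    return float(out) if out.ndim == 0 else out


def kernel_peak_time(sigma_d: float, sigma_r: float) -> float:
    """Argmax of the kernel: (sigma_d sigma_r/(sigma_d-sigma_r)) ln(sigma_d/sigma_r)."""
    return sigma_d * sigma_r / (sigma_d - sigma_r) * math.log(sigma_d / sigma_r)


@dataclass
class SynapticState:
    """Per-neuron conductances G and auxiliary rise variables H, one pair per
    receptor type (mS/cm^2)."""

    G_E: np.ndarray
    G_I: np.ndarray
    H_E: np.ndarray
    H_I: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SynapticState":
        return cls(*(np.zeros(n) for _ in range(4)))

    def copy(self) -> "SynapticState":
        return SynapticState(self.G_E.copy(), self.G_I.copy(),
                             self.H_E.copy(), self.H_I.copy())


def decay_step(state: SynapticState, dt: float, params: SynapseParams) -> SynapticState:
    """Exact spike-free evolution over dt:  H -> H e^{-dt/sigma_d},
    G -> G e^{-dt/sigma_r} + H kernel(sigma_d, sigma_r, dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = SynapticState.zeros(len(state.G_E))
    for rec, G, H, Go, Ho in (("E", state.G_E, state.H_E, out.G_E, out.H_E),
                              ("I", state.G_I, state.H_I, out.G_I, out.H_I)):
        sd, sr = params.tau(rec)
        Ho[:] = H * math.exp(-dt / sd)
        Go[:] = G * math.exp(-dt / sr) + H * kernel(sd, sr, dt)
    return out


def recalibrate(state: SynapticState, t_end: float, params: SynapseParams, *,
                t_start: float = -np.inf,
                feedforward=(), ff_strength: float = 0.0,
                synaptic=()) -> SynapticState:
    """Fold spikes with times in (t_start, t_end] into an already-decayed state.

    Each spike at time u adds ``strength * e^{-(t_end-u)/sigma_d}`` to H and
    ``strength * kernel(sigma_d, sigma_r, t_end-u)`` to G of its receptor type.

    Parameters
    ----------
    feedforward : iterable of (neuron_id, time); each adds ff_strength to the
        neuron's excitatory pair.
    synaptic : iterable of (time, weights, receptor) where weights is a
        per-target array and receptor is 'E' or 'I'.
    """
    out = state.copy()
    for i, u in feedforward:
        if not (t_start < u <= t_end):
            raise ValueError(f"feedforward spike at {u} outside ({t_start}, {t_end}]")
        sd, sr = params.tau("E")
        d = t_end - u
        out.H_E[i] += ff_strength * math.exp(-d / sd)
        out.G_E[i] += ff_strength * kernel(sd, sr, d)
    for u, weights, receptor in synaptic:
        if not (t_start < u <= t_end):
            raise ValueError(f"synaptic spike at {u} outside ({t_start}, {t_end}]")
        sd, sr = params.tau(receptor)
        d = t_end - u
        w = np.asarray(weights, dtype=float)
        if receptor == "E":
            out.H_E += w * math.exp(-d / sd)
            out.G_E += w * kernel(sd, sr, d)
        else:
            out.H_I += w * math.exp(-d / sd)
            out.G_I += w * kernel(sd, sr, d)
    return out


@dataclass
class FeedforwardTrain:
    """Per-neuron sorted feedforward spike times (ms) on [0, T]."""

    times: list = field(default_factory=list)  # list of np.ndarray, one per neuron

    @property
    def n_neurons(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.times)

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All events merged and sorted by time: (times, neuron_ids)."""
        if self.n_events == 0:
            return np.empty(0), np.empty(0, dtype=np.int64)
        t = np.concatenate(self.times)
        i = np.concatenate([np.full(len(ti), k, dtype=np.int64)
                            for k, ti in enumerate(self.times)])
        order = np.argsort(t, kind="stable")
        return t[order], i[order]

    def save(self, path) -> None:
        """Two-column text serialization, one event per line."""
        with open(path, "w") as fh:
            fh.write("# neuron time_ms\n")
            for k, ti in enumerate(self.times):
                for u in ti:
                    fh.write(f"{k} {float(u)!r}\n")

    @classmethod
    def load(cls, path, n_neurons: int | None = None) -> "FeedforwardTrain":
        ids, times = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split()
                ids.append(int(a))
                times.append(float(b))
        n = n_neurons if n_neurons is not None else (max(ids) + 1 if ids else 0)
        per = [[] for _ in range(n)]
        for i, u in zip(ids, times):
            per[i].append(u)
        return cls([np.array(sorted(p)) for p in per])


def draw_poisson_trains(n: int, nu_hz: float, T: float,
                        rng: np.random.Generator | int | None) -> FeedforwardTrain:
    """Independent homogeneous Poisson spike trains, one per neuron.

    nu_hz is the rate in Hz (stored internally per ms: 300 Hz = 0.3 ms^-1);
    T is the duration in ms. Event times are exact, not grid-aligned.
    """
    if nu_hz < 0:
        raise ValueError("rate must be non-negative")
    if T <= 0:
        raise ValueError("duration must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rate_ms = nu_hz / 1000.0
    trains = []
    for _ in range(n):
        if rate_ms == 0:
            trains.append(np.empty(0))
            continue
        # draw inter-arrival times in blocks until past T
        t = []
        acc = 0.0
        while acc <= T:
            gaps = rng.exponential(1.0 / rate_ms, size=max(16, int(rate_ms * T * 0.2)))
            for g in gaps:
                acc += g
                if acc > T:
                    break
                t.append(acc)
        trains.append(np.array(t))
    return FeedforwardTrain(trains)
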