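"""Error metrics, convergence-order estimation and firing-rate statistics.

The accuracy of a run against a fine-step reference is measured by two
Euclidean norms across neurons: the final-time membrane-potential difference
(`error_V`) and the last-spike-time difference (`error_tau`).  Convergence
order is the least-squares slope of log(error) against log(dt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import NetworkConfig, SimulationResult, simulate

log = logging.getLogger(__name__)


def error_V(V_run, V_ref) -> float:
    """Euclidean norm across neurons of the final-time voltage difference."""
    V_run = np.asarray(V_run, dtype=float)
    V_ref = np.asarray(V_ref, dtype=float)
    if V_run.shape != V_ref.shape:
        raise ValueError("voltage vectors must have equal length")
    return float(np.sqrt(np.sum((V_run - V_ref) ** 2)))


def error_tau(last_spikes_run, last_spikes_ref):
    """Euclidean norm across neurons of last-spike-time differences.

    Neurons without a spike in either run (NaN entries) are dropped pairwise;
    returns None if no neuron spiked in both runs.
    """
    a = np.asarray(last_spikes_run, dtype=float)
    b = np.asarray(last_spikes_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spike-time vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    dropped = a.size - int(ok.sum())
    if dropped:
        log.info("error_tau: dropped %d neuron(s) without spikes in both runs",
                 dropped)
    if not ok.any():
        return None
    return float(np.sqrt(np.sum((a[ok] - b[ok]) ** 2)))


def convergence_order(dts, errors) -> float:
    """Least-squares slope of log(error) vs log(dt); zero errors excluded."""
    dts = np.asarray(dts, dtype=float)
    errors = np.asarray(errors, dtype=float)
    ok = errors > 0
    if not ok.all():
        log.warning("convergence_order: excluded %d zero error(s)",
                    int((~ok).sum()))
    if ok.sum() < 2:
        raise ValueError("need at least two positive (dt, error) pairs")
    return float(np.polyfit(np.log(dts[ok]), np.log(errors[ok]), 1)[0])


def mean_firing_rate(spikes, n_neurons: int, T_ms: float) -> float:
    """Population mean rate in Hz: spike count / (N * T)."""
    if T_ms <= 0:
        raise ValueError("T must be positive")
    count = int(spikes) if np.isscalar(spikes) else len(spikes)
    return count / (n_neurons * T_ms) * 1000.0


def relative_rate_error(rate_method: float, rate_benchmark: float) -> float:
    """|rate_method - rate_benchmark| / rate_benchmark (a fraction)."""
    return abs(rate_method - rate_benchmark) / rate_benchmark


def efficiency_ratio(dt_aetd2: float, dt_rk2: float) -> float:
    """Step-count efficiency ratio of AETD2 over RK2 at a common run time:
    (T/dt_rk2)/(T/dt_aetd2) = dt_aetd2/dt_rk2."""
    return dt_aetd2 / dt_rk2


@dataclass
class ErrorReport:
    """Per-method errors over a list of time steps plus fitted slopes."""

    table: pd.DataFrame              # columns: method, dt, error_V, error_tau
    slopes: dict                     # method -> {"V": slope, "tau": slope}
    ref_dt: float

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def result_rate(result: SimulationResult) -> float:
    """Mean rate of a finished run over its actually simulated duration."""
    return mean_firing_rate(result.spike_times, result.config.n,
                            result.n_steps * result.config.dt)


def convergence_study(config: NetworkConfig, dts,
                      methods=("naive-rk2", "rk2", "etd2", "aetd2"),
                      ref_dt: float = 2.0 ** -16,
                      ref_method: str = "rk2") -> ErrorReport:
    """Run each method over the given time steps against one fine-step
    reference run; all runs share the seed and hence the same feedforward
    realization and initial conditions."""
    ref = simulate(replace(config, method=ref_method, dt=ref_dt))
    ref_last = ref.last_spike_times()
    rows = []
    for method in methods:
        for dt in dts:
            res = simulate(replace(config, method=method, dt=float(dt)))
            rows.append({
                "method": method, "dt": float(dt),
                "error_V": error_V(res.V, ref.V),
                "error_tau": error_tau(res.last_spike_times(), ref_last),
            })
    table = pd.DataFrame(rows)
    slopes = {}
    for method in methods:
        sub = table[table.method == method]
        slopes[method] = {}
        if len(sub) >= 2:
            slopes[method]["V"] = convergence_order(sub.dt, sub.error_V)
            tau_ok = sub.error_tau.notna()
            if tau_ok.sum() >= 2:
                slopes[method]["tau"] = convergence_order(
                    sub.dt[tau_ok], sub.error_tau[tau_ok])
    return ErrorReport(table=table, slopes=slopes, ref_dt=ref_dt)


def rate_table(config: NetworkConfig,
               dts_by_method: dict,
               benchmark_dt: float = 0.005,
               benchmark_method: str = "rk2") -> pd.DataFrame:
    """Accuracy table: mean rate and relative rate error per (method, dt)
    against one converged small-step benchmark run sharing the seed."""
    bench = simulate(replace(config, method=benchmark_method, dt=benchmark_dt))
    bench_rate = result_rate(bench)
    rows = [{"method": benchmark_method, "dt": benchmark_dt,
             "rate_hz": bench_rate, "relative_error": 0.0, "benchmark": True}]
    for method, dts in dts_by_method.items():
        for dt in dts:
            res = simulate(replace(config, method=method, dt=float(dt)))
            rate = result_rate(res)
            rows.append({"method": method, "dt": float(dt), "rate_hz": rate,
                         "relative_error": relative_rate_error(rate, bench_rate),
                         "benchmark": False})
    return pd.DataFrame(rows)
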