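"""Compiled inner loops for the network simulator.

Everything here is scalar-level numba code: gating-rate evaluation, the
phi-functions of exponential integrators, the unified ETD2RK/Heun single-neuron
step, and the full fixed-step network loop (spike-free evolution, threshold
detection with linear spike-time interpolation, end-of-step conductance
recalibration, stiff-period bookkeeping).

The Python-facing modules (`model`, `synapses`, `integrators`, `network`) wrap
these functions; `integrators` additionally carries an independent pure-Python
implementation of the single steps used to cross-check this module in tests.
"""

import math

import numpy as np
from numba import njit

# model kinds
HH = 0
RTM = 1

# method codes
METHOD_RK2 = 0
METHOD_ETD2 = 1
METHOD_AETD2 = 2
METHOD_NAIVE_RK2 = 3

# run status
OK = 0
NONFINITE = 1
SPIKE_OVERFLOW = 2

# phi1/phi2 switch to a 6-term Taylor series below this |x|: the direct
# expm1-based forms lose ~|eps/x| relative accuracy to cancellation.
PHI_SERIES_THRESHOLD = 1e-4

# guarded series for x/(1-exp(-x)) below this |x|
XEXPREL_THRESHOLD = 1e-6


@njit(cache=True, inline="always")
def _xexprel(x):
    """x / (1 - exp(-x)) with its removable singularity at x = 0 filled in."""
    if abs(x) < XEXPREL_THRESHOLD:
        # 1 - e^{-x} = x (1 - x/2 + x^2/6 - ...)
        return 1.0 / (1.0 - x * (0.5 - x / 6.0))
    return x / (1.0 - math.exp(-x))


@njit(cache=True)
def rates(V, model):
    """All six voltage-dependent gating rates (alpha_m, beta_m, alpha_h,
    beta_h, alpha_n, beta_n) in ms^-1 at membrane potential V (mV)."""
    if model == HH:
        am = _xexprel(0.1 * V + 4.0)
        bm = 4.0 * math.exp(-(V + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(V + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-3.5 - 0.1 * V))
        an = 0.1 * _xexprel(0.1 * V + 5.5)
        bn = 0.125 * math.exp(-(V + 65.0) / 80.0)
    else:
        # reduced Traub-Miles
        am = 1.28 * _xexprel((V + 54.0) / 4.0)
        bm = 1.4 * _xexprel(-(V + 27.0) / 5.0)
        ah = 0.128 * math.exp(-(V + 50.0) / 18.0)
        bh = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
        an = 0.16 * _xexprel((V + 52.0) / 5.0)
        bn = 0.5 * math.exp(-(V + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, inline="always")
def phi_funcs(x):
    """(e^x, phi1(x), phi2(x)) with phi1 = (e^x-1)/x, phi2 = (e^x-1-x)/x^2."""
    if x == 0.0:
        return 1.0, 1.0, 0.5
    if abs(x) < PHI_SERIES_THRESHOLD:
        p1 = 1.0 + x * (1.0 / 2.0 + x * (1.0 / 6.0 + x * (1.0 / 24.0
             + x * (1.0 / 120.0 + x / 720.0))))
        p2 = 0.5 + x * (1.0 / 6.0 + x * (1.0 / 24.0 + x * (1.0 / 120.0
             + x * (1.0 / 720.0 + x / 5040.0))))
        return math.exp(x), p1, p2
    em1 = math.expm1(x)
    return em1 + 1.0, em1 / x, (em1 - x) / (x * x)


@njit(cache=True, inline="always")
def syn_kernel(sd, sr, t):
    """Double-exponential conductance kernel, zero for t <= 0."""
    if t <= 0.0:
        return 0.0
    return sd * sr / (sd - sr) * (math.exp(-t / sd) - math.exp(-t / sr))


@njit(cache=True, inline="always")
def dvdt(V, m, h, n, gE, gI, C, VNa, VK, VL, gNa, gK, gL, VGE, VGI):
    """Full membrane-potential right-hand side (mV/ms)."""
    ionic = (-(V - VNa) * gNa * m * m * m * h
             - (V - VK) * gK * n * n * n * n
             - (V - VL) * gL)
    synaptic = -gE * (V - VGE) - gI * (V - VGI)
    return (ionic + synaptic) / C


@njit(cache=True)
def step_neuron(model, use_c, V, m, h, n, gE0, gI0, gE1, gI1, dt, mp, sp):
    """One ETD2RK step for a single neuron.

    With use_c = True the linear coefficients c_z are frozen from the
    step-start state; with use_c = False all c_z = 0, in which case the
    formulas reduce exactly to Heun's method (explicit trapezoid RK2).
    gE0/gI0 and gE1/gI1 are the spike-free synaptic conductances at the start
    and end of the step.
    """
    C = mp[0]
    VNa = mp[1]
    VK = mp[2]
    VL = mp[3]
    gNa = mp[4]
    gK = mp[5]
    gL = mp[6]
    VGE = sp[0]
    VGI = sp[1]

    am, bm, ah, bh, an, bn = rates(V, model)
    if model == RTM:
        m = am / (am + bm)

    if use_c:
        cV = (-gNa * m * m * m * h - gK * n * n * n * n - gL) / C
        cm = -(am + bm)
        ch = -(ah + bh)
        cn = -(an + bn)
    else:
        cV = 0.0
        cm = 0.0
        ch = 0.0
        cn = 0.0

    FV0 = dvdt(V, m, h, n, gE0, gI0, C, VNa, VK, VL, gNa, gK, gL, VGE, VGI) - cV * V
    Fh0 = (1.0 - h) * ah - h * bh - ch * h
    Fn0 = (1.0 - n) * an - n * bn - cn * n

    eV, p1V, p2V = phi_funcs(cV * dt)
    eh, p1h, p2h = phi_funcs(ch * dt)
    en, p1n, p2n = phi_funcs(cn * dt)

    aV = V * eV + FV0 * dt * p1V
    ahp = h * eh + Fh0 * dt * p1h
    anp = n * en + Fn0 * dt * p1n

    if model == HH:
        Fm0 = (1.0 - m) * am - m * bm - cm * m
        em, p1m, p2m = phi_funcs(cm * dt)
        amp = m * em + Fm0 * dt * p1m
    else:
        Fm0 = 0.0
        p2m = 0.0
        amp = 0.0

    # second stage at t_k + dt on the predictor state
    am1, bm1, ah1, bh1, an1, bn1 = rates(aV, model)
    if model == RTM:
        amp = am1 / (am1 + bm1)

    FV1 = dvdt(aV, amp, ahp, anp, gE1, gI1,
               C, VNa, VK, VL, gNa, gK, gL, VGE, VGI) - cV * aV
    Fh1 = (1.0 - ahp) * ah1 - ahp * bh1 - ch * ahp
    Fn1 = (1.0 - anp) * an1 - anp * bn1 - cn * anp

    V1 = aV + (FV1 - FV0) * dt * p2V
    h1 = ahp + (Fh1 - Fh0) * dt * p2h
    n1 = anp + (Fn1 - Fn0) * dt * p2n

    if model == HH:
        Fm1 = (1.0 - amp) * am1 - amp * bm1 - cm * amp
        m1 = amp + (Fm1 - Fm0) * dt * p2m
    else:
        amr, bmr, _, _, _, _ = rates(V1, model)
        m1 = amr / (amr + bmr)

    return V1, m1, h1, n1


@njit(cache=True)
def run_network(V, m, h, n, gE, gI, hE, hI,
                W, is_exc,
                ff_t, ff_i,
                k0, dt, n_steps,
                method, model, mp, sp,
                stiff_duration, refractory, slope_threshold,
                stiff_until, refr_until,
                rec_idx, rec_every, rec_t, rec_V,
                spike_t, spike_i, n_stiff_steps):
    """Fixed-step network loop (Algorithms RK2/AETD2). All state arrays are
    advanced in place; detected spikes are appended to spike_t/spike_i.

    Per step: (1) every neuron advances by its scheme using spike-free
    conductances at the step endpoints; (2) conductances advance by exact
    decay; (3) upward threshold crossings of eligible neurons are located by
    linear interpolation; (4) conductances are recalibrated with the step's
    feedforward and synaptic spikes; (5) stiff/refractory trackers update.
    Voltages are not re-integrated after recalibration.

    Returns (n_spikes, n_recorded, status).
    """
    N = V.shape[0]
    Vth = mp[7]
    srE = sp[2]
    sdE = sp[3]
    srI = sp[4]
    sdI = sp[5]
    FE = sp[6]
    FI = sp[7]

    # per-run decay scalars for the fixed step
    dec_gE = math.exp(-dt / srE)
    dec_hE = math.exp(-dt / sdE)
    kerE = syn_kernel(sdE, srE, dt)
    dec_gI = math.exp(-dt / srI)
    dec_hI = math.exp(-dt / sdI)
    kerI = syn_kernel(sdI, srI, dt)

    gE_new = np.empty(N)
    gI_new = np.empty(N)
    step_sp_i = np.empty(N, dtype=np.int64)
    step_sp_tau = np.empty(N)

    cap = spike_t.shape[0]
    n_ff = ff_t.shape[0]
    ptr = np.searchsorted(ff_t, k0 * dt, side="right")
    nsp = 0
    nrec = 0
    status = OK

    C = mp[0]
    VNa = mp[1]
    VK = mp[2]
    VL = mp[3]
    gNa = mp[4]
    gK = mp[5]
    gL = mp[6]
    VGE = sp[0]
    VGI = sp[1]

    for k in range(n_steps):
        tk = (k0 + k) * dt
        t_end = (k0 + k + 1) * dt

        if rec_every > 0 and k % rec_every == 0:
            rec_t[nrec] = tk
            for r in range(rec_idx.shape[0]):
                rec_V[nrec, r] = V[rec_idx[r]]
            nrec += 1

        n_step_sp = 0
        for i in range(N):
            gE1 = gE[i] * dec_gE + hE[i] * kerE
            gI1 = gI[i] * dec_gI + hI[i] * kerI

            if method == METHOD_ETD2:
                use_c = True
            elif method == METHOD_AETD2:
                use_c = tk < stiff_until[i]
                if model == RTM and not use_c:
                    amr, bmr, _, _, _, _ = rates(V[i], RTM)
                    mi = amr / (amr + bmr)
                    slope = dvdt(V[i], mi, h[i], n[i], gE[i], gI[i],
                                 C, VNa, VK, VL, gNa, gK, gL, VGE, VGI)
                    use_c = abs(slope) >= slope_threshold
            else:
                use_c = False

            oldV = V[i]
            V1, m1, h1, n1 = step_neuron(model, use_c, oldV, m[i], h[i], n[i],
                                         gE[i], gI[i], gE1, gI1, dt, mp, sp)
            if not math.isfinite(V1):
                return nsp, nrec, NONFINITE

            if use_c:
                n_stiff_steps[i] += 1

            V[i] = V1
            m[i] = m1
            h[i] = h1
            n[i] = n1
            gE_new[i] = gE1
            gI_new[i] = gI1

            # upward threshold crossing of an eligible neuron
            if tk >= refr_until[i] and oldV < Vth and V1 >= Vth:
                if method == METHOD_NAIVE_RK2:
                    tau = t_end
                else:
                    tau = tk + dt * (Vth - oldV) / (V1 - oldV)
                step_sp_i[n_step_sp] = i
                step_sp_tau[n_step_sp] = tau
                n_step_sp += 1
                refr_until[i] = tau + refractory
                stiff_until[i] = tau + stiff_duration

        for i in range(N):
            gE[i] = gE_new[i]
            gI[i] = gI_new[i]
            hE[i] = hE[i] * dec_hE
            hI[i] = hI[i] * dec_hI

        # fold in feedforward events with times in (tk, t_end]
        while ptr < n_ff and ff_t[ptr] <= t_end:
            u = ff_t[ptr]
            i = ff_i[ptr]
            d = t_end - u
            if FE > 0.0:
                hE[i] += FE * math.exp(-d / sdE)
                gE[i] += FE * syn_kernel(sdE, srE, d)
            if FI > 0.0:
                hI[i] += FI * math.exp(-d / sdI)
                gI[i] += FI * syn_kernel(sdI, srI, d)
            ptr += 1

        # fold in this step's synaptic spikes
        for s in range(n_step_sp):
            j = step_sp_i[s]
            tau = step_sp_tau[s]
            if nsp >= cap:
                return nsp, nrec, SPIKE_OVERFLOW
            spike_t[nsp] = tau
            spike_i[nsp] = j
            nsp += 1
            d = t_end - tau
            if is_exc[j]:
                eh_ = math.exp(-d / sdE)
                eg_ = syn_kernel(sdE, srE, d)
                for i2 in range(N):
                    w = W[i2, j]
                    if w != 0.0:
                        hE[i2] += w * eh_
                        gE[i2] += w * eg_
            else:
                eh_ = math.exp(-d / sdI)
                eg_ = syn_kernel(sdI, srI, d)
                for i2 in range(N):
                    w = W[i2, j]
                    if w != 0.0:
                        hI[i2] += w * eh_
                        gI[i2] += w * eg_

    if rec_every > 0:
        rec_t[nrec] = (k0 + n_steps) * dt
        for r in range(rec_idx.shape[0]):
            rec_V[nrec, r] = V[rec_idx[r]]
        nrec += 1

    return nsp, nrec, status
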