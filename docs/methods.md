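# Methods notes

## Model and scope

The simulator evolves pulse-coupled conductance-based networks. Two neuron
models are built in: the classical Hodgkin–Huxley (HH) squid-axon
parameterization (state V, m, h, n) and the reduced Traub–Miles (RTM) model,
in which sodium activation is instantaneous, m = α_m(V)/(α_m(V)+β_m(V)), so
the dynamical state is (V, h, n) and m is recomputed at every stage
evaluation. Units are fixed package-wide — mV, ms, mS·cm⁻², μF·cm⁻²,
μA·cm⁻² — with no conversion layer; the feedforward Poisson rate is accepted
in Hz and converted once to ms⁻¹ internally.

Synapses are double-exponential conductance pairs (G, H) per receptor type,
E (σ_r = 0.5 ms, σ_d = 3 ms, reversal 0 mV) and I (σ_r = 0.5 ms, σ_d = 7 ms,
reversal −80 mV). Coupling is pulse-based with zero synaptic delay: a spike
of neuron j at its interpolated time τ adds weight S/N to every postsynaptic
target's pair, routed E or I by the presynaptic type. Because (G, H) are
linear in the spike events, the whole conductance trajectory is an exact
superposition of decaying kernels — the test suite exploits this as an
end-to-end oracle for the event bookkeeping.

## The step

Every method advances the network over a fixed step [t_k, t_k+Δt] in the
same order:

1. each neuron's (V, m, h, n) advances with spike-free conductances — the
   exact decays G(t_k) and G̃(t_k+Δt) at the two stage times; no mid-step
   conductance interpolation is needed for second order;
2. the conductance pairs advance by their exact decay;
3. upward threshold crossings (V_k < V_th ≤ V_{k+1}) of eligible neurons are
   located by linear interpolation between the bracketing voltages;
4. all feedforward events and detected spikes with times in the half-open
   window (t_k, t_k+Δt] are folded into the conductances with their exact
   kernel contribution at t_k+Δt (events landing exactly on the grid point
   belong to the step that ends there);
5. voltages are *not* re-integrated after recalibration, and the
   spike-containing step is not recomputed with the stiff scheme.

The per-neuron schemes are a single parametrized formula: the ETD2RK
predictor–corrector with frozen linear coefficients c_z, whose c → 0 limit
is algebraically Heun's method. The RK2 method runs this formula with
c ≡ 0; AETD2 toggles c per neuron and per step. This makes "AETD2 with an
empty stiff window is bitwise RK2" an exact identity rather than an
approximation, and it is tested as such.

## Stiff-period and detection bookkeeping

Two per-neuron windows start at each interpolated spike time:

* `stiff_duration` (default 3.5 ms) — the AETD2 scheme window: a step whose
  *start* lies inside it uses ETD2. 3.5 ms covers the HH action potential's
  stiff region (upstroke, peak, repolarization).
* `refractory` (default 3.5 ms) — the detection-eligibility window: a neuron
  whose step starts inside it cannot trigger a new spike. This guards
  against re-detection on the descending flank, and bounds the spike count
  (used to size the output buffers).

The two defaults coincide, so by default they behave as a single window;
they are separate fields so that scheme selection can be forced (e.g. an
infinite stiff window makes AETD2 equal ETD2 from each neuron's first spike
onward) without also disabling spike detection.

In RTM mode the spike upstroke is far too fast (~0.03 ms) for a window that
starts at threshold crossing, so a neuron is additionally stiff whenever
|dV/dt| at its current state exceeds `stiff_slope_threshold` (default
20 mV/ms); the post-spike window is kept as well, which prevents the slope
criterion from chattering at the two crossings of the threshold slope within
one action potential.

## Numerical choices

* φ₁(x) = (eˣ−1)/x and φ₂(x) = (eˣ−1−x)/x² switch to 6-term Taylor series
  for |x| < 10⁻⁴; above that, expm1-based forms are used. The crossover is
  seamless to < 10⁻¹⁰ relative (tested).
* The gating-rate form x/(1−e^{−x}) uses a guarded series for |x| < 10⁻⁶,
  so the removable singularities (V = −40, −55 mV for HH; −54, −27, −52 mV
  for RTM) evaluate to their analytic limits even on grid-aligned voltages.
* Initial conditions (a protocol choice): V(0) = −65 mV for every neuron,
  gates at their voltage-clamp steady values, conductances zero. An optional
  seeded uniform jitter on V(0) is available but off by default. A
  zero-input network initialized at the autonomous fixed point stays there
  to < 10⁻⁹ per step.
* All randomness derives from one seed through three independent
  substreams (feedforward trains, initial-condition jitter, topology), so
  changing one consumer does not shift another's draws. Poisson event times
  are exact (inter-arrival exponentials), never grid-aligned. Runs are
  bitwise reproducible; block-wise stepping equals a single run bitwise
  because step times are computed from integer step indices.
* A non-finite membrane potential aborts the run with a diagnostic naming
  the method and step size (explicit RK2 is unstable during spikes for
  Δt ≳ 0.05 ms; plain ETD2 at large steps loses spikes but must stay
  finite — both behaviours are tested).

## Error metrics and reference runs

Accuracy against a fine-step reference is measured by Euclidean norms across
neurons of (a) the final-time voltage difference and (b) the last-spike-time
difference; neurons silent in either run are dropped pairwise from (b) with
a logged count. The sum-of-squares is rooted so that fitted log–log slopes
match first/second-order guide lines directly. Convergence order is the
least-squares slope of log(error) vs log(Δt).

Problem sizes are chosen to keep a desk-scale run meaningful: the
convergence study uses the reference network over T = 100 ms with a shared
feedforward realization, Δt ∈ {2⁻⁵ … 2⁻⁹} ms and an RK2 reference at
Δt = 2⁻¹⁶ ms; rate-accuracy comparisons use the full T = 10 s with an RK2
Δt = 0.005 ms benchmark (the rate is already converged at 0.005–0.02 ms, so
a far finer benchmark only changes the comparison below its sampling noise).
The efficiency ratio of AETD2 over RK2 is reported as the step-count ratio
Δt_AETD2/Δt_RK2 (e.g. 0.277/0.01 = 27.7); wall-clock timing is deliberately
out of scope as hardware-dependent.

## What the synthetic drive does and does not emulate

The feedforward generator produces independent homogeneous Poisson trains
per neuron at a common rate — the stationary, uncorrelated drive regime.
It does not emulate rate modulation, input correlations shared across
neurons, or inhibitory feedforward input (F_I = 0). Passing tests therefore
demonstrate numerical correctness and the stiff/non-stiff adaptivity under
stationary asynchronous drive; they do not probe strongly synchronized or
non-stationary input regimes.

## Known limitations

* With AETD2, each neuron's *first* action potential is integrated entirely
  by the RK2 branch (no spike history → non-stiff), so at the largest steps
  (Δt ≈ 0.277 ms) initial conditions far from rest — e.g. a large initial
  voltage jitter — can destabilize the first few milliseconds. The default
  rest-state initialization is unaffected.
* Coarse-step rate errors are sensitive to protocol details that published
  tables rarely pin down (initial conditions, input realization, transient
  handling): with this package's protocol the converged reference-network
  rate is ≈ 13.9 Hz and AETD2 at Δt = 0.277 ms deviates by ≈ 1.7–2.2 %
  across seeds (computed, not assumed — see the acceptance tests).
* No synaptic delays, conduction latencies, or plasticity; single-process
  execution only. The per-neuron stepping is embarrassingly parallel, but
  parallelization is out of scope.
* At most one threshold crossing per neuron per step is assumed, justified
  for Δt ≤ 0.277 ms ≪ the effective refractory period.
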