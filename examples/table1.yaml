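# Reference all-to-all network: 80 excitatory / 20 inhibitory HH neurons,
# Poisson drive f=0.06 mS/cm^2 at 300 Hz, coupling S=0.2 mS/cm^2.
n: 100
n_exc: 80
n_inh: 20
topology: all-to-all
S: 0.2
f: 0.06
nu_hz: 300.0
dt: 0.01
T: 10000.0
method: rk2
seed: 1
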