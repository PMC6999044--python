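"""Measure the effective refractory period with the paired-EPSC protocol.

A first EPSC always evokes a spike; a second EPSC follows at increasing lags
after the spike peak.  The effective refractory period is the smallest lag at
which the second EPSC drives the voltage back above the +20 mV transmitter
release threshold.  Dropping the steady-state outward current and the
synaptic reflux shortens the period from ~20 ms to a few ms, showing that
those two mechanisms, not the spike currents, protect the bidirectionally
coupled nerve net from re-excitation.
"""

import moonjelly as mj

p = mj.NeuronParams()
s = mj.SynapseParams()

full = mj.measure_refractory(p, s)
print(f"full model                      : {full.period:5.1f} ms")

no_ss = mj.measure_refractory(p.without("steady_state"), s)
print(f"without steady-state current    : {no_ss.period:5.1f} ms")

deficient = mj.measure_refractory(p.without("steady_state", "reflux"), s)
print(f"without steady-state and reflux : {deficient.period:5.1f} ms")

probe = mj.measure_refractory(p, s, lags=[7.0, 25.0])
print(f"max post-spike V at 7 ms lag    : {probe.max_post_spike_v[0]:5.1f} mV"
      " (bump only)")
print(f"max post-spike V at 25 ms lag   : {probe.max_post_spike_v[1]:5.1f} mV"
      " (second spike)")
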