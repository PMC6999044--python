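"""Evoke one action potential with a single EPSC and decompose the currents.

A resting model neuron receives one synaptic EPSC at t = 0.  The script
prints the resting potential, the spike time (+20 mV crossing), the time and
height of the voltage peak, and the peak contribution of each transmembrane
current.  The AP should peak roughly 2.5 ms after the EPSC onset.
"""

import numpy as np

import moonjelly as mj

p = mj.NeuronParams()
s = mj.SynapseParams()

v_rest, _ = mj.resting_state(p)
trace, spikes = mj.integrate_neuron(None, [0.0], p, s, T=60.0)

i_peak = int(np.argmax(trace.v))
print(f"resting potential      : {v_rest:8.2f} mV")
print(f"spike (threshold) time : {spikes[0]:8.2f} ms")
print(f"AP peak                : {trace.v[i_peak]:8.2f} mV "
      f"at t = {trace.t[i_peak]:.2f} ms")
print(f"inflection (take-off)  : "
      f"{mj.neuron.ap_inflection_voltage(trace):8.2f} mV")
print("peak current magnitudes (pA):")
for name, cur in trace.currents.items():
    print(f"  {name:5s}: {np.abs(cur).max():9.1f}")
# The inward current (II) dominates the upstroke; the fast transient outward
# current (IFT) repolarizes; the reflux EPSC holds V near zero afterwards.
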