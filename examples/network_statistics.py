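"""Build motor nerve nets and compare their synaptic density to measurement.

The anatomical anchor is a mean spacing of ~70 um between neighboring
synapses along a neurite (~70 synapses on a 5 mm neuron).  Networks whose
neurite orientations follow the position-dependent von Mises law are more
sparsely connected than uniformly oriented ones at the same size, so they
need more neurons to reach the measured density.
"""

import numpy as np

import moonjelly as mj

for orientation, n in (("von_mises", 8000), ("uniform", 5000)):
    isd, spn = [], []
    for seed in range(3):
        net = mj.build_mnn(n, orientation=orientation, seed=seed)
        isd.append(mj.mean_intersynaptic_distance(net))
        spn.append(mj.mean_synapses_per_neuron(net))
    print(f"{orientation:10s} n={n}: "
          f"intersynaptic distance {np.mean(isd):5.1f} um, "
          f"synapses/neuron {np.mean(spn):5.1f}")

net = mj.build_mnn(2000, seed=0)
print(f"\ndelays of a 2000-neuron net: "
      f"{net.syn_delay.min():.2f} - {net.syn_delay.max():.2f} ms "
      "(printed range: 0.5 - 1.5 ms)")
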