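# moonjelly

Neuromuscular simulation of the moon jelly *Aurelia aurita*, from ion
channels to muscle forces.  The package is aimed at computational
neuroscientists and biomechanicists studying how the radially symmetric,
decentralized nervous system of a scyphozoan jellyfish produces and steers
its swimming stroke.

It provides, as one consistent model chain:

- a **Hodgkin-Huxley-type neuron** fitted to scyphozoan voltage-clamp data —
  a transient inward current and fast/slow transient plus steady-state
  outward currents,

  `Cm dV/dt = Isyn − II − IFT − IST − ISS − IL`,

  with logistic gate steady states, Gaussian voltage-dependent gate time
  constants, and a rectifying double-exponential EPSC with presynaptic
  **transmitter reflux** (the synapses are anatomically symmetric);
- **geometric nerve nets**: the motor nerve net (MNN, 5 mm bipolar neurites)
  and diffuse nerve net (DNN, 2 mm) built as random line segments on the
  subumbrellar disc, synapses at segment intersections, transmission delay
  `ρ = 0.5 ms + 2 ms/cm · (dist(A,x) + dist(B,x))`, and neurite orientations
  drawn from the position-dependent von Mises law
  `f(φ|d,α) ∝ exp[8(d−0.5) cos(φ−3α)]`;
- **activation-wave simulation** of whole nets with full membrane dynamics
  and per-pair delays, plus straight-line **cutting experiments**;
- the **three-state automaton** (resting/firing/refractory) whose fire-once
  theorem — every vertex of a connected graph fires exactly once per wave —
  serves as a combinatorial oracle for the network simulator;
- **swim muscles**: twitch kernel `a(t) = t^m e^{−kt}`, Gaussian
  force-length relation `F_I(L) = F_O exp[−((L/L_O−1)/S)²]`, 64 circular + 8
  radial muscle units with post-hoc normalization to 0.4 N / 0.8 N;
- the **elastic 2D bell cross-section** (two-exponent outline family, damped
  springs, muscle attachments) exported as plain-text `.vertex`/`.spring`
  files for an external immersed-boundary fluid solver.  Solving the fluid
  equations themselves is out of scope.

## Worked example

```python
import moonjelly as mj

net = mj.build_mnn(3000, seed=0)                  # von Mises MNN, 4 cm bell
record = mj.run_network(net, mj.StimulusProtocol.single(net.pacemakers[0]),
                        T=400.0)
print(record.counts.max(), record.counts.min())   # 1 1  -> fires exactly once
print(mj.conduction_delay(record, net, initiator=0))   # 38.2 ms
report = mj.oracle_compare(net, record, initial_firing=[int(net.pacemakers[0])])
print(report["counts_match"], round(report["spearman_rho"], 3))  # True 0.992
```

Firing one rhopalial pacemaker launches a wave that covers the whole net,
every neuron spiking exactly once (the automaton oracle confirms the counts,
and spike order tracks BFS distance).  The wave needs 38 ms to reach the
opposing pacemaker at this size; at the estimated natural size of ~10,000
neurons the delay drops to ~29 ms.  The `examples/` directory holds one
short script per capability (single-neuron AP, refractory period, network
statistics, waves, cuts, muscle forces, bell export); each prints the
numbers it computes and what they mean.

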