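# Methods

This note documents the model, the numerical choices and the limits of what
the tests show.  Units throughout the membrane model: mV, ms, pF, nS, pA
(then `nS·mV = pA` and `pA/pF = mV/ms`, so the voltage equation is
dimensionally closed).  Nerve-net geometry is in cm and ms; the bell mesh is
in meters.

## Membrane model

The neuron is a single compartment with five currents: a transient inward
current `II` (activation gate a, inactivation gate b), fast and slow
transient outward currents `IFT` (c, d) and `IST` (e, f), a steady-state
outward current `ISS` (g) and an ohmic leak.  Each gate follows
`dG/dt = (G∞(V) − G)/τ(V)` with a logistic `G∞` (negative slope factor =
inactivation) and a Gaussian-bell `τ(V) = C_base + C_amp·exp(−(V_max−V)²/σ²)`.
The default constants are the fitted values for scyphozoan motor-nerve-net
neurons (`NeuronParams()`); the leak conductance of 953 pS is stored as
0.953 nS.  The free neuron's rest sits at −70.76 mV (the −70 mV leak
reversal minus the small standing steady-state current), found by root
solving the stationary current balance.

The EPSC kernel is `g_syn (1−e^{−t/τ_rise})(a e^{−t/τ_fast} +
(1−a) e^{−t/τ_slow}) · max(E_syn − V, 0)`: the max implements the observed
rectification (no reversed synaptic current above +4.32 mV).  The printed
rise constant (20 ms) is long relative to the decay constants; it is used as
printed and can be overridden in `SynapseParams`.  Transmitter release is
triggered when V crosses +20 mV from below; that crossing is the operational
spike definition everywhere in the package.  Because the synapses are
morphologically symmetric, every release also delivers an EPSC back to the
releasing neuron (reflux); in a network the reflux returns after the base
synaptic delay plus the round trip soma→synapse→soma at 2 ms/cm — the round
trip is our choice of the minimal rule consistent with the delay model, and
is configurable.  For a lone neuron the reflux arrives after the base delay
(synapse at the soma).

Deficient-model switches (`NeuronParams.without(...)`) disable the
steady-state current, the reflux or the rectifier for mechanism-attribution
experiments: without steady-state current and reflux the effective
refractory period collapses from ~20 ms to ~6 ms; without the rectifier the
spike amplitude drops (the synapse then pulls V toward +4.32 mV).

**Protocol conventions.** The paired-EPSC refractory protocol delivers the
second EPSC at a given lag after the *peak* of the first spike and reads the
maximum voltage after the first spike ends (first downward 0 mV crossing);
the period is the first lag on a 1–40 ms, 0.5 ms grid whose response crosses
+20 mV.  The AP *inflection point* is the upstroke take-off — the point of
maximal voltage acceleration between EPSC onset and peak, where the fast
transient currents take over from the synaptic drive.  In this model it sits
at +6.7 mV, just above the synaptic reversal where the rectifier hands the
upstroke to the inward current.  (The maximum-slope point, by contrast, lies
at +20 mV inside the regenerative phase.)

## Integration

All neurons advance on a shared fixed-step grid with classical RK4,
`dt = 0.01 ms` by default; halving dt moves the AP peak time by far less
than 1% (tested).  Gate curves (`G∞`, `τ`) and gate powers `G^p` are
tabulated on dense grids (0.01 mV in V over ±150 mV; 4096 points in G) and
linearly interpolated inside the compiled kernel; interpolation error is
~1e−8 and is covered by the convergence test.  Gates are clamped to [0, 1]
after each step.  Threshold crossings are located by linear interpolation
within the step.

The total synaptic drive is carried by four exponential accumulators (the
EPSC kernel is a sum of four exponentials), which decay analytically between
steps; an onset increments all four by 1, which is exact for onsets snapped
to the grid (snapping error ≤ dt = 0.01 ms, far below the 0.5 ms minimum
delay).  Scheduled onsets live in a ring buffer of per-step counts.  Neurons
at rest with no pending input are skipped; a neuron rejoins the rest pool
when its voltage is within 1e−3 mV of rest, its gates within 1e−5 of their
resting values, and its synaptic drive below 1e−6 (residual current
< 0.01 pA).  A run may stop early when no input is pending and all neurons
are at rest, or — for delay measurements — once every neuron has spiked.
Non-finite states abort with the offending time; any neuron reaching three
spikes aborts with a diagnostic, since through-conduction theory forbids it.

## Nerve-net geometry

Neurons are straight neurite segments with the soma at the midpoint: MNN
5 mm, DNN 2 mm.  Somata are uniform **in area** on the annulus (inner
0.5 cm, outer 2 cm on the 4 cm bell; the DNN extends 0.25 cm further into
the margin).  For other bell diameters all radii scale proportionally — the
simplest consistent choice.  Eight pacemaker neurons sit at 45° spacing on
the outer annulus edge, radially oriented, and are ordinary model neurons
stimulated by one standard EPSC to emulate rhopalial firing.

Orientations: `von_mises` draws φ from concentration κ = 8(d − 0.5) and mean
3α, exactly as printed, with α the polar angle from the center→rhopalium-0
line (a global convention; negative κ at d < 0.5 is realized as the
equivalent distribution with mean shifted by π).  `uniform` draws on the
circle.  The DNN's `radial_bias` mode has no printed distribution; we use a
von Mises about the radial direction with κ = 2 (configurable) — enough to
reproduce the qualitative slowing of conduction.

Synapses are the pairwise segment intersections (at most one per pair;
parallel and collinear-overlap pairs yield none, endpoint contact counts).
Candidates come from a uniform spatial hash with cell = neurite length, so a
bounding box spans ≤ 2×2 cells; an O(n²) brute-force path is kept as the
reference and tested for equality.  The delay is 0.5 ms + 2 ms/cm times the
two soma-to-synapse distances, hence within [0.5, 1.5] ms for the MNN and
[0.5, 0.9] ms for the DNN.

**Intersynaptic spacing.** `mean_intersynaptic_distance` sorts each neuron's
synapses along its segment and by default returns the pooled mean of all
consecutive gaps — the direct analogue of measuring distances between
neighboring synapses along neurites.  A per-neuron variant (average the gaps
within each neuron first) is available; it up-weights sparsely innervated
edge neurons and reads ~10% higher on the same nets.  With the pooled
estimator the von Mises net crosses the measured 70 µm at ≈ 7700 neurons;
the uniform net needs ≈ 5600 (edge effects depress crossing counts ~8%
below the bulk Poisson-line estimate, so the uniform net at 5000 neurons
reads ~78 µm rather than 70 µm).

**Cuts** are straight segments; a severed neurite keeps the soma-bearing
part, and synapses on dead parts disappear for both partners while surviving
delays are unchanged.  The shipped layouts (octagon with a configurable gap;
16 interdigitating radial cuts) parameterize the classical experiments —
only drawings of them exist, so radii and gap width are configuration
values.

## Waves, oracle, muscles, bell

A network run integrates every neuron; a spike schedules one EPSC at every
synaptic partner after the pair delay, plus the reflux.  The conduction
delay is the spike-time difference between the initiating and the
diametrically opposing pacemaker.  At 10,000 von Mises neurons on the 4 cm
bell the mean over 10 realizations is ≈ 29 ms, at the lower edge of the
reference ~35 ms; the delay decreases with neuron count and grows with bell
size, as expected from better-approximated shortest paths and EPSC
summation.

The three-state automaton (synchronous updates; refractory lasts one step by
default, configurable) provides the fire-once oracle: exhaustive enumeration
over all connected graphs with ≤ 7 vertices checks that every vertex fires
exactly once at its BFS distance, and `oracle_compare` checks any network
run's spike counts against it.

Muscle twitches use the millisecond time base, so k = 2.15e−2 /ms puts the
twitch peak at m/k = 50 ms, within reported jellyfish twitch durations.  The
64 circular units tile 8 octants (centered on the rhopalia) × 8 equal-width
radial bands over the MNN annulus — the drawing gives no band radii, so
equal widths spanning the annulus are used and configurable.  Radial units
occupy the margin band.  A neuron innervates the unit containing its soma.
Normalization happens after the run, per muscle kind, so relative strengths
are independent of neuron count and conduction speed.  A fixed-length mode
(L ≡ L_O) makes the module testable without a fluid solver; a length time
series can be supplied for coupled use.  Force-velocity dependence is
deliberately absent.

The bell outline uses the printed two-exponent angle family; the height
profile `h(i) = C_base(N_p − i) + C_amp·exp(+i²/σ²)` is implemented as
printed with σ = 3000 treated as dimensionless width (switches expose the
exponent sign and a σ²-convention).  As printed, h(0) = 118 mm with the
default constants — far taller than the drawn bell; since no corrected
formula is printable, the discrepancy is documented rather than silently
fixed.  Surface springs (2e7 N/m) run along each surface, internal springs
(8e7 N/m) connect subumbrellar to exumbrellar vertices, damping is
2.5 kg/s.  Circular-muscle forces act from interior subumbrellar vertices
toward the center line (the margin and bell center carry none; the index
bounds are configuration values); radial muscles act between neighboring
margin vertices.  The export writes plain-text `.vertex`/`.spring` files
(1-based indices) with a YAML manifest carrying the fluid parameters
(µ = 0.005 Ns/m², ρ = 1000 kg/m², 180×240 grid, dt = 1e−5 s); the fluid
solve itself, and therefore all swimming and turning kinematics, is out of
scope.

## What the synthetic networks do and do not capture

The generators reproduce the documented geometry: neurite lengths, annulus
radii, soma density, orientation law, synaptic delay range and density.
They deliberately omit known biological complexity: multipolar neurons,
distributed neurite lengths, multiple synapses per pair, the exumbrellar/
manubrium/tentacle extensions of the DNN, the marginal "pseudo-nerve ring",
and any pacemaker rhythm or sensory resetting (stimulation times are user
inputs).  Passing tests therefore show that the idealized geometry and
membrane model jointly reproduce the measured density, delay and
through-conduction behavior — not that these simplifications are harmless
for other quantities.

## Problem sizes and runtimes

Tests run single-neuron protocols at full resolution and network experiments
at 1500–2000 neurons (plus one 10-seed set at 10,000 for the conduction
delay); the acceptance script uses 10 realizations per stochastic quantity,
size sweeps of 4500–9000 neurons for the density crossings, and 10 × 10,000
neurons for the conduction delay.  The whole suite takes ~10 minutes and the
acceptance script ~5 minutes on one core.

## Interface choices

The package is a library: the importable API plus `examples/` scripts are
the user interface, and network/spike/force/structure data round-trip
through CSV, HDF5 and YAML.  No shell command is shipped — every documented
operation is a one-liner from Python, and the examples are the runnable
entry points.
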