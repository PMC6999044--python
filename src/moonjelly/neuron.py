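"""Conductance-based model of a scyphozoan motor-nerve-net neuron.

The membrane carries a fast transient inward current, fast and slow transient
outward currents, a steady-state outward current and a passive leak:

    Cm dV/dt = Isyn - II - IFT - IST - ISS - IL

Each voltage-gated current opens according to Hodgkin-Huxley style gating
variables with logistic steady-state curves and Gaussian voltage-dependent
time constants.  Chemical synapses are symmetric (bidirectional): transmitter
release is triggered when the presynaptic voltage crosses +20 mV from below,
and it feeds an EPSC both to the postsynaptic neuron and back to the
presynaptic one ("transmitter reflux").  The EPSC rectifies: above its
reversal potential the synaptic current stays zero instead of reversing.

Units used throughout: mV, ms, pF, nS, pA (so nS * mV = pA and
pA / pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from . import _engine
from .errors import IntegrationError, ProtocolError, RunawayActivityError

GATE_NAMES = ("a", "b", "c", "d", "e", "f", "g")

#: transmitter-release threshold (mV); a spike is an upward crossing of this
SPIKE_THRESHOLD_MV = 20.0


@dataclass
class GateParams:
    """Parameters of one gating variable.

    ``p`` is the exponent applied to the gate in the current equation,
    ``v_half``/``rho`` the midpoint and slope of the logistic steady-state
    curve (a negative ``rho`` makes the gate an inactivation gate), and the
    time constant is ``c_base + c_amp * exp(-(v_max - V)^2 / sigma^2)``.
    """

    p: float
    v_half: float  # mV
    rho: float     # mV
    c_base: float  # ms
    c_amp: float   # ms
    v_max: float   # mV
    sigma: float   # mV

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError("gate exponent p must be > 0")
        if self.c_base <= 0:
            raise ValueError("c_base must be > 0")
        if self.c_amp < 0:
            raise ValueError("c_amp must be >= 0")
        if self.sigma == 0:
            raise ValueError("sigma must be nonzero")


def _default_gates() -> dict[str, GateParams]:
    p = (1.77, 4.82, 8.64, 2.51, 3.85, 1.15, 1.0)
    v_half = (-2.02, -10.94, 2.4, 2.21e-2, 10.65, -10.01, 48.58)
    rho = (3.99, -13.03, 22.55, -8.97, 26.43, -4.57, 22.41)
    c_base = (5.2e-1, 1.3, 1.65e-1, 2.73, 1.13, 7.66, 10.43)
    c_amp = (4.66e-1, 2.42e-1, 7.51, 10.0, 16.64, 2.0, 4.96)
    v_max = (-5.87e-1, 2.68e-1, -35.22, -29.96, -12.71, -34.0, -39.93)
    sigma = (1.0, 6.62, 23.12, 15.13, 43.6, 20.0, 29.88)
    return {
        name: GateParams(p[k], v_half[k], rho[k], c_base[k], c_amp[k],
                         v_max[k], sigma[k])
        for k, name in enumerate(GATE_NAMES)
    }


@dataclass
class NeuronParams:
    """Membrane parameters fitted to scyphozoan voltage-clamp recordings.

    Conductances in nS (the leak of 953 pS is stored as 0.953 nS), reversal
    potentials in mV, capacitance in pF.  The three boolean switches disable
    individual mechanisms for "deficient-model" experiments: the steady-state
    outward current, the synaptic transmitter reflux, and the synaptic
    rectifier.
    """

    cm: float = 1.0       # pF
    g_i: float = 345.0    # nS, transient inward
    g_ft: float = 39.8    # nS, fast transient outward
    g_st: float = 27.2    # nS, slow transient outward
    g_ss: float = 10.8    # nS, steady-state outward
    g_l: float = 0.953    # nS (= 953 pS), leak
    e_i: float = 76.7     # mV
    e_o: float = -84.6    # mV
    e_l: float = -70.0    # mV
    gates: dict[str, GateParams] = field(default_factory=_default_gates)
    use_steady_state: bool = True
    use_reflux: bool = True
    use_rectifier: bool = True

    def __post_init__(self):
        for name, g in (("g_i", self.g_i), ("g_ft", self.g_ft),
                        ("g_st", self.g_st), ("g_ss", self.g_ss),
                        ("g_l", self.g_l)):
            if g < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.cm <= 0:
            raise ValueError("membrane capacitance must be > 0")
        missing = set(GATE_NAMES) - set(self.gates)
        if missing:
            raise ValueError(f"missing gate parameters: {sorted(missing)}")

    def without(self, *mechanisms: str) -> "NeuronParams":
        """Copy with mechanisms disabled: 'steady_state', 'reflux', 'rectifier'."""
        kw = {}
        for m in mechanisms:
            if m not in ("steady_state", "reflux", "rectifier"):
                raise ValueError(f"unknown mechanism {m!r}")
            kw[f"use_{m}"] = False
        return replace(self, **kw)


@dataclass
class SynapseParams:
    """Synaptic EPSC kernel, rectification and delay parameters.

    The kernel rises with ``tau_rise`` and decays as a double exponential
    with fast fraction ``fast_fraction``.  The transmission delay between two
    somata is ``base_delay + delay_per_cm * (soma-to-synapse distances)``.
    """

    g_syn: float = 75.0          # nS
    tau_rise: float = 20.0       # ms
    tau_fast: float = 3.0        # ms
    tau_slow: float = 6.0        # ms
    fast_fraction: float = 9.57e-1
    e_syn: float = 4.32          # mV
    threshold: float = SPIKE_THRESHOLD_MV  # mV, transmitter release
    base_delay: float = 0.5      # ms
    delay_per_cm: float = 2.0    # ms/cm travel cost along neurites

    def __post_init__(self):
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must be in [0, 1]")
        for name, tau in (("tau_rise", self.tau_rise),
                          ("tau_fast", self.tau_fast),
                          ("tau_slow", self.tau_slow)):
            if tau <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NeuronState:
    """Instantaneous state: voltage, seven gates, pending EPSC onsets (ms)."""

    v: float
    gates: np.ndarray  # shape (7,), values in [0, 1]
    pending_epsc_onsets: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.gates = np.clip(np.asarray(self.gates, dtype=float), 0.0, 1.0)
        if self.gates.shape != (7,):
            raise ValueError("gates must have shape (7,)")


@dataclass
class VoltageTrace:
    """Uniformly sampled voltage trace with optional current decomposition.

    ``currents`` maps 'II', 'IFT', 'IST', 'ISS', 'IL', 'Isyn' to pA arrays.
    """

    t: np.ndarray
    v: np.ndarray
    currents: dict[str, np.ndarray] | None = None
    gates: np.ndarray | None = None  # (n_samples, 7)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self):
        import pandas as pd

        data = {"time_ms": self.t, "v_mV": self.v}
        if self.currents is not None:
            for k, arr in self.currents.items():
                data[f"{k}_pA"] = arr
        return pd.DataFrame(data)

    def save_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def save_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.t)
            f.create_dataset("v_mV", data=self.v)
            if self.currents is not None:
                grp = f.create_group("currents_pA")
                for k, arr in self.currents.items():
                    grp.create_dataset(k, data=arr)


# ---------------------------------------------------------------------------
# elementary voltage dependences


def gate_steady_state(v, g: GateParams):
    """Logistic steady-state open probability of a gate at voltage ``v``."""
    return 1.0 / (1.0 + np.exp((g.v_half - np.asarray(v, dtype=float)) / g.rho))


def gate_time_constant(v, g: GateParams):
    """Gaussian-bell time constant (ms) of a gate at voltage ``v``."""
    v = np.asarray(v, dtype=float)
    return g.c_base + g.c_amp * np.exp(-((g.v_max - v) ** 2) / g.sigma**2)


def membrane_currents(state: NeuronState, p: NeuronParams):
    """The five transmembrane currents (II, IFT, IST, ISS, IL) in pA."""
    v = state.v
    G = state.gates
    gp = [p.gates[name] for name in GATE_NAMES]
    ii = p.g_i * G[0] ** gp[0].p * G[1] ** gp[1].p * (v - p.e_i)
    ift = p.g_ft * G[2] ** gp[2].p * G[3] ** gp[3].p * (v - p.e_o)
    ist = p.g_st * G[4] ** gp[4].p * G[5] ** gp[5].p * (v - p.e_o)
    g_ss = p.g_ss if p.use_steady_state else 0.0
    iss = g_ss * G[6] ** gp[6].p * (v - p.e_o)
    il = p.g_l * (v - p.e_l)
    return ii, ift, ist, iss, il


def epsc_current(t_since_onset, v, s: SynapseParams, rectify: bool = True):
    """Synaptic current (pA) of a single EPSC, ``t_since_onset`` ms after onset.

    Zero before onset (Heaviside); with the rectifier enabled the current is
    zero at voltages above the reversal potential instead of reversing.
    """
    t = np.asarray(t_since_onset, dtype=float)
    kern = np.where(
        t > 0,
        (1.0 - np.exp(-t / s.tau_rise))
        * (s.fast_fraction * np.exp(-t / s.tau_fast)
           + (1.0 - s.fast_fraction) * np.exp(-t / s.tau_slow)),
        0.0,
    )
    drive = s.e_syn - np.asarray(v, dtype=float)
    if rectify:
        drive = np.maximum(drive, 0.0)
    return s.g_syn * kern * drive


# ---------------------------------------------------------------------------
# engine plumbing


def _gate_list(p: NeuronParams) -> list[GateParams]:
    return [p.gates[name] for name in GATE_NAMES]


def build_gate_tables(p: NeuronParams):
    """Tabulate steady states, time constants and gate powers for the kernel."""
    vg = np.linspace(_engine.V_GRID_LO, _engine.V_GRID_HI, _engine.V_GRID_N)
    xg = np.linspace(0.0, 1.0, _engine.POW_GRID_N)
    ginf = np.empty((7, vg.size))
    tau = np.empty((7, vg.size))
    pw = np.empty((7, xg.size))
    for k, g in enumerate(_gate_list(p)):
        ginf[k] = gate_steady_state(vg, g)
        tau[k] = gate_time_constant(vg, g)
        pw[k] = xg**g.p
    return ginf, tau, pw


def pack_scalars(p: NeuronParams, s: SynapseParams) -> np.ndarray:
    sc = np.zeros(_engine.N_SC)
    sc[_engine.SC_CM] = p.cm
    sc[_engine.SC_GI] = p.g_i
    sc[_engine.SC_GFT] = p.g_ft
    sc[_engine.SC_GST] = p.g_st
    sc[_engine.SC_GSS] = p.g_ss if p.use_steady_state else 0.0
    sc[_engine.SC_GL] = p.g_l
    sc[_engine.SC_EI] = p.e_i
    sc[_engine.SC_EO] = p.e_o
    sc[_engine.SC_EL] = p.e_l
    sc[_engine.SC_GSYN] = s.g_syn
    sc[_engine.SC_AFRAC] = s.fast_fraction
    sc[_engine.SC_ESYN] = s.e_syn
    sc[_engine.SC_RECT] = 1.0 if p.use_rectifier else 0.0
    sc[_engine.SC_THRESH] = s.threshold
    return sc


def syn_decay_rates(s: SynapseParams) -> np.ndarray:
    """Decay rates (1/ms) of the four exponentials spanning the EPSC kernel."""
    return np.array([
        1.0 / s.tau_fast,
        1.0 / s.tau_slow,
        1.0 / s.tau_rise + 1.0 / s.tau_fast,
        1.0 / s.tau_rise + 1.0 / s.tau_slow,
    ])


def resting_state(p: NeuronParams) -> tuple[float, np.ndarray]:
    """Resting potential (mV) and steady-state gate vector of the free neuron."""

    def total_current(v):
        gates = np.array([gate_steady_state(v, g) for g in _gate_list(p)])
        return sum(membrane_currents(NeuronState(v, gates), p))

    v_rest = brentq(total_current, -110.0, -40.0, xtol=1e-10)
    g_rest = np.array([gate_steady_state(v_rest, g) for g in _gate_list(p)])
    return float(v_rest), g_rest


def _simulate(n, p, s, *, T, dt, stim, initial_v=None, initial_g=None,
              syn_csr=None, refl_csr=None, record=False, stop_mode=0,
              runaway_limit=1000):
    """Low-level wrapper around the compiled stepping kernel.

    ``stim`` is a sequence of (neuron index, onset time ms).  ``syn_csr`` is
    (offsets, neighbors, delays) over directed edges; ``refl_csr`` is
    (offsets, delays) of per-neuron reflux delays.  Returns a dict with spike
    times/counts, the recording array and stopping metadata.
    """
    v_rest, g_rest = resting_state(p)
    V = np.full(n, v_rest if initial_v is None else 0.0)
    if initial_v is not None:
        V[:] = initial_v
    G = np.tile(g_rest, (n, 1))
    if initial_g is not None:
        G[:] = initial_g
    X = np.zeros((n, 4))
    active = ((np.abs(V - v_rest) > 1e-9)
              | (np.abs(G - g_rest).max(axis=1) > 1e-9)).astype(np.uint8)

    if syn_csr is None:
        syn_off = np.zeros(n + 1, dtype=np.int64)
        syn_nbr = np.zeros(0, dtype=np.int64)
        syn_delay = np.zeros(0)
    else:
        syn_off, syn_nbr, syn_delay = syn_csr
    if refl_csr is None or not p.use_reflux:
        refl_off = np.zeros(n + 1, dtype=np.int64)
        refl_delay = np.zeros(0)
    else:
        refl_off, refl_delay = refl_csr

    n_steps = int(round(T / dt))
    stim = sorted(stim, key=lambda x: x[1])
    stim_step = np.array([int(round(t / dt)) for _, t in stim], dtype=np.int64)
    stim_neuron = np.array([i for i, _ in stim], dtype=np.int64)
    if stim_step.size and (stim_step.min() < 0 or stim_step.max() >= n_steps):
        raise ValueError("stimulus onset outside the simulation horizon")

    max_delay = 0.0
    if syn_delay.size:
        max_delay = float(syn_delay.max())
    if refl_delay.size:
        max_delay = max(max_delay, float(refl_delay.max()))
    ring_len = max(int(np.ceil(max_delay / dt)) + 4, 8)
    ring = np.zeros((ring_len, n))

    cap = min(max(runaway_limit, 5), 16)
    spike_t = np.full((n, cap), np.nan)
    spike_n = np.zeros(n, dtype=np.int64)
    if record:
        rec = np.zeros((n_steps + 1, n, 12))
    else:
        rec = np.zeros((1, 1, 12))

    ginf_tab, tau_tab, pow_tab = build_gate_tables(p)
    sc = pack_scalars(p, s)
    lam = syn_decay_rates(s)
    out = np.zeros(4)

    _engine.run_core(V, G, X, active, sc, ginf_tab, tau_tab, pow_tab, lam,
                     syn_off, syn_nbr, syn_delay, refl_off, refl_delay,
                     stim_step, stim_neuron, n_steps, dt, ring,
                     spike_t, spike_n, rec, record,
                     v_rest, g_rest, stop_mode, runaway_limit, out)

    status, t_end, steps_done = int(out[0]), float(out[1]), int(out[2])
    if status == _engine.STATUS_NONFINITE:
        raise IntegrationError(t_end)
    if status == _engine.STATUS_RUNAWAY:
        raise RunawayActivityError(int(out[3]), t_end)
    return {
        "spike_t": spike_t,
        "spike_n": spike_n,
        "rec": rec[: steps_done + 1] if record else None,
        "status": status,
        "t_end": t_end,
        "steps_done": steps_done,
        "v_rest": v_rest,
        "g_rest": g_rest,
        "V": V,
        "dt": dt,
    }


def _decompose_currents(rec, p: NeuronParams, s: SynapseParams):
    """Per-current traces (pA) from a recorded (steps, 1, 12) state array."""
    v = rec[:, 0, 0]
    G = rec[:, 0, 1:8]
    X = rec[:, 0, 8:12]
    gp = _gate_list(p)
    ii = p.g_i * G[:, 0] ** gp[0].p * G[:, 1] ** gp[1].p * (v - p.e_i)
    ift = p.g_ft * G[:, 2] ** gp[2].p * G[:, 3] ** gp[3].p * (v - p.e_o)
    ist = p.g_st * G[:, 4] ** gp[4].p * G[:, 5] ** gp[5].p * (v - p.e_o)
    g_ss = p.g_ss if p.use_steady_state else 0.0
    iss = g_ss * G[:, 6] ** gp[6].p * (v - p.e_o)
    il = p.g_l * (v - p.e_l)
    a = s.fast_fraction
    ks = a * X[:, 0] + (1 - a) * X[:, 1] - a * X[:, 2] - (1 - a) * X[:, 3]
    drive = s.e_syn - v
    if p.use_rectifier:
        drive = np.maximum(drive, 0.0)
    isyn = s.g_syn * ks * drive
    return {"II": ii, "IFT": ift, "IST": ist, "ISS": iss, "IL": il,
            "Isyn": isyn}


# ---------------------------------------------------------------------------
# protocols


def integrate_neuron(initial: NeuronState | None, epsc_onsets: Sequence[float],
                     p: NeuronParams, s: SynapseParams, T: float,
                     dt: float = 0.01, reflux_delay: float | None = None,
                     record_currents: bool = True,
                     ) -> tuple[VoltageTrace, np.ndarray]:
    """Integrate a single neuron receiving EPSCs at the given onset times.

    Spike times are the upward crossings of the transmitter-release threshold
    (+20 mV), linearly interpolated between grid points.  With reflux enabled
    every spike feeds one EPSC back to the neuron after ``reflux_delay``
    (default: the base synaptic delay, i.e. a synapse at the soma).

    Returns the voltage trace (with per-current decomposition) and the spike
    times.  Raises :class:`IntegrationError` if the state becomes non-finite.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be > 0")
    onsets = [(0, float(t)) for t in epsc_onsets]
    if initial is not None:
        onsets += [(0, float(t)) for t in initial.pending_epsc_onsets]
    if reflux_delay is None:
        reflux_delay = s.base_delay
    refl_csr = (np.array([0, 1], dtype=np.int64), np.array([reflux_delay]))
    res = _simulate(
        1, p, s, T=T, dt=dt, stim=onsets,
        initial_v=None if initial is None else np.array([initial.v]),
        initial_g=None if initial is None else initial.gates[None, :],
        refl_csr=refl_csr, record=True, stop_mode=0,
    )
    rec = res["rec"]
    t = np.arange(rec.shape[0]) * dt
    currents = _decompose_currents(rec, p, s) if record_currents else None
    trace = VoltageTrace(t=t, v=rec[:, 0, 0], currents=currents,
                         gates=rec[:, 0, 1:8])
    n_sp = int(res["spike_n"][0])
    spikes = res["spike_t"][0, :n_sp]
    return trace, spikes


def ap_inflection_voltage(trace: VoltageTrace, onset: float = 0.0) -> float:
    """Voltage (mV) at the inflection point of an action-potential upstroke.

    The upstroke of a synaptically evoked spike has two phases: a synaptic
    depolarization followed by the regenerative rise driven by the fast
    transient currents.  The inflection point is where the trajectory turns
    from the first into the second phase, estimated as the point of maximal
    voltage acceleration (max d2V/dt2) between EPSC onset and the spike peak.
    """
    i0 = int(np.searchsorted(trace.t, onset))
    ipk = i0 + int(np.argmax(trace.v[i0:]))
    d2 = np.gradient(np.gradient(trace.v, trace.t), trace.t)
    iinf = i0 + int(np.argmax(d2[i0:ipk + 1]))
    return float(trace.v[iinf])


@dataclass
class RefractoryResult:
    """Outcome of the paired-EPSC excitability protocol."""

    lags: np.ndarray              # ms between the two EPSC onsets
    max_post_spike_v: np.ndarray  # mV, highest V after the first spike ends
    period: float                 # ms, first lag that elicits a second spike

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"lag_ms": self.lags,
                             "max_post_spike_v_mV": self.max_post_spike_v})


def measure_refractory(p: NeuronParams, s: SynapseParams,
                       lags: Sequence[float] | None = None,
                       dt: float = 0.01, settle: float = 60.0,
                       ) -> RefractoryResult:
    """Effective refractory period from a two-EPSC protocol.

    One suprathreshold EPSC is delivered at t = 0; it always evokes a spike.
    A second EPSC is delivered ``lag`` ms after the *peak* of that first
    spike, for each lag on the grid (default 1-40 ms in 0.5 ms steps).  For
    each lag the maximum voltage reached after the end of the first spike
    (the first downward 0 mV crossing) is recorded; the effective refractory
    period is the smallest lag at which that maximum crosses the +20 mV
    transmission threshold.
    """
    if lags is None:
        lags = np.arange(1.0, 40.0 + 1e-9, 0.5)
    lags = np.asarray(sorted(lags), dtype=float)
    if np.any(lags <= 0):
        raise ValueError("lags must be positive")

    trace0, spikes0 = integrate_neuron(None, [0.0], p, s, T=settle, dt=dt)
    if spikes0.size == 0:
        raise ProtocolError("first EPSC did not elicit a spike")
    t_peak = float(trace0.t[np.argmax(trace0.v)])

    max_post = np.empty(lags.size)
    period = np.nan
    for idx, lag in enumerate(lags):
        trace, spikes = integrate_neuron(None, [0.0, t_peak + lag], p, s,
                                         T=t_peak + lag + settle, dt=dt,
                                         record_currents=False)
        v = trace.v
        # end of the first spike: first downward 0 mV crossing after it
        i_sp = int(np.ceil(spikes[0] / dt))
        after = np.nonzero((v[i_sp:-1] >= 0.0) & (v[i_sp + 1:] < 0.0))[0]
        if after.size == 0:
            raise ProtocolError("first spike never returned below 0 mV")
        i_end = i_sp + int(after[0]) + 1
        max_post[idx] = v[i_end:].max()
        if np.isnan(period) and max_post[idx] >= s.threshold:
            period = float(lag)
    return RefractoryResult(lags=lags, max_post_spike_v=max_post,
                            period=period)


@dataclass
class ClampTrace:
    """Voltage-clamp response: total and per-channel currents (pA)."""

    t: np.ndarray
    v: np.ndarray
    currents: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return (self.currents["II"] + self.currents["IFT"]
                + self.currents["IST"] + self.currents["ISS"]
                + self.currents["IL"])


def simulate_voltage_clamp(v_hold: float, v_step: float, p: NeuronParams,
                           T: float = 50.0, dt: float = 0.01) -> ClampTrace:
    """Step-clamp protocol: gates equilibrated at ``v_hold``, then V is held
    at ``v_step`` for ``T`` ms while the gates relax exponentially (the gate
    equations are linear at fixed voltage, so the update is exact)."""
    gp = _gate_list(p)
    n_steps = int(round(T / dt))
    t = np.arange(n_steps + 1) * dt
    G = np.empty((n_steps + 1, 7))
    G[0] = [gate_steady_state(v_hold, g) for g in gp]
    ginf = np.array([gate_steady_state(v_step, g) for g in gp])
    decay = np.array([np.exp(-dt / gate_time_constant(v_step, g)) for g in gp])
    for k in range(n_steps):
        G[k + 1] = ginf + (G[k] - ginf) * decay
    v = np.full(n_steps + 1, float(v_step))
    ii = p.g_i * G[:, 0] ** gp[0].p * G[:, 1] ** gp[1].p * (v - p.e_i)
    ift = p.g_ft * G[:, 2] ** gp[2].p * G[:, 3] ** gp[3].p * (v - p.e_o)
    ist = p.g_st * G[:, 4] ** gp[4].p * G[:, 5] ** gp[5].p * (v - p.e_o)
    g_ss = p.g_ss if p.use_steady_state else 0.0
    iss = g_ss * G[:, 6] ** gp[6].p * (v - p.e_o)
    il = p.g_l * (v - p.e_l)
    return ClampTrace(t=t, v=v, currents={"II": ii, "IFT": ift, "IST": ist,
                                          "ISS": iss, "IL": il})


# ---------------------------------------------------------------------------
# parameter file round trip


def save_params(path, p: NeuronParams, s: SynapseParams) -> None:
    """Write neuron + synapse parameters to a YAML file (field-for-field)."""
    doc = {
        "neuron": {
            "cm": p.cm, "g_i": p.g_i, "g_ft": p.g_ft, "g_st": p.g_st,
            "g_ss": p.g_ss, "g_l": p.g_l, "e_i": p.e_i, "e_o": p.e_o,
            "e_l": p.e_l,
            "gates": {
                name: {f: getattr(g, f) for f in
                       ("p", "v_half", "rho", "c_base", "c_amp", "v_max",
                        "sigma")}
                for name, g in p.gates.items()
            },
        },
        "synapse": {
            "g_syn": s.g_syn, "tau_rise": s.tau_rise, "tau_fast": s.tau_fast,
            "tau_slow": s.tau_slow, "fast_fraction": s.fast_fraction,
            "e_syn": s.e_syn, "threshold": s.threshold,
            "base_delay": s.base_delay, "delay_per_cm": s.delay_per_cm,
        },
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=True)


def load_params(path) -> tuple[NeuronParams, SynapseParams]:
    """Read parameters written by :func:`save_params`; validates invariants."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    ngates = {name: GateParams(**gd) for name, gd in
              doc["neuron"].pop("gates").items()}
    p = NeuronParams(gates=ngates, **doc["neuron"])
    s = SynapseParams(**doc["synapse"])
    return p, s
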