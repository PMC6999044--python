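"""Activation-wave simulation on a nerve net.

Every neuron in the net is integrated with the full conductance-based
membrane model.  When a neuron crosses the +20 mV transmitter-release
threshold from below, an EPSC onset is scheduled at each synaptic partner
after that synapse's delay, and a reflux EPSC at the neuron itself (the
symmetric synapse releases transmitter toward both sides).  Pacemaker firing
is emulated by delivering a single exogenous EPSC to a pacemaker neuron.

In a connected net this produces a single through-conducted wave in which
every neuron fires exactly once; a built-in detector aborts with a
diagnostic if any neuron spikes three times, which the three-state automaton
model proves impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .errors import PropagationError
from .geometry import CutLine, NerveNet, apply_cut, build_dnn, build_mnn
from .neuron import NeuronParams, SynapseParams, _simulate


@dataclass
class StimulusProtocol:
    """Exogenous EPSC onsets: (neuron index, onset time in ms) pairs."""

    events: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        for i, t in self.events:
            if t < 0:
                raise ValueError("stimulus times must be >= 0")

    @classmethod
    def single(cls, neuron: int, t: float = 0.0) -> "StimulusProtocol":
        return cls([(int(neuron), float(t))])


@dataclass
class SpikeRecord:
    """Spike times of a network run.

    ``times[i, k]`` is the k-th spike of neuron i (NaN-padded), ``counts[i]``
    its total spike count, ``horizon`` the simulated duration (ms).
    """

    times: np.ndarray
    counts: np.ndarray
    horizon: float

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def first(self) -> np.ndarray:
        """First spike time per neuron (NaN where the neuron stayed silent)."""
        return self.times[:, 0]

    def spike_times(self, i: int) -> np.ndarray:
        return self.times[i, : self.counts[i]]

    def to_dataframe(self):
        import pandas as pd

        idx, k = np.nonzero(~np.isnan(self.times))
        return pd.DataFrame({"neuron_id": idx,
                             "spike_time_ms": self.times[idx, k]})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def raster(self, ax=None, **kwargs):
        """Raster plot (neuron index vs spike time)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_dataframe()
        ax.plot(df.spike_time_ms, df.neuron_id, ".", ms=2, **kwargs)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("neuron")
        return ax


def _network_csrs(net: NerveNet, s: SynapseParams):
    """Directed-edge CSR (EPSC targets) and per-neuron reflux-delay CSR.

    The reflux EPSC returns to the presynaptic soma after the base synaptic
    delay plus the round trip soma -> synapse -> soma along its own neurite.
    """
    n = net.n_neurons
    src = np.concatenate([net.syn_i, net.syn_j])
    dst = np.concatenate([net.syn_j, net.syn_i])
    delay = np.concatenate([net.syn_delay, net.syn_delay])
    d_src = np.concatenate([net.syn_d_i, net.syn_d_j])
    order = np.argsort(src, kind="stable")
    src, dst, delay, d_src = src[order], dst[order], delay[order], d_src[order]
    off = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=off[1:])
    refl_delay = s.base_delay + s.delay_per_cm * 2.0 * d_src
    return (off, dst.astype(np.int64), delay), (off.copy(), refl_delay)


def run_network(net: NerveNet, stim: StimulusProtocol, T: float = 200.0,
                dt: float = 0.01, p: NeuronParams | None = None,
                s: SynapseParams | None = None, stop: str = "quiescent",
                runaway_limit: int = 3) -> SpikeRecord:
    """Simulate an activation wave through the net.

    ``stop`` controls early termination: 'quiescent' (default) ends the run
    once no EPSC is pending and all neurons have returned to rest,
    'all_spiked' additionally ends it as soon as every neuron has fired
    (sufficient for conduction-delay measurements), 'none' runs the full
    horizon ``T``.
    """
    if net.n_neurons == 0:
        raise ValueError("empty net")
    if p is None:
        p = NeuronParams()
    if s is None:
        s = SynapseParams()
    if stop not in ("quiescent", "all_spiked", "none"):
        raise ValueError("stop must be 'quiescent', 'all_spiked' or 'none'")
    syn_csr, refl_csr = _network_csrs(net, s)
    res = _simulate(net.n_neurons, p, s, T=T, dt=dt, stim=stim.events,
                    syn_csr=syn_csr, refl_csr=refl_csr,
                    stop_mode=1 if stop == "all_spiked" else 0,
                    runaway_limit=runaway_limit)
    return SpikeRecord(times=res["spike_t"], counts=res["spike_n"],
                       horizon=res["t_end"])


def conduction_delay(record: SpikeRecord, net: NerveNet,
                     initiator: int | None = None) -> float:
    """Spike-time difference (ms) between opposing and initiating pacemakers.

    ``initiator`` is the index *into the pacemaker list*; by default the
    pacemaker that fired first.  Raises :class:`PropagationError` if either
    pacemaker stayed silent.
    """
    pm = net.pacemakers
    if pm.size == 0:
        raise ValueError("net has no pacemakers")
    first = record.first[pm]
    if initiator is None:
        if np.all(np.isnan(first)):
            raise PropagationError("no pacemaker fired")
        initiator = int(np.nanargmin(first))
    opposing = (initiator + pm.size // 2) % pm.size
    t0 = first[initiator]
    t1 = first[opposing]
    if np.isnan(t0):
        raise PropagationError("initiating pacemaker did not fire")
    if np.isnan(t1):
        raise PropagationError("opposing pacemaker did not fire")
    return float(t1 - t0)


def mnn_conduction_delay(n_neurons: int, diameter: float = 4.0,
                         orientation: str = "von_mises", seed=None,
                         T: float = 300.0, dt: float = 0.01) -> float:
    """Build an MNN, fire pacemaker 0 once, and measure the through-conduction
    delay to the diametrically opposing pacemaker."""
    net = build_mnn(n_neurons, diameter=diameter, orientation=orientation,
                    seed=seed)
    rec = run_network(net, StimulusProtocol.single(net.pacemakers[0]),
                      T=T, dt=dt, stop="all_spiked")
    return conduction_delay(rec, net, initiator=0)


def dnn_conduction_delay(n_neurons: int, orientation: str = "uniform",
                         seed=None, diameter: float = 4.0, T: float = 1000.0,
                         dt: float = 0.01) -> float:
    """Same protocol as :func:`mnn_conduction_delay` on a diffuse nerve net.

    DNN conduction is slower (2 mm neurites mean more synaptic hops), so the
    default horizon is longer.
    """
    net = build_dnn(n_neurons, diameter=diameter, orientation=orientation,
                    seed=seed)
    rec = run_network(net, StimulusProtocol.single(net.pacemakers[0]),
                      T=T, dt=dt, stop="all_spiked")
    return conduction_delay(rec, net, initiator=0)


def reachable_component(net: NerveNet, sources) -> np.ndarray:
    """Indices of neurons reachable from ``sources`` in the synapse graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import breadth_first_order

    n = net.n_neurons
    src = np.concatenate([net.syn_i, net.syn_j])
    dst = np.concatenate([net.syn_j, net.syn_i])
    adj = coo_matrix((np.ones(src.size), (src, dst)), shape=(n, n)).tocsr()
    reach = set()
    for s0 in np.atleast_1d(sources):
        if int(s0) in reach:
            continue
        order = breadth_first_order(adj, int(s0), directed=False,
                                    return_predecessors=False)
        reach.update(int(v) for v in order)
    return np.array(sorted(reach), dtype=np.int64)


def run_cut_experiment(net: NerveNet, cuts, stim: StimulusProtocol | None = None,
                       T: float = 400.0, dt: float = 0.01,
                       p: NeuronParams | None = None,
                       s: SynapseParams | None = None,
                       ) -> tuple[SpikeRecord, float, NerveNet]:
    """Cut the net, run a wave, and report the coverage of the reachable part.

    Coverage is the fraction of neurons in the synapse-graph component(s)
    reachable from the stimulated neurons that actually fired.  Returns
    (record, coverage, cut net).
    """
    cut_net = apply_cut(net, cuts) if cuts else net
    if stim is None:
        stim = StimulusProtocol.single(cut_net.pacemakers[0])
    rec = run_network(cut_net, stim, T=T, dt=dt, p=p, s=s, stop="quiescent")
    sources = [i for i, _ in stim.events]
    reach = reachable_component(cut_net, sources)
    coverage = float((rec.counts[reach] > 0).mean())
    return rec, coverage, cut_net
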