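"""Three-state automaton model of a through-conducting nerve net.

Each vertex of an undirected graph is resting, firing, or refractory.  In
discrete time: a resting vertex with at least one firing neighbor fires in
the next step; a firing vertex becomes refractory; a refractory vertex
becomes resting.  Starting from any nonempty set of firing vertices in an
otherwise resting connected graph, every vertex fires exactly once, at the
step equal to its BFS distance from the initially firing set — the
qualitative explanation of why symmetric, suprathreshold synapses do not
cause runaway activity in the nerve net.  The automaton therefore serves as
a fast combinatorial oracle for the full membrane-model simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RESTING, FIRING, REFRACTORY = 0, 1, 2
_STATE_NAMES = {RESTING: "resting", FIRING: "firing", REFRACTORY: "refractory"}


@dataclass
class StateGraph:
    """Undirected graph in CSR form with per-vertex three-valued state."""

    off: np.ndarray            # (n+1,) CSR offsets
    nbr: np.ndarray            # neighbor indices
    state: np.ndarray          # (n,) in {RESTING, FIRING, REFRACTORY}
    refr_left: np.ndarray      # remaining refractory steps per vertex
    time: int = 0
    refractory_steps: int = 1

    @property
    def n_vertices(self) -> int:
        return self.off.shape[0] - 1

    @classmethod
    def from_edges(cls, n: int, edges, refractory_steps: int = 1,
                   ) -> "StateGraph":
        edges = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        src = np.concatenate([edges[:, 0], edges[:, 1]])
        dst = np.concatenate([edges[:, 1], edges[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        off = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(src, minlength=n), out=off[1:])
        return cls(off=off, nbr=dst, state=np.zeros(n, dtype=np.uint8),
                   refr_left=np.zeros(n, dtype=np.int64),
                   refractory_steps=refractory_steps)

    @classmethod
    def from_nerve_net(cls, net, refractory_steps: int = 1) -> "StateGraph":
        return cls.from_edges(net.n_neurons,
                              np.column_stack([net.syn_i, net.syn_j]),
                              refractory_steps=refractory_steps)

    @classmethod
    def from_edge_csv(cls, path, refractory_steps: int = 1) -> "StateGraph":
        import pandas as pd

        df = pd.read_csv(path)
        edges = df.iloc[:, :2].to_numpy(dtype=np.int64)
        n = int(edges.max()) + 1 if edges.size else 0
        return cls.from_edges(n, edges, refractory_steps=refractory_steps)

    def set_firing(self, vertices) -> None:
        self.state[np.asarray(vertices, dtype=np.int64)] = FIRING

    def state_names(self) -> list[str]:
        return [_STATE_NAMES[int(x)] for x in self.state]


def step(g: StateGraph) -> StateGraph:
    """One synchronous update; returns a new graph, the input is unchanged."""
    firing = g.state == FIRING
    has_firing_nbr = np.zeros(g.n_vertices, dtype=bool)
    if firing.any():
        deg = np.diff(g.off)
        src_firing = np.repeat(firing, deg)
        has_firing_nbr[np.unique(g.nbr[src_firing])] = True
    new_state = g.state.copy()
    new_refr = g.refr_left.copy()
    # refractory vertices count down toward resting
    refr = g.state == REFRACTORY
    new_refr[refr] -= 1
    new_state[refr & (new_refr <= 0)] = RESTING
    # firing vertices become refractory
    new_state[firing] = REFRACTORY
    new_refr[firing] = g.refractory_steps
    # resting vertices with a firing neighbor fire
    ignite = (g.state == RESTING) & has_firing_nbr
    new_state[ignite] = FIRING
    return StateGraph(off=g.off, nbr=g.nbr, state=new_state,
                      refr_left=new_refr, time=g.time + 1,
                      refractory_steps=g.refractory_steps)


def run_until_quiescent(g: StateGraph, initial_firing,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Run from an initial firing set until no vertex is firing.

    Returns (first firing step per vertex, -1 where the vertex never fired;
    firing counts per vertex).  On a connected graph every count is 1 and the
    first firing step equals the BFS distance to the initial set.
    """
    initial_firing = np.asarray(initial_firing, dtype=np.int64)
    if initial_firing.size == 0:
        raise ValueError("initial firing set must be nonempty")
    n = g.n_vertices
    cur = StateGraph(off=g.off, nbr=g.nbr,
                     state=np.zeros(n, dtype=np.uint8),
                     refr_left=np.zeros(n, dtype=np.int64),
                     refractory_steps=g.refractory_steps)
    cur.set_firing(initial_firing)
    first = np.full(n, -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    max_steps = n * (g.refractory_steps + 2) + 2
    for _ in range(max_steps):
        firing = cur.state == FIRING
        if not firing.any():
            break
        counts[firing] += 1
        newly = firing & (first < 0)
        first[newly] = cur.time
        cur = step(cur)
    else:
        raise RuntimeError("automaton failed to reach quiescence")
    return first, counts


def bfs_distances(g: StateGraph, sources) -> np.ndarray:
    """Shortest path length (in hops) from the source set; -1 if unreachable."""
    n = g.n_vertices
    dist = np.full(n, -1, dtype=np.int64)
    frontier = np.unique(np.asarray(sources, dtype=np.int64))
    dist[frontier] = 0
    d = 0
    while frontier.size:
        nxt = []
        for v in frontier:
            nb = g.nbr[g.off[v]:g.off[v + 1]]
            nxt.append(nb[dist[nb] < 0])
        if nxt:
            frontier = np.unique(np.concatenate(nxt))
            frontier = frontier[dist[frontier] < 0]
        else:
            frontier = np.zeros(0, dtype=np.int64)
        d += 1
        dist[frontier] = d
    return dist


def oracle_compare(net, record, initial_firing=None) -> dict:
    """Check a membrane-model spike record against the automaton oracle.

    The automaton runs on the synapse graph of ``net`` seeded with
    ``initial_firing`` (default: the earliest-spiking neuron of the record).
    Reports whether per-neuron spike counts agree and the Spearman rank
    correlation between membrane-model spike times and BFS firing steps.
    """
    from scipy.stats import spearmanr

    g = StateGraph.from_nerve_net(net)
    hh_counts = np.asarray(record.counts)
    if initial_firing is None:
        first = record.first
        if np.all(np.isnan(first)):
            auto_counts = np.zeros(net.n_neurons, dtype=np.int64)
            auto_first = np.full(net.n_neurons, -1, dtype=np.int64)
        else:
            initial_firing = [int(np.nanargmin(first))]
            auto_first, auto_counts = run_until_quiescent(g, initial_firing)
    else:
        auto_first, auto_counts = run_until_quiescent(g, initial_firing)
    match = bool(np.array_equal(hh_counts, auto_counts))
    fired = (hh_counts > 0) & (auto_counts > 0)
    if fired.sum() >= 3:
        rho = float(spearmanr(record.first[fired], auto_first[fired]).statistic)
    else:
        rho = np.nan
    return {
        "counts_match": match,
        "n_mismatch": int(np.sum(hh_counts != auto_counts)),
        "spearman_rho": rho,
        "automaton_counts": auto_counts,
        "automaton_first": auto_first,
    }
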