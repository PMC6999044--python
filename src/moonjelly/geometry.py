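"""Geometric construction of the subumbrellar nerve nets.

Neurons are bipolar: each is represented by a straight neurite segment with
the soma at its midpoint.  Motor-nerve-net (MNN) neurites are 5 mm long with
somata on an annulus (outer radius 2 cm, inner radius 0.5 cm on the default
4 cm bell); the diffuse nerve net (DNN) has 2 mm neurites and extends 0.25 cm
further into the bell margin.  Two neurons are synaptically connected where
their segments intersect; the transmission delay between their somata is

    rho = 0.5 ms + (dist(A, x) + dist(B, x)) * 2 ms/cm

where x is the intersection point.  Neurite orientations are drawn either
uniformly or from a position-dependent von Mises distribution with
concentration kappa = 8 (d - 0.5) and mean direction 3 alpha, where d is the
somatic distance from the bell center (cm) and alpha its polar angle relative
to the line from the center to a reference rhopalium.

All lengths are in cm, delays in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UndefinedStatisticError

MNN_NEURITE_CM = 0.5
DNN_NEURITE_CM = 0.2
N_PACEMAKERS = 8
#: reference bell: 4 cm diameter -> MNN annulus radii and margin width (cm)
REF_DIAMETER_CM = 4.0
REF_R_OUTER = 2.0
REF_R_INNER = 0.5
REF_MARGIN_W = 0.25
BASE_DELAY_MS = 0.5
DELAY_PER_CM = 2.0


@dataclass
class CutLine:
    """A straight cut through the nerve net, given by its endpoints (cm)."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self):
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("cut endpoints must be finite")
        if np.allclose(a, b):
            raise ValueError("cut must have nonzero length")
        self.p0 = tuple(a)
        self.p1 = tuple(b)


@dataclass
class NerveNet:
    """A nerve net: neurite segments plus the synapses derived from them.

    ``soma`` lies on the segment [``e0``, ``e1``] (at its midpoint for uncut
    nets).  Synapses are unordered pairs (``syn_i`` < ``syn_j``) with the
    intersection point, the two soma-to-synapse distances and the symmetric
    transmission delay.  ``pacemakers`` indexes the rhopalial neurons.
    """

    soma: np.ndarray          # (n, 2) cm
    angle: np.ndarray         # (n,) rad
    e0: np.ndarray            # (n, 2) cm
    e1: np.ndarray            # (n, 2) cm
    syn_i: np.ndarray         # (m,)
    syn_j: np.ndarray         # (m,)
    syn_xy: np.ndarray        # (m, 2) cm
    syn_d_i: np.ndarray       # (m,) cm, soma_i -> synapse
    syn_d_j: np.ndarray       # (m,) cm
    syn_delay: np.ndarray     # (m,) ms
    pacemakers: np.ndarray    # (k,)
    kind: str = "mnn"
    diameter: float = REF_DIAMETER_CM
    orientation_mode: str = "von_mises"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.soma.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.syn_i.shape[0]

    @property
    def length(self) -> np.ndarray:
        """Current neurite lengths (cm), accounting for cuts."""
        return np.linalg.norm(self.e1 - self.e0, axis=1)

    @classmethod
    def from_segments(cls, soma, angle, length, pacemakers=(), kind="custom",
                      base_delay=BASE_DELAY_MS, delay_per_cm=DELAY_PER_CM,
                      **meta):
        """Build a net from explicit somata/orientations/neurite lengths."""
        soma = np.atleast_2d(np.asarray(soma, dtype=float))
        angle = np.asarray(angle, dtype=float)
        length = np.broadcast_to(np.asarray(length, dtype=float),
                                 angle.shape).copy()
        u = np.column_stack([np.cos(angle), np.sin(angle)])
        e0 = soma - 0.5 * length[:, None] * u
        e1 = soma + 0.5 * length[:, None] * u
        syn = find_synapses(e0, e1, soma, base_delay=base_delay,
                            delay_per_cm=delay_per_cm)
        return cls(soma=soma, angle=angle, e0=e0, e1=e1,
                   pacemakers=np.asarray(pacemakers, dtype=np.int64),
                   kind=kind, meta=dict(meta), **syn)

    def neurons_dataframe(self):
        import pandas as pd

        is_pm = np.zeros(self.n_neurons, dtype=bool)
        is_pm[self.pacemakers] = True
        return pd.DataFrame({
            "x": self.soma[:, 0], "y": self.soma[:, 1],
            "angle": self.angle, "length": self.length,
            "is_pacemaker": is_pm,
            "e0x": self.e0[:, 0], "e0y": self.e0[:, 1],
            "e1x": self.e1[:, 0], "e1y": self.e1[:, 1],
        })

    def synapses_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "i": self.syn_i, "j": self.syn_j,
            "x": self.syn_xy[:, 0], "y": self.syn_xy[:, 1],
            "dist_i": self.syn_d_i, "dist_j": self.syn_d_j,
            "delay_ms": self.syn_delay,
        })

    def save_csv(self, prefix) -> None:
        """Write ``<prefix>.neurons.csv`` and ``<prefix>.synapses.csv``."""
        self.neurons_dataframe().to_csv(f"{prefix}.neurons.csv", index=False)
        self.synapses_dataframe().to_csv(f"{prefix}.synapses.csv", index=False)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("soma", "angle", "e0", "e1", "syn_i", "syn_j",
                         "syn_xy", "syn_d_i", "syn_d_j", "syn_delay",
                         "pacemakers"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["kind"] = self.kind
            f.attrs["diameter"] = self.diameter
            f.attrs["orientation_mode"] = self.orientation_mode

    @classmethod
    def load_hdf5(cls, path) -> "NerveNet":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in
                  ("soma", "angle", "e0", "e1", "syn_i", "syn_j", "syn_xy",
                   "syn_d_i", "syn_d_j", "syn_delay", "pacemakers")}
            return cls(kind=str(f.attrs["kind"]),
                       diameter=float(f.attrs["diameter"]),
                       orientation_mode=str(f.attrs["orientation_mode"]),
                       **kw)


# ---------------------------------------------------------------------------
# orientation sampling


def sample_orientation(d, alpha, rng, kappa_scale: float = 8.0,
                       d_offset: float = 0.5):
    """Draw neurite orientations from the position-dependent von Mises law.

    Concentration kappa = ``kappa_scale`` * (d - ``d_offset``) and mean
    direction 3*alpha; at d = ``d_offset`` the distribution is uniform on the
    circle.  A negative kappa (d < ``d_offset``) is realized as the
    equivalent von Mises with the mean shifted by pi.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance d must be >= 0")
    alpha = np.asarray(alpha, dtype=float)
    kappa = kappa_scale * (d - d_offset)
    mu = np.where(kappa < 0, 3.0 * alpha + np.pi, 3.0 * alpha)
    return rng.vonmises(mu, np.abs(kappa))


def von_mises_density(phi, d, alpha, kappa_scale: float = 8.0,
                      d_offset: float = 0.5):
    """Probability density of :func:`sample_orientation` at angle ``phi``."""
    from scipy.special import i0

    kappa = kappa_scale * (d - d_offset)
    return (np.exp(kappa * np.cos(np.asarray(phi) - 3.0 * alpha))
            / (2.0 * np.pi * i0(kappa)))


# ---------------------------------------------------------------------------
# synapse derivation (segment intersections)


def _cross(ax, ay, bx, by):
    return ax * by - ay * bx


def _candidate_pairs(e0, e1, cell: float) -> tuple[np.ndarray, np.ndarray]:
    """Candidate index pairs from a uniform spatial hash.

    The grid cell equals the longest neurite, so a segment's bounding box
    spans at most 2x2 cells; pairs sharing any cell are candidates.
    """
    n = e0.shape[0]
    lo = np.minimum(e0, e1)
    hi = np.maximum(e0, e1)
    i0 = np.floor(lo / cell).astype(np.int64)
    i1 = np.floor(hi / cell).astype(np.int64)
    if np.any(i1 - i0 > 1):
        raise ValueError("grid cell smaller than a segment bounding box")
    ids = np.arange(n, dtype=np.int64)
    keys = []
    segs = []
    off = i0.min(axis=0)
    ncols = int((i1[:, 1] - off[1]).max()) + 2
    for dx in (0, 1):
        for dy in (0, 1):
            cx = np.minimum(i0[:, 0] + dx, i1[:, 0]) - off[0]
            cy = np.minimum(i0[:, 1] + dy, i1[:, 1]) - off[1]
            keys.append(cx * ncols + cy)
            segs.append(ids)
    keys = np.concatenate(keys)
    segs = np.concatenate(segs)
    # drop duplicate (cell, segment) entries from boxes spanning one cell
    ks = np.unique(keys * n + segs)
    keys, segs = ks // n, ks % n
    order = np.argsort(keys, kind="stable")
    keys, segs = keys[order], segs[order]
    bounds = np.flatnonzero(np.diff(keys)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [keys.size]])
    pi_all, pj_all = [], []
    for a, b in zip(starts, ends):
        if b - a < 2:
            continue
        grp = segs[a:b]
        ii, jj = np.triu_indices(grp.size, 1)
        pi_all.append(grp[ii])
        pj_all.append(grp[jj])
    if not pi_all:
        return (np.zeros(0, dtype=np.int64),) * 2
    pi = np.concatenate(pi_all)
    pj = np.concatenate(pj_all)
    lo_idx = np.minimum(pi, pj)
    hi_idx = np.maximum(pi, pj)
    codes = np.unique(lo_idx * n + hi_idx)
    return codes // n, codes % n


def _intersect_pairs(e0, e1, pi, pj):
    """Exact segment-segment intersection for candidate pairs.

    Parallel (including collinear-overlap) pairs yield no synapse; endpoint
    contact counts as an intersection.  Returns a mask and the intersection
    points.
    """
    p = e0[pi]
    r = e1[pi] - e0[pi]
    q = e0[pj]
    s = e1[pj] - e0[pj]
    denom = _cross(r[:, 0], r[:, 1], s[:, 0], s[:, 1])
    ok = denom != 0.0
    denom_safe = np.where(ok, denom, 1.0)
    qp = q - p
    t = _cross(qp[:, 0], qp[:, 1], s[:, 0], s[:, 1]) / denom_safe
    u = _cross(qp[:, 0], qp[:, 1], r[:, 0], r[:, 1]) / denom_safe
    ok &= (t >= 0.0) & (t <= 1.0) & (u >= 0.0) & (u <= 1.0)
    x = p + t[:, None] * r
    return ok, x


def find_synapses(e0, e1, soma, base_delay=BASE_DELAY_MS,
                  delay_per_cm=DELAY_PER_CM, brute_force=False) -> dict:
    """All pairwise segment intersections with their transmission delays.

    ``brute_force=True`` tests all n(n-1)/2 pairs directly and is the
    reference implementation; the default uses a spatial hash with identical
    results.
    """
    n = e0.shape[0]
    if brute_force or n <= 2:
        pi, pj = np.triu_indices(n, 1)
        pi = pi.astype(np.int64)
        pj = pj.astype(np.int64)
    else:
        lengths = np.linalg.norm(e1 - e0, axis=1)
        cell = max(float(lengths.max()), 1e-9)
        pi, pj = _candidate_pairs(e0, e1, cell)
    ok, x = _intersect_pairs(e0, e1, pi, pj)
    pi, pj, x = pi[ok], pj[ok], x[ok]
    d_i = np.linalg.norm(x - soma[pi], axis=1)
    d_j = np.linalg.norm(x - soma[pj], axis=1)
    delay = base_delay + delay_per_cm * (d_i + d_j)
    return {"syn_i": pi, "syn_j": pj, "syn_xy": x, "syn_d_i": d_i,
            "syn_d_j": d_j, "syn_delay": delay}


# ---------------------------------------------------------------------------
# net builders


def _pacemaker_segments(r_out: float):
    """Eight radially oriented neurons at 45 deg spacing on the outer edge."""
    ang = np.arange(N_PACEMAKERS) * (2.0 * np.pi / N_PACEMAKERS)
    soma = r_out * np.column_stack([np.cos(ang), np.sin(ang)])
    return soma, ang


def _build_net(n_neurons, diameter, orientation, seed, neurite, r_in_ref,
               r_out_ref, kind, kappa_scale, radial_bias_kappa):
    if n_neurons < N_PACEMAKERS:
        raise ValueError(
            f"need at least {N_PACEMAKERS} neurons (8 rhopalial pacemakers)")
    scale = diameter / REF_DIAMETER_CM
    r_in = r_in_ref * scale
    r_out = r_out_ref * scale
    rng = np.random.default_rng(seed)

    pm_soma, pm_angle = _pacemaker_segments(REF_R_OUTER * scale)
    n_rand = n_neurons - N_PACEMAKERS
    rr = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n_rand))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n_rand)
    soma = np.concatenate(
        [pm_soma, np.column_stack([rr * np.cos(th), rr * np.sin(th)])])

    if orientation == "uniform":
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_rand)
    elif orientation == "von_mises":
        phi = sample_orientation(rr, th, rng, kappa_scale=kappa_scale)
    elif orientation == "radial_bias":
        phi = rng.vonmises(th, radial_bias_kappa)
    else:
        raise ValueError(f"unknown orientation mode {orientation!r}")
    angle = np.concatenate([pm_angle, phi])

    net = NerveNet.from_segments(soma, angle, neurite,
                                 pacemakers=np.arange(N_PACEMAKERS),
                                 kind=kind)
    net.diameter = diameter
    net.orientation_mode = orientation
    net.seed = seed
    return net


def build_mnn(n_neurons: int, diameter: float = REF_DIAMETER_CM,
              orientation: str = "von_mises", seed=None,
              neurite_length: float = MNN_NEURITE_CM,
              kappa_scale: float = 8.0) -> NerveNet:
    """Motor nerve net: somata uniform on the annulus (0.5-2 cm at 4 cm
    diameter, radii scaled proportionally otherwise), 5 mm neurites, eight
    radially oriented pacemaker neurons on the outer annulus edge.

    ``orientation`` is 'von_mises' (position-dependent, the anatomical
    default) or 'uniform'.
    """
    if orientation not in ("von_mises", "uniform"):
        raise ValueError("MNN orientation must be 'von_mises' or 'uniform'")
    return _build_net(n_neurons, diameter, orientation, seed, neurite_length,
                      REF_R_INNER, REF_R_OUTER, "mnn", kappa_scale, 0.0)


def build_dnn(n_neurons: int, diameter: float = REF_DIAMETER_CM,
              orientation: str = "uniform", seed=None,
              neurite_length: float = DNN_NEURITE_CM,
              radial_bias_kappa: float = 2.0) -> NerveNet:
    """Diffuse nerve net: 2 mm neurites, somata extending 0.25 cm further
    into the bell margin than the MNN annulus.

    ``orientation`` is 'uniform' (default) or 'radial_bias' (von Mises about
    the radial direction with concentration ``radial_bias_kappa``; no
    quantitative anatomical estimate exists, so the concentration is a
    configuration knob).
    """
    if orientation not in ("uniform", "radial_bias"):
        raise ValueError("DNN orientation must be 'uniform' or 'radial_bias'")
    return _build_net(n_neurons, diameter, orientation, seed, neurite_length,
                      REF_R_INNER, REF_R_OUTER + REF_MARGIN_W, "dnn",
                      8.0, radial_bias_kappa)


# ---------------------------------------------------------------------------
# network statistics


def mean_synapses_per_neuron(net: NerveNet) -> float:
    """Average synapse count per neuron (each synapse touches two neurons)."""
    return 2.0 * net.n_synapses / net.n_neurons


def mean_intersynaptic_distance(net: NerveNet, per_neuron: bool = False) -> float:
    """Mean spacing (micrometers) of consecutive synapses along a neurite.

    For every neuron with at least two synapses, its synapse positions are
    sorted along the segment and the consecutive gaps collected.  By default
    the pooled mean over all gaps is returned (every synapse pair weighted
    equally, the direct analogue of measuring distances between neighboring
    synapses under a microscope); ``per_neuron=True`` instead averages the
    gaps within each neuron first and returns the grand mean over neurons,
    which up-weights sparsely innervated neurons.
    """
    if net.n_synapses < 1:
        raise UndefinedStatisticError("net has no synapses")
    u = net.e1 - net.e0
    norm = np.linalg.norm(u, axis=1)
    norm[norm == 0] = 1.0
    u = u / norm[:, None]
    ids = np.concatenate([net.syn_i, net.syn_j])
    pts = np.concatenate([net.syn_xy, net.syn_xy])
    proj = np.einsum("ij,ij->i", pts - net.e0[ids], u[ids])
    order = np.lexsort((proj, ids))
    ids, proj = ids[order], proj[order]
    same = ids[1:] == ids[:-1]
    gaps = np.diff(proj)[same]
    gap_ids = ids[1:][same]
    if gaps.size == 0:
        raise UndefinedStatisticError("no neuron carries >= 2 synapses")
    if per_neuron:
        uniq, inv, counts = np.unique(gap_ids, return_inverse=True,
                                      return_counts=True)
        sums = np.bincount(inv, weights=gaps)
        return float((sums / counts).mean() * 1e4)  # cm -> um
    return float(gaps.mean() * 1e4)


# ---------------------------------------------------------------------------
# cutting experiments


def apply_cut(net: NerveNet, cuts: Sequence[CutLine]) -> NerveNet:
    """Sever neurites along straight cuts.

    Where a cut crosses a neurite, the part carrying the soma survives and
    the other part dies off: the segment is truncated at the cut and every
    synapse on the removed part is deleted (on both participating neurons).
    Delays of surviving synapses are unchanged.
    """
    e0 = net.e0.copy()
    e1 = net.e1.copy()
    soma = net.soma
    for cut in cuts:
        c0 = np.asarray(cut.p0)
        c1 = np.asarray(cut.p1)
        r = e1 - e0
        s = c1 - c0
        denom = _cross(r[:, 0], r[:, 1], s[0], s[1])
        ok = denom != 0.0
        denom_safe = np.where(ok, denom, 1.0)
        qp = c0 - e0
        t = _cross(qp[:, 0], qp[:, 1], s[0], s[1]) / denom_safe
        uu = _cross(qp[:, 0], qp[:, 1], r[:, 0], r[:, 1]) / denom_safe
        hit = ok & (t >= 0.0) & (t <= 1.0) & (uu >= 0.0) & (uu <= 1.0)
        if not np.any(hit):
            continue
        x = e0[hit] + t[hit, None] * r[hit]
        # the side of the intersection away from the soma dies off
        udir = r[hit] / np.linalg.norm(r[hit], axis=1, keepdims=True)
        side = np.einsum("ij,ij->i", x - soma[hit], udir)
        idx = np.flatnonzero(hit)
        fwd = side > 0.0
        e1[idx[fwd]] = x[fwd]
        e0[idx[~fwd]] = x[~fwd]

    # a synapse survives only if its point is still on both kept sub-segments
    def on_kept(idx_arr):
        u = e1[idx_arr] - e0[idx_arr]
        norm = np.linalg.norm(u, axis=1)
        norm[norm == 0] = 1.0
        u = u / norm[:, None]
        pos = np.einsum("ij,ij->i", net.syn_xy - e0[idx_arr], u)
        return (pos >= -1e-9) & (pos <= norm + 1e-9)

    keep = on_kept(net.syn_i) & on_kept(net.syn_j)
    return NerveNet(
        soma=soma.copy(), angle=net.angle.copy(), e0=e0, e1=e1,
        syn_i=net.syn_i[keep], syn_j=net.syn_j[keep],
        syn_xy=net.syn_xy[keep], syn_d_i=net.syn_d_i[keep],
        syn_d_j=net.syn_d_j[keep], syn_delay=net.syn_delay[keep],
        pacemakers=net.pacemakers.copy(), kind=net.kind,
        diameter=net.diameter, orientation_mode=net.orientation_mode,
        seed=net.seed, meta=dict(net.meta, cut=True),
    )


def octagon_cuts(radius: float = 1.25, gap: float = 0.4,
                 gap_side: int = 0) -> list[CutLine]:
    """Cuts along the outline of an octagon, one side interrupted by a gap.

    Reproduces the classical experiment in which an inner disc is almost
    completely severed from the outer ring, connected only through a small
    bridge of width ``gap`` (cm) centered on side ``gap_side``.
    """
    ang = np.arange(9) * (2.0 * np.pi / 8) + np.pi / 8
    verts = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    cuts = []
    for k in range(8):
        a, b = verts[k], verts[k + 1]
        if k == gap_side:
            side_len = float(np.linalg.norm(b - a))
            f = max(0.0, 0.5 * (1.0 - gap / side_len))
            if f > 0:
                cuts.append(CutLine(tuple(a), tuple(a + f * (b - a))))
                cuts.append(CutLine(tuple(b - f * (b - a)), tuple(b)))
        else:
            cuts.append(CutLine(tuple(a), tuple(b)))
    return cuts


def radial_cuts(n_cuts: int = 16, r_inner_start: float = 0.3,
                r_inner_end: float = 1.4, r_outer_start: float = 1.0,
                r_outer_end: float = 2.3) -> list[CutLine]:
    """Interdigitating radial cuts forming a zig-zag conduction path.

    Even-numbered cuts run from near the bell center outward to
    ``r_inner_end``; odd-numbered cuts run from ``r_outer_start`` out past
    the bell edge.  The two families overlap radially, so an activation wave
    has to weave between the interleaving cuts.
    """
    cuts = []
    for k in range(n_cuts):
        th = 2.0 * np.pi * k / n_cuts
        u = np.array([np.cos(th), np.sin(th)])
        if k % 2 == 0:
            cuts.append(CutLine(tuple(r_inner_start * u),
                                tuple(r_inner_end * u)))
        else:
            cuts.append(CutLine(tuple(r_outer_start * u),
                                tuple(r_outer_end * u)))
    return cuts


def read_cuts(path) -> list[CutLine]:
    """Read cuts from a CSV with columns x0, y0, x1, y1 (cm)."""
    import pandas as pd

    df = pd.read_csv(path)
    return [CutLine((row.x0, row.y0), (row.x1, row.y1))
            for row in df.itertuples()]


def save_cuts(path, cuts: Sequence[CutLine]) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"x0": c.p0[0], "y0": c.p0[1], "x1": c.p1[0], "y1": c.p1[1]}
         for c in cuts]).to_csv(path, index=False)
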