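"""Swim-muscle force generation from nerve-net spikes.

A single spike of an innervating neuron produces a stereotyped activation
twitch a(t) = t^m exp(-k t) (t in ms); twitches of all spikes innervating a
muscle fiber sum linearly.  The force a fiber can exert depends on its
instantaneous length through a Gaussian force-length relation peaked at the
optimal (resting) length.  After a nerve-net simulation the peak force is
normalized: the maximal summed activation over all fibers of a kind is scaled
to F_Norm (0.4 N for the circular swim muscles, 0.8 N for the radial margin
muscles), so relative strengths between fibers are preserved independently of
neuron count and conduction speed.

The circular muscles form eight blocks of eight units, ordered radially, one
block per rhopalium (64 fibers); the radial muscles form eight blocks in the
bell margin.  A neuron innervates the fiber whose area contains its soma
(MNN -> circular, DNN -> radial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .geometry import NerveNet, REF_DIAMETER_CM, REF_R_INNER, REF_R_OUTER, \
    REF_MARGIN_W

N_SECTORS = 8
N_BANDS = 8


@dataclass
class MuscleParams:
    """Twitch shape, force-length width and normalization constants."""

    m: float = 1.075            # twitch rise exponent (dimensionless)
    k: float = 2.15e-2          # twitch decay rate (1/ms)
    s: float = 0.4              # force-length width (dimensionless)
    f_norm_circular: float = 0.4  # N
    f_norm_radial: float = 0.8    # N

    def __post_init__(self):
        for name in ("m", "k", "s", "f_norm_circular", "f_norm_radial"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def f_norm(self, kind: str) -> float:
        return self.f_norm_circular if kind == "circular" else self.f_norm_radial


@dataclass
class MuscleFiber:
    """One muscle unit: a polar sector patch with its innervating neurons."""

    id: int
    kind: str                   # 'circular' | 'radial'
    theta_lo: float             # rad
    theta_hi: float
    r_lo: float                 # cm
    r_hi: float
    l_opt: float                # cm, optimal (= resting) length
    f_opt: float = np.nan       # N, set by the normalization step
    neurons: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))


@dataclass
class MuscleLayout:
    """Polar-grid muscle layout for a bell of a given diameter.

    Circular fibers tile 8 angular octants (centered on the rhopalia)
    times 8 radial bands of equal width spanning the muscle annulus; radial
    fibers form one block per octant in the bell margin.
    """

    fibers: list[MuscleFiber]
    diameter: float = REF_DIAMETER_CM

    @classmethod
    def default(cls, diameter: float = REF_DIAMETER_CM) -> "MuscleLayout":
        scale = diameter / REF_DIAMETER_CM
        r_in = REF_R_INNER * scale
        r_out = REF_R_OUTER * scale
        margin_out = (REF_R_OUTER + REF_MARGIN_W) * scale
        half = np.pi / N_SECTORS
        fibers = []
        fid = 0
        band_edges = np.linspace(r_in, r_out, N_BANDS + 1)
        for sec in range(N_SECTORS):
            th0 = sec * 2 * np.pi / N_SECTORS - half
            for b in range(N_BANDS):
                r_lo, r_hi = band_edges[b], band_edges[b + 1]
                r_mid = 0.5 * (r_lo + r_hi)
                fibers.append(MuscleFiber(
                    id=fid, kind="circular", theta_lo=th0,
                    theta_hi=th0 + 2 * half, r_lo=r_lo, r_hi=r_hi,
                    l_opt=r_mid * 2 * half))  # arc length of the unit
                fid += 1
        for sec in range(N_SECTORS):
            th0 = sec * 2 * np.pi / N_SECTORS - half
            fibers.append(MuscleFiber(
                id=fid, kind="radial", theta_lo=th0, theta_hi=th0 + 2 * half,
                r_lo=r_out, r_hi=margin_out, l_opt=margin_out - r_out))
            fid += 1
        return cls(fibers=fibers, diameter=diameter)

    def of_kind(self, kind: str) -> list[MuscleFiber]:
        return [f for f in self.fibers if f.kind == kind]


def twitch(t, p: MuscleParams):
    """Activation t^m exp(-k t) for t > 0, zero otherwise (t in ms).

    The single interior maximum sits at t = m/k (50 ms with the default
    parameters, within the twitch durations reported for jellyfish muscle).
    """
    t = np.asarray(t, dtype=float)
    return np.where(t > 0, np.power(np.maximum(t, 0.0), p.m) * np.exp(-p.k * t),
                    0.0)


def force_length(length, fiber: MuscleFiber, p: MuscleParams,
                 f_opt: float | None = None):
    """Maximal force (N) a fiber of the given instantaneous length can exert.

    Gaussian in the relative extension: F_O exp(-((L/L_O - 1)/S)^2), peaked
    at the optimal length L_O.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("muscle length must be > 0")
    fo = fiber.f_opt if f_opt is None else f_opt
    return fo * np.exp(-(((length / fiber.l_opt) - 1.0) / p.s) ** 2)


def _sector_index(theta):
    """Octant index for polar angle, sectors centered on the rhopalia."""
    half = np.pi / N_SECTORS
    return (np.floor((theta + half) / (2 * half)).astype(int)) % N_SECTORS


def map_neurons_to_muscles(net: NerveNet, layout: MuscleLayout,
                           ) -> dict[int, np.ndarray]:
    """Assign each neuron to the fiber whose area contains its soma.

    MNN neurons innervate circular fibers, DNN neurons radial ones; somata
    outside every fiber area stay unassigned.  Returns fiber id -> neuron
    index array (also stored on the fibers).
    """
    kind = "circular" if net.kind != "dnn" else "radial"
    r = np.linalg.norm(net.soma, axis=1)
    theta = np.arctan2(net.soma[:, 1], net.soma[:, 0])
    sec = _sector_index(theta)
    out: dict[int, np.ndarray] = {}
    for f in layout.fibers:
        if f.kind != kind:
            f.neurons = np.zeros(0, dtype=np.int64)
            out[f.id] = f.neurons
            continue
        f_sec = _sector_index(np.array([0.5 * (f.theta_lo + f.theta_hi)]))[0]
        inside = (sec == f_sec) & (r >= f.r_lo) & (r < f.r_hi)
        f.neurons = np.flatnonzero(inside).astype(np.int64)
        out[f.id] = f.neurons
    return out


@dataclass
class MuscleForceSeries:
    """Per-fiber force time series (N) on a uniform time grid (ms)."""

    t: np.ndarray
    force: np.ndarray           # (n_samples, n_fibers)
    fiber_ids: np.ndarray
    kinds: list[str]
    f_opt: dict[str, float]     # normalization constant per muscle kind

    def to_dataframe(self):
        import pandas as pd

        n_t, n_f = self.force.shape
        return pd.DataFrame({
            "time_ms": np.repeat(self.t, n_f),
            "fiber_id": np.tile(self.fiber_ids, n_t),
            "force_N": self.force.ravel(),
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.t)
            f.create_dataset("force_N", data=self.force)
            f.create_dataset("fiber_id", data=self.fiber_ids)


def muscle_force_series(record, layout: MuscleLayout, p: MuscleParams,
                        t_grid: np.ndarray | None = None,
                        lengths: np.ndarray | None = None,
                        ) -> MuscleForceSeries:
    """Muscle forces generated by a finished nerve-net run.

    For fiber j with innervating spike times t_ij, the activation is
    A_j(t) = sum_i a(t - t_ij); the normalization constant F_O of each muscle
    kind is chosen *after* the run so that max_{t,j} F_O A_j(t) = F_Norm.
    The force is F_I(L_j(t)) * A_j(t) with the force-length factor F_I
    evaluated at the supplied per-fiber length series (default: fixed at the
    optimal lengths, so the force-length factor is F_O).

    ``lengths`` has shape (n_samples, n_fibers) in cm when given.
    """
    if t_grid is None:
        horizon = record.horizon + 5.0 / p.k  # cover the slow twitch tail
        t_grid = np.arange(0.0, horizon, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    fibers = layout.fibers
    n_f = len(fibers)
    act = np.zeros((t_grid.size, n_f))
    for col, f in enumerate(fibers):
        for i in f.neurons:
            for ts in record.spike_times(int(i)):
                act[:, col] += twitch(t_grid - ts, p)

    f_opt: dict[str, float] = {}
    for kind in ("circular", "radial"):
        cols = [c for c, f in enumerate(fibers) if f.kind == kind]
        peak = act[:, cols].max() if cols else 0.0
        innervated = any(fibers[c].neurons.size for c in cols)
        if innervated and peak == 0.0:
            warnings.warn(
                f"no spikes reached any {kind} muscle; normalization "
                "undefined, forces are zero", stacklevel=2)
        f_opt[kind] = p.f_norm(kind) / peak if peak > 0 else 0.0
    for f in fibers:
        f.f_opt = f_opt[f.kind]

    force = np.empty_like(act)
    for col, f in enumerate(fibers):
        if lengths is None:
            fl = f.f_opt
            force[:, col] = fl * act[:, col]
        else:
            force[:, col] = force_length(lengths[:, col], f, p) * act[:, col]
    return MuscleForceSeries(
        t=t_grid, force=force,
        fiber_ids=np.array([f.id for f in fibers]),
        kinds=[f.kind for f in fibers], f_opt=f_opt)


def save_innervation_csv(path, layout: MuscleLayout) -> None:
    """Innervation map as CSV rows (fiber_id, kind, neuron_id)."""
    import pandas as pd

    rows = [{"fiber_id": f.id, "kind": f.kind, "neuron_id": int(i)}
            for f in layout.fibers for i in f.neurons]
    pd.DataFrame(rows, columns=["fiber_id", "kind", "neuron_id"]).to_csv(
        path, index=False)
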