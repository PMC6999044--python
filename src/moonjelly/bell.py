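"""Elastic 2D cross-section of the jellyfish bell and its structure export.

The relaxed subumbrellar outline of each bell half is a chain of N_p vertices
at constant spacing r/N_p (the first at half spacing from the center), whose
segment angles below the horizontal follow a two-exponent curvature family

    phi(i) = -alpha (1-p) (i/N_p)^n1 - alpha p (i/N_p)^n2 .

For n1 = n2 = 1 the outline is a semicircle of radius 2r/pi.  The
exumbrellar surface lies a height h(i) above the subumbrellar curve along its
local normal, with h a linear base profile plus a Gaussian hump.  Damped
springs run along both surfaces and connect them; circular swim muscles pull
subumbrellar vertices toward the bell's center line, radial margin muscles
act between neighboring margin vertices.  The mesh is exported in the plain
text .vertex/.spring format used by immersed-boundary fluid solvers, with a
YAML manifest carrying the fluid parameters and the muscle attachment map.

Geometry is in meters in the mesh and exports; the printed height constants
are in millimeters and converted on construction.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateGeometryError, ExportError

MM = 1e-3

#: fluid-solver parameters exported as metadata alongside the structure
DEFAULT_FLUID = {
    "mu_Ns_per_m2": 0.005,
    "rho_kg_per_m2": 1000.0,
    "dt_s": 1e-5,
    "x_length_m": 0.06,
    "y_length_m": 0.08,
    "x_grid": 180,
    "y_grid": 240,
}


@dataclass
class BellParams:
    """Geometry and spring parameters of the 2D bell cross-section.

    ``r`` is the half arc length of the subumbrellar outline (m).  The
    curvature exponents n1/n2 and mixing weight ``p`` shape the bell from
    prolate (small exponents) to oblate.  Height constants are in mm as
    printed; ``sigma`` is the dimensionless width constant of the central
    hump.  ``hump_exp_sign`` selects exp(+i^2/sigma^2) (as printed; with the
    default sigma the factor is nearly constant) or exp(-i^2/sigma^2);
    ``sigma_is_squared`` treats ``sigma`` as already being sigma^2.
    """

    r: float = 0.02            # m, half-length of the subumbrella curve
    n_p: int = 224             # vertices per half
    alpha: float = math.pi / 2
    p: float = 0.5
    n1: float = 1.0
    n2: float = 2.0
    c_base: float = 0.5        # mm
    c_amp: float = 6.0         # mm
    sigma: float = 3000.0      # dimensionless
    ks_surface: float = 2e7    # N/m
    ks_internal: float = 8e7   # N/m
    bs: float = 2.5            # kg/s
    hump_exp_sign: int = +1
    sigma_is_squared: bool = False
    # index fractions of each half left without circular muscles
    center_gap_frac: float = 0.1
    margin_frac: float = 0.15

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("curvature mix p must be in [0, 1]")
        if self.n_p < 2:
            raise ValueError("need at least 2 vertices per half")
        if self.hump_exp_sign not in (+1, -1):
            raise ValueError("hump_exp_sign must be +1 or -1")


def segment_angle(i, bp: BellParams):
    """Angle phi(i) (rad, negative) of outline segment i below the horizontal."""
    x = np.asarray(i, dtype=float) / bp.n_p
    return (-bp.alpha * (1.0 - bp.p) * x**bp.n1
            - bp.alpha * bp.p * x**bp.n2)


def subumbrella_outline(bp: BellParams) -> np.ndarray:
    """Vertex coordinates (m) of the relaxed subumbrellar curve, both halves.

    Row layout: right half (indices 0..N_p-1 from center to margin) followed
    by the mirrored left half.
    """
    phi = segment_angle(np.arange(bp.n_p), bp)
    steps = np.full(bp.n_p, bp.r / bp.n_p)
    steps[0] = bp.r / (2 * bp.n_p)
    dxy = steps[:, None] * np.column_stack([np.cos(phi), np.sin(phi)])
    right = np.cumsum(dxy, axis=0)
    left = right * np.array([-1.0, 1.0])
    return np.concatenate([right, left])


def umbrella_height(i, bp: BellParams):
    """Bell height h(i) (m) above subumbrellar vertex i: linear base profile
    plus a Gaussian central hump."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 0) or np.any(i > bp.n_p - 1):
        raise ValueError("vertex index out of range")
    s2 = bp.sigma if bp.sigma_is_squared else bp.sigma**2
    hump = np.exp(bp.hump_exp_sign * i**2 / s2)
    return (bp.c_base * (bp.n_p - i) + bp.c_amp * hump) * MM


def _outline_normals(right: np.ndarray) -> np.ndarray:
    """Unit normals (pointing to the exumbrellar side) of one half outline."""
    tang = np.empty_like(right)
    tang[1:-1] = right[2:] - right[:-2]
    tang[0] = right[1] - right[0]
    tang[-1] = right[-1] - right[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return np.column_stack([-tang[:, 1], tang[:, 0]])


@dataclass
class BellMesh:
    """Vertices, damped springs and muscle attachments of the bell section.

    Vertex order: right subumbrella (N_p), left subumbrella (N_p), right
    exumbrella (N_p), left exumbrella (N_p).  ``springs`` columns are
    (i, j, ks, rest_length); damping is uniform (``bs``).  Circular muscles
    attach at ``circ_attach`` subumbrellar vertices and pull toward the
    center line; radial muscles act along the ``radial_springs`` vertex
    pairs in the margin.
    """

    vertices: np.ndarray        # (4 N_p, 2) m
    springs: np.ndarray         # (n_springs, 4): i, j, ks, rest length
    bs: float
    n_p: int
    circ_attach: np.ndarray     # vertex indices
    radial_springs: np.ndarray  # (n, 2) vertex index pairs
    params: BellParams | None = None

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def subumbrella(self) -> np.ndarray:
        return self.vertices[: 2 * self.n_p]

    @property
    def exumbrella(self) -> np.ndarray:
        return self.vertices[2 * self.n_p:]


def build_bell_mesh(bp: BellParams) -> BellMesh:
    """Construct the full elastic mesh from the outline parameters."""
    np_ = bp.n_p
    sub = subumbrella_outline(bp)
    right, left = sub[:np_], sub[np_:]
    h = umbrella_height(np.arange(np_), bp)
    ex_right = right + h[:, None] * _outline_normals(right)
    ex_left = ex_right * np.array([-1.0, 1.0])
    vertices = np.concatenate([right, left, ex_right, ex_left])

    springs = []

    def add(i, j, ks):
        rl = float(np.linalg.norm(vertices[i] - vertices[j]))
        springs.append((i, j, ks, rl))

    for base in (0, np_, 2 * np_, 3 * np_):  # along each surface chain
        for k in range(np_ - 1):
            add(base + k, base + k + 1, bp.ks_surface)
    add(0, np_, bp.ks_surface)            # bridge the two sub halves
    add(2 * np_, 3 * np_, bp.ks_surface)  # and the two ex halves
    for k in range(np_):                  # connect the surfaces
        add(k, 2 * np_ + k, bp.ks_internal)
        add(np_ + k, 3 * np_ + k, bp.ks_internal)

    lo = int(round(bp.center_gap_frac * np_))
    hi = int(round((1.0 - bp.margin_frac) * np_))
    circ = np.concatenate([np.arange(lo, hi), np_ + np.arange(lo, hi)])
    radial = []
    for base in (0, np_):
        for k in range(hi, np_ - 1):
            radial.append((base + k, base + k + 1))
    return BellMesh(vertices=vertices,
                    springs=np.array(springs, dtype=float),
                    bs=bp.bs, n_p=np_, circ_attach=circ,
                    radial_springs=np.array(radial, dtype=np.int64),
                    params=bp)


def spring_force(x1, x2, v1, v2, rest_length: float, ks: float, bs: float,
                 ) -> np.ndarray:
    """Damped-spring force (N) acting on the vertex at ``x1``.

    Restoring along the connector, zero at rest length with zero relative
    speed; the damping term opposes the rate of change of the connector
    length.  The force on ``x2`` is the negative.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    d = x1 - x2
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise DegenerateGeometryError("coincident spring endpoints")
    u = d / dist
    dldt = float(np.dot(np.asarray(v1, dtype=float)
                        - np.asarray(v2, dtype=float), u))
    return -ks * (1.0 - rest_length / dist) * d - bs * dldt * u


def export_ib2d(mesh: BellMesh, out_dir, name: str = "jellyfish",
                fluid: dict | None = None) -> dict[str, Path]:
    """Write ``.vertex``/``.spring`` structure files plus a YAML manifest.

    The vertex file holds the vertex count followed by one ``x y`` line per
    vertex; the spring file holds the spring count followed by
    ``i j ks rest_length`` lines with 1-based vertex indices.  The manifest
    records the fluid parameters, damping coefficient and the muscle
    attachment map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = mesh.n_vertices
    idx = mesh.springs[:, :2].astype(int)
    if idx.min() < 0 or idx.max() >= n:
        raise ExportError("spring vertex index out of range")
    if mesh.circ_attach.size and (mesh.circ_attach.min() < 0
                                  or mesh.circ_attach.max() >= n):
        raise ExportError("muscle attachment index out of range")

    vertex_path = out_dir / f"{name}.vertex"
    with open(vertex_path, "w") as f:
        f.write(f"{n}\n")
        for x, y in mesh.vertices:
            f.write(f"{x:.16e} {y:.16e}\n")

    spring_path = out_dir / f"{name}.spring"
    with open(spring_path, "w") as f:
        f.write(f"{mesh.springs.shape[0]}\n")
        for i, j, ks, rl in mesh.springs:
            f.write(f"{int(i) + 1} {int(j) + 1} {ks:.16e} {rl:.16e}\n")

    manifest = {
        "fluid": dict(DEFAULT_FLUID if fluid is None else fluid),
        "damping_kg_per_s": mesh.bs,
        "n_vertices": int(n),
        "n_p": int(mesh.n_p),
        "circular_muscle_vertices_1based":
            (mesh.circ_attach + 1).tolist(),
        "radial_muscle_springs_1based":
            (mesh.radial_springs + 1).tolist(),
        "units": {"length": "m", "stiffness": "N/m"},
    }
    if mesh.params is not None:
        manifest["bell_params"] = asdict(mesh.params)
    manifest_path = out_dir / f"{name}.yaml"
    with open(manifest_path, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)
    return {"vertex": vertex_path, "spring": spring_path,
            "manifest": manifest_path}


def read_ib2d(out_dir, name: str = "jellyfish",
              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back exported structure files (round-trip of :func:`export_ib2d`).

    Returns (vertices, springs with 0-based indices, manifest dict).
    """
    out_dir = Path(out_dir)
    with open(out_dir / f"{name}.vertex") as f:
        n = int(f.readline())
        vertices = np.array([[float(v) for v in f.readline().split()]
                             for _ in range(n)])
    with open(out_dir / f"{name}.spring") as f:
        m = int(f.readline())
        springs = np.array([[float(v) for v in f.readline().split()]
                            for _ in range(m)])
    springs[:, 0] -= 1
    springs[:, 1] -= 1
    with open(out_dir / f"{name}.yaml") as f:
        manifest = yaml.safe_load(f)
    return vertices, springs, manifest
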