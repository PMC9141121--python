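"""Virtual load–deflection laboratory: a 3D space-frame beam solver.

A 0.014-inch archwire (d = 0.3556 mm over a ~100 mm span) is an extremely
slender circular beam, and the calibration experiments it is subjected to are
linear (the measured stiffness k = F/x is independent of F).  The wire is
therefore modeled with 2-node space-frame elements — axial (EA), torsional
(GJ) and biaxial Euler–Bernoulli bending (EI) stiffness, 6 DOF per node —
clamped at both ends, loaded with a point force at a station, and solved with
a dense symmetric factorization.  For straight prismatic wires under nodal
point loads the Hermite shape functions make nodal deflections exact, which
gives closed-form oracles (e.g. x = F L^3 / (192 E I) for a clamped-clamped
center load).

Units: geometry in mm, forces in N, E and G supplied in Pa and converted to
N/mm^2 (MPa) internally, so stiffness k = F/x comes out in N/mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import scipy.linalg

from .arch_geometry import WirePath, station_from_chord

__all__ = [
    "Material",
    "BeamModel",
    "LoadCase",
    "BeamSolution",
    "shear_modulus_from",
    "material_preset",
    "discretize",
    "assemble_stiffness",
    "assemble_and_solve",
    "probe_deflection",
]


def shear_modulus_from(E: float, nu: float) -> float:
    """Isotropic shear modulus G = E / (2 (1 + nu))."""
    if E <= 0:
        raise ValueError("E must be positive")
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (-1, 0.5)")
    return E / (2.0 * (1.0 + nu))


@dataclass(frozen=True)
class Material:
    """Linear isotropic material.  SI units (Pa, kg/m^3)."""

    name: str
    density: float
    youngs_modulus: float
    shear_modulus: float
    poisson: float

    def __post_init__(self):
        if self.youngs_modulus <= 0 or self.shear_modulus <= 0:
            raise ValueError("elastic moduli must be positive")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def isotropy_mismatch(self) -> float:
        """Relative deviation of the stored G from E/(2(1+nu)).

        Preset tables may quote a transverse modulus that is not exactly
        consistent with (E, nu); this reports how far off it is.
        """
        g_iso = shear_modulus_from(self.youngs_modulus, self.poisson)
        return abs(self.shear_modulus - g_iso) / self.shear_modulus


def _load_presets() -> dict:
    text = resources.files("orthowire.data").joinpath("materials.json").read_text()
    return json.loads(text)


def material_preset(name: str) -> Material:
    """Load a shipped material preset: nitinol, nicr, bone or enamel."""
    presets = _load_presets()
    if name not in presets or name.startswith("_"):
        valid = [k for k in presets if not k.startswith("_")]
        raise KeyError(f"unknown material {name!r}; presets: {valid}")
    p = presets[name]
    return Material(
        name=p["name"],
        density=p["density_kg_m3"],
        youngs_modulus=p["youngs_modulus_Pa"],
        shear_modulus=p["shear_modulus_Pa"],
        poisson=p["poisson_ratio"],
    )


@dataclass(frozen=True)
class BeamModel:
    """A wire discretized into space-frame elements, clamped at both ends."""

    path: WirePath
    node_stations: np.ndarray  # arc-length positions, mm, strictly increasing
    nodes: np.ndarray  # (n, 3) coordinates, mm
    section_diameter: float
    material: Material

    def __post_init__(self):
        s = np.asarray(self.node_stations, dtype=float)
        if len(s) < 3 or np.any(np.diff(s) <= 0):
            raise ValueError("need >= 3 strictly increasing node stations")
        object.__setattr__(self, "node_stations", s)
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))

    @property
    def n_elements(self) -> int:
        return len(self.node_stations) - 1

    # circular section properties, mm^2 / mm^4
    @property
    def area(self) -> float:
        return np.pi * self.section_diameter**2 / 4.0

    @property
    def bending_inertia(self) -> float:
        return np.pi * self.section_diameter**4 / 64.0

    @property
    def torsion_constant(self) -> float:
        return np.pi * self.section_diameter**4 / 32.0

    def node_at(self, station: float, tol: float = 1e-6) -> int:
        """Index of the node at arc station ``station`` (mm)."""
        i = int(np.argmin(np.abs(self.node_stations - station)))
        if abs(self.node_stations[i] - station) > tol:
            raise KeyError(f"no node at station {station} mm")
        return i


@dataclass(frozen=True)
class LoadCase:
    """A point force at a station given as chord (z) or arc (y) coordinate."""

    station: float
    force: float  # N, magnitude
    direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    frame: str = "z"  # "z": chord coordinate; "y": arc-length coordinate

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector (|d| = 1 within 1e-12)")
        if self.force <= 0:
            raise ValueError("force must be positive")
        if self.frame not in ("z", "y"):
            raise ValueError("frame must be 'z' or 'y'")
        object.__setattr__(self, "direction", d)

    def arc_station(self, path: WirePath) -> float:
        return self.station if self.frame == "y" else station_from_chord(path, self.station)


@dataclass(frozen=True)
class BeamSolution:
    """Nodal displacements (mm) and rotations (rad) of a solved load case."""

    model: BeamModel
    displacements: np.ndarray  # (n_nodes, 6): ux, uy, uz, rx, ry, rz
    load_node: int

    @property
    def load_point_deflection(self) -> float:
        """Translation magnitude at the loaded node, mm."""
        return float(np.linalg.norm(self.displacements[self.load_node, :3]))


# ---------------------------------------------------------------------------


def discretize(
    path: WirePath,
    max_element_length: float = 1.0,
    stations: list[float] | None = None,
    section_diameter: float = 0.3556,
    material: Material | None = None,
) -> BeamModel:
    """Divide a wire into frame elements no longer than ``max_element_length``.

    ``stations`` (arc-length, mm) are inserted as exact node positions so
    loads can be applied and probed at nodes.
    """
    if max_element_length <= 0:
        raise ValueError("max_element_length must be positive")
    L = path.total_length
    if L <= max_element_length:
        raise ValueError("path shorter than one element")
    n_div = int(np.ceil(L / max_element_length))
    s = np.linspace(0.0, L, n_div + 1)
    if stations:
        extra = np.asarray(stations, dtype=float)
        if np.any((extra <= 0) | (extra >= L)):
            raise ValueError("stations must lie strictly inside the span")
        s = np.unique(np.concatenate([s, extra]))
        # drop grid nodes that collide with a requested station
        keep = np.ones(len(s), dtype=bool)
        keep[1:] = np.diff(s) > 1e-9
        s = s[keep]
    nodes = np.vstack([path.point_at(si) for si in s])
    material = material or material_preset("nitinol")
    return BeamModel(
        path=path,
        node_stations=s,
        nodes=nodes,
        section_diameter=section_diameter,
        material=material,
    )


def _element_stiffness_local(E, G, A, Iy, Iz, J, L):
    """12x12 space-frame stiffness in local coordinates (x along the chord)."""
    k = np.zeros((12, 12))
    # axial
    k[np.ix_([0, 6], [0, 6])] += (E * A / L) * np.array([[1, -1], [-1, 1]])
    # torsion
    k[np.ix_([3, 9], [3, 9])] += (G * J / L) * np.array([[1, -1], [-1, 1]])
    # bending about local z (deflection along local y): DOFs v1, rz1, v2, rz2
    kb = (E / L**3) * np.array(
        [
            [12, 6 * L, -12, 6 * L],
            [6 * L, 4 * L**2, -6 * L, 2 * L**2],
            [-12, -6 * L, 12, -6 * L],
            [6 * L, 2 * L**2, -6 * L, 4 * L**2],
        ]
    )
    k[np.ix_([1, 5, 7, 11], [1, 5, 7, 11])] += Iz * kb
    # bending about local y (deflection along local z): DOFs w1, ry1, w2, ry2
    sign = np.array([[1, -1, 1, -1], [-1, 1, -1, 1], [1, -1, 1, -1], [-1, 1, -1, 1]])
    k[np.ix_([2, 4, 8, 10], [2, 4, 8, 10])] += Iy * kb * sign
    return k


def _element_rotation(p0, p1, reference=np.array([0.0, 0.0, 1.0])):
    """3x3 direction-cosine matrix mapping global to local element axes."""
    ex = p1 - p0
    L = np.linalg.norm(ex)
    ex = ex / L
    ref = reference
    if abs(ex @ ref) > 0.999:
        ref = np.array([0.0, 1.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez])


def assemble_stiffness(model: BeamModel) -> np.ndarray:
    """Assemble the global (unconstrained) stiffness matrix, N/mm units."""
    E = model.material.youngs_modulus / 1e6  # Pa -> MPa = N/mm^2
    G = model.material.shear_modulus / 1e6
    A, I, J = model.area, model.bending_inertia, model.torsion_constant
    n = len(model.node_stations)
    K = np.zeros((6 * n, 6 * n))
    for e in range(n - 1):
        p0, p1 = model.nodes[e], model.nodes[e + 1]
        L = np.linalg.norm(p1 - p0)
        if L <= 0:
            raise ValueError(f"zero-length element {e}")
        R = _element_rotation(p0, p1)
        T = scipy.linalg.block_diag(R, R, R, R)
        ke = T.T @ _element_stiffness_local(E, G, A, I, I, J, L) @ T
        dofs = np.r_[6 * e : 6 * e + 6, 6 * (e + 1) : 6 * (e + 1) + 6]
        K[np.ix_(dofs, dofs)] += ke
    return K


class FrameSolver:
    """Clamped-clamped wire solver with a cached factorization.

    Both end nodes are fully fixed (6 DOF each); the reduced stiffness is
    symmetric positive definite and factorized once, so repeated load cases
    (the force sweeps of the calibration protocol) cost one triangular solve
    each.
    """

    def __init__(self, model: BeamModel):
        self.model = model
        n = len(model.node_stations)
        K = assemble_stiffness(model)
        fixed = np.r_[0:6, 6 * (n - 1) : 6 * n]
        self.free = np.setdiff1d(np.arange(6 * n), fixed)
        self._cho = scipy.linalg.cho_factor(K[np.ix_(self.free, self.free)])

    def solve(self, load: LoadCase) -> BeamSolution:
        model = self.model
        s = load.arc_station(model.path)
        node = model.node_at(s, tol=1e-6)
        if node in (0, len(model.node_stations) - 1):
            raise ValueError("load applied at a clamped end")
        n = len(model.node_stations)
        f = np.zeros(6 * n)
        f[6 * node : 6 * node + 3] = load.force * load.direction
        u = np.zeros(6 * n)
        u[self.free] = scipy.linalg.cho_solve(self._cho, f[self.free])
        return BeamSolution(
            model=model, displacements=u.reshape(n, 6), load_node=node
        )


def assemble_and_solve(model: BeamModel, load: LoadCase) -> BeamSolution:
    """One-shot solve of a single load case (see FrameSolver for sweeps)."""
    return FrameSolver(model).solve(load)


def probe_deflection(solution: BeamSolution, station: float, frame: str = "y") -> float:
    """Deflection magnitude (mm) at the node at the given station."""
    s = station if frame == "y" else station_from_chord(solution.model.path, station)
    node = solution.model.node_at(s, tol=1e-6)
    return float(np.linalg.norm(solution.displacements[node, :3]))
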