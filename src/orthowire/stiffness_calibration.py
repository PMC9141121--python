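"""Stiffness calibration protocol for a clamped archwire.

Sweeps point forces over stations along the wire in the beam "virtual
laboratory", computes the elastic constant k = F/x at each (station, force)
pair, verifies that k is independent of F (the linearity signature of the
underlying elasticity), and collapses the sweep into a node table (y, k)
with the implicit (0, 0) node prepended — the input of the sextic force-law
fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arch_geometry import WirePath, station_from_chord
from .beam_fem import BeamModel, FrameSolver, LoadCase, discretize

__all__ = [
    "StiffnessRecord",
    "CalibrationTable",
    "compute_k",
    "run_load_sweep",
    "check_force_invariance",
    "build_node_table",
    "DEFAULT_FORCES_N",
    "DEFAULT_STATIONS_Z_MM",
]

#: the published force sweep, N
DEFAULT_FORCES_N = (0.1, 0.2, 0.3, 0.4, 0.5, 0.8, 0.9, 1.0, 2.0, 5.0, 10.0)
#: chord stations of the published sweeps, mm; "mid" = half the trimmed length
DEFAULT_STATIONS_Z_MM = (10.0, 20.0, 30.0, 40.0, 50.0, "mid")


def compute_k(F: float, x: float) -> float:
    """Elastic constant k = F / x (N/mm)."""
    if x <= 0:
        raise ValueError("deflection x must be positive")
    return F / x


@dataclass(frozen=True)
class StiffnessRecord:
    """One virtual load–deflection experiment row."""

    z: float  # chord station, mm
    y: float  # arc-length station, mm
    F: float  # applied force, N
    x: float  # measured deflection, mm
    k: float  # F/x, N/mm

    def __post_init__(self):
        if min(self.z, self.y, self.F, self.x, self.k) <= 0:
            raise ValueError("all StiffnessRecord fields must be positive")
        if abs(self.k - self.F / self.x) > 1e-9 * self.k:
            raise ValueError("inconsistent record: k != F/x")


@dataclass
class CalibrationTable:
    """Sweep records plus the collapsed (y, k) calibration nodes."""

    records: list[StiffnessRecord]
    nodes: list[tuple[float, float]] = field(default_factory=list)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def station_groups(self) -> dict[float, list[StiffnessRecord]]:
        groups: dict[float, list[StiffnessRecord]] = {}
        for r in self.records:
            groups.setdefault(r.z, []).append(r)
        return groups


def run_load_sweep(
    model: BeamModel,
    stations_z=DEFAULT_STATIONS_Z_MM,
    forces=DEFAULT_FORCES_N,
    direction=None,
) -> CalibrationTable:
    """Run the force sweep at each chord station and tabulate k = F/x.

    The load direction defaults to the normal of the arch's best-fit plane
    (a transverse pull on the wire); the stiffness matrix is factorized once
    and reused across all load cases.
    """
    if direction is None:
        direction = _arch_plane_normal(model.path)
    path = model.path
    L = path.total_length
    # "mid" is the wire middle in arc length (half the trimmed length)
    arc_stations = [
        0.5 * L if s == "mid" else station_from_chord(path, float(s))
        for s in stations_z
    ]
    chord_stations = [
        float(np.linalg.norm(path.point_at(s) - path.samples[0])) if z == "mid" else float(z)
        for z, s in zip(stations_z, arc_stations)
    ]
    model = discretize(
        model.path,
        max_element_length=L / model.n_elements,
        stations=arc_stations,
        section_diameter=model.section_diameter,
        material=model.material,
    )
    solver = FrameSolver(model)
    records = []
    for z, s_arc in zip(chord_stations, arc_stations):
        for F in forces:
            sol = solver.solve(
                LoadCase(station=s_arc, force=float(F), direction=direction, frame="y")
            )
            x = sol.load_point_deflection
            records.append(StiffnessRecord(z=z, y=s_arc, F=float(F), x=x, k=compute_k(F, x)))
    table = CalibrationTable(records=records)
    table.nodes = build_node_table(table, model.path)
    return table


def _arch_plane_normal(path: WirePath) -> np.ndarray:
    pts = path.samples - path.samples.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    n = vt[2]
    return n if n[2] >= 0 else -n


def check_force_invariance(table: CalibrationTable, tol: float = 1e-9) -> dict:
    """Verify that k is independent of F at every station.

    Returns a report dict: per-station relative spread of k, the worst
    spread, and a boolean ``passed``.  Report-only; never raises.
    """
    spreads = {}
    for z, recs in table.station_groups().items():
        ks = np.array([r.k for r in recs])
        spreads[z] = float((ks.max() - ks.min()) / ks.mean()) if len(ks) > 1 else 0.0
    worst = max(spreads.values()) if spreads else 0.0
    return {"per_station_spread": spreads, "max_spread": worst, "tol": tol,
            "passed": worst <= tol}


def build_node_table(table: CalibrationTable, path: WirePath) -> list[tuple[float, float]]:
    """Collapse the sweep into sorted (y, k) calibration nodes.

    Each station's node k is taken from its smallest applied force (all
    forces give the same k under linearity; the spread is available through
    ``check_force_invariance``).  The implicit (0, 0) node — zero stiffness
    lever arm at the clamp — is prepended.
    """
    nodes = [(0.0, 0.0)]
    for z, recs in sorted(table.station_groups().items()):
        rec = min(recs, key=lambda r: r.F)
        nodes.append((rec.y, rec.k))
    ys = [y for y, _ in nodes]
    if len(set(np.round(ys, 9))) != len(ys):
        raise ValueError("duplicate y stations in node table")
    return nodes


# ---------------------------------------------------------------------------
# printed-table import


def load_published_sweeps(filename=None) -> CalibrationTable:
    """Load the bundled published load sweeps (stations z = 10, 20, 51.38 mm).

    The published rows carry no independent y measurement, so y is set equal
    to z here; the published y values live in the bundled node table.
    """
    if filename is None:
        from importlib import resources

        filename = resources.files("orthowire.data").joinpath("load_sweeps_upper.csv")
    df = pd.read_csv(filename)
    records = [
        StiffnessRecord(z=r.z_mm, y=r.z_mm, F=r.F_N, x=r.x_mm, k=compute_k(r.F_N, r.x_mm))
        for r in df.itertuples()
    ]
    return CalibrationTable(records=records)


def load_published_nodes(filename=None, column: str = "k_y"):
    """Load the bundled published (y, k) calibration node table.

    ``column`` selects the stiffness column: ``"k_y"`` (the values the
    published interpolation system uses; default) or ``"K_sweep"`` (the
    values carried over from the sweeps).  The two disagree by a factor of
    10 at y = 20.04 — an inconsistency in the source that the audit reports.
    """
    if filename is None:
        from importlib import resources

        filename = resources.files("orthowire.data").joinpath(
            "calibration_nodes_upper.csv"
        )
    df = pd.read_csv(filename)
    return [(float(y), float(k)) for y, k in zip(df["y_mm"], df[column])]
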