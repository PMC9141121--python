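"""Synthetic dental-arch and archwire geometry.

The downstream stiffness calibration and force evaluation only need a smooth
3D centerline with an arc-length parameterization; the clinical provenance of
that centerline (CBCT, scanning, CAD) is out of scope.  This module generates
parametric U-shaped arch curves, trims them to arch length, measures the two
station coordinates used throughout the pipeline — the curvilinear coordinate
``y`` (cumulative arc length from the wire start) and the chord coordinate
``z`` (straight-line distance from the wire start) — and builds "deformed"
wire paths displaced at bracket sites, from which per-tooth deformations
``x`` are measured.

All coordinates are millimetres in a right-handed frame whose XY plane is the
occlusal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "WirePath",
    "BracketSite",
    "DeformationPair",
    "generate_arch_curve",
    "trim_wire",
    "arc_length_coordinate",
    "chord_coordinate",
    "build_deformed_path",
    "measure_deformation",
    "make_bracket_sites",
]

DEFAULT_PROJECTION_TOL_MM = 0.5
#: default archwire diameter, mm (0.014 inch nitinol)
DEFAULT_WIRE_DIAMETER_MM = 0.3556


class ProjectionError(ValueError):
    """Point too far from the wire centerline to define a station."""


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class WirePath:
    """A 3D wire centerline stored as a densely sampled polyline.

    Parameters
    ----------
    control_points : (n, 3) array
        The points the curve was built from (kept for provenance).
    samples : (m, 3) array
        Dense polyline samples; consecutive samples must be distinct.
    arch : str
        ``"upper"`` or ``"lower"``.
    """

    control_points: np.ndarray
    samples: np.ndarray
    arch: str = "upper"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3 or len(samples) < 2:
            raise ValueError("samples must be an (m >= 2, 3) array")
        seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("samples contain zero-length segments")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(
            self, "control_points", np.asarray(self.control_points, dtype=float)
        )

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arc length at each sample, starting at 0."""
        return _polyline_arclength(self.samples)

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point on the polyline at arc-length station ``s``."""
        s = float(s)
        cs = self.arclength
        if not (-1e-9 <= s <= cs[-1] + 1e-9):
            raise ValueError(f"station s={s} outside [0, {cs[-1]}]")
        s = min(max(s, 0.0), cs[-1])
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, cs, self.samples[:, k])
        return out

    def resample(self, n_samples: int) -> "WirePath":
        """Return a copy resampled at ``n_samples`` uniform arc-length stations.

        A path already uniformly sampled at ``n_samples`` is returned
        unchanged, which makes resampling exactly idempotent.
        """
        if n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        cs = self.arclength
        if len(self.samples) == n_samples:
            # already uniform (to a small fraction of the spacing): no-op,
            # so repeated resampling cannot drift the polyline
            target = np.linspace(0.0, cs[-1], n_samples)
            spacing = cs[-1] / (n_samples - 1)
            if np.abs(cs - target).max() <= 1e-4 * spacing:
                return self
        target = np.linspace(0.0, cs[-1], n_samples)
        pts = np.column_stack(
            [np.interp(target, cs, self.samples[:, k]) for k in range(3)]
        )
        return replace(self, samples=pts)


@dataclass(frozen=True)
class BracketSite:
    """A bracket/tube bonding site: an FDI tooth code plus three guide points.

    The three guide points define the local bracket frame (and hence a force
    direction as the plane normal); they must not be collinear.
    """

    tooth: str
    guide_points: np.ndarray
    arch: str = "upper"
    collinearity_tol: float = 1e-8

    def __post_init__(self):
        gp = np.asarray(self.guide_points, dtype=float)
        if gp.shape != (3, 3):
            raise ValueError("guide_points must be a (3, 3) array")
        object.__setattr__(self, "guide_points", gp)
        n = np.cross(gp[1] - gp[0], gp[2] - gp[0])
        scale = max(
            np.linalg.norm(gp[1] - gp[0]) * np.linalg.norm(gp[2] - gp[0]), 1e-300
        )
        if np.linalg.norm(n) / scale < self.collinearity_tol:
            raise ValueError(f"guide points of site {self.tooth} are collinear")

    @property
    def anchor(self) -> np.ndarray:
        """Centroid of the guide points — the nominal wire attachment point."""
        return self.guide_points.mean(axis=0)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the guide-point plane."""
        gp = self.guide_points
        n = np.cross(gp[1] - gp[0], gp[2] - gp[0])
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class DeformationPair:
    """An undeformed wire, its deformed counterpart, and their correspondences.

    ``correspondences`` maps a tooth code to a pair of matched points
    (on the undeformed and deformed centerlines); the per-tooth deformation
    ``x`` is the Euclidean distance between the two.
    """

    undeformed: WirePath
    deformed: WirePath
    correspondences: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.undeformed.arch != self.deformed.arch:
            raise ValueError("undeformed and deformed paths carry different arch labels")


# ---------------------------------------------------------------------------
# arch curve generation


def generate_arch_curve(
    width: float = 46.0,
    depth: float = 38.0,
    flatness: float = 2.6,
    plane_tilt_deg: float = 0.0,
    total_length: float = 109.68,
    n_samples: int = 2001,
    arch: str = "upper",
    seed: int = 0,
) -> WirePath:
    """Generate a smooth symmetric U-shaped arch curve of exact total length.

    The curve is half of a superellipse ``|X/a|^m + |Y/b|^m = 1`` (``m`` =
    ``flatness``; ``m = 2`` with ``width = 2 depth`` gives a semicircle),
    optionally tilted out of the occlusal plane, then uniform-speed resampled
    and scaled isotropically so the polyline length equals ``total_length``
    exactly.  Deterministic; ``seed`` is accepted for interface uniformity
    with the other generators but no randomness is used here.
    """
    del seed
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if width <= 0 or depth <= 0 or flatness < 1.0:
        raise ValueError("degenerate arch form parameters")

    a, b, m = width / 2.0, depth, flatness
    # dense parameter grid; endpoint singularities of the superellipse are
    # handled by the |.|^(2/m) parametrization below
    t = np.linspace(0.0, np.pi, max(4 * n_samples, 8192))
    x = a * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / m)
    y = b * np.abs(np.sin(t)) ** (2.0 / m)
    pts = np.column_stack([x, y, np.zeros_like(x)])
    if plane_tilt_deg:
        c, s = np.cos(np.radians(plane_tilt_deg)), np.sin(np.radians(plane_tilt_deg))
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
        pts = pts @ rot.T

    path = WirePath(control_points=pts[:: len(t) // 16], samples=pts, arch=arch)
    path = path.resample(n_samples)
    scale = total_length / path.total_length
    scaled = replace(
        path,
        samples=path.samples * scale,
        control_points=path.control_points * scale,
    )
    return scaled


def trim_wire(path: WirePath, target_length: float, mode: str = "symmetric") -> WirePath:
    """Shorten a wire to ``target_length`` by cutting arc length off the ends.

    ``mode="symmetric"`` removes half the excess from each end;
    ``mode="from-end"`` removes it all from the far end.  The removed length
    is ``path.total_length - target_length``.
    """
    L = path.total_length
    if not 0 < target_length <= L + 1e-12:
        raise ValueError(
            f"target_length {target_length} not in (0, {L}]"
        )
    excess = max(L - target_length, 0.0)
    if mode == "symmetric":
        s0, s1 = excess / 2.0, L - excess / 2.0
    elif mode == "from-end":
        s0, s1 = 0.0, L - excess
    else:
        raise ValueError(f"unknown trim mode {mode!r}")

    cs = path.arclength
    inner = (cs > s0 + 1e-12) & (cs < s1 - 1e-12)
    pts = np.vstack([path.point_at(s0), path.samples[inner], path.point_at(s1)])
    return replace(path, samples=pts)


# ---------------------------------------------------------------------------
# station coordinates


def _project(path: WirePath, point, tol: float):
    """Foot of the orthogonal projection of ``point`` on the polyline.

    Returns (s, foot, distance); raises ProjectionError beyond ``tol``.
    """
    p = np.asarray(point, dtype=float)
    a = path.samples[:-1]
    d = np.diff(path.samples, axis=0)
    L2 = np.einsum("ij,ij->i", d, d)
    tpar = np.clip(np.einsum("ij,ij->i", p - a, d) / L2, 0.0, 1.0)
    feet = a + tpar[:, None] * d
    dist = np.linalg.norm(feet - p, axis=1)
    i = int(np.argmin(dist))
    if dist[i] > tol:
        raise ProjectionError(
            f"point {p} is {dist[i]:.4g} mm from the wire (tolerance {tol} mm)"
        )
    s = path.arclength[i] + tpar[i] * np.sqrt(L2[i])
    return float(s), feet[i], float(dist[i])


def arc_length_coordinate(
    path: WirePath, point, tol: float = DEFAULT_PROJECTION_TOL_MM
) -> float:
    """Curvilinear coordinate y: arc length from the wire start to the
    projection of ``point`` onto the centerline."""
    s, _, _ = _project(path, point, tol)
    return s


def chord_coordinate(
    path: WirePath, point, tol: float = DEFAULT_PROJECTION_TOL_MM
) -> float:
    """Chord coordinate z: straight-line distance from the wire start to the
    projection of ``point``.  Always z <= y, with equality on a straight wire."""
    _, foot, _ = _project(path, point, tol)
    return float(np.linalg.norm(foot - path.samples[0]))


def station_from_chord(path: WirePath, z: float) -> float:
    """Invert z -> s: the first arc-length station whose chord distance from
    the wire start equals ``z``.  Monotone along a convex arch hemiarch."""
    chord = np.linalg.norm(path.samples - path.samples[0], axis=1)
    if z < 0 or z > chord.max() + 1e-9:
        raise ValueError(f"chord station z={z} unreachable (max {chord.max():.4g})")
    idx = np.nonzero(chord >= z)[0]
    i = int(idx[0])
    if i == 0:
        return 0.0
    # linear interpolation of s between the bracketing samples
    c0, c1 = chord[i - 1], chord[i]
    f = 0.0 if c1 == c0 else (z - c0) / (c1 - c0)
    cs = path.arclength
    return float(cs[i - 1] + f * (cs[i] - cs[i - 1]))


# ---------------------------------------------------------------------------
# bracket sites and deformed wires


def make_bracket_sites(
    path: WirePath,
    stations: dict,
    arch: str | None = None,
    pad_size: float = 1.5,
) -> list[BracketSite]:
    """Place bracket sites on the wire at given arc-length stations.

    ``stations`` maps FDI tooth codes to arc-length positions (mm).  Each
    site's three guide points form a small triangle spanning the local
    tangent and the occlusal-plane normal, so they are never collinear.
    """
    arch = arch or path.arch
    codes = list(stations)
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate tooth codes")
    sites = []
    for tooth, s in stations.items():
        if not 0 <= s <= path.total_length:
            raise ValueError(f"site {tooth} at s={s} outside the wire span")
        p = path.point_at(s)
        ds = min(pad_size, path.total_length / 100.0)
        tangent = path.point_at(min(s + ds, path.total_length)) - path.point_at(
            max(s - ds, 0.0)
        )
        tangent = tangent / np.linalg.norm(tangent)
        up = np.array([0.0, 0.0, 1.0])
        if abs(tangent @ up) > 0.99:
            up = np.array([0.0, 1.0, 0.0])
        gp = np.vstack(
            [
                p - 0.5 * pad_size * tangent,
                p + 0.5 * pad_size * tangent,
                p + 0.5 * pad_size * up,
            ]
        )
        sites.append(BracketSite(tooth=tooth, guide_points=gp, arch=arch))
    return sites


def build_deformed_path(
    undeformed: WirePath,
    sites: list[BracketSite],
    offsets,
    tol: float = DEFAULT_PROJECTION_TOL_MM,
) -> DeformationPair:
    """Displace the wire at each bracket site and rebuild a smooth deformed path.

    The displacement field is a componentwise cubic spline in arc length that
    is zero at both wire ends and equals the prescribed offset at each site
    anchor; this mimics a wire constrained into displaced bracket slots.
    Correspondences (undeformed anchor, its displaced image projected back
    onto the resampled deformed centerline) are recorded per site.
    """
    offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
    if len(sites) < 2:
        raise ValueError("need at least 2 bracket sites")
    if offsets.shape != (len(sites), 3) or not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be a finite (n_sites, 3) array")

    anchors_s, anchors_p = [], []
    for site in sites:
        s, foot, _ = _project(undeformed, site.anchor, tol=max(tol, 2.0))
        anchors_s.append(s)
        anchors_p.append(foot)
    order = np.argsort(anchors_s)

    L = undeformed.total_length
    knots_s = [0.0] + [anchors_s[i] for i in order] + [L]
    knots_u = [np.zeros(3)] + [offsets[i] for i in order] + [np.zeros(3)]
    if len(set(np.round(knots_s, 9))) != len(knots_s):
        raise ValueError("bracket sites coincide with each other or a wire end")
    spline = CubicSpline(knots_s, np.vstack(knots_u), axis=0, bc_type="natural")

    cs = undeformed.arclength
    deformed_samples = undeformed.samples + spline(cs)
    deformed = WirePath(
        control_points=undeformed.control_points,
        samples=deformed_samples,
        arch=undeformed.arch,
    ).resample(len(undeformed.samples))

    correspondences = {}
    for idx, site in enumerate(sites):
        target = anchors_p[idx] + offsets[idx]
        if np.linalg.norm(offsets[idx]) == 0.0:
            matched = anchors_p[idx]
        else:
            _, matched, _ = _project(
                deformed, target, tol=max(tol, 2.0 + np.linalg.norm(offsets[idx]))
            )
        correspondences[site.tooth] = (anchors_p[idx].copy(), matched.copy())
    return DeformationPair(
        undeformed=undeformed, deformed=deformed, correspondences=correspondences
    )


def measure_deformation(pair: DeformationPair, site: BracketSite | str) -> float:
    """Deformation x at a site: distance between its corresponding points."""
    tooth = site if isinstance(site, str) else site.tooth
    try:
        p_u, p_d = pair.correspondences[tooth]
    except KeyError:
        raise KeyError(f"no correspondence recorded for tooth {tooth}") from None
    return float(np.linalg.norm(p_d - p_u))


# ---------------------------------------------------------------------------
# I/O


def write_wirepath_csv(path: WirePath, filename) -> None:
    """Write the sampled centerline as CSV with header ``s_mm,x_mm,y_mm,z_mm``."""
    import pandas as pd

    cs = path.arclength
    df = pd.DataFrame(
        {
            "s_mm": cs,
            "x_mm": path.samples[:, 0],
            "y_mm": path.samples[:, 1],
            "z_mm": path.samples[:, 2],
        }
    )
    df.to_csv(filename, index=False)


def read_wirepath_csv(filename, arch: str = "upper") -> WirePath:
    import pandas as pd

    df = pd.read_csv(filename)
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return WirePath(control_points=pts[:: max(len(pts) // 16, 1)], samples=pts, arch=arch)


def export_wire_stl(
    path: WirePath,
    filename,
    diameter: float = DEFAULT_WIRE_DIAMETER_MM,
    n_around: int = 12,
) -> None:
    """Export the wire as a swept circular tube (ASCII STL, visualization only)."""
    try:
        import trimesh
    except ImportError as exc:  # pragma: no cover
        raise ImportError("STL export requires the optional 'trimesh' extra") from exc

    pts = path.resample(min(len(path.samples), 400)).samples
    # sweep a circle along the polyline with a parallel-transported frame
    r = diameter / 2.0
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normal = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ normal) > 0.9:
        normal = np.array([0.0, 1.0, 0.0])
    rings = []
    for i in range(len(pts)):
        t = tangents[i]
        normal = normal - (normal @ t) * t
        normal /= np.linalg.norm(normal)
        binorm = np.cross(t, normal)
        ang = np.linspace(0, 2 * np.pi, n_around, endpoint=False)
        ring = pts[i] + r * (np.outer(np.cos(ang), normal) + np.outer(np.sin(ang), binorm))
        rings.append(ring)
    rings = np.asarray(rings)
    faces = []
    for i in range(len(pts) - 1):
        for j in range(n_around):
            a = i * n_around + j
            b = i * n_around + (j + 1) % n_around
            c = (i + 1) * n_around + j
            d = (i + 1) * n_around + (j + 1) % n_around
            faces += [[a, b, c], [b, d, c]]
    mesh = trimesh.Trimesh(vertices=rings.reshape(-1, 3), faces=np.asarray(faces))
    mesh.export(filename)
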