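"""Linear-elastic tet4 FEM on a synthetic tooth-in-bone geometry.

The final stage of the pipeline applies the per-bracket elastic forces to
the supporting tissues and maps their mechanical response.  Patient geometry
is out of reach, so a parameterized synthetic stand-in is meshed instead:
frustum-shaped teeth embedded in a rectangular bone block with bonded
bracket pads on the buccal face.  The mesh is a structured hexahedral grid
split into six tetrahedra per cell (a Kuhn triangulation), which is
conforming and watertight by construction; region labels (tooth / bone /
bracket) partition the elements.

The solver assembles standard 4-node linear tetrahedra (3 DOF/node),
supports prescribed boundary displacements (enabling the constant-strain
patch test), and reports nodal displacements (mm), elemental strain, von
Mises stress (Pa) and strain energy (J), together with the field maxima and
their locations.  Units are mm-N-MPa internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .beam_fem import Material

__all__ = [
    "TetMesh",
    "FieldMap",
    "build_synthetic_tooth_model",
    "build_box_mesh",
    "solve_elasticity",
    "export_maps",
    "mesh_quality",
]

# six tets per cube on local vertex ids (Kuhn / Freudenthal split along the
# main diagonal 0-7); vertices: bit order (i, j, k) -> x + 2y + 4z
_CUBE_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ]
)


@dataclass
class TetMesh:
    """A region-labeled tetrahedral mesh (coordinates in mm)."""

    nodes: np.ndarray  # (n, 3)
    tets: np.ndarray  # (m, 4), positively oriented
    region_labels: np.ndarray  # (m,) strings: tooth | bone | bracket
    pad_nodes: dict = field(default_factory=dict)  # tooth code -> node ids

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels)
        if len(self.region_labels) != len(self.tets):
            raise ValueError("one region label per tet required")
        vols = self.volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{np.sum(vols <= 0)} tets have non-positive volume")
        if len(np.unique(self.tets)) != len(self.nodes):
            raise ValueError("mesh contains unreferenced nodes")

    def volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return (
            np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0
        )

    def region(self, label: str) -> np.ndarray:
        return np.nonzero(self.region_labels == label)[0]

    def boundary_triangles(self) -> np.ndarray:
        """Faces belonging to exactly one tet, outward orientation not enforced."""
        faces = self.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]


def mesh_quality(mesh: TetMesh) -> float:
    """Minimum normalized radius ratio 3*r_in/r_circ over all tets (1 = regular)."""
    p = mesh.nodes[mesh.tets]
    vol = mesh.volumes()
    # face areas
    def tri_area(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    a, b, c, d = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    areas = (
        tri_area(b, c, d) + tri_area(a, c, d) + tri_area(a, b, d) + tri_area(a, b, c)
    )
    r_in = 3.0 * vol / areas
    # circumradius via the Cayley-Menger-free formula
    aa = b - a
    bb = c - a
    cc = d - a
    num = np.linalg.norm(
        np.einsum("ij,i->ij", np.cross(bb, cc), np.einsum("ij,ij->i", aa, aa))
        + np.einsum("ij,i->ij", np.cross(cc, aa), np.einsum("ij,ij->i", bb, bb))
        + np.einsum("ij,i->ij", np.cross(aa, bb), np.einsum("ij,ij->i", cc, cc)),
        axis=1,
    )
    r_circ = num / (12.0 * vol)
    return float(np.min(3.0 * r_in / r_circ))


def _structured_tet_grid(extent, cells, seed=None, jitter=0.0):
    """Grid of ``cells`` cubes over ``extent``, six tets each, optional jitter
    of strictly interior nodes (fraction of the cell size)."""
    W, D, H = extent
    nx, ny, nz = cells
    xs = np.linspace(0, W, nx + 1)
    ys = np.linspace(0, D, ny + 1)
    zs = np.linspace(0, H, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    if jitter > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        h = np.array([W / nx, D / ny, H / nz])
        interior = (
            (nodes[:, 0] > 0) & (nodes[:, 0] < W)
            & (nodes[:, 1] > 0) & (nodes[:, 1] < D)
            & (nodes[:, 2] > 0) & (nodes[:, 2] < H)
        )
        nodes[interior] += (rng.uniform(-jitter, jitter, (interior.sum(), 3))) * h

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corners = np.array(
                    [nid(i + (v & 1), j + ((v >> 1) & 1), k + ((v >> 2) & 1)) for v in range(8)]
                )
                tets.append(corners[_CUBE_TETS])
    tets = np.vstack(tets)
    # enforce positive orientation
    p = nodes[tets]
    neg = np.linalg.det(p[:, 1:] - p[:, :1]) < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    return nodes, tets


def build_box_mesh(extent=(10.0, 2.0, 2.0), cells=(10, 2, 2), region="bone") -> TetMesh:
    """A single-region rectangular bar mesh (oracle and patch-test geometry)."""
    nodes, tets = _structured_tet_grid(extent, cells)
    return TetMesh(
        nodes=nodes, tets=tets, region_labels=np.full(len(tets), region, dtype=object)
    )


def build_synthetic_tooth_model(
    n_teeth: int = 3,
    root_length: float = 12.0,
    crown_radius: float = 3.5,
    root_radius: float = 1.6,
    bone_block=(36.0, 14.0, 20.0),
    cells=(18, 7, 10),
    pad_size: float = 4.0,
    tooth_codes=None,
    seed: int = 0,
    jitter: float = 0.12,
) -> TetMesh:
    """Mesh a simplified segment of alveolar bone with embedded teeth.

    ``n_teeth`` frustum-shaped teeth (radius tapering from ``crown_radius``
    at the occlusal surface to ``root_radius`` at root depth) are embedded in
    a ``bone_block`` (W x D x H mm), with a square bracket pad bonded on the
    buccal face (y = 0) over each tooth.  Region labels are assigned per tet
    by centroid with priority bracket > tooth > bone.  ``seed`` jitters the
    interior nodes slightly so repeated builds with different seeds exercise
    different meshes; the build is deterministic per seed.
    """
    if n_teeth < 1:
        raise ValueError("need at least one tooth")
    W, D, H = bone_block
    pitch = W / n_teeth
    if 2 * crown_radius > pitch or root_length >= H:
        raise ValueError("degenerate geometry: teeth overlap or roots pierce the block")
    nodes, tets = _structured_tet_grid(bone_block, cells, seed=seed, jitter=jitter)
    centers = [(i + 0.5) * pitch for i in range(n_teeth)]
    if tooth_codes is None:
        tooth_codes = [f"1.{i + 1}" for i in range(n_teeth)]
    if len(tooth_codes) != n_teeth:
        raise ValueError("tooth_codes length must equal n_teeth")

    centroids = nodes[tets].mean(axis=1)
    labels = np.full(len(tets), "bone", dtype=object)
    cy = D / 2.0
    for cx in centers:
        depth = (H - centroids[:, 2]) / root_length  # 0 at crown, 1 at apex
        radius = crown_radius + (root_radius - crown_radius) * np.clip(depth, 0, 1)
        in_tooth = (
            (centroids[:, 2] >= H - root_length)
            & (np.hypot(centroids[:, 0] - cx, centroids[:, 1] - cy) <= radius)
        )
        labels[in_tooth] = "tooth"
    pad_depth = D / cells[1]  # one cell layer thick
    z0, z1 = H - 0.45 * root_length - pad_size / 2, H - 0.45 * root_length + pad_size / 2
    pad_nodes: dict = {}
    for cx, code in zip(centers, tooth_codes):
        in_pad = (
            (centroids[:, 1] <= pad_depth)
            & (np.abs(centroids[:, 0] - cx) <= pad_size / 2)
            & (centroids[:, 2] >= z0)
            & (centroids[:, 2] <= z1)
        )
        labels[in_pad] = "bracket"
        on_face = (
            (nodes[:, 1] == 0.0)
            & (np.abs(nodes[:, 0] - cx) <= pad_size / 2 + 1e-9)
            & (nodes[:, 2] >= z0 - 1e-9)
            & (nodes[:, 2] <= z1 + 1e-9)
        )
        pad_nodes[code] = np.nonzero(on_face)[0]
        if len(pad_nodes[code]) == 0:
            raise ValueError(f"mesh too coarse: pad for tooth {code} captured no nodes")

    mesh = TetMesh(nodes=nodes, tets=tets, region_labels=labels, pad_nodes=pad_nodes)
    for region in ("tooth", "bone", "bracket"):
        if len(mesh.region(region)) == 0:
            raise ValueError(f"meshing produced an empty region {region!r}")
    if len(tets) < 200:
        raise ValueError("mesh density too low (< 200 tets)")
    return mesh


# ---------------------------------------------------------------------------
# solver


def _isotropic_C(E_mpa: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness (Voigt order xx, yy, zz, xy, yz, zx), MPa."""
    lam = E_mpa * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E_mpa / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def _element_B_and_volume(nodes, tets):
    """Strain-displacement matrices B (m, 6, 12) and volumes (m,)."""
    p = nodes[tets]
    J = p[:, 1:] - p[:, :1]  # rows: edge vectors
    vol = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    # gradients of the four shape functions
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((len(tets), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B, vol


@dataclass
class FieldMap:
    """Solved fields: displacements (mm), strain, von Mises (Pa), energy (J)."""

    mesh: TetMesh
    nodal_displacement: np.ndarray  # (n, 3) mm
    elemental_strain: np.ndarray  # (m, 6) Voigt, engineering shear
    elemental_von_mises: np.ndarray  # (m,) Pa
    elemental_strain_energy: np.ndarray  # (m,) J
    applied_force: np.ndarray  # (3n,) global load vector, N
    fixed_nodes: np.ndarray
    reactions: np.ndarray  # (len(fixed), 3) N

    @property
    def maxima(self) -> dict:
        cent = self.mesh.nodes[self.mesh.tets].mean(axis=1)
        umag = np.linalg.norm(self.nodal_displacement, axis=1)
        eps = np.abs(self.elemental_strain[:, :3]).max(axis=1)
        i_u = int(np.argmax(umag))
        i_e = int(np.argmax(eps))
        i_s = int(np.argmax(self.elemental_von_mises))
        i_w = int(np.argmax(self.elemental_strain_energy))
        return {
            "displacement": {
                "value_mm": float(umag[i_u]),
                "value_m": float(umag[i_u]) * 1e-3,
                "location_mm": self.mesh.nodes[i_u].tolist(),
            },
            "strain": {
                "value": float(eps[i_e]),
                "location_mm": cent[i_e].tolist(),
            },
            "von_mises": {
                "value_Pa": float(self.elemental_von_mises[i_s]),
                "location_mm": cent[i_s].tolist(),
            },
            "strain_energy": {
                "value_J": float(self.elemental_strain_energy[i_w]),
                "location_mm": cent[i_w].tolist(),
            },
        }

    @property
    def total_strain_energy(self) -> float:
        """J; equals (1/2) u.f for a linear solve with zero fixed displacements."""
        return float(self.elemental_strain_energy.sum())


def bottom_nodes(mesh: TetMesh) -> np.ndarray:
    z0 = mesh.nodes[:, 2].min()
    return np.nonzero(mesh.nodes[:, 2] <= z0 + 1e-9)[0]


def face_load(mesh: TetMesh, node_ids, total_force) -> np.ndarray:
    """Consistent nodal loads for a uniform traction totaling ``total_force``
    over the boundary triangles whose vertices all lie in ``node_ids``."""
    node_set = set(int(i) for i in np.atleast_1d(node_ids))
    tris = [
        t
        for t in mesh.boundary_triangles()
        if all(int(v) in node_set for v in t)
    ]
    if not tris:
        raise ValueError("no boundary triangles span the given node set")
    tris = np.asarray(tris)
    p = mesh.nodes[tris]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    f = np.zeros((len(mesh.nodes), 3))
    total_area = areas.sum()
    for tri, area in zip(tris, areas):
        for v in tri:
            f[v] += np.asarray(total_force) * (area / 3.0) / total_area
    return f.ravel()


def solve_elasticity(
    mesh: TetMesh,
    materials: dict[str, Material],
    forces=None,
    fixed="bottom",
    fixed_values: np.ndarray | None = None,
) -> FieldMap:
    """Solve K u = f on the labeled mesh and derive the result maps.

    Parameters
    ----------
    materials : dict
        Region label -> Material (E, nu in SI; converted to MPa internally).
    forces : optional
        Either a global (3n,) load vector (N), or a list of ToothRecord with
        directions — each record's force is spread as a uniform traction over
        its bracket pad face.
    fixed : "bottom" | array of node ids
        Fully constrained nodes.  ``fixed_values`` optionally prescribes
        their displacements (mm), enabling patch tests; default zero.
    """
    E = {r: m.youngs_modulus / 1e6 for r, m in materials.items()}  # MPa
    nu = {r: m.poisson for r, m in materials.items()}
    missing = set(np.unique(mesh.region_labels)) - set(materials)
    if missing:
        raise KeyError(f"no material for regions {sorted(missing)}")

    B, vol = _element_B_and_volume(mesh.nodes, mesh.tets)
    C = np.empty((len(mesh.tets), 6, 6))
    for region in np.unique(mesh.region_labels):
        idx = mesh.region(region)
        C[idx] = _isotropic_C(E[region], nu[region])
    ke = np.einsum("mji,mjk,mkl,m->mil", B, C, B, vol, optimize=True)

    n = len(mesh.nodes)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = scipy.sparse.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(3 * n, 3 * n)
    ).tocsc()

    if forces is None:
        f = np.zeros(3 * n)
    elif isinstance(forces, np.ndarray) and forces.shape == (3 * n,):
        f = forces.astype(float)
    else:
        f = np.zeros(3 * n)
        for rec in forces:
            if rec.tooth not in mesh.pad_nodes:
                raise KeyError(f"no bracket pad for tooth {rec.tooth}")
            if rec.direction is None:
                raise ValueError(f"record {rec.tooth} has no force direction")
            pad = mesh.pad_nodes[rec.tooth]
            try:
                f += face_load(mesh, pad, rec.F * rec.direction)
            except ValueError:
                # pad face too coarse for whole triangles: split evenly
                fv = rec.F * np.asarray(rec.direction) / len(pad)
                for v in pad:
                    f[3 * v : 3 * v + 3] += fv

    fixed_ids = bottom_nodes(mesh) if isinstance(fixed, str) and fixed == "bottom" else np.asarray(fixed)
    if len(fixed_ids) == 0:
        raise ValueError("no fixed nodes: the structure floats")
    fixed_dofs = (3 * fixed_ids[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(3 * n), fixed_dofs)

    u = np.zeros(3 * n)
    if fixed_values is not None:
        u[fixed_dofs] = np.asarray(fixed_values, dtype=float).ravel()
    rhs = f[free] - K[free][:, fixed_dofs] @ u[fixed_dofs]
    try:
        lu = scipy.sparse.linalg.splu(K[free][:, free].tocsc())
        u[free] = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "singular stiffness matrix: check for floating substructures "
            "or a fully constrained model"
        ) from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError("solver produced non-finite displacements")

    strain = np.einsum("mij,mj->mi", B, u[dof.reshape(len(mesh.tets), 12)])
    stress = np.einsum("mij,mj->mi", C, strain)  # MPa
    s = stress
    vm_mpa = np.sqrt(
        0.5
        * (
            (s[:, 0] - s[:, 1]) ** 2
            + (s[:, 1] - s[:, 2]) ** 2
            + (s[:, 2] - s[:, 0]) ** 2
            + 6.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
        )
    )
    energy_nmm = 0.5 * np.einsum("mi,mi,m->m", stress, strain, vol)
    reactions = (K @ u - f)[fixed_dofs].reshape(-1, 3)

    return FieldMap(
        mesh=mesh,
        nodal_displacement=u.reshape(n, 3),
        elemental_strain=strain,
        elemental_von_mises=vm_mpa * 1e6,
        elemental_strain_energy=energy_nmm * 1e-3,
        applied_force=f,
        fixed_nodes=fixed_ids,
        reactions=reactions,
    )


# ---------------------------------------------------------------------------
# export


def write_vtk(mesh: TetMesh, filename, point_data=None, cell_data=None) -> None:
    """Write a legacy ASCII VTK unstructured grid with optional fields."""
    with open(filename, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\northowire tissue maps\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.nodes)} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        m = len(mesh.tets)
        fh.write(f"CELLS {m} {5 * m}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["10"] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {len(mesh.nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{v:.9g}\n")
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr):
                    fh.write(f"{v:.9g}\n")


def export_maps(fields: FieldMap, mesh: TetMesh, outdir) -> dict:
    """Write the result maps (VTK) and the maxima table (JSON + CSV).

    Returns the paths written.  Output is deterministic: re-exporting the
    same solution produces byte-identical files.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region_id = {"bone": 0, "tooth": 1, "bracket": 2}
    vtk_path = outdir / "tissue_maps.vtk"
    write_vtk(
        mesh,
        vtk_path,
        point_data={"displacement_mm": fields.nodal_displacement},
        cell_data={
            "von_mises_Pa": fields.elemental_von_mises,
            "strain_energy_J": fields.elemental_strain_energy,
            "max_principal_abs_strain": np.abs(fields.elemental_strain[:, :3]).max(axis=1),
            "region": np.array([region_id.get(r, -1) for r in mesh.region_labels], float),
        },
    )
    maxima = fields.maxima
    json_path = outdir / "maxima.json"
    with open(json_path, "w") as fh:
        json.dump(maxima, fh, indent=1, sort_keys=True)
    csv_path = outdir / "maxima.csv"
    with open(csv_path, "w") as fh:
        fh.write("field,value,units\n")
        fh.write(f"displacement,{maxima['displacement']['value_m']:.9g},m\n")
        fh.write(f"strain,{maxima['strain']['value']:.9g},1\n")
        fh.write(f"von_mises,{maxima['von_mises']['value_Pa']:.9g},Pa\n")
        fh.write(f"strain_energy,{maxima['strain_energy']['value_J']:.9g},J\n")
    return {"vtk": vtk_path, "maxima_json": json_path, "maxima_csv": csv_path}
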