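"""Per-tooth elastic forces from measured wire coordinates and deformations.

Each bracket/tube is described by an FDI tooth code, the curvilinear
coordinate y of its site on the wire, and the deformation x between the
undeformed and deformed wire at that site.  The force law gives the force
magnitude F = |k(y) · x^n|; directions are assigned from the bracket
guide-point plane normals, and a summary report flags forces beyond the
~1 N level usually cited as the upper bound of optimal orthodontic force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .arch_geometry import BracketSite
from .force_law import ExtrapolationWarning, SexticForceLaw, evaluate_force

__all__ = [
    "ToothRecord",
    "compute_tooth_forces",
    "assign_directions",
    "summarize",
    "audit_against_published",
    "load_published_measurements",
]

#: commonly cited upper bound of optimal orthodontic force, N
OPTIMAL_FORCE_LIMIT_N = 1.0

_QUADRANT_ARCH = {"1": "upper", "2": "upper", "3": "lower", "4": "lower"}


def _parse_fdi(code: str) -> tuple[int, int]:
    """Validate an FDI code like '4.6' and return (quadrant, position)."""
    parts = str(code).split(".")
    if len(parts) != 2 or not all(p.isdigit() for p in parts):
        raise ValueError(f"malformed FDI tooth code {code!r}")
    q, p = int(parts[0]), int(parts[1])
    if not (1 <= q <= 4 and 1 <= p <= 8):
        raise ValueError(f"FDI code {code!r} out of range (quadrant 1-4, tooth 1-8)")
    return q, p


@dataclass(frozen=True)
class ToothRecord:
    """One bracket/tube: FDI code, wire coordinate y, deformation x, force F."""

    tooth: str
    arch: str
    y: float
    x: float
    F: float = 0.0
    direction: np.ndarray | None = None
    extrapolated: bool = False

    def __post_init__(self):
        q, _ = _parse_fdi(self.tooth)
        if _QUADRANT_ARCH[str(q)] != self.arch:
            raise ValueError(
                f"tooth {self.tooth} is in quadrant {q}, inconsistent with "
                f"arch {self.arch!r}"
            )
        if self.y <= 0 or self.x < 0 or self.F < 0:
            raise ValueError("require y > 0, x >= 0, F >= 0")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            object.__setattr__(self, "direction", d / np.linalg.norm(d))


def compute_tooth_forces(
    records, law: SexticForceLaw, warn_extrapolation: bool = False
) -> list[ToothRecord]:
    """Evaluate F = |k(y) · x^n| for each (tooth, y, x) measurement.

    ``records`` is an iterable of ToothRecord or (tooth, arch, y, x) tuples.
    Entries with y beyond the law's last calibration node are flagged
    ``extrapolated``.  Output is sorted by FDI quadrant, then tooth position.
    """
    out = []
    for rec in records:
        if not isinstance(rec, ToothRecord):
            tooth, arch, y, x = rec
            rec = ToothRecord(tooth=tooth, arch=arch, y=float(y), x=float(x))
        with warnings.catch_warnings():
            if not warn_extrapolation:
                warnings.simplefilter("ignore", ExtrapolationWarning)
            F = evaluate_force(law, rec.x, rec.y)
        out.append(
            replace(rec, F=abs(F), extrapolated=bool(rec.y > law.max_node_y))
        )
    out.sort(key=lambda r: _parse_fdi(r.tooth))
    _check_unique(out)
    return out


def _check_unique(records) -> None:
    seen = set()
    for r in records:
        key = (r.arch, r.tooth)
        if key in seen:
            raise ValueError(f"duplicate tooth code {r.tooth} in arch {r.arch}")
        seen.add(key)


def assign_directions(records, sites: list[BracketSite]) -> list[ToothRecord]:
    """Set each record's force direction to its bracket plane's unit normal."""
    by_tooth = {s.tooth: s for s in sites}
    out = []
    for rec in records:
        try:
            site = by_tooth[rec.tooth]
        except KeyError:
            raise KeyError(f"no bracket site for tooth {rec.tooth}") from None
        out.append(replace(rec, direction=site.normal))
    return out


def summarize(records, force_limit: float = OPTIMAL_FORCE_LIMIT_N) -> dict:
    """Per-arch force statistics and clinically relevant counts."""
    report: dict = {"per_arch": {}, "force_limit_N": force_limit}
    records = list(records)
    for arch in sorted({r.arch for r in records}):
        Fs = np.array([r.F for r in records if r.arch == arch])
        report["per_arch"][arch] = {
            "count": int(len(Fs)),
            "min_N": float(Fs.min()),
            "max_N": float(Fs.max()),
            "mean_N": float(Fs.mean()),
            "total_N": float(Fs.sum()),
        }
    report["n_records"] = len(records)
    report["n_extrapolated"] = sum(r.extrapolated for r in records)
    report["n_exceeding_limit"] = sum(r.F > force_limit for r in records)
    report["exceeding_limit"] = sorted(
        r.tooth for r in records if r.F > force_limit
    )
    return report


# ---------------------------------------------------------------------------
# published-data import and audit


def load_published_measurements(filename=None) -> pd.DataFrame:
    """The bundled per-tooth (FDI, arch, y, x, published F) measurement table."""
    if filename is None:
        from importlib import resources

        filename = resources.files("orthowire.data").joinpath("tooth_measurements.csv")
    return pd.read_csv(filename, dtype={"tooth": str})


def audit_against_published(
    df: pd.DataFrame, laws: dict[str, SexticForceLaw], rel_tol: float = 0.01
) -> pd.DataFrame:
    """Recompute each published force under every candidate coefficient set.

    Returns a per-row audit: the published force, the recomputed force and
    relative error per law, and which laws reproduce the row within
    ``rel_tol``.  Discrepant rows are listed, never corrected.
    """
    rows = []
    for r in df.itertuples():
        row = {
            "tooth": r.tooth,
            "arch": r.arch,
            "y_mm": r.y_mm,
            "x_mm": r.x_mm,
            "F_published_N": r.F_published_N,
        }
        matches = []
        for name, law in laws.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                F = abs(evaluate_force(law, r.x_mm, r.y_mm))
            rel = abs(F - r.F_published_N) / r.F_published_N
            row[f"F_{name}_N"] = F
            row[f"rel_err_{name}"] = rel
            if rel <= rel_tol:
                matches.append(name)
        row["reproduced_by"] = ",".join(matches)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_dataframe(df: pd.DataFrame) -> list[ToothRecord]:
    return [
        ToothRecord(tooth=str(r.tooth), arch=r.arch, y=float(r.y_mm), x=float(r.x_mm))
        for r in df.itertuples()
    ]


def write_forces_csv(records, filename) -> None:
    """Write ``tooth,arch,y_mm,x_mm,F_N,dx,dy,dz,extrapolated`` rows."""
    rows = []
    for r in records:
        d = r.direction if r.direction is not None else (np.nan,) * 3
        rows.append(
            {
                "tooth": r.tooth,
                "arch": r.arch,
                "y_mm": r.y,
                "x_mm": r.x,
                "F_N": r.F,
                "dx": d[0],
                "dy": d[1],
                "dz": d[2],
                "extrapolated": r.extrapolated,
            }
        )
    pd.DataFrame(rows).to_csv(filename, index=False)


def read_forces_csv(filename) -> list[ToothRecord]:
    df = pd.read_csv(filename, dtype={"tooth": str})
    out = []
    for r in df.itertuples():
        direction = None
        if not np.isnan(r.dx):
            direction = np.array([r.dx, r.dy, r.dz])
        out.append(
            ToothRecord(
                tooth=str(r.tooth),
                arch=r.arch,
                y=float(r.y_mm),
                x=float(r.x_mm),
                F=float(r.F_N),
                direction=direction,
                extrapolated=bool(r.extrapolated),
            )
        )
    return out
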