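"""Sextic elastic-constant force law  F = k(y) · x^n.

The position-dependent elastic constant of a clamped archwire is modeled as
a degree-6 polynomial k(y) interpolating exactly seven calibration nodes
(y_i, k_i), one of which is (0, 0) so the constant term g vanishes.  With
g = 0 the remaining six coefficients (a..f, highest power first) solve a
6x6 Vandermonde-type linear system.  The monomial Vandermonde at stations up
to y ~ 60 mm is severely ill-conditioned (cond ~ 1e10), so the solve uses a
pivoted LU factorization plus one step of iterative refinement in extended
precision, and the fit is cross-checked in the tests against an independent
barycentric-interpolation oracle.

The force on a bracket at curvilinear coordinate y with wire deformation x
is F = k(y) · x^n, with n = 1 for metallic wires (n up to 3 supported for
non-metallic ones).  Beyond the last calibration node the sextic blows up,
so extrapolated evaluations are flagged with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "SexticForceLaw",
    "ExtrapolationWarning",
    "fit_sextic",
    "evaluate_k",
    "evaluate_force",
    "published_law",
]

CONDITION_WARN_THRESHOLD = 1e12


class ExtrapolationWarning(UserWarning):
    """Evaluation beyond the span of the calibration nodes."""


class IllConditionedFitWarning(UserWarning):
    """Interpolation system condition number above the audit threshold."""


@dataclass(frozen=True)
class SexticForceLaw:
    """Coefficients (a, b, c, d, e, f, g) of k(y), highest power first.

    Units: k in N/mm with y in mm, so the coefficient of y^p carries units
    N/mm^(p+1).
    """

    coefficients: np.ndarray  # length 7, descending powers y^6 .. y^0
    arch: str = "upper"
    node_set: tuple = field(default_factory=tuple)  # (y, k) provenance
    exponent: int = 1

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (7,):
            raise ValueError("need exactly 7 coefficients (degree 6 .. 0)")
        if self.exponent not in (1, 2, 3):
            raise ValueError("exponent n must be 1, 2 or 3")
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "node_set", tuple(map(tuple, self.node_set)))

    @property
    def a(self):
        return self.coefficients[0]

    @property
    def e(self):
        return self.coefficients[4]

    @property
    def f(self):
        return self.coefficients[5]

    @property
    def g(self):
        return self.coefficients[6]

    @property
    def max_node_y(self) -> float:
        return max((y for y, _ in self.node_set), default=np.inf)

    def to_json(self, filename) -> None:
        payload = {
            "coefficients_desc": [repr(float(c)) for c in self.coefficients],
            "arch": self.arch,
            "nodes": [[y, k] for y, k in self.node_set],
            "exponent": self.exponent,
        }
        with open(filename, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, filename) -> "SexticForceLaw":
        with open(filename) as fh:
            payload = json.load(fh)
        return cls(
            coefficients=np.array([float(c) for c in payload["coefficients_desc"]]),
            arch=payload["arch"],
            node_set=tuple(map(tuple, payload["nodes"])),
            exponent=payload["exponent"],
        )


def fit_sextic(nodes, arch: str = "upper", exponent: int = 1) -> SexticForceLaw:
    """Fit the degree-6 polynomial interpolating exactly seven (y, k) nodes.

    When one node is (0, k0) the constant term is fixed at g = k0 (normally
    0) and the six remaining coefficients solve the 6x6 system; without a
    zero node all seven coefficients are fit together.  Raises on duplicate
    y; warns when the system's condition number exceeds 1e12.  The returned
    law reproduces every node to <= 1e-9 absolute.
    """
    nodes = [(float(y), float(k)) for y, k in nodes]
    if len(nodes) != 7:
        raise ValueError(f"need exactly 7 nodes, got {len(nodes)}")
    ys = np.array([y for y, _ in nodes])
    ks = np.array([k for _, k in nodes])
    if len(np.unique(ys)) != 7:
        raise ValueError("duplicate y values make the interpolation system singular")

    zero = np.isclose(ys, 0.0, atol=1e-12)
    if zero.any():
        g = float(ks[zero][0])
        yy, kk = ys[~zero], ks[~zero] - g
        A = np.vander(yy, 7, increasing=False)[:, :6]  # columns y^6 .. y^1
        coef6 = _solve_refined(A, kk)
        coefficients = np.append(coef6, g)
        cond = np.linalg.cond(A)
    else:
        A = np.vander(ys, 7, increasing=False)
        coefficients = _solve_refined(A, ks)
        cond = np.linalg.cond(A)
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"interpolation system condition number {cond:.3g} exceeds "
            f"{CONDITION_WARN_THRESHOLD:.0e}; coefficients may lose digits",
            IllConditionedFitWarning,
            stacklevel=2,
        )

    law = SexticForceLaw(
        coefficients=coefficients, arch=arch, node_set=nodes, exponent=exponent
    )
    resid = np.max(np.abs(np.polyval(coefficients, ys) - ks))
    if resid > 1e-9:
        raise ArithmeticError(
            f"interpolation residual {resid:.3g} exceeds 1e-9; nodes too ill-posed"
        )
    return law


def _solve_refined(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pivoted LU solve with one step of iterative refinement.

    The residual for the correction step is computed in extended precision
    (math.fsum of float products), which recovers most of the digits lost to
    the Vandermonde conditioning.
    """
    lu = scipy.linalg.lu_factor(A)
    x = scipy.linalg.lu_solve(lu, b)
    import math

    r = np.array(
        [
            math.fsum([A[i, j] * x[j] for j in range(A.shape[1])] + [-b[i]])
            for i in range(A.shape[0])
        ]
    )
    return x - scipy.linalg.lu_solve(lu, r)


def evaluate_k(law: SexticForceLaw, y: float, warn_extrapolation: bool = True) -> float:
    """Evaluate k(y) (N/mm) by Horner's scheme.

    Negative y is a domain error; y beyond the last calibration node emits
    an ExtrapolationWarning (a sextic diverges fast outside its node span).
    The value may legitimately be negative between nodes — the interpolant
    oscillates; force magnitudes are taken downstream.
    """
    y = float(y)
    if y < 0:
        raise ValueError("curvilinear coordinate y must be non-negative")
    if warn_extrapolation and y > law.max_node_y:
        warnings.warn(
            f"y = {y} mm lies beyond the last calibration node "
            f"({law.max_node_y} mm); sextic extrapolation is unreliable",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(np.polyval(law.coefficients, y))


def evaluate_force(
    law: SexticForceLaw, x: float, y: float, warn_extrapolation: bool = True
) -> float:
    """Signed elastic force F = k(y) · x^n (N) for deformation x (mm).

    The restoring force the wire exerts on the bracket is the reaction -F;
    magnitudes are reported by the per-tooth pipeline.
    """
    x = float(x)
    if x < 0:
        raise ValueError("deformation x must be non-negative")
    k = evaluate_k(law, y, warn_extrapolation=warn_extrapolation)
    return k * x**law.exponent


def published_law(arch: str = "upper", validated: bool = True) -> SexticForceLaw:
    """Load a published coefficient set from the bundled data.

    With ``validated=True`` (default) the set returned is the one that
    brute-force evaluation shows actually regenerates the published per-tooth
    force table for ``arch`` — for both arches that is the set published
    under the "upper" label (the published arch labels appear swapped).
    ``validated=False`` returns the set as labeled.
    """
    from importlib import resources

    payload = json.loads(
        resources.files("orthowire.data").joinpath("published_laws.json").read_text()
    )
    key = payload["validated_for"][arch] if validated else arch
    # attach the published calibration nodes so the extrapolation span is known
    from .stiffness_calibration import load_published_nodes

    return SexticForceLaw(
        coefficients=np.array(payload[key]),
        arch=arch,
        node_set=tuple(load_published_nodes()),
    )
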