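import numpy as np
import pytest

from orthowire.arch_geometry import WirePath, generate_arch_curve, trim_wire
from orthowire.beam_fem import material_preset


def straight_path(length=20.0, n=201, direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = np.linspace(0.0, length, n)
    pts = t[:, None] * d
    return WirePath(control_points=pts[:: max(n // 10, 1)], samples=pts)


@pytest.fixture
def straight_wire():
    return straight_path()


@pytest.fixture(scope="session")
def nitinol():
    return material_preset("nitinol")


@pytest.fixture(scope="session")
def arch_wire():
    """A trimmed synthetic upper archwire at the study's lengths."""
    full = generate_arch_curve(total_length=152.12, n_samples=2001)
    return trim_wire(full, 109.68).resample(2001)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
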