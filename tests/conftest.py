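import math

import numpy as np
import pytest

from sphpatch.geometry import (
    SphericalTriangle,
    canonicalize,
    geodesic_params,
)


def canonical_triangle(beta2: float, beta3: float, alpha: float) -> SphericalTriangle:
    """Triangle already in canonical position: pole, (beta3, 0), (beta2, alpha)."""
    return SphericalTriangle(
        (0.0, 0.0, 1.0),
        (math.sin(beta3), 0.0, math.cos(beta3)),
        (
            math.sin(beta2) * math.cos(alpha),
            math.sin(beta2) * math.sin(alpha),
            math.cos(beta2),
        ),
    )


def canonical_frame(beta2: float, beta3: float, alpha: float):
    frame = canonicalize(canonical_triangle(beta2, beta3, alpha), pole_index=1)
    return frame, geodesic_params(frame)


def random_rotation(rng) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
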