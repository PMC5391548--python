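import numpy as np
import pytest

from masscontour import Contour


@pytest.fixture
def unit_square() -> Contour:
    """Anticlockwise square of side 2 with corner at the origin."""
    return Contour(np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]]))


@pytest.fixture
def circle_contour():
    """Dense exact (non-digitized) circle sampler."""

    def make(radius=50.0, center=(0.0, 0.0), n=360):
        theta = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack(
            (center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta))
        )
        return Contour(pts)

    return make


@pytest.fixture
def ellipse_points():
    """Exact parametric ellipse vertex sampler (anticlockwise)."""

    def make(a, b, center=(0.0, 0.0), n=360):
        theta = 2 * np.pi * np.arange(n) / n
        return np.column_stack(
            (center[0] + a * np.cos(theta), center[1] + b * np.sin(theta))
        )

    return make
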