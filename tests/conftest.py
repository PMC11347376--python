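import numpy as np
import pytest

from vesselmorph.shape_io import Contour


@pytest.fixture
def circle() -> Contour:
    """Unit-radius circle sampled at 256 points."""
    t = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    return Contour(np.column_stack([np.cos(t), np.sin(t)]))


@pytest.fixture
def unit_square() -> Contour:
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


def ellipse_contour(a: float, b: float, n: int = 512) -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))
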