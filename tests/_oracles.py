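"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the elliptic Fourier
oracle integrates the arc-length parameterization by dense trapezoidal
quadrature instead of the closed-form segment sums, and the clustering
oracle is scipy's linkage implementation.
"""

from __future__ import annotations

import numpy as np

from vesselmorph.shape_io import Contour, resample_contour


def quadrature_efd(c: Contour, n_harmonics: int, samples: int = 10_000):
    """Fourier coefficients of x(t), y(t) by trapezoidal quadrature.

    The sample count is rounded up to a multiple of the vertex count so that
    every polygon vertex is a quadrature node (the integrand is smooth
    between nodes and the rule converges at O(1/M^2) there).
    """
    m = len(c.points)
    samples = m * int(np.ceil(samples / m))
    r = resample_contour(c, samples)
    pts = np.vstack([r.points, r.points[:1]])  # close the period
    t = np.linspace(0.0, 1.0, samples + 1)
    coeffs = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        cos_t = np.cos(2.0 * np.pi * n * t)
        sin_t = np.sin(2.0 * np.pi * n * t)
        coeffs[n - 1] = [
            2.0 * np.trapezoid(pts[:, 0] * cos_t, t),
            2.0 * np.trapezoid(pts[:, 0] * sin_t, t),
            2.0 * np.trapezoid(pts[:, 1] * cos_t, t),
            2.0 * np.trapezoid(pts[:, 1] * sin_t, t),
        ]
    a0 = np.trapezoid(pts[:, 0], t)
    c0 = np.trapezoid(pts[:, 1], t)
    return a0, c0, coeffs


def scipy_average_linkage(x: np.ndarray) -> np.ndarray:
    """Average-linkage merge heights from scipy, sorted ascending."""
    from scipy.cluster.hierarchy import linkage

    return linkage(x, method="average", metric="euclidean")[:, 2]
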