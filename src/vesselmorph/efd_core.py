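"""Elliptic Fourier analysis of closed vessel outlines.

A closed polygon traversed at constant speed defines periodic coordinate
functions x(t), y(t) with period T (the perimeter). Their truncated Fourier
series

    x(t) = A0 + sum_n [ a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T) ]
    y(t) = C0 + sum_n [ c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T) ]

is the elliptic Fourier expansion; harmonic 1 is the best-fit ellipse of the
outline. Because the traversal is piecewise linear, the Fourier integrals
have the closed form used in :func:`compute_efd` (sums over polygon segments
of the chord slopes times trigonometric differences), which is exact for the
polygon — no quadrature is involved.

Normalization removes everything that is not shape: the starting point on
the outline, rigid rotation, uniform scale, and traversal chirality are all
factored out through the first-harmonic ellipse, after which the per-harmonic
magnitudes

    D_n = sqrt(a_n^2 + b_n^2 + c_n^2 + d_n^2)

are the scalar Fourier descriptors used for morphology classification. By
construction D_1 = sqrt(1 + (minor/major)^2): sqrt(2) for a circle, falling
toward 1 as the best-fit ellipse elongates; D_2.. capture divergence from a
pure ellipse.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .shape_io import Contour, ContourError, polygon_geometry

__all__ = [
    "EFDCoefficients",
    "compute_efd",
    "normalize_efd",
    "descriptors",
    "reconstruct",
    "descriptor_table",
    "write_descriptor_table",
    "read_descriptor_table",
]

DEFAULT_HARMONICS = 20
DEFAULT_DESCRIPTORS = 5


@dataclass(frozen=True)
class EFDCoefficients:
    """Elliptic Fourier coefficients of one closed contour.

    ``harmonics`` is an (N, 4) array with rows (a_n, b_n, c_n, d_n) for
    n = 1..N. ``A0``/``C0`` are the DC offsets (the traversal centroid) in
    pixel units; both are zero after normalization.
    """

    A0: float
    C0: float
    harmonics: np.ndarray
    normalized: bool = False
    vessel_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (N, 4) array")
        object.__setattr__(self, "harmonics", h)
        if self.normalized:
            a1, b1, c1, d1 = h[0]
            if (
                abs(a1 - 1.0) > 1e-9
                or abs(b1) > 1e-9
                or abs(c1) > 1e-9
                or d1 < -1e-9
            ):
                raise ValueError(
                    "normalized coefficients must satisfy a1=1, b1=c1=0, d1>=0"
                )

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)


def compute_efd(c: Contour, n_harmonics: int = DEFAULT_HARMONICS) -> EFDCoefficients:
    """Exact elliptic Fourier coefficients of a closed polygon.

    For each segment p with chord (dx_p, dy_p), length dt_p and cumulative
    arc length t_p:

        a_n = T / (2 n^2 pi^2) * sum_p (dx_p / dt_p)
              * [cos(2 pi n t_p / T) - cos(2 pi n t_{p-1} / T)]

    with b_n using sines and c_n, d_n the analogous y-sums; A0 and C0 come
    from the segmentwise first-moment integrals.
    """
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    pts = c.points
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ContourError("zero-perimeter contour")

    n = np.arange(1, n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * t / T
    cos_diff = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_diff = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (cos_diff @ vx)
    b = const * (sin_diff @ vx)
    cc = const * (cos_diff @ vy)
    dd = const * (sin_diff @ vy)

    # DC terms: integrate the piecewise-linear x(t), y(t) over one period
    xi = np.cumsum(d[:, 0]) - d[:, 0] - (d[:, 0] / dt) * t[:-1]
    delta = np.cumsum(d[:, 1]) - d[:, 1] - (d[:, 1] / dt) * t[:-1]
    A0 = pts[0, 0] + float(
        np.sum((d[:, 0] / (2.0 * dt)) * np.diff(t**2) + xi * dt) / T
    )
    C0 = pts[0, 1] + float(
        np.sum((d[:, 1] / (2.0 * dt)) * np.diff(t**2) + delta * dt) / T
    )
    return EFDCoefficients(
        A0=A0,
        C0=C0,
        harmonics=np.column_stack([a, b, cc, dd]),
        vessel_id=c.vessel_id,
        sample_id=c.sample_id,
    )


def _rotate_start(h: np.ndarray, theta: float) -> np.ndarray:
    """Shift the traversal start by phase theta (right-multiplication)."""
    out = np.empty_like(h)
    for i in range(len(h)):
        n = i + 1
        ct, st = np.cos(n * theta), np.sin(n * theta)
        m = h[i].reshape(2, 2) @ np.array([[ct, -st], [st, ct]])
        out[i] = m.ravel()
    return out


def _candidate(h: np.ndarray, theta: float) -> np.ndarray:
    """Fully normalized coefficients for one choice of start phase."""
    out = _rotate_start(h, theta)
    a1, _, c1, _ = out[0]
    psi = np.arctan2(c1, a1)
    cp, sp = np.cos(psi), np.sin(psi)
    rot = np.array([[cp, sp], [-sp, cp]])
    for i in range(len(out)):
        out[i] = (rot @ out[i].reshape(2, 2)).ravel()
    out /= out[0, 0]
    if out[0, 3] < 0:  # chirality: traversal direction is an imaging artifact
        out[:, 1] *= -1.0
        out[:, 3] *= -1.0
    return out


def normalize_efd(e: EFDCoefficients) -> EFDCoefficients:
    """Remove start point, rotation, scale and chirality from coefficients.

    The start-point phase and orientation are read off the first-harmonic
    ellipse; the coefficients are phase-shifted to start on its semi-major
    axis, rotated to align that axis with x, scaled so a_1 = 1, and reflected
    if needed so d_1 >= 0. The residual half-turn ambiguity (either end of
    the major axis is a valid start) is fixed by choosing the candidate whose
    rounded coefficient sequence is lexicographically larger, which is a
    shape-intrinsic, transform-independent rule.
    """
    if e.normalized:
        return e
    h = e.harmonics
    a1, b1, c1, d1 = h[0]
    if np.hypot(np.hypot(a1, b1), np.hypot(c1, d1)) < 1e-12:
        raise ValueError("degenerate first harmonic; cannot normalize")
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 - b1**2 + c1**2 - d1**2
    )
    # theta and theta + pi/2 are the two semi-axes; start on the major one
    probe = _rotate_start(h[:1], theta)[0]
    if np.hypot(probe[0], probe[2]) < np.hypot(probe[1], probe[3]):
        theta += 0.5 * np.pi
    cand_a = _candidate(h, theta)
    cand_b = _candidate(h, theta + np.pi)
    ra, rb = np.round(cand_a.ravel(), 9), np.round(cand_b.ravel(), 9)
    chosen = cand_a if tuple(ra) >= tuple(rb) else cand_b
    # clamp the exact-by-construction entries
    chosen[0, 0] = 1.0
    chosen[0, 1] = 0.0
    chosen[0, 2] = 0.0
    chosen[0, 3] = abs(chosen[0, 3])
    return replace(e, A0=0.0, C0=0.0, harmonics=chosen, normalized=True)


def descriptors(e: EFDCoefficients, k: int = DEFAULT_DESCRIPTORS) -> np.ndarray:
    """First k scalar Fourier descriptors D_n of normalized coefficients."""
    if not e.normalized:
        raise ValueError("descriptors are defined on normalized coefficients only")
    if k > e.n_harmonics:
        raise ValueError(f"requested {k} descriptors from {e.n_harmonics} harmonics")
    return np.sqrt((e.harmonics[:k] ** 2).sum(axis=1))


def reconstruct(
    e: EFDCoefficients, n_points: int = 256, harmonics: int | None = None
) -> np.ndarray:
    """Inverse elliptic Fourier sum sampled at n_points parameter values."""
    n_h = e.n_harmonics if harmonics is None else harmonics
    if n_h > e.n_harmonics:
        raise ValueError("cannot reconstruct with more harmonics than computed")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, n_h + 1)[:, None]
    arg = 2.0 * np.pi * n * t
    cos_t, sin_t = np.cos(arg), np.sin(arg)
    h = e.harmonics[:n_h]
    x = e.A0 + h[:, 0] @ cos_t + h[:, 1] @ sin_t
    y = e.C0 + h[:, 2] @ cos_t + h[:, 3] @ sin_t
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# descriptor tables
# ---------------------------------------------------------------------------


def descriptor_table(
    contours: list[Contour],
    n_harmonics: int = DEFAULT_HARMONICS,
    k: int = DEFAULT_DESCRIPTORS,
) -> pd.DataFrame:
    """Per-vessel descriptor table: sample_id, vessel_id, D1..Dk, perimeter, area."""
    rows = []
    for c in contours:
        d = descriptors(normalize_efd(compute_efd(c, n_harmonics)), k)
        area, perimeter, _ = polygon_geometry(c)
        rows.append(
            {
                "sample_id": c.sample_id,
                "vessel_id": c.vessel_id,
                **{f"D{i + 1}": d[i] for i in range(k)},
                "perimeter": perimeter,
                "area": area,
            }
        )
    cols = ["sample_id", "vessel_id"] + [f"D{i + 1}" for i in range(k)] + [
        "perimeter",
        "area",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_descriptor_table(
    df: pd.DataFrame,
    path: str | Path,
    n_harmonics: int = DEFAULT_HARMONICS,
    k: int = DEFAULT_DESCRIPTORS,
) -> None:
    """Write a descriptor TSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"# vesselmorph descriptor table\n")
        fh.write(f"# harmonics_computed: {n_harmonics}\n")
        fh.write(f"# descriptors_retained: {k}\n")
        fh.write(
            "# normalization: first-harmonic ellipse; a1=1, b1=c1=0, d1>=0; "
            "D_n = sqrt(a_n^2+b_n^2+c_n^2+d_n^2)\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        body = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(io.StringIO(body), sep="\t")
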