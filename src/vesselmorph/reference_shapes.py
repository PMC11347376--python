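"""Synthetic vessel-outline generator: designed shape classes and tumor samples.

The panel of five designed outline classes — circular, rectangular,
irregular, concave, indented — stands in for the test shapes used to probe
the discriminatory power of elliptic Fourier analysis, and synthetic tumor
"samples" are mixtures of vessels drawn from those classes, mimicking the
three observed tumor-vessel phenotypes (normal, indented, angular). All
shapes are star-convex radial functions r(theta) about the origin, which
rules out self-intersection by construction; smooth periodic noise comes
from a small sum of random low-order angular harmonics.

`render_vessel_field` additionally rasterizes vessel outlines into a label
mask plus a synthetic perivascular stain image whose reach from the vessel
surface differs between the two sides of each vessel, with the ground truth
recorded — the closed-loop fixture for penetration-depth measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .shape_io import Contour, rasterize

__all__ = [
    "SHAPE_CLASSES",
    "SAMPLE_GROUPS",
    "DEFAULT_MIXTURES",
    "ShapeSpec",
    "SyntheticSample",
    "make_shape",
    "make_panel",
    "make_sample_set",
    "default_sample_specs",
    "render_vessel_field",
]

SHAPE_CLASSES = ("circular", "rectangular", "irregular", "concave", "indented")
SAMPLE_GROUPS = ("normal", "indented", "angular")

# group -> mixture over shape classes; "irregular-mild" is the irregular
# recipe at reduced amplitude (see _MILD_IRREGULARITY)
DEFAULT_MIXTURES: dict[str, dict[str, float]] = {
    "normal": {"circular": 0.8, "irregular-mild": 0.2},
    "indented": {"indented": 0.7, "circular": 0.3},
    "angular": {"rectangular": 0.6, "irregular": 0.4},
}

_MILD_IRREGULARITY = 0.08
_DEFAULT_IRREGULARITY = 0.18


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one synthetic vessel outline.

    size is the mean radius in pixels; noise the fractional radial jitter
    applied to every class. Class-specific knobs: aspect (rectangular,
    >= 1), lobes/depth/sharpness (indented), depth (concave),
    irregularity (irregular).
    """

    shape_class: str
    size: float = 60.0
    noise: float = 0.03
    aspect: float = 2.2
    lobes: int = 4
    depth: float = 0.5
    sharpness: float = 4.0
    irregularity: float = _DEFAULT_IRREGULARITY
    seed: int = 0
    n_theta: int = 360

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(
                f"unknown shape class {self.shape_class!r}; "
                f"expected one of {SHAPE_CLASSES}"
            )
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.lobes < 2:
            raise ValueError("indented shapes need >= 2 lobes")
        if self.aspect < 1:
            raise ValueError("aspect ratio must be >= 1")


@dataclass(frozen=True)
class SyntheticSample:
    """One synthetic tumor sample: a mixture of vessel shapes."""

    sample_id: str
    group: str
    n_vessels: int = 20
    weights: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    noise: float = 0.03

    def __post_init__(self) -> None:
        if self.group not in SAMPLE_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {SAMPLE_GROUPS}"
            )
        if self.n_vessels < 1:
            raise ValueError("need at least one vessel per sample")
        w = self.weights or dict(DEFAULT_MIXTURES[self.group])
        total = sum(w.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        object.__setattr__(self, "weights", w)


def _smooth_noise(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth periodic perturbation, unit RMS, from <=4 harmonics."""
    orders = rng.choice(np.arange(2, 7), size=4, replace=False)
    amps = rng.uniform(0.3, 1.0, size=4)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    g = np.zeros_like(theta)
    for o, a, p in zip(orders, amps, phases):
        g += a * np.cos(o * theta + p)
    rms = np.sqrt(np.mean(g**2))
    return g / rms if rms > 0 else g


def _radial_profile(spec: ShapeSpec, rng: np.random.Generator, theta: np.ndarray):
    """Relative radius r(theta)/size for the requested class."""
    cls = spec.shape_class
    if cls == "circular":
        return np.ones_like(theta)
    if cls == "rectangular":
        # superellipse: sharp-cornered oval of the given aspect ratio
        p = 8.0
        phase = rng.uniform(0.0, np.pi)
        a, b = 1.0, 1.0 / spec.aspect
        r = (
            np.abs(np.cos(theta + phase) / a) ** p
            + np.abs(np.sin(theta + phase) / b) ** p
        ) ** (-1.0 / p)
        return r / np.mean(r)
    if cls == "irregular":
        # random low-frequency radial perturbation: every order 3..6 present
        # (random phase, mildly jittered amplitude) so the class forms a
        # coherent cloud in descriptor space while individual outlines differ;
        # order 2 is left out because a dominant 2-lobe dip reads as concave
        orders = np.arange(3, 7)
        amps = rng.uniform(0.9, 1.1, size=orders.size)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=orders.size)
        g = np.zeros_like(theta)
        for o, a, p in zip(orders, amps, phases):
            g += a * np.cos(o * theta + p)
        g *= spec.irregularity / np.sqrt(np.mean(g**2))
        return 1.0 + g
    if cls == "concave":
        # one deep smooth invagination
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        dtheta = np.angle(np.exp(1j * (theta - theta0)))
        return 1.0 - 1.7 * spec.depth * np.exp(-0.5 * (dtheta / 0.8) ** 2)
    if cls == "indented":
        # sharp inward notches at `lobes` equally spaced angles
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        notch = np.maximum(0.0, np.cos(spec.lobes * (theta - theta0)))
        return 1.0 - spec.depth * notch**spec.sharpness
    raise AssertionError(cls)


def make_shape(
    spec: ShapeSpec, vessel_id: str = "", sample_id: str = ""
) -> Contour:
    """Generate one closed outline of the requested class, centered at origin.

    Deterministic given spec.seed. Raises if the parameters push the radial
    function near zero (a self-intersecting or degenerate outline).
    """
    # separate streams for class geometry and jitter, so degenerate class
    # parameters (e.g. indentation depth 0) reduce exactly to the circular
    # recipe at the same seed
    rng_class = np.random.default_rng([spec.seed, 1])
    rng_noise = np.random.default_rng([spec.seed, 0])
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_theta, endpoint=False)
    r = _radial_profile(spec, rng_class, theta)
    if spec.noise > 0:
        r = r * (1.0 + spec.noise * _smooth_noise(theta, rng_noise))
    r = r * spec.size
    if np.min(r) < 0.05 * spec.size:
        raise ValueError(
            f"{spec.shape_class} parameters produce a degenerate "
            "(near self-intersecting) outline"
        )
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(pts, vessel_id=vessel_id, sample_id=sample_id)


def make_panel(
    n_per_class: int = 20,
    noise: float = 0.03,
    seed: int = 0,
    size_range: tuple[float, float] = (40.0, 80.0),
) -> tuple[list[Contour], list[str]]:
    """Reference panel: n_per_class shapes per designed class, with labels.

    Sizes vary uniformly within size_range so that downstream descriptors are
    exercised across scales (they must not depend on size).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root = np.random.default_rng(seed)
    contours: list[Contour] = []
    labels: list[str] = []
    for cls in SHAPE_CLASSES:
        for i in range(n_per_class):
            sub = int(root.integers(0, 2**31 - 1))
            size = float(root.uniform(*size_range))
            spec = ShapeSpec(
                shape_class=cls, size=size, noise=noise, seed=sub
            )
            contours.append(
                make_shape(spec, vessel_id=f"{cls}_{i:03d}", sample_id=cls)
            )
            labels.append(cls)
    return contours, labels


def default_sample_specs(
    n_per_group: int = 8,
    n_vessels: int = 20,
    seed: int = 0,
    noise: float = 0.03,
) -> list[SyntheticSample]:
    """Standard three-group study design: n_per_group samples per phenotype."""
    root = np.random.default_rng(seed)
    specs = []
    for group in SAMPLE_GROUPS:
        for i in range(n_per_group):
            specs.append(
                SyntheticSample(
                    sample_id=f"{group}_{i:02d}",
                    group=group,
                    n_vessels=n_vessels,
                    seed=int(root.integers(0, 2**31 - 1)),
                    noise=noise,
                )
            )
    return specs


def make_sample_set(
    specs: list[SyntheticSample],
) -> tuple[dict[str, list[Contour]], dict[str, str]]:
    """Draw per-sample vessel outlines from each sample's class mixture.

    Returns (contours grouped by sample_id, sample_id -> true group).
    """
    by_sample: dict[str, list[Contour]] = {}
    truth: dict[str, str] = {}
    for s in specs:
        rng = np.random.default_rng(s.seed)
        classes = list(s.weights)
        probs = np.array([s.weights[c] for c in classes])
        contours = []
        for v in range(s.n_vessels):
            drawn = classes[int(rng.choice(len(classes), p=probs))]
            irregularity = _DEFAULT_IRREGULARITY
            if drawn == "irregular-mild":
                drawn, irregularity = "irregular", _MILD_IRREGULARITY
            spec = ShapeSpec(
                shape_class=drawn,
                size=float(rng.uniform(40.0, 80.0)),
                noise=s.noise,
                irregularity=irregularity,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            contours.append(
                make_shape(spec, vessel_id=f"{s.sample_id}_v{v:03d}",
                           sample_id=s.sample_id)
            )
        by_sample[s.sample_id] = contours
        truth[s.sample_id] = s.group
    return by_sample, truth


# ---------------------------------------------------------------------------
# raster rendering for penetration-depth fixtures
# ---------------------------------------------------------------------------


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(major, minor) unit axes of a point set, from its covariance."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, 1], vecs[:, 0]  # eigh sorts ascending


def render_vessel_field(
    contours: list[Contour],
    shape: tuple[int, int],
    reaches: list[tuple[float, float]],
    floor: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Rasterize vessels and paint a perivascular stain with per-side reach.

    Each vessel i gets stain on its two sides (split by the outline's
    principal axis): intensity falls linearly from 1.0 at the vessel surface
    to `floor` at the side's reach, then drops to zero — so any threshold
    below `floor` recovers the full reach. Ground truth (reach_left,
    reach_right and their arithmetic mean, the quantity penetration-depth
    measurement should report) is returned as a DataFrame. Overlapping
    vessels are an error: ground truth must stay unambiguous.
    """
    if len(reaches) != len(contours):
        raise ValueError("need one (left, right) reach pair per contour")
    mask = np.zeros(shape, dtype=np.int32)
    for i, c in enumerate(contours):
        single = rasterize([c], shape, labels=[i + 1])
        if np.any(mask[single > 0]):
            raise ValueError(f"vessel {i + 1} overlaps a previously placed vessel")
        if not np.any(single):
            raise ValueError(f"vessel {i + 1} does not intersect the image")
        mask[single > 0] = i + 1

    # distance from every background pixel to the nearest vessel pixel, and
    # which vessel that is
    dist, (ir, ic) = ndimage.distance_transform_edt(mask == 0, return_indices=True)
    owner = mask[ir, ic]

    stain = np.zeros(shape, dtype=float)
    stain[mask > 0] = 1.0
    rows = []
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, c in enumerate(contours):
        label = i + 1
        left, right = reaches[i]
        vr, vc = np.nonzero(mask == label)
        vessel_xy = np.column_stack([vc, vr]).astype(float)
        _, minor = _principal_axes(vessel_xy)
        center = vessel_xy.mean(axis=0)
        sel = (owner == label) & (mask == 0)
        px = np.column_stack([xx[sel], yy[sel]]).astype(float)
        side = (px - center) @ minor
        reach = np.where(side < 0, left, right)
        d = dist[sel]
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.where(
                (d <= reach) & (reach > 0), 1.0 - (1.0 - floor) * d / reach, 0.0
            )
        stain[yy[sel], xx[sel]] = value
        rows.append(
            {
                "vessel": label,
                "reach_left": left,
                "reach_right": right,
                "reach_mean": 0.5 * (left + right),
            }
        )
    truth = pd.DataFrame(rows)
    return mask, stain, truth
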