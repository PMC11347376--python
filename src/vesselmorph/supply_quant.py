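"""Drug-supply and permeability quantification for tumor vasculature studies.

Formula-backed readouts that accompany the vessel morphometry:

* Miles assay: extravasated Evans blue, read at 620 nm with hemoglobin
  correction A620(corrected) = A620 - A740, converted to dye amount through
  a linear standard curve.
* Doxorubicin biodistribution: tissue fluorescence -> amount via standard
  curve -> percent of the injected dose recovered per gram of tissue
  (%ID/g; the reference bolus is 100 ug).
* Caliper tumor volume V = pi/6 * l * w^2 (l = longer diameter, w = shorter
  perpendicular diameter, both mm).
* Tracer penetration depth: per vessel, the maximal distance from the vessel
  surface reached by stain on each of the vessel's two sides (split by its
  principal axis), averaged; aggregated as the mean over vessels.
* Microvessel density (objects per mm^2) and positive-area fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "StandardCurve",
    "PenetrationResult",
    "evans_blue_corrected",
    "fit_standard_curve",
    "invert_standard_curve",
    "tumor_volume",
    "percent_id_per_gram",
    "penetration_depth",
    "microvessel_density",
    "positive_area_fraction",
]

DEFAULT_INJECTED_DOSE_UG = 100.0  # reference doxorubicin bolus
MIN_VESSELS_PER_FIELD = 10


def evans_blue_corrected(a620: float, a740: float) -> tuple[float, bool]:
    """Hemoglobin-corrected Miles-assay absorbance, A620 - A740.

    Returns (corrected value, warning flag); the flag marks negative results
    (blank-dominated samples), which are returned as-is.
    """
    if not (np.isfinite(a620) and np.isfinite(a740)):
        raise ValueError("absorbances must be finite")
    corrected = a620 - a740
    flagged = corrected < 0
    if flagged:
        warnings.warn(
            f"corrected absorbance {corrected:.4g} < 0 (blank-dominated sample)",
            stacklevel=2,
        )
    return corrected, flagged


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line signal = slope * quantity + intercept."""

    slope: float
    intercept: float
    r_squared: float
    x_min: float
    x_max: float

    def signal(self, quantity: float) -> float:
        return self.slope * quantity + self.intercept


def fit_standard_curve(
    quantities: np.ndarray, signals: np.ndarray
) -> StandardCurve:
    """Ordinary least-squares calibration line through (quantity, signal)."""
    x = np.asarray(quantities, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("standard curve needs >= 2 distinct calibration points")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise ValueError("flat standard curve cannot be inverted")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def invert_standard_curve(
    curve: StandardCurve, signal: float
) -> tuple[float, bool]:
    """Quantity producing the given signal; flags extrapolation."""
    quantity = (signal - curve.intercept) / curve.slope
    extrapolated = not (curve.x_min <= quantity <= curve.x_max)
    if extrapolated:
        warnings.warn(
            f"inverted quantity {quantity:.4g} outside calibration range "
            f"[{curve.x_min:g}, {curve.x_max:g}]",
            stacklevel=2,
        )
    return float(quantity), extrapolated


def tumor_volume(l: float, w: float) -> float:
    """Caliper tumor volume V = pi/6 * l * w^2 (mm, mm -> mm^3)."""
    if l <= 0 or w <= 0:
        raise ValueError("caliper diameters must be positive")
    if w > l:
        warnings.warn(
            "shorter diameter exceeds longer one; swapping (caliper convention)",
            stacklevel=2,
        )
        l, w = w, l
    return np.pi / 6.0 * l * w**2


def percent_id_per_gram(
    amount_per_gram: float, injected_dose: float = DEFAULT_INJECTED_DOSE_UG
) -> float:
    """Percent of the injected dose extracted per gram tissue.

    amount_per_gram and injected_dose must share units (ug by default).
    """
    if injected_dose <= 0:
        raise ValueError("injected dose must be positive")
    return amount_per_gram / injected_dose * 100.0


@dataclass(frozen=True)
class PenetrationResult:
    """Per-vessel and aggregate stain penetration distances (pixels)."""

    per_vessel: pd.DataFrame  # vessel, max_left, max_right, mean, empty_side
    mean_depth: float
    n_vessels: int
    threshold: float
    enough_vessels: bool


def penetration_depth(
    vessel_mask: np.ndarray,
    stain: np.ndarray,
    threshold: float | None = None,
    min_vessels: int = MIN_VESSELS_PER_FIELD,
) -> PenetrationResult:
    """Maximal stain reach from the vessel surface, per side, per vessel.

    Every stain-positive pixel (stain >= threshold; default threshold is
    Otsu's on the stain raster) outside the vessels is assigned to the vessel
    whose surface is nearest (Euclidean distance transform). Each vessel's
    principal axis splits its surroundings into two sides; the per-side
    maximal distance-to-surface is taken, the per-vessel value is the
    arithmetic mean of the two side maxima, and the aggregate is the mean
    over vessels. Sides without stain contribute 0 and are flagged, as is a
    field with fewer than min_vessels vessels.
    """
    mask = np.asarray(vessel_mask)
    stain = np.asarray(stain, dtype=float)
    if mask.shape != stain.shape:
        raise ValueError("vessel mask and stain raster must have the same shape")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("vessel mask contains no vessels")
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(stain))

    dist, (ir, ic) = ndimage.distance_transform_edt(mask == 0, return_indices=True)
    owner = np.where(mask == 0, mask[ir, ic], mask)
    positive = (stain >= threshold) & (mask == 0)

    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    rows = []
    for label in labels:
        vr, vc = np.nonzero(mask == label)
        vxy = np.column_stack([vc, vr]).astype(float)
        centered = vxy - vxy.mean(axis=0)
        _, vecs = np.linalg.eigh(centered.T @ centered)
        minor = vecs[:, 0]
        sel = positive & (owner == label)
        side = (
            np.column_stack([xx[sel], yy[sel]]).astype(float) - vxy.mean(axis=0)
        ) @ minor
        d = dist[sel]
        maxima = []
        empty = False
        for side_sel in (side < 0, side >= 0):
            if np.any(side_sel):
                maxima.append(float(d[side_sel].max()))
            else:
                maxima.append(0.0)
                empty = True
        if empty:
            warnings.warn(
                f"vessel {int(label)}: no stain-positive pixels on one side",
                stacklevel=2,
            )
        rows.append(
            {
                "vessel": int(label),
                "max_left": maxima[0],
                "max_right": maxima[1],
                "mean": 0.5 * (maxima[0] + maxima[1]),
                "empty_side": empty,
            }
        )
    per_vessel = pd.DataFrame(rows)
    enough = len(per_vessel) >= min_vessels
    if not enough:
        warnings.warn(
            f"only {len(per_vessel)} vessel(s) in field; "
            f"at least {min_vessels} recommended per stack",
            stacklevel=2,
        )
    return PenetrationResult(
        per_vessel=per_vessel,
        mean_depth=float(per_vessel["mean"].mean()),
        n_vessels=len(per_vessel),
        threshold=float(threshold),
        enough_vessels=enough,
    )


def microvessel_density(
    n_vessels: int | None = None,
    tissue_area_mm2: float | None = None,
    mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> float:
    """Microvessel density in objects per mm^2.

    Either pass an explicit count and tissue area, or a label mask plus the
    pixel size (um per pixel), in which case the count is the number of
    distinct labels and the area is the full image area.
    """
    if mask is not None:
        mask = np.asarray(mask)
        labels = np.unique(mask)
        n_vessels = int((labels > 0).sum())
        if tissue_area_mm2 is None:
            if pixel_size_um is None:
                raise ValueError("physical density needs pixel_size_um")
            tissue_area_mm2 = mask.size * (pixel_size_um / 1000.0) ** 2
    if n_vessels is None or tissue_area_mm2 is None:
        raise ValueError("need (n_vessels, tissue_area_mm2) or (mask, pixel size)")
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    return n_vessels / tissue_area_mm2


def positive_area_fraction(
    positive_mask: np.ndarray, tissue_mask: np.ndarray
) -> float:
    """Stain-positive tissue fraction, in percent of the tissue area."""
    pos = np.asarray(positive_mask).astype(bool)
    tis = np.asarray(tissue_mask).astype(bool)
    if pos.shape != tis.shape:
        raise ValueError("masks must have the same shape")
    n_tissue = int(tis.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    return 100.0 * int((pos & tis).sum()) / n_tissue
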