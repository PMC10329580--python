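"""C-arm calibration from radiographs.

Three calibration products are derived from board and caliper images:

* per-image **orb detections** — metallic orbs on the calibration board show
  up as dark circular blobs; their intensity-weighted centroids are averaged
  (at least three per image) to obtain the per-image **pivot center**, the
  x-coordinate about which projections rotate with gantry angle;
* the **pivot model** — a family of per-angle polynomials in gantry height
  fitted to all pivot centers, evaluated at unfitted angles by linear
  interpolation between the neighboring fitted angles;
* the **pixel-to-mm scale** — the zero-intercept least-squares slope of
  measured caliper extents in pixels against their known lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import measure

from .errors import (
    ConfigurationError,
    InsufficientOrbsError,
    MissingDataError,
    UnderdeterminedFitError,
)

__all__ = [
    "OrbDetection",
    "PivotModel",
    "CaliperMeasurement",
    "detect_orbs",
    "pivot_center_from_orbs",
    "fit_pivot_model",
    "estimate_px_per_mm",
    "load_radiograph",
]

#: Minimum number of orb centers averaged per image.
MIN_ORBS = 3


@dataclass(frozen=True)
class OrbDetection:
    """A detected orb: sub-pixel center (column, row), blob radius, and a
    normalized detector response in [0, 1]."""

    center_px: tuple
    radius_px: float
    score: float

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ConfigurationError("radius_px must be > 0")
        if not 0.0 <= self.score <= 1.0:
            raise ConfigurationError("score must lie in [0, 1]")


@dataclass(frozen=True)
class CaliperMeasurement:
    """A known physical extent (mm) and its measured extent on the
    radiograph (px)."""

    length_mm: float
    length_px: float

    def __post_init__(self) -> None:
        if not (self.length_mm > 0 and self.length_px > 0):
            raise ConfigurationError("caliper lengths must be > 0")


def load_radiograph(path) -> np.ndarray:
    """Read a grayscale radiograph (PNG/TIFF, 8/16-bit, or DICOM pixel data)
    as a float array scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        arr = pydicom.dcmread(path).pixel_array.astype(float)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path).astype(float)
        if arr.ndim == 3:  # collapse an accidental RGB read
            arr = arr.mean(axis=2)
    top = arr.max()
    return arr / top if top > 0 else arr


def detect_orbs(
    image: np.ndarray,
    threshold: float = 0.5,
    min_radius_px: float = 2.0,
    max_radius_px: float = 30.0,
    smoothing_sigma_px: float = 1.0,
) -> List[OrbDetection]:
    """Detect dark circular blobs (metallic orbs) on a bright radiograph.

    Pipeline: Gaussian smoothing, intensity inversion, absolute threshold,
    connected components, intensity-weighted centroid and equivalent radius
    per component. Components outside the radius band are discarded and the
    result is sorted by x (column).

    Raises
    ------
    InsufficientOrbsError
        If fewer than three orbs survive; the pivot center needs at least
        three averaged orb centers.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise MissingDataError("empty image")
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError("threshold must lie strictly in (0, 1)")
    if not (0 < min_radius_px < max_radius_px):
        raise ConfigurationError("invalid radius band")

    smoothed = ndimage.gaussian_filter(img, smoothing_sigma_px)
    depth = np.clip(threshold - smoothed, 0.0, None)  # darkness below threshold
    labels = measure.label(depth > 0)
    detections: List[OrbDetection] = []
    for region in measure.regionprops(labels, intensity_image=depth):
        r_eq = np.sqrt(region.area / np.pi)
        if not (min_radius_px <= r_eq <= max_radius_px):
            continue
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        w = depth[rows, cols]
        total = w.sum()
        if total <= 0:
            continue
        cx = float((cols * w).sum() / total)
        cy = float((rows * w).sum() / total)
        score = float(np.clip(w.max() / threshold, 0.0, 1.0))
        detections.append(
            OrbDetection(center_px=(cx, cy), radius_px=float(r_eq), score=score)
        )
    detections.sort(key=lambda d: d.center_px[0])
    if len(detections) < MIN_ORBS:
        raise InsufficientOrbsError(
            f"found {len(detections)} orbs; at least {MIN_ORBS} are required"
        )
    return detections


def pivot_center_from_orbs(detections: Sequence[OrbDetection]) -> float:
    """Average the orb center x-coordinates of one image to the pivot
    x-coordinate (px). Requires at least three detections."""
    if len(detections) < MIN_ORBS:
        raise InsufficientOrbsError(
            f"{len(detections)} orb detections; at least {MIN_ORBS} are required"
        )
    return float(np.mean([d.center_px[0] for d in detections]))


@dataclass
class PivotModel:
    """Family of per-angle polynomials mapping gantry height (cm) to the
    pivot x-coordinate (px).

    ``coefficients`` maps each fitted angle to ascending-power polynomial
    coefficients. Evaluation at an unfitted angle linearly interpolates the
    predictions of the two neighboring fitted angles (clamped at the ends of
    the fitted range).
    """

    coefficients: Dict[float, np.ndarray]
    degree: int
    residuals: Dict[float, float]

    @property
    def angles(self) -> np.ndarray:
        return np.array(sorted(self.coefficients))

    def evaluate(self, height_cm: float, angle_deg: float) -> float:
        angles = self.angles
        preds = np.array(
            [
                np.polynomial.polynomial.polyval(height_cm, self.coefficients[a])
                for a in angles
            ]
        )
        return float(np.interp(angle_deg, angles, preds))

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "degree": int(self.degree),
            "angles": {
                float(a): {
                    "coefficients": [float(c) for c in self.coefficients[a]],
                    "residual": float(self.residuals[a]),
                }
                for a in self.coefficients
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PivotModel":
        data = yaml.safe_load(Path(path).read_text())
        coeffs = {
            float(a): np.asarray(entry["coefficients"], dtype=float)
            for a, entry in data["angles"].items()
        }
        residuals = {float(a): float(entry["residual"]) for a, entry in data["angles"].items()}
        return cls(coefficients=coeffs, degree=int(data["degree"]), residuals=residuals)


def fit_pivot_model(
    samples: Iterable[tuple],
    degree: int = 2,
) -> PivotModel:
    """Fit per-angle least-squares polynomials in height to pivot samples.

    Parameters
    ----------
    samples:
        Iterable of ``(height_cm, angle_deg, pivot_x_px)`` triples.
    degree:
        Polynomial degree in height (default 2 — low degree resists
        overfitting the few gantry heights typically imaged).

    Raises
    ------
    UnderdeterminedFitError
        If any fitted angle has fewer than ``degree + 1`` distinct heights.
    """
    rows = [(float(h), float(a), float(p)) for h, a, p in samples]
    if not rows:
        raise MissingDataError("no pivot samples")
    by_angle: Dict[float, list] = {}
    for h, a, p in rows:
        by_angle.setdefault(a, []).append((h, p))
    coefficients: Dict[float, np.ndarray] = {}
    residuals: Dict[float, float] = {}
    for angle, pairs in by_angle.items():
        heights = np.array([h for h, _ in pairs])
        pivots = np.array([p for _, p in pairs])
        if len(np.unique(heights)) < degree + 1:
            raise UnderdeterminedFitError(
                f"angle {angle}°: {len(np.unique(heights))} distinct heights; "
                f"degree {degree} needs at least {degree + 1}"
            )
        coefs = np.polynomial.polynomial.polyfit(heights, pivots, degree)
        fit = np.polynomial.polynomial.polyval(heights, coefs)
        coefficients[angle] = coefs
        residuals[angle] = float(np.sqrt(np.mean((fit - pivots) ** 2)))
    return PivotModel(coefficients=coefficients, degree=degree, residuals=residuals)


def estimate_px_per_mm(measurements: Sequence[CaliperMeasurement]) -> float:
    """Pixel-to-mm conversion: slope of the zero-intercept least-squares fit
    of caliper extents in px on their known lengths in mm.

    The fit is forced through the origin because the mapping is a physical
    proportionality (0 mm maps to 0 px).
    """
    if len(measurements) == 0:
        raise MissingDataError("no caliper measurements")
    mm = np.array([m.length_mm for m in measurements])
    px = np.array([m.length_px for m in measurements])
    return float((mm @ px) / (mm @ mm))


# -- CSV interfaces -------------------------------------------------------


def pivot_samples_from_csv(path) -> List[tuple]:
    """Read pivot samples from CSV with header (height_cm, angle_deg, pivot_x_px)."""
    df = pd.read_csv(path)
    return list(df[["height_cm", "angle_deg", "pivot_x_px"]].itertuples(index=False, name=None))


def pivot_samples_to_csv(samples: Iterable[tuple], path) -> None:
    pd.DataFrame(samples, columns=["height_cm", "angle_deg", "pivot_x_px"]).to_csv(
        path, index=False
    )


def caliper_from_csv(path) -> List[CaliperMeasurement]:
    """Read caliper measurements from CSV with header (length_mm, length_px)."""
    df = pd.read_csv(path)
    return [
        CaliperMeasurement(length_mm=row.length_mm, length_px=row.length_px)
        for row in df.itertuples(index=False)
    ]
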