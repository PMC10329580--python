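"""C-arm imaging geometry.

The mobile C-arm is modeled as a rotating projective imaging device. The
world (image) coordinate frame is anchored at the gantry pivot point,
projected to the center of the reference 90-degree view:

* ``x`` — detector horizontal in the 90° view,
* ``y`` — the gantry rotation axis (table direction); its pixel coordinate
  is unaffected by gantry rotation in parallel mode,
* ``z`` — beam direction at 90° (source above, detector below the table).

The frame is right-handed. Gantry angles are given in degrees everywhere;
90° is the reference (vertical beam) view, and the sweep used for
triangulation is 75°/90°/105°.

Two projection models are available. ``parallel`` treats each view as an
orthographic projection along the beam (rays through the image are
orthogonal to the detector); it is the default because the three-view
triangulation intersects orthogonal rays. ``pinhole`` adds depth-dependent
magnification with the source at a configurable source–detector distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .errors import ConfigurationError, DegenerateGeometryError

__all__ = [
    "GantryPose",
    "Ray",
    "CArmModel",
    "beam_direction",
    "project",
    "pixel_ray",
]

#: Default orbital sweep (degrees) within which poses are considered valid.
DEFAULT_SWEEP_DEG: Tuple[float, float] = (75.0, 105.0)


@dataclass(frozen=True)
class GantryPose:
    """Orbital angle (degrees, 90 = vertical reference beam) and gantry
    height above the floor reference (cm)."""

    angle_deg: float
    height_cm: float = 110.0

    def __post_init__(self) -> None:
        if not self.height_cm > 0:
            raise ConfigurationError(f"height_cm must be > 0, got {self.height_cm}")


@dataclass(frozen=True)
class Ray:
    """A 3D ray: point ``origin_mm`` plus unit ``direction``."""

    origin_mm: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin_mm, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ConfigurationError(f"ray direction must be unit length, |d|={n}")
        object.__setattr__(self, "origin_mm", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin_mm + t * self.direction

    def distance_to(self, point_mm) -> float:
        """Orthogonal distance from a 3D point to the (infinite) ray line."""
        p = np.asarray(point_mm, dtype=float).reshape(3) - self.origin_mm
        return float(np.linalg.norm(p - (p @ self.direction) * self.direction))


def beam_direction(pose: GantryPose) -> np.ndarray:
    """Unit beam direction for a gantry pose.

    The gantry rotates about the image y-axis; at 90° the beam points along
    +z, so the direction is ``(sin(angle-90°), 0, cos(angle-90°))``.
    """
    delta = np.deg2rad(pose.angle_deg - 90.0)
    return np.array([np.sin(delta), 0.0, np.cos(delta)])


@dataclass
class CArmModel:
    """Projection parameters of a calibrated C-arm.

    Parameters
    ----------
    px_per_mm:
        Detector scale (pixels per mm at the pivot plane).
    principal_point_px:
        Pixel coordinate (column, row), 0-based and sub-pixel valued, of the
        pivot point in the 90° image.
    pivot_model:
        Optional calibrated pivot model (see :mod:`hybridnav.calibration`)
        giving the pivot x-coordinate as a function of gantry height and
        angle. When absent, the principal point is used for every view.
    projection_mode:
        ``"parallel"`` (default) or ``"pinhole"``.
    source_detector_distance_mm:
        Required in pinhole mode. The source is placed halfway between
        source and detector from the pivot (isocentric mounting), so the
        nominal magnification at the pivot plane is absorbed into
        ``px_per_mm``.
    sweep_deg:
        Valid orbital range for poses.
    """

    px_per_mm: float
    principal_point_px: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0])
    )
    pivot_model: Optional[object] = None
    projection_mode: str = "parallel"
    source_detector_distance_mm: Optional[float] = None
    sweep_deg: Tuple[float, float] = DEFAULT_SWEEP_DEG

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise ConfigurationError(f"px_per_mm must be > 0, got {self.px_per_mm}")
        if self.projection_mode not in ("parallel", "pinhole"):
            raise ConfigurationError(
                f"projection_mode must be 'parallel' or 'pinhole', got "
                f"{self.projection_mode!r}"
            )
        if self.projection_mode == "pinhole":
            if (
                self.source_detector_distance_mm is None
                or not self.source_detector_distance_mm > 0
            ):
                raise ConfigurationError(
                    "pinhole mode requires source_detector_distance_mm > 0"
                )
        self.principal_point_px = np.asarray(
            self.principal_point_px, dtype=float
        ).reshape(2)

    # -- geometry ---------------------------------------------------------

    def check_pose(self, pose: GantryPose) -> None:
        lo, hi = self.sweep_deg
        if not (lo <= pose.angle_deg <= hi):
            raise ConfigurationError(
                f"gantry angle {pose.angle_deg}° outside sweep range [{lo}, {hi}]"
            )

    def view_axes(self, pose: GantryPose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (u, v, w) axes of the rotated view frame: u = detector
        horizontal, v = detector vertical (= world y), w = beam direction."""
        delta = np.deg2rad(pose.angle_deg - 90.0)
        u = np.array([np.cos(delta), 0.0, -np.sin(delta)])
        v = np.array([0.0, 1.0, 0.0])
        return u, v, beam_direction(pose)

    def principal_point_for(self, pose: GantryPose) -> np.ndarray:
        """Pivot-corrected principal point (column, row) for a view."""
        cx, cy = self.principal_point_px
        if self.pivot_model is not None:
            cx = float(self.pivot_model.evaluate(pose.height_cm, pose.angle_deg))
        return np.array([cx, cy])

    def _source_object_distance(self) -> float:
        assert self.source_detector_distance_mm is not None
        return 0.5 * self.source_detector_distance_mm

    def project(self, point_mm, pose: GantryPose) -> np.ndarray:
        """Project 3D point(s) (mm, world frame) to pixel coordinates.

        Accepts a single point of shape (3,) or an array of shape (n, 3);
        returns shape (2,) or (n, 2) accordingly.
        """
        self.check_pose(pose)
        pts = np.asarray(point_mm, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        u, v, w = self.view_axes(pose)
        xv = pts @ u
        yv = pts @ v
        if self.projection_mode == "pinhole":
            d_so = self._source_object_distance()
            depth = d_so + pts @ w
            if np.any(depth <= 1e-9):
                raise DegenerateGeometryError(
                    "point at or behind the X-ray source in pinhole mode"
                )
            mag = d_so / depth
            xv = xv * mag
            yv = yv * mag
        c = self.principal_point_for(pose)
        px = np.column_stack([c[0] + self.px_per_mm * xv, c[1] + self.px_per_mm * yv])
        return px[0] if single else px

    def pixel_ray(self, pixel, pose: GantryPose) -> Ray:
        """Back-project a pixel to the 3D ray of world points imaged there.

        Parallel mode: the ray passes through the in-plane back-projection
        of the pixel with direction equal to the beam direction (orthogonal
        to the detector). Pinhole mode: the ray runs from the source through
        the pivot-plane point that images at the pixel.
        """
        self.check_pose(pose)
        px = np.asarray(pixel, dtype=float).reshape(2)
        c = self.principal_point_for(pose)
        u, v, w = self.view_axes(pose)
        s = (px[0] - c[0]) / self.px_per_mm
        t = (px[1] - c[1]) / self.px_per_mm
        plane_point = s * u + t * v
        if self.projection_mode == "parallel":
            return Ray(origin_mm=plane_point, direction=w)
        source = -self._source_object_distance() * w
        d = plane_point - source
        return Ray(origin_mm=source, direction=d / np.linalg.norm(d))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "px_per_mm": float(self.px_per_mm),
            "principal_point_px": [float(x) for x in self.principal_point_px],
            "projection_mode": self.projection_mode,
            "source_detector_distance_mm": self.source_detector_distance_mm,
            "sweep_deg": [float(self.sweep_deg[0]), float(self.sweep_deg[1])],
        }

    def to_yaml(self, path, pivot_model_path: Optional[str] = None) -> None:
        data = self.to_dict()
        if pivot_model_path is not None:
            data["pivot_model_path"] = str(pivot_model_path)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CArmModel":
        data = yaml.safe_load(Path(path).read_text())
        pivot = None
        pivot_path = data.pop("pivot_model_path", None)
        if pivot_path:
            from .calibration import PivotModel

            resolved = Path(pivot_path)
            if not resolved.is_absolute():
                resolved = Path(path).parent / resolved
            pivot = PivotModel.from_yaml(resolved)
        sweep = tuple(data.pop("sweep_deg", DEFAULT_SWEEP_DEG))
        return cls(pivot_model=pivot, sweep_deg=sweep, **data)


def project(point_mm, pose: GantryPose, model: CArmModel) -> np.ndarray:
    """Functional form of :meth:`CArmModel.project`."""
    return model.project(point_mm, pose)


def pixel_ray(pixel, pose: GantryPose, model: CArmModel) -> Ray:
    """Functional form of :meth:`CArmModel.pixel_ray`."""
    return model.pixel_ray(pixel, pose)
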