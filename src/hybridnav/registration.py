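"""Three-view triangulation, rigid EMT-to-image registration, error metrics.

A navigation step yields a *snapshot triplet*: the sensor's 2D detection at
gantry angles 75°, 90° and 105°. The 3D sensor position is the least-squares
intersection of the three back-projected rays (closed-form normal
equations). The stream of triangulated positions and the matching EMT
samples form two corresponding point sets which are aligned by rigid
(rotation + translation) least-squares registration; tracking accuracy is
reported as per-axis RMSE plus a combined RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .carm import CArmModel, GantryPose
from .errors import ConfigurationError, DegenerateGeometryError
from . import carm

__all__ = [
    "SnapshotTriplet",
    "RigidTransform",
    "ErrorReport",
    "triangulate",
    "triangulate_rays",
    "rigid_register",
    "apply_transform",
    "error_report",
]

#: The three orbital angles of one acquisition triplet (degrees).
TRIPLET_ANGLES: Tuple[float, float, float] = (75.0, 90.0, 105.0)


@dataclass
class SnapshotTriplet:
    """Per-angle 2D detections (column, row, px) for one navigation step."""

    detections: Dict[float, np.ndarray]
    timestamp_s: float = 0.0
    pose_height_cm: float = 110.0
    angles: Tuple[float, ...] = TRIPLET_ANGLES

    def __post_init__(self) -> None:
        self.detections = {
            float(a): np.asarray(p, dtype=float).reshape(2)
            for a, p in self.detections.items()
        }
        missing = set(self.angles) - set(self.detections)
        if missing:
            raise ConfigurationError(f"triplet missing angles: {sorted(missing)}")
        extra = set(self.detections) - set(self.angles)
        if extra:
            raise ConfigurationError(f"triplet has unexpected angles: {sorted(extra)}")


@dataclass
class RigidTransform:
    """Proper rigid transform y = R x + t (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise ConfigurationError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ConfigurationError("rotation must have determinant +1")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "rotation": [float(x) for x in self.rotation.reshape(9)],  # row-major
            "translation": [float(x) for x in self.translation],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RigidTransform":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            rotation=np.asarray(data["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(data["translation"], dtype=float),
        )


@dataclass(frozen=True)
class ErrorReport:
    """Per-axis RMSE (mm) and the combined RMSE = sqrt(mean of the three
    per-axis mean squared errors)."""

    e_x: float
    e_y: float
    e_z: float
    n: int
    rmse: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "rmse",
            float(np.sqrt((self.e_x**2 + self.e_y**2 + self.e_z**2) / 3.0)),
        )

    def as_dict(self) -> dict:
        return {
            "e_x": self.e_x,
            "e_y": self.e_y,
            "e_z": self.e_z,
            "rmse": self.rmse,
            "n": self.n,
        }

    def summary(self) -> str:
        return (
            f"n={self.n}  E_X={self.e_x:.2f} mm  E_Y={self.e_y:.2f} mm  "
            f"E_Z={self.e_z:.2f} mm  RMSE={self.rmse:.2f} mm"
        )


def triangulate_rays(rays: Sequence[carm.Ray]) -> np.ndarray:
    """Point minimizing the sum of squared distances to a set of rays.

    Solves the normal equations sum(I - d dᵀ) p = sum((I - d dᵀ) o). Raises
    :class:`DegenerateGeometryError` when all rays are (anti)parallel, in
    which case the system is singular along the common direction.
    """
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for ray in rays:
        P = np.eye(3) - np.outer(ray.direction, ray.direction)
        A += P
        b += P @ ray.origin_mm
    # Smallest eigenvalue of A is sum_i sin^2(angle to best common axis);
    # zero iff all rays share a direction.
    eigvals = np.linalg.eigvalsh(A)
    if eigvals[0] < 1e-9 * max(len(rays), 1):
        raise DegenerateGeometryError("all rays are parallel; intersection undefined")
    return np.linalg.solve(A, b)


def triangulate(triplet: SnapshotTriplet, model: CArmModel) -> np.ndarray:
    """Reconstruct the 3D sensor position (mm) from a snapshot triplet.

    Back-projects each per-angle detection to a ray and returns the
    least-squares ray intersection. Works for two or more views through the
    same normal-equations path; three views is the standard acquisition.
    """
    rays = [
        model.pixel_ray(pixel, GantryPose(angle_deg=a, height_cm=triplet.pose_height_cm))
        for a, pixel in sorted(triplet.detections.items())
    ]
    return triangulate_rays(rays)


def rigid_register(source, target) -> RigidTransform:
    """Least-squares rigid alignment of corresponding point sets.

    Centroid alignment followed by orthogonal Procrustes (SVD) with the
    proper-rotation correction, so the returned rotation always has
    determinant +1 even when the unconstrained optimum is a reflection.
    Correspondence is positional: ``source[i]`` pairs with ``target[i]``.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    dst = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ConfigurationError("source and target must have equal shapes")
    if len(src) < 3:
        raise DegenerateGeometryError("rigid registration needs at least 3 points")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    # Collinear sources leave a free rotation about the line.
    if np.linalg.matrix_rank(sc, tol=1e-9 * max(1.0, np.abs(sc).max())) < 2:
        raise DegenerateGeometryError("source points are collinear")
    H = sc.T @ dc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return RigidTransform(rotation=R, translation=t)


def apply_transform(transform: RigidTransform, points) -> np.ndarray:
    """Apply y = R x + t to one point (3,) or a stack (n, 3)."""
    return transform.apply(points)


def error_report(estimates, references) -> ErrorReport:
    """Tracking-error report between estimated and reference positions.

    Per-axis error is the RMSE of the coordinate differences; the combined
    RMSE is the root of the mean of the three per-axis mean squared errors.
    """
    est = np.asarray(estimates, dtype=float).reshape(-1, 3)
    ref = np.asarray(references, dtype=float).reshape(-1, 3)
    if est.shape != ref.shape:
        raise ConfigurationError("estimates and references must have equal shapes")
    if len(est) == 0:
        raise ConfigurationError("error report needs at least one pair")
    diff = est - ref
    ex, ey, ez = np.sqrt(np.mean(diff**2, axis=0))
    return ErrorReport(e_x=float(ex), e_y=float(ey), e_z=float(ez), n=len(est))


# -- CSV interfaces -------------------------------------------------------


def triplets_from_csv(path) -> List[SnapshotTriplet]:
    """Read triplets from CSV with header (step, angle_deg, u_px, v_px,
    timestamp_s); one row per view, three rows per step."""
    df = pd.read_csv(path)
    triplets: List[SnapshotTriplet] = []
    for step, group in df.groupby("step", sort=True):
        detections = {
            float(row.angle_deg): np.array([row.u_px, row.v_px])
            for row in group.itertuples(index=False)
        }
        triplets.append(
            SnapshotTriplet(
                detections=detections,
                timestamp_s=float(group["timestamp_s"].iloc[0]),
            )
        )
    return triplets


def triplets_to_csv(triplets: Iterable[SnapshotTriplet], path) -> None:
    rows = []
    for step, trip in enumerate(triplets):
        for angle, px in sorted(trip.detections.items()):
            rows.append(
                {
                    "step": step,
                    "angle_deg": angle,
                    "u_px": px[0],
                    "v_px": px[1],
                    "timestamp_s": trip.timestamp_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def emt_points_from_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read an EMT stream from CSV (timestamp_s, x_mm, y_mm, z_mm); returns
    (timestamps, points)."""
    df = pd.read_csv(path)
    return (
        df["timestamp_s"].to_numpy(dtype=float),
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
    )


def emt_points_to_csv(timestamps, points, path) -> None:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    pd.DataFrame(
        {
            "timestamp_s": np.asarray(timestamps, dtype=float),
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2],
        }
    ).to_csv(path, index=False)
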