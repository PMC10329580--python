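"""Synthetic C-arm / EMT study generator.

Everything the navigation pipeline consumes can be generated here without
hardware: a smooth spatially varying EMT distortion field whose per-axis
RMS magnitudes are configurable (defaults are Z-dominant, ~2/1.7/23 mm,
the scale of uncompensated EMT error next to a C-arm), a 60-step x 2 mm
guidewire retraction, the 25x25 Lego-board training grid with off-grid
validation points, rendered calibration/sensor radiographs with known
ground truth, analog-video frame averaging, and the automated acquisition
timing model (1.0 s gantry setup, 4 deg/s rotation, 100 ms exposures).

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .carm import CArmModel, GantryPose
from .errors import ConfigurationError
from .registration import TRIPLET_ANGLES, SnapshotTriplet, triangulate
from .compensation import TrainingSet

__all__ = [
    "DistortionField",
    "Trajectory",
    "AcquisitionTimingModel",
    "RadiographScene",
    "generate_distortion_field",
    "generate_retraction",
    "generate_lego_grid",
    "render_radiograph",
    "average_frames",
    "schedule_triplet",
    "default_carm_model",
    "dataset_manifest",
    "simulate_study",
]

#: Detector scale chosen so integer-pixel quantization produces the
#: canonical 0.32 mm position noise: sigma = px_size / sqrt(12).
DEFAULT_PX_PER_MM = 1.0 / (0.32 * np.sqrt(12.0))

#: Lego stud pitch (mm) of the training board and brick height (mm) of the
#: sensor-fixture risers.
LEGO_PITCH_MM = 8.0
LEGO_BRICK_MM = 9.6

#: Default workspace (mm) over which distortion-field RMS amplitudes are
#: normalized: the Lego-board extent plus the sensor excursion above it.
DEFAULT_WORKSPACE = np.array([[-96.0, 96.0], [-96.0, 96.0], [0.0, 48.0]])


# ---------------------------------------------------------------------------
# Distortion field
# ---------------------------------------------------------------------------


class DistortionField:
    """Smooth, seeded 3D -> 3D EMT displacement field.

    Per axis the displacement is an affine trend (a dominant constant
    offset plus a mild gradient) and a sum of low-frequency sinusoids
    (infinitely differentiable), normalized post hoc so the RMS
    displacement of each axis over the workspace equals the requested
    amplitude, with ``nonlinear_fraction`` of the displacement variance in
    the genuinely non-affine sinusoid residual. The default amplitudes are
    Z-dominant, mimicking metal-induced distortion along the beam axis.

    Parameters
    ----------
    amplitudes_mm:
        Target per-axis RMS displacement over the workspace.
    length_scale_mm:
        Shortest sinusoid wavelength; wavelengths are drawn from
        [length_scale, 2 x length_scale]. The default (600 mm) is about
        three workspace diameters: metal-induced EMT distortion varies on
        the scale of the C-arm geometry, so across the workspace it is a
        dominantly affine warp with mild curvature.
    nonlinear_fraction:
        Fraction of per-axis displacement variance that is genuinely
        non-affine over the workspace (the rest is the affine trend).
        The small default reflects distortion that is dominantly an
        affine warp across a compact workspace, with mild curvature that
        only a higher-order correction can remove.
    workspace:
        (3, 2) axis-aligned bounds (mm) over which amplitudes are
        normalized.
    seed:
        Seeds frequencies, phases and trend directions; the field is a
        deterministic function of (parameters, seed).
    """

    N_WAVES = 12  # sinusoid components per axis
    OFFSET_SHARE = 0.97  # share of affine-trend variance in the constant term
    _N_NORM = 20000  # Monte Carlo sample used to normalize RMS

    def __init__(
        self,
        amplitudes_mm=(2.0, 1.7, 23.0),
        length_scale_mm: float = 600.0,
        nonlinear_fraction: float = 0.05,
        workspace=DEFAULT_WORKSPACE,
        seed: int = 0,
    ) -> None:
        amps = np.asarray(amplitudes_mm, dtype=float).reshape(3)
        if np.any(amps < 0):
            raise ConfigurationError("distortion amplitudes must be >= 0")
        if not 0.0 <= nonlinear_fraction <= 1.0:
            raise ConfigurationError("nonlinear_fraction must lie in [0, 1]")
        if not length_scale_mm > 0:
            raise ConfigurationError("length_scale_mm must be > 0")
        self.amplitudes_mm = amps
        self.length_scale_mm = float(length_scale_mm)
        self.nonlinear_fraction = float(nonlinear_fraction)
        self.workspace = np.asarray(workspace, dtype=float).reshape(3, 2)
        self.seed = int(seed)

        rng = np.random.default_rng(self.seed)
        center = self.workspace.mean(axis=1)
        halfwidth = np.maximum((self.workspace[:, 1] - self.workspace[:, 0]) / 2, 1e-9)
        self._center = center
        self._halfwidth = halfwidth

        # Random wave vectors (unit direction / wavelength) and phases.
        directions = rng.normal(size=(3, self.N_WAVES, 3))
        directions /= np.linalg.norm(directions, axis=2, keepdims=True)
        wavelengths = rng.uniform(
            self.length_scale_mm, 2.0 * self.length_scale_mm, size=(3, self.N_WAVES)
        )
        self._wave_k = 2.0 * np.pi * directions / wavelengths[:, :, None]
        self._phases = rng.uniform(0.0, 2.0 * np.pi, size=(3, self.N_WAVES))
        self._wave_w = rng.normal(size=(3, self.N_WAVES))  # relative weights
        # Affine trend per axis: a dominant constant offset plus a mild
        # gradient. Distortion of this magnitude varies on the scale of the
        # C-arm, far larger than the workspace, so within the workspace it
        # is mostly bias; the 97/3 variance split also bounds the
        # displacement slope at ~0.3 x amplitude / halfwidth, keeping the
        # EMT map fold-free (invertible) for every seed.
        signs = np.where(rng.random(3) < 0.5, -1.0, 1.0)
        grad_dirs = rng.normal(size=(3, 3))
        grad_dirs /= np.linalg.norm(grad_dirs, axis=1, keepdims=True)
        self._trend = np.column_stack(
            [signs * np.sqrt(self.OFFSET_SHARE),
             np.sqrt((1.0 - self.OFFSET_SHARE) * 3.0) * grad_dirs]
        )  # (3, 4): unit-RMS constant + gradient over the workspace

        # Normalize trend and sinusoid parts to the requested variance split
        # by Monte Carlo over the workspace. The affine component of the
        # sinusoids (long wavelengths are nearly affine over the workspace)
        # is projected out first, so nonlinear_fraction is the share of
        # genuinely non-affine displacement variance regardless of the
        # frequency draw.
        sample = rng.uniform(
            self.workspace[:, 0], self.workspace[:, 1], size=(self._N_NORM, 3)
        )
        A = self._affine_design(sample)
        self._wave_affine, *_ = np.linalg.lstsq(A, self._wave_raw(sample), rcond=None)
        trend_raw = self._trend_raw(sample)
        wave_nl = self._wave_raw(sample) - A @ self._wave_affine
        trend_rms = np.sqrt(np.mean(trend_raw**2, axis=0))
        wave_rms = np.sqrt(np.mean(wave_nl**2, axis=0))
        nl = self.nonlinear_fraction
        with np.errstate(divide="ignore", invalid="ignore"):
            self._trend_gain = np.where(
                trend_rms > 0, amps * np.sqrt(1.0 - nl) / trend_rms, 0.0
            )
            self._wave_gain = np.where(
                wave_rms > 0, amps * np.sqrt(nl) / wave_rms, 0.0
            )

    def _affine_design(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - self._center) / self._halfwidth
        return np.column_stack([np.ones(len(pts)), q])

    def _trend_raw(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - self._center) / self._halfwidth
        return self._trend[:, 0][None, :] + q @ self._trend[:, 1:].T

    def _wave_raw(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros((len(pts), 3))
        for axis in range(3):
            phase = pts @ self._wave_k[axis].T + self._phases[axis]
            out[:, axis] = np.sin(phase) @ self._wave_w[axis]
        return out

    def __call__(self, points) -> np.ndarray:
        """Displacement (mm) at one point (3,) or a stack (n, 3)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        wave_nl = self._wave_raw(pts2) - self._affine_design(pts2) @ self._wave_affine
        disp = self._trend_raw(pts2) * self._trend_gain + wave_nl * self._wave_gain
        return disp[0] if single else disp

    def distort(self, points) -> np.ndarray:
        """EMT-reported position(s): truth plus displacement."""
        return np.asarray(points, dtype=float) + self(points)

    def rms_per_axis(self, n: int = 100_000, seed: int = 12345) -> np.ndarray:
        """Monte Carlo per-axis RMS displacement over the workspace."""
        rng = np.random.default_rng(seed)
        sample = rng.uniform(
            self.workspace[:, 0], self.workspace[:, 1], size=(n, 3)
        )
        return np.sqrt(np.mean(self(sample) ** 2, axis=0))


def generate_distortion_field(
    amplitudes_mm=(2.0, 1.7, 23.0), seed: int = 0, **kwargs
) -> DistortionField:
    """Build a :class:`DistortionField`; see the class for parameters."""
    return DistortionField(amplitudes_mm=amplitudes_mm, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Trajectories and training grids
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Ordered sensor positions (mm) with constant arc-length spacing."""

    points: np.ndarray
    step_mm: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_steps(self) -> int:
        return len(self.points)


def generate_retraction(
    n_steps: int = 60,
    step_mm: float = 2.0,
    start=(40.0, 55.0, 26.0),
    direction=(-0.45, -0.86, 0.24),
    bend_radius_mm: float = 35.0,
    climb_mm: float = 25.0,
    path: str = "helix",
) -> Trajectory:
    """Guidewire retraction trajectory: ``n_steps`` positions spaced
    ``step_mm`` apart (arc-length parameterized) along either a straight
    line or a vessel-like curve — a helical sweep of radius
    ``bend_radius_mm`` climbing ``climb_mm`` over its length, imitating a
    catheter path through curved anatomy.

    The default placement mimics the evaluation phantom sitting on the
    operating table above the training board: the pull-back runs obliquely
    across the workspace and partly above the heights spanned by the
    training fixture.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    if step_mm <= 0:
        raise ConfigurationError("step_mm must be > 0")
    if path not in ("line", "helix"):
        raise ConfigurationError("path must be 'line' or 'helix'")
    start = np.asarray(start, dtype=float).reshape(3)
    d = np.asarray(direction, dtype=float).reshape(3)
    d = d / np.linalg.norm(d)
    s = np.arange(n_steps) * step_mm
    if path == "line":
        pts = start[None, :] + s[:, None] * d[None, :]
        return Trajectory(points=pts, step_mm=step_mm)
    # Helix with axis along `d`: circular bend of radius `bend_radius_mm`
    # in the plane orthogonal to the axis plus a linear climb along it.
    helper = np.array([0.0, 0.0, 1.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    # Climb rate is defined against the standard 118 mm pull-back so the
    # path *shape* does not depend on how many steps are sampled.
    reference_length = 118.0
    b = climb_mm / reference_length
    if not 0.0 <= b < 1.0:
        raise ConfigurationError("climb_mm must lie in [0, 118) mm")
    # ds^2 = (r dtheta)^2 + (b ds)^2  =>  dtheta/ds = sqrt(1-b^2)/r
    theta = s * np.sqrt(1.0 - b**2) / bend_radius_mm
    pts = (
        start[None, :]
        + bend_radius_mm * (np.cos(theta) - 1.0)[:, None] * e1[None, :]
        + bend_radius_mm * np.sin(theta)[:, None] * e2[None, :]
        + (b * s)[:, None] * d[None, :]
    )
    return Trajectory(points=pts, step_mm=step_mm)


def generate_lego_grid(
    rows: int = 25,
    cols: int = 25,
    pitch_mm: float = LEGO_PITCH_MM,
    n_train: int = 100,
    n_val: int = 32,
    brick_mm: float = LEGO_BRICK_MM,
    n_levels: int = 4,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Training and validation sensor positions on the Lego board.

    Training points sit on grid nodes (a uniform random subsample of the
    ``rows x cols`` studs, board centered on the origin at z = 0) raised by
    0..``n_levels``-1 stacked bricks; having at least four distinct heights
    keeps the cubic z-basis identifiable from board data. Validation
    points are placed arbitrarily (uniformly) inside the board volume,
    off-node. Returns ``(train_points, val_points)``; reproducible by seed.
    """
    if n_train > rows * cols:
        raise ConfigurationError(
            f"n_train={n_train} exceeds the {rows * cols} board nodes"
        )
    if min(rows, cols, n_train, n_val) < 0 or n_levels < 1:
        raise ConfigurationError("invalid grid configuration")
    rng = np.random.default_rng(seed)
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch_mm
    ys = (np.arange(rows) - (rows - 1) / 2.0) * pitch_mm
    nodes = np.array([(x, y) for y in ys for x in xs])
    chosen = rng.choice(len(nodes), size=n_train, replace=False)
    levels = rng.integers(0, n_levels, size=n_train)
    train = np.column_stack([nodes[chosen], levels * brick_mm])
    half_x = (cols - 1) / 2.0 * pitch_mm
    half_y = (rows - 1) / 2.0 * pitch_mm
    val = np.column_stack(
        [
            rng.uniform(-half_x, half_x, size=n_val),
            rng.uniform(-half_y, half_y, size=n_val),
            rng.uniform(0.0, (n_levels - 1) * brick_mm, size=n_val),
        ]
    )
    return train, val


# ---------------------------------------------------------------------------
# Radiograph rendering and frame averaging
# ---------------------------------------------------------------------------


@dataclass
class RadiographScene:
    """Objects to render: list of (shape, position_mm, size_mm) with shape
    in {'orb', 'sensor-tip', 'line'}, plus background noise sigma (on the
    [0, 1] intensity scale)."""

    objects: List[tuple]
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if not self.objects:
            raise ConfigurationError("scene must contain at least one object")
        for shape, _, _ in self.objects:
            if shape not in ("orb", "sensor-tip", "line"):
                raise ConfigurationError(f"unknown scene object shape {shape!r}")


def render_radiograph(
    scene: RadiographScene,
    pose: GantryPose,
    model: CArmModel,
    seed: int = 0,
    shape: Tuple[int, int] = (256, 256),
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a synthetic radiograph and return (image, true_centers_px).

    Objects appear as dark Gaussian blobs (lines as a chain of blobs) on a
    bright noisy background; intensities are floats in [0, 1]. The exact
    projected centers of orb/sensor-tip objects are returned for use as
    detection ground truth.
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, 0.85)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    centers = []
    for kind, position, size_mm in scene.objects:
        if kind == "line":
            p0, p1 = np.asarray(position, dtype=float).reshape(2, 3)
            for t in np.linspace(0.0, 1.0, 64):
                c = model.project(p0 + t * (p1 - p0), pose)
                r_px = max(0.5 * size_mm * model.px_per_mm, 0.75)
                img -= 0.5 * np.exp(
                    -((cols - c[0]) ** 2 + (rows - c[1]) ** 2) / (2 * r_px**2)
                )
            continue
        c = model.project(np.asarray(position, dtype=float), pose)
        centers.append(c)
        r_px = max(0.5 * size_mm * model.px_per_mm, 0.75)
        depth = 0.7 if kind == "orb" else 0.55
        img -= depth * np.exp(
            -((cols - c[0]) ** 2 + (rows - c[1]) ** 2) / (2 * r_px**2)
        )
    if scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, size=shape)
    return np.clip(img, 0.0, 1.0), np.array(centers).reshape(-1, 2)


def average_frames(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise mean of equally shaped frames (the analog-video noise
    suppression step; i.i.d. noise shrinks as 1/sqrt(n))."""
    if len(frames) == 0:
        raise ConfigurationError("need at least one frame")
    first = np.asarray(frames[0], dtype=float)
    for f in frames[1:]:
        if np.asarray(f).shape != first.shape:
            raise ConfigurationError("frames must share one shape")
    return np.mean([np.asarray(f, dtype=float) for f in frames], axis=0)


# ---------------------------------------------------------------------------
# Acquisition timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionTimingModel:
    """Gantry timing: setup latency per rotation (s) and angular velocity
    (deg/s), as measured on the automated C-arm."""

    t_setup_s: float = 1.0
    omega_deg_per_s: float = 4.0

    def __post_init__(self) -> None:
        if not (self.t_setup_s > 0 and self.omega_deg_per_s > 0):
            raise ConfigurationError("timing parameters must be > 0")

    def rotation_time_s(self, from_deg: float, to_deg: float) -> float:
        """Time for one gantry rotation; zero for an empty rotation."""
        if from_deg == to_deg:
            return 0.0
        return self.t_setup_s + abs(to_deg - from_deg) / self.omega_deg_per_s


def schedule_triplet(
    angles: Sequence[float] = TRIPLET_ANGLES,
    timing: AcquisitionTimingModel = AcquisitionTimingModel(),
    exposure_s: float = 0.1,
) -> Tuple[float, List[tuple]]:
    """Schedule of one automated snapshot sweep over sorted angles.

    Returns ``(total_s, events)``: events are ``(angle_deg, start_s,
    duration_s)`` exposure records; total time is the sum of rotation times
    (setup + angular distance / omega) between consecutive angles plus the
    exposures (100 ms is the minimum exposure for a usable image).
    """
    angles = list(angles)
    if angles != sorted(angles):
        raise ConfigurationError("angles must be sorted ascending")
    if exposure_s <= 0:
        raise ConfigurationError("exposure_s must be > 0")
    t = 0.0
    events: List[tuple] = []
    previous: Optional[float] = None
    for angle in angles:
        if previous is not None:
            t += timing.rotation_time_s(previous, angle)
        events.append((float(angle), t, exposure_s))
        t += exposure_s
        previous = angle
    return t, events


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------


def default_carm_model(px_per_mm: float = DEFAULT_PX_PER_MM) -> CArmModel:
    """Parallel-projection C-arm with the principal point at the center of
    a 256 x 256 detector and the quantization-matched pixel scale."""
    return CArmModel(px_per_mm=px_per_mm, principal_point_px=np.array([128.0, 128.0]))


def quantized_detection(model: CArmModel, point_mm, pose: GantryPose) -> np.ndarray:
    """Project a point and round to integer pixels — the synthetic stand-in
    for 2D sensor detection, carrying exactly the pixel quantization noise."""
    return np.round(model.project(point_mm, pose))


def triplet_for_point(
    model: CArmModel,
    point_mm,
    timestamp_s: float = 0.0,
    height_cm: float = 110.0,
    quantize: bool = True,
) -> SnapshotTriplet:
    """Synthesize the snapshot triplet observing one 3D point."""
    detections = {}
    for angle in TRIPLET_ANGLES:
        pose = GantryPose(angle_deg=angle, height_cm=height_cm)
        px = model.project(point_mm, pose)
        detections[angle] = np.round(px) if quantize else px
    return SnapshotTriplet(
        detections=detections, timestamp_s=timestamp_s, pose_height_cm=height_cm
    )


#: Image and EMT-point counts of the study dataset the simulator emulates,
#: by pipeline role. Image subtotals: 60 + 10 + (154+60+14) + (100+32) + 180.
STUDY_MANIFEST = {
    "pivot": {"images": 60, "emt_points": 0},
    "px2mm": {"images": 10, "emt_points": 0},
    "sensor_detection": {"images": 154 + 60 + 14, "emt_points": 0},
    "compensation": {"images": 100 + 32, "emt_points": 46_229 + 12_857},
    "final_evaluation": {"images": 180, "emt_points": 52_278},
}


def dataset_manifest() -> dict:
    """Role -> counts manifest of the emulated study dataset, with totals."""
    manifest = {k: dict(v) for k, v in STUDY_MANIFEST.items()}
    manifest["total"] = {
        "images": sum(v["images"] for v in STUDY_MANIFEST.values()),
        "emt_points": sum(v["emt_points"] for v in STUDY_MANIFEST.values()),
    }
    return manifest


@dataclass
class SimulatedStudy:
    """Bundle of everything one synthetic navigation study produces."""

    carm: CArmModel
    field: DistortionField
    emt_frame: "object"  # RigidTransform: image frame -> EMT frame
    training_set: TrainingSet
    trajectory: Trajectory
    triplets: List[SnapshotTriplet]
    references_mm: np.ndarray  # triangulated X-ray positions per step
    truth_mm: np.ndarray  # noiseless trajectory positions
    emt_raw_mm: np.ndarray  # distorted EMT samples per step (EMT frame)


def simulate_study(
    seed: int = 0,
    n_steps: int = 60,
    step_mm: float = 2.0,
    amplitudes_mm=(2.0, 1.7, 23.0),
    nonlinear_fraction: float = 0.05,
    length_scale_mm: float = 600.0,
    quantize: bool = True,
) -> SimulatedStudy:
    """Run the full synthetic acquisition: distortion field, Lego-board
    training pairs, retraction trajectory, quantized snapshot triplets and
    triangulated per-step references.

    The EMT frame is offset from the image frame by a fixed small rigid
    transform (a tilted, shifted field generator); EMT samples are the
    rigidly mapped truth plus the distortion-field displacement evaluated
    in the EMT frame.
    """
    from scipy.spatial.transform import Rotation

    from .registration import RigidTransform

    rng = np.random.default_rng(seed)
    carm_model = default_carm_model()
    field = DistortionField(
        amplitudes_mm=amplitudes_mm,
        nonlinear_fraction=nonlinear_fraction,
        length_scale_mm=length_scale_mm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    # Field-generator mounting: nominally aligned with the image frame,
    # with a degree of residual tilt and a couple of mm of offset.
    emt_frame = RigidTransform(
        rotation=Rotation.from_euler(
            "xyz", rng.uniform(-1.0, 1.0, size=3), degrees=True
        ).as_matrix(),
        translation=rng.uniform(-2.0, 2.0, size=3),
    )

    def emt_measure(points: np.ndarray) -> np.ndarray:
        in_emt = emt_frame.apply(points)
        return field.distort(in_emt)

    # Training pairs: EMT sample vs X-ray-detected position at the fixed
    # 90 degree view (x, y from quantized pixels; z from board geometry).
    train_pts, val_pts = generate_lego_grid(seed=int(rng.integers(0, 2**31 - 1)))
    grid_truth = np.vstack([train_pts, val_pts])
    pose90 = GantryPose(angle_deg=90.0)
    if quantize:
        px = np.round(carm_model.project(grid_truth, pose90))
        c = carm_model.principal_point_for(pose90)
        detected_xy = (px - c) / carm_model.px_per_mm
        grid_ref = np.column_stack(
            [detected_xy[:, 0], detected_xy[:, 1], grid_truth[:, 2]]
        )
    else:
        grid_ref = grid_truth
    training_set = TrainingSet.from_arrays(
        src=emt_measure(grid_truth), dst=grid_ref, n_train=len(train_pts)
    )

    trajectory = generate_retraction(n_steps=n_steps, step_mm=step_mm)
    truth = trajectory.points
    emt_raw = emt_measure(truth)
    triplets = [
        triplet_for_point(carm_model, p, timestamp_s=float(i), quantize=quantize)
        for i, p in enumerate(truth)
    ]
    references = np.array([triangulate(t, carm_model) for t in triplets])
    return SimulatedStudy(
        carm=carm_model,
        field=field,
        emt_frame=emt_frame,
        training_set=training_set,
        trajectory=trajectory,
        triplets=triplets,
        references_mm=references,
        truth_mm=truth,
        emt_raw_mm=emt_raw,
    )
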