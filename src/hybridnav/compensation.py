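"""Polynomial EMT distortion compensation.

Electromagnetic tracking near a C-arm suffers a smooth, spatially varying,
metal-induced position error (strongest along the beam axis). Offline
compensation fits, per output axis, an ordinary-least-squares polynomial
over the full trivariate monomial basis of total degree <= ``degree``
(4 terms for linear, 20 for cubic), mapping EMT-reported positions directly
to X-ray-derived reference positions. The map therefore folds frame
alignment and distortion correction into one polynomial, matching how the
training pairs are collected (EMT sample vs. detected sensor position).

Inputs are centered and scaled to the training bounding box before the
monomials are formed; this affects conditioning only and the scaling is
stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, UnderdeterminedFitError
from .registration import ErrorReport, error_report, rigid_register

__all__ = [
    "TrainingSet",
    "CompensationModel",
    "basis_size",
    "monomial_exponents",
    "design_matrix",
    "fit_compensation",
    "apply_compensation",
]


def basis_size(degree: int) -> int:
    """Number of trivariate monomials with total degree <= degree:
    C(degree + 3, 3)."""
    if degree < 0:
        raise ConfigurationError("degree must be >= 0")
    return comb(degree + 3, 3)


def monomial_exponents(degree: int) -> List[Tuple[int, int, int]]:
    """Exponent triples (a, b, c), a+b+c <= degree, in graded
    lexicographic order with the constant term first."""
    if degree < 0:
        raise ConfigurationError("degree must be >= 0")
    out: List[Tuple[int, int, int]] = []
    for total in range(degree + 1):
        for a in range(total, -1, -1):
            for b in range(total - a, -1, -1):
                out.append((a, b, total - a - b))
    return out


def design_matrix(
    points,
    degree: int,
    center=(0.0, 0.0, 0.0),
    scale=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """(n, C(degree+3, 3)) matrix of monomials of the (centered, scaled)
    coordinates, columns in graded-lex order, constant column first."""
    if degree < 1:
        raise ConfigurationError("degree must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    q = (pts - np.asarray(center, dtype=float)) / np.asarray(scale, dtype=float)
    # Precompute coordinate powers once; monomial columns are products.
    powers = [
        np.vander(q[:, axis], degree + 1, increasing=True) for axis in range(3)
    ]
    cols = [
        powers[0][:, a] * powers[1][:, b] * powers[2][:, c]
        for a, b, c in monomial_exponents(degree)
    ]
    return np.column_stack(cols)


@dataclass
class TrainingSet:
    """Paired EMT-reported (``src``) and X-ray-derived reference (``dst``)
    positions in mm, with per-point split labels ('train'/'validation')."""

    src: np.ndarray
    dst: np.ndarray
    split: np.ndarray

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 3)
        self.dst = np.asarray(self.dst, dtype=float).reshape(-1, 3)
        self.split = np.asarray(self.split, dtype=object)
        if not (len(self.src) == len(self.dst) == len(self.split)):
            raise ConfigurationError("src, dst and split must have equal length")
        bad = set(self.split) - {"train", "validation"}
        if bad:
            raise ConfigurationError(f"unknown split labels: {sorted(bad)}")

    @classmethod
    def from_arrays(
        cls, src, dst, n_train: Optional[int] = None
    ) -> "TrainingSet":
        """Label the first ``n_train`` pairs 'train' and the rest
        'validation' (all 'train' when ``n_train`` is None)."""
        src = np.asarray(src, dtype=float).reshape(-1, 3)
        n_train = len(src) if n_train is None else n_train
        split = np.array(
            ["train"] * n_train + ["validation"] * (len(src) - n_train), dtype=object
        )
        return cls(src=src, dst=dst, split=split)

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "train"

    @property
    def validation_mask(self) -> np.ndarray:
        return self.split == "validation"

    @property
    def n_train(self) -> int:
        return int(self.train_mask.sum())

    @property
    def n_validation(self) -> int:
        return int(self.validation_mask.sum())

    # -- CSV --------------------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "split": self.split,
                "src_x": self.src[:, 0],
                "src_y": self.src[:, 1],
                "src_z": self.src[:, 2],
                "dst_x": self.dst[:, 0],
                "dst_y": self.dst[:, 1],
                "dst_z": self.dst[:, 2],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        df = pd.read_csv(path)
        return cls(
            src=df[["src_x", "src_y", "src_z"]].to_numpy(dtype=float),
            dst=df[["dst_x", "dst_y", "dst_z"]].to_numpy(dtype=float),
            split=df["split"].to_numpy(dtype=object),
        )


@dataclass
class CompensationModel:
    """Fitted per-axis polynomial correction of EMT positions.

    ``coefficients`` has shape (basis_size(degree), 3): one weight vector
    per output axis over the shared monomial basis. ``center`` and
    ``scale`` record the training bounding-box normalization.
    """

    degree: int
    coefficients: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    training_report: Optional[ErrorReport] = None
    validation_report: Optional[ErrorReport] = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(
            basis_size(self.degree), 3
        )
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.scale = np.asarray(self.scale, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coefficients)):
            raise ConfigurationError("coefficients must be finite")

    # -- fitting ----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        training_set: TrainingSet,
        degree: int = 3,
        align_rigid_first: bool = False,
    ) -> "CompensationModel":
        """Least-squares fit of the reference positions on the monomial
        design of the EMT positions (per output axis).

        With ``align_rigid_first`` the training sources are first brought
        into the reference frame by rigid registration and the polynomial
        corrects only the residual distortion; the rigid map is folded into
        the evaluation so the model surface is unchanged.

        Raises
        ------
        UnderdeterminedFitError
            When there are fewer training pairs than basis functions
            (a cubic needs at least 20).
        """
        nb = basis_size(degree)
        src = training_set.src[training_set.train_mask]
        dst = training_set.dst[training_set.train_mask]
        if len(src) < nb:
            raise UnderdeterminedFitError(
                f"degree {degree} needs >= {nb} training points, got {len(src)}"
            )
        rigid = rigid_register(src, dst) if align_rigid_first else None
        src_in = rigid.apply(src) if rigid is not None else src
        lo = src_in.min(axis=0)
        hi = src_in.max(axis=0)
        center = (lo + hi) / 2.0
        scale = np.maximum((hi - lo) / 2.0, 1e-9)
        X = design_matrix(src_in, degree, center, scale)
        coefficients, *_ = np.linalg.lstsq(X, dst, rcond=None)
        model = cls(
            degree=degree,
            coefficients=coefficients,
            center=center,
            scale=scale,
        )
        model._rigid = rigid
        model.training_report = error_report(model.apply(src), dst)
        if training_set.n_validation:
            vsrc = training_set.src[training_set.validation_mask]
            vdst = training_set.dst[training_set.validation_mask]
            model.validation_report = error_report(model.apply(vsrc), vdst)
        return model

    _rigid = None  # optional pre-alignment (set by fit)

    def apply(self, points) -> np.ndarray:
        """Evaluate the per-axis polynomials at one point (3,) or a stack
        (n, 3); deterministic."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        if self._rigid is not None:
            pts2 = self._rigid.apply(pts2)
        out = design_matrix(pts2, self.degree, self.center, self.scale) @ self.coefficients
        return out[0] if single else out

    def summary(self) -> str:
        lines = [
            f"Polynomial compensation (degree {self.degree}, "
            f"{basis_size(self.degree)} basis terms per axis)"
        ]
        if self.training_report is not None:
            lines.append(f"  training    {self.training_report.summary()}")
        if self.validation_report is not None:
            lines.append(f"  validation  {self.validation_report.summary()}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "degree": int(self.degree),
            "center": [float(x) for x in self.center],
            "scale": [float(x) for x in self.scale],
            "coefficients": {
                axis: [float(c) for c in self.coefficients[:, i]]
                for i, axis in enumerate("xyz")
            },
        }
        if self._rigid is not None:
            data["rigid_pre_alignment"] = {
                "rotation": [float(v) for v in self._rigid.rotation.reshape(9)],
                "translation": [float(v) for v in self._rigid.translation],
            }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CompensationModel":
        data = yaml.safe_load(Path(path).read_text())
        coefficients = np.column_stack(
            [np.asarray(data["coefficients"][axis], dtype=float) for axis in "xyz"]
        )
        model = cls(
            degree=int(data["degree"]),
            coefficients=coefficients,
            center=np.asarray(data["center"], dtype=float),
            scale=np.asarray(data["scale"], dtype=float),
        )
        if "rigid_pre_alignment" in data:
            from .registration import RigidTransform

            block = data["rigid_pre_alignment"]
            model._rigid = RigidTransform(
                rotation=np.asarray(block["rotation"], dtype=float).reshape(3, 3),
                translation=np.asarray(block["translation"], dtype=float),
            )
        return model


def fit_compensation(
    training_set: TrainingSet, degree: int = 3, align_rigid_first: bool = False
) -> CompensationModel:
    """Functional form of :meth:`CompensationModel.fit`."""
    return CompensationModel.fit(training_set, degree, align_rigid_first)


def apply_compensation(model: CompensationModel, points) -> np.ndarray:
    """Functional form of :meth:`CompensationModel.apply`."""
    return model.apply(points)
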