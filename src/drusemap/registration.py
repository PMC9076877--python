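"""Landmark-based registration of en-face retinal channels.

Each spectral channel (fundus autofluorescence, infrared SLO, green SLO) is
aligned to the grid of the reference color fundus photograph using paired
vessel-bifurcation landmarks — typically eight pairs per channel, which
over-determine the 6-parameter affine model comfortably.

Coordinate convention, used everywhere in this package: ``(row, col)``,
0-based, origin at the top-left pixel, pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import skimage.transform as sktf

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "LandmarkSet",
    "SpatialTransform",
    "AlignmentReport",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "estimate_transform",
    "warp_image",
    "check_alignment",
]

TransformModel = Literal["affine", "similarity"]

_MIN_PAIRS = {"affine": 3, "similarity": 2}


@dataclass(frozen=True)
class LandmarkSet:
    """Paired landmark coordinates, moving frame and fixed (reference) frame.

    Both arrays are ``(n, 2)`` in (row, col) order. The conventional
    acquisition protocol marks eight vessel bifurcations, but any n >= 2/3
    (similarity/affine) non-degenerate pairs are accepted.
    """

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        moving = np.asarray(self.moving, dtype=float)
        fixed = np.asarray(self.fixed, dtype=float)
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "fixed", fixed)
        if moving.ndim != 2 or moving.shape[1] != 2:
            raise ValidationError("moving points must have shape (n, 2)")
        if fixed.ndim != 2 or fixed.shape[1] != 2:
            raise ValidationError("fixed points must have shape (n, 2)")
        if fixed.shape != moving.shape:
            raise ValidationError(
                f"landmark count mismatch: {moving.shape[0]} moving vs "
                f"{fixed.shape[0]} fixed"
            )
        if not (np.isfinite(moving).all() and np.isfinite(fixed).all()):
            raise ValidationError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.moving.shape[0]


@dataclass(frozen=True)
class SpatialTransform:
    """A fitted 2-D linear map from the moving frame to the fixed frame.

    ``matrix`` is the 2x3 coefficient block: ``fixed_rc = A @ moving_rc + t``
    with ``A = matrix[:, :2]`` and ``t = matrix[:, 2]``.
    """

    model: str
    matrix: np.ndarray
    residual_rmse: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (2, 3):
            raise ValidationError("transform matrix must be 2x3")
        if not np.isfinite(m).all():
            raise DegenerateGeometryError("transform matrix is not finite")
        if self.residual_rmse < 0:
            raise ValidationError("residual_rmse must be >= 0")

    @classmethod
    def identity(cls, model: str = "affine") -> "SpatialTransform":
        return cls(model=model, matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points_rc: np.ndarray) -> np.ndarray:
        """Map (n, 2) row/col points from the moving into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "SpatialTransform":
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        det = np.linalg.det(A)
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise DegenerateGeometryError("transform is not invertible")
        Ainv = np.linalg.inv(A)
        return SpatialTransform(
            model=self.model,
            matrix=np.hstack([Ainv, (-Ainv @ t)[:, None]]),
        )


@dataclass(frozen=True)
class AlignmentReport:
    """Post-registration quality report: landmark residual and image NCC."""

    landmark_rmse: float
    correlation: float
    n_landmarks: int


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    """Read a landmark pair file.

    Expected columns: ``moving_row,moving_col,fixed_row,fixed_col`` with a
    header row, one landmark pair per line.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as validation failure
        raise ValidationError(f"cannot read landmark CSV {path}: {exc}") from exc
    required = ["moving_row", "moving_col", "fixed_row", "fixed_col"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"landmark CSV {path} missing columns: {missing}")
    bad = df[required].apply(lambda s: ~np.isfinite(pd.to_numeric(s, errors="coerce")))
    if bad.any().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0]) + 2  # 1-based + header
        raise ValidationError(f"landmark CSV {path}: non-numeric value at line {row}")
    return LandmarkSet(
        moving=df[["moving_row", "moving_col"]].to_numpy(float),
        fixed=df[["fixed_row", "fixed_col"]].to_numpy(float),
    )


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "moving_row": landmarks.moving[:, 0],
            "moving_col": landmarks.moving[:, 1],
            "fixed_row": landmarks.fixed[:, 0],
            "fixed_col": landmarks.fixed[:, 1],
        }
    ).to_csv(path, index=False)


def _to_xy(points_rc: np.ndarray) -> np.ndarray:
    return np.asarray(points_rc, float)[:, ::-1]


def _collinear(points: np.ndarray) -> bool:
    centered = points - points.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2


def estimate_transform(
    landmarks: LandmarkSet, model: TransformModel = "affine"
) -> SpatialTransform:
    """Least-squares fit of a moving→fixed transform to landmark pairs.

    Affine (6 dof) is the default; a similarity transform (4 dof: rotation,
    isotropic scale, translation) is available for poorly conditioned
    landmark layouts. Raises :class:`DegenerateGeometryError` when the point
    geometry cannot determine the model (too few pairs, collinear points).
    """
    if model not in _MIN_PAIRS:
        raise ValidationError(f"unknown transform model: {model!r}")
    n = len(landmarks)
    if n < _MIN_PAIRS[model]:
        raise DegenerateGeometryError(
            f"{model} fit needs >= {_MIN_PAIRS[model]} landmark pairs, got {n}"
        )
    if model == "affine" and (_collinear(landmarks.moving) or _collinear(landmarks.fixed)):
        raise DegenerateGeometryError("landmarks are collinear; affine fit is degenerate")

    cls = sktf.AffineTransform if model == "affine" else sktf.SimilarityTransform
    src, dst = _to_xy(landmarks.moving), _to_xy(landmarks.fixed)
    if hasattr(cls, "from_estimate"):
        tf = cls.from_estimate(src, dst)
        ok = bool(tf)
    else:  # scikit-image < 0.26
        tf = cls()
        ok = tf.estimate(src, dst)
    if not ok or not np.isfinite(tf.params).all():
        raise DegenerateGeometryError("transform estimation failed (degenerate geometry)")

    # skimage works in (x, y) = (col, row); convert the homogeneous matrix
    # back to the package's (row, col) convention.
    P = tf.params
    matrix = np.array(
        [
            [P[1, 1], P[1, 0], P[1, 2]],
            [P[0, 1], P[0, 0], P[0, 2]],
        ]
    )
    out = SpatialTransform(model=model, matrix=matrix)
    resid = out.apply(landmarks.moving) - landmarks.fixed
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SpatialTransform(model=model, matrix=matrix, residual_rmse=rmse)


def _as_sk_transform(transform: SpatialTransform) -> sktf.AffineTransform:
    m = transform.matrix
    params = np.array(
        [
            [m[1, 1], m[1, 0], m[1, 2]],
            [m[0, 1], m[0, 0], m[0, 2]],
            [0.0, 0.0, 1.0],
        ]
    )
    return sktf.AffineTransform(matrix=params)


def warp_image(
    image: np.ndarray,
    transform: SpatialTransform,
    target_shape: tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` onto the fixed-frame grid of ``target_shape``.

    Bilinear interpolation; pixels whose pre-image falls outside the moving
    image footprint take ``fill`` (default 0 — they are excluded later by the
    macular mask anyway).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValidationError("cannot warp an empty image")
    transform.inverse()  # raises DegenerateGeometryError if singular
    sk = _as_sk_transform(transform)
    return sktf.warp(
        img,
        inverse_map=sk.inverse,
        output_shape=tuple(target_shape),
        order=1,
        cval=fill,
        mode="constant",
        preserve_range=True,
    )


def check_alignment(
    imageA: np.ndarray, imageB: np.ndarray, landmarksB: LandmarkSet
) -> AlignmentReport:
    """Automated alignment surrogate for visual flicker comparison.

    Both images must live on a common grid. Reports the residual RMSE of
    landmarksB (moving vs fixed positions, both now nominally in the shared
    frame) and the normalized cross-correlation of the two images.
    """
    a = np.asarray(imageA, float).ravel()
    b = np.asarray(imageB, float).ravel()
    if a.shape != b.shape:
        raise ValidationError("check_alignment requires images on a common grid")
    resid = landmarksB.moving - landmarksB.fixed
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        ncc = 0.0
    else:
        ncc = float(np.corrcoef(a, b)[0, 1])
    return AlignmentReport(landmark_rmse=rmse, correlation=ncc, n_landmarks=len(landmarksB))
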