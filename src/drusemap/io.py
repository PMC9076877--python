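"""Disk formats: images (PNG/TIFF), landmark CSVs, theme-map artifacts,
visit directories and cohort manifests.

A visit directory holds ``faf.png``, ``ir.png``, ``green.png`` (16-bit
grayscale), ``cfp.png`` (8-bit RGB reference), ``landmarks_<channel>.csv``
and ``annotation.png`` (binary, 0/255).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .clustering import ThemeMap
from .errors import ValidationError
from .phantom import CHANNELS, CohortEye, PhantomVisit
from .pipeline import VisitInputs
from .preprocessing import MacularMask
from .quantify import AnnotationMask
from .registration import LandmarkSet, read_landmarks_csv, write_landmarks_csv

__all__ = [
    "read_image",
    "write_gray16",
    "write_rgb8",
    "write_binary_mask",
    "read_binary_mask",
    "write_theme_map",
    "write_visit_dir",
    "read_visit_dir",
    "write_cohort",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF image as a numpy array (dtype preserved)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_gray16(image: np.ndarray, path: str | Path) -> None:
    """Write a float [0,1] raster as 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    out = np.round(arr * 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_rgb8(image: np.ndarray, path: str | Path) -> None:
    out = np.round(np.clip(np.asarray(image, float), 0, 1) * 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


def write_binary_mask(mask: np.ndarray, path: str | Path) -> None:
    """Binary mask as 0/255 8-bit PNG (foreground white)."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_binary_mask(path: str | Path) -> np.ndarray:
    img = read_image(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > (np.iinfo(img.dtype).max // 2 if img.dtype.kind == "u" else 0.5)


def write_theme_map(theme_map: ThemeMap, out_dir: str | Path, prefix: str = "themes") -> None:
    """Serialize a ThemeMap: 16-bit label PNG (label + 1; 0 = outside mask),
    a class-statistics CSV and the pairwise divergence CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = (theme_map.labels + 1).astype(np.uint16)
    iio.imwrite(out / f"{prefix}_labels.png", labels)
    rows = []
    for c in theme_map.classes:
        cov = c.covariance
        rows.append(
            {
                "class_id": c.class_id,
                "mean_faf": c.mean[0],
                "mean_ir": c.mean[1],
                "mean_green": c.mean[2],
                **{
                    f"cov_{i}{j}": cov[i, j]
                    for i in range(3)
                    for j in range(3)
                    if j >= i
                },
                "pixel_count": c.pixel_count,
            }
        )
    pd.DataFrame(rows).to_csv(out / f"{prefix}_classes.csv", index=False)
    if theme_map.pairwise_td is not None:
        pd.DataFrame(
            theme_map.pairwise_td,
            index=theme_map.class_ids,
            columns=theme_map.class_ids,
        ).to_csv(out / f"{prefix}_pairwise_td.csv")


def write_visit_dir(visit: PhantomVisit, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in CHANNELS:
        write_gray16(visit.channels[name], out / f"{name}.png")
        write_landmarks_csv(visit.landmarks[name], out / f"landmarks_{name}.csv")
    write_rgb8(visit.cfp, out / "cfp.png")
    write_binary_mask(visit.annotation, out / "annotation.png")
    write_binary_mask(visit.truth_drusen, out / "truth_drusen.png")


def read_visit_dir(path: str | Path, mask: MacularMask | None = None) -> VisitInputs:
    """Load a visit directory into pipeline inputs."""
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    landmarks: dict[str, LandmarkSet] = {}
    for name in CHANNELS:
        img_path = path / f"{name}.png"
        if not img_path.exists():
            img_path = path / f"{name}.tif"
        if not img_path.exists():
            raise ValidationError(f"missing channel image {name} in {path}")
        channels[name] = read_image(img_path)
        lm_path = path / f"landmarks_{name}.csv"
        if not lm_path.exists():
            raise ValidationError(f"missing landmark file {lm_path}")
        landmarks[name] = read_landmarks_csv(lm_path)
    ann_path = path / "annotation.png"
    if not ann_path.exists():
        raise ValidationError(f"missing annotation mask in {path}")
    annotation = AnnotationMask(read_binary_mask(ann_path), provenance=str(ann_path))
    return VisitInputs(
        channels=channels,
        landmarks=landmarks,
        annotation=annotation,
        reference_shape=annotation.shape,
        mask=mask,
    )


def write_cohort(eyes: list[CohortEye], out_dir: str | Path) -> Path:
    """Write a phantom cohort to disk with a manifest CSV; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in eyes:
        for vi, visit in ((1, eye.pair.visit1), (2, eye.pair.visit2)):
            write_visit_dir(visit, out / eye.eye_id / f"visit{vi}")
        rows.append(
            {
                "eye_id": eye.eye_id,
                "label": eye.label,
                "true_pct_change": eye.true_percent_change,
                "visit1_dir": str(out / eye.eye_id / "visit1"),
                "visit2_dir": str(out / eye.eye_id / "visit2"),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
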