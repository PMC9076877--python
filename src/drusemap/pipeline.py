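"""End-to-end orchestration: register → preprocess → cluster → assign →
quantify → classify change, for one eye across two visits or a whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    ClusteringConfig,
    MultispectralStack,
    ThemeMap,
    cluster_with_separability,
)
from .errors import ValidationError
from .phantom import CHANNELS, CohortEye, PhantomVisit
from .preprocessing import (
    MacularMask,
    PreprocessConfig,
    disc_mask,
    preprocess_channel,
    to_gray_normalized,
)
from .quantify import (
    AnnotationMask,
    ChangeResult,
    ChangeThresholds,
    assign_theme_classes,
    change_result,
    drusen_area,
    drusen_mask,
)
from .registration import LandmarkSet, estimate_transform, warp_image

__all__ = [
    "PipelineConfig",
    "VisitInputs",
    "VisitResult",
    "PairResult",
    "analyze_visit",
    "analyze_pair",
    "visit_inputs_from_phantom",
    "run_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis pipeline in one validated bundle."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    thresholds: ChangeThresholds = field(default_factory=ChangeThresholds)
    overlap_threshold: float = 0.5
    transform_model: str = "affine"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValidationError("overlap_threshold must be in (0, 1]")
        if self.transform_model not in ("affine", "similarity"):
            raise ValidationError("transform_model must be affine or similarity")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file; unknown keys are rejected, sections optional."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {
            "preprocess": PreprocessConfig,
            "clustering": ClusteringConfig,
            "thresholds": ChangeThresholds,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in known:
                if not isinstance(value, dict):
                    raise ValidationError(f"config section {key!r} must be a mapping")
                section_cls = known[key]
                valid = set(section_cls.__dataclass_fields__)
                unknown = set(value) - valid
                if unknown:
                    raise ValidationError(
                        f"unknown keys in config section {key!r}: {sorted(unknown)}"
                    )
                kwargs[key] = section_cls(**value)
            elif key in ("overlap_threshold", "transform_model", "seed"):
                kwargs[key] = value
            else:
                raise ValidationError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Return a copy with both the pipeline and clustering seeds set."""
        return PipelineConfig(
            preprocess=self.preprocess,
            clustering=ClusteringConfig(
                **{**_dataclass_dict(self.clustering), "seed": int(seed)}
            ),
            thresholds=self.thresholds,
            overlap_threshold=self.overlap_threshold,
            transform_model=self.transform_model,
            seed=int(seed),
        )

    def to_dict(self) -> dict:
        return {
            "preprocess": _dataclass_dict(self.preprocess),
            "clustering": _dataclass_dict(self.clustering),
            "thresholds": _dataclass_dict(self.thresholds),
            "overlap_threshold": self.overlap_threshold,
            "transform_model": self.transform_model,
            "seed": self.seed,
        }


def _dataclass_dict(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


@dataclass
class VisitInputs:
    """Raw inputs for one eye-visit: per-channel rasters in their own frames,
    landmark pairs into the reference frame, and the expert annotation on
    the reference grid."""

    channels: dict  # name -> raster
    landmarks: dict  # name -> LandmarkSet
    annotation: AnnotationMask
    reference_shape: tuple[int, int]
    mask: MacularMask | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValidationError(f"missing channels: {missing}")
        missing = [c for c in CHANNELS if c not in self.landmarks]
        if missing:
            raise ValidationError(f"missing landmarks for channels: {missing}")


@dataclass
class VisitResult:
    stack: MultispectralStack
    theme_map: ThemeMap
    drusen_class_ids: set
    drusen_mask: np.ndarray
    area: int
    registration_rmse: dict


@dataclass
class PairResult:
    visit1: VisitResult
    visit2: VisitResult
    change: ChangeResult


def analyze_visit(inputs: VisitInputs, config: PipelineConfig | None = None) -> VisitResult:
    """Run registration through quantification for a single visit."""
    config = config or PipelineConfig()
    mask = inputs.mask or disc_mask(
        inputs.reference_shape, config.preprocess.mask_radius_fraction
    )
    processed = []
    reg_rmse = {}
    for name in CHANNELS:
        tf = estimate_transform(inputs.landmarks[name], config.transform_model)
        reg_rmse[name] = tf.residual_rmse
        # normalize to [0,1] grayscale before resampling so bit depth is
        # interpreted on the original raster, not the warped float array
        gray = to_gray_normalized(inputs.channels[name])
        aligned = warp_image(gray, tf, inputs.reference_shape)
        chan, _ = preprocess_channel(aligned, config.preprocess, mask)
        processed.append(chan)
    stack = MultispectralStack(np.stack(processed, axis=-1), mask.mask)
    theme_map = cluster_with_separability(stack, config.clustering)
    ids = assign_theme_classes(theme_map, inputs.annotation, config.overlap_threshold)
    dmask = drusen_mask(theme_map, ids)
    return VisitResult(
        stack=stack,
        theme_map=theme_map,
        drusen_class_ids=ids,
        drusen_mask=dmask,
        area=drusen_area(dmask),
        registration_rmse=reg_rmse,
    )


def analyze_pair(
    visit1: VisitInputs, visit2: VisitInputs, config: PipelineConfig | None = None
) -> PairResult:
    """Analyze two visits of one eye and classify the drusen-area change."""
    config = config or PipelineConfig()
    r1 = analyze_visit(visit1, config)
    r2 = analyze_visit(visit2, config)
    return PairResult(
        visit1=r1, visit2=r2, change=change_result(r1.area, r2.area, config.thresholds)
    )


def visit_inputs_from_phantom(visit: PhantomVisit) -> VisitInputs:
    """Adapt a generated phantom visit to pipeline inputs."""
    shape = visit.annotation.shape
    return VisitInputs(
        channels=dict(visit.channels),
        landmarks=dict(visit.landmarks),
        annotation=AnnotationMask(visit.annotation, provenance="phantom truth + dilation"),
        reference_shape=shape,
    )


def phantom_analysis_config(seed: int = 0) -> PipelineConfig:
    """Recommended pipeline configuration at the phantom's working scale.

    Two deliberate departures from the plain defaults, both documented in
    the methods note:

    * theme classes smaller than 3% of the macular area are dissolved into
      their neighbours — at a ~192 px frame such slivers are boundary-
      resampling artifacts of registration, not tissue classes, and
      dissolving them keeps the class structure of the two visits
      commensurate;
    * the drusen-assignment overlap threshold is 0.3 rather than the 0.5
      majority rule, matching the phantom's conservative expert annotation
      (graders outline the unambiguous lesion core, so a lesion-boundary
      class shows partial overlap even when it is drusen).
    """
    return PipelineConfig(
        clustering=ClusteringConfig(min_class_fraction=0.03, seed=seed),
        overlap_threshold=0.3,
        seed=seed,
    )


def run_cohort(
    eyes: list[CohortEye], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Run the full pipeline over a phantom cohort.

    Uses :func:`phantom_analysis_config` when no config is given. Returns
    one row per eye: planted label and true change, measured areas,
    measured percent change and category, and the number of theme classes
    assigned to drusen at each visit.
    """
    config = config or phantom_analysis_config()
    rows = []
    for eye in eyes:
        res = analyze_pair(
            visit_inputs_from_phantom(eye.pair.visit1),
            visit_inputs_from_phantom(eye.pair.visit2),
            config,
        )
        rows.append(
            {
                "eye_id": eye.eye_id,
                "label": eye.label,
                "true_pct_change": eye.true_percent_change,
                "area1_px": res.change.area_visit1,
                "area2_px": res.change.area_visit2,
                "percent_change": res.change.percent_change,
                "category": res.change.category,
                "n_drusen_classes_v1": len(res.visit1.drusen_class_ids),
                "n_drusen_classes_v2": len(res.visit2.drusen_class_ids),
                "k_final_v1": res.visit1.theme_map.k,
                "k_final_v2": res.visit2.theme_map.k,
                "min_td_v1": res.visit1.theme_map.min_pairwise_td(),
                "min_td_v2": res.visit2.theme_map.min_pairwise_td(),
            }
        )
    return pd.DataFrame(rows)
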