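"""Drusen class assignment, duochrome mask construction, area quantification
and longitudinal change classification.

Theme classes are labelled drusen / not-drusen by majority overlap with an
expert-annotated drusen mask drawn on the reference color fundus photograph.
The member pixels of all drusen classes are pooled into a single binary
(duochrome) mask — pigmentary-abnormality classes stay out of the pool —
whose foreground pixel count is the drusen area for that visit. Change
between two visits is the signed percent difference in area; eyes are
categorised as progression (> +5%), regression (< −5%) or stable
([−5%, +5%], endpoints inclusive in stable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .clustering import ThemeMap
from .errors import ValidationError

__all__ = [
    "AnnotationMask",
    "ChangeThresholds",
    "ChangeResult",
    "assign_theme_classes",
    "drusen_mask",
    "drusen_area",
    "percent_change",
    "classify_change",
    "change_result",
]

log = logging.getLogger(__name__)

PROGRESSION = "progression"
STABLE = "stable"
REGRESSION = "regression"
CATEGORIES = (PROGRESSION, STABLE, REGRESSION)


@dataclass(frozen=True)
class AnnotationMask:
    """Expert-drawn binary drusen annotation on the reference grid."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValidationError("annotation mask must be 2-D")
        # an empty annotation (no drusen marked) is legitimate

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class ChangeThresholds:
    """Categorical change rule: progression above +5%, regression below −5%,
    stable on the closed interval between them."""

    progression_gt: float = 5.0
    regression_lt: float = -5.0

    def __post_init__(self) -> None:
        if not self.regression_lt < self.progression_gt:
            raise ValidationError("regression_lt must be < progression_gt")


@dataclass(frozen=True)
class ChangeResult:
    """Drusen area at two visits with the derived change category."""

    area_visit1: int
    area_visit2: int
    percent_change: float
    category: str
    incident_drusen: bool = False


def assign_theme_classes(
    theme_map: ThemeMap,
    annotation: AnnotationMask,
    overlap_threshold: float = 0.5,
) -> set[int]:
    """Label theme classes as drusen by majority overlap with the annotation.

    Class c is drusen iff (pixels of c inside the annotation) / (pixels of c)
    >= overlap_threshold. Returns a possibly-empty id set.
    """
    if annotation.shape != theme_map.labels.shape:
        raise ValidationError(
            f"annotation grid {annotation.shape} does not match theme map "
            f"{theme_map.labels.shape}"
        )
    if not 0 < overlap_threshold <= 1:
        raise ValidationError("overlap_threshold must be in (0, 1]")
    drusen_ids: set[int] = set()
    for cls in theme_map.classes:
        member = theme_map.labels == cls.class_id
        inside = int(np.count_nonzero(member & annotation.mask))
        if inside / cls.pixel_count >= overlap_threshold:
            drusen_ids.add(cls.class_id)
    return drusen_ids


def drusen_mask(theme_map: ThemeMap, drusen_class_ids: set[int]) -> np.ndarray:
    """Union of the member pixels of the drusen classes (the duochrome
    foreground). All other in-mask pixels and all out-of-mask pixels are
    False."""
    known = set(theme_map.class_ids)
    unknown = set(drusen_class_ids) - known
    if unknown:
        raise ValidationError(f"unknown theme class ids: {sorted(unknown)}")
    out = np.isin(theme_map.labels, sorted(drusen_class_ids))
    out &= theme_map.mask
    return out


def drusen_area(mask: np.ndarray) -> int:
    """Foreground (drusen) pixel count of a binary mask."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def percent_change(area1: int, area2: int) -> float:
    """Signed percent change in drusen area, 100·(area2 − area1)/area1.

    Both areas zero is defined as 0% (stable). A zero baseline with
    nonzero follow-up has no defined percentage — see :func:`change_result`
    for the incident-drusen handling.
    """
    if area1 < 0 or area2 < 0:
        raise ValidationError("areas must be non-negative pixel counts")
    if area1 == 0:
        if area2 == 0:
            return 0.0
        return math.inf
    return 100.0 * (area2 - area1) / area1


def classify_change(pct: float, thresholds: ChangeThresholds | None = None) -> str:
    """Map a percent change onto {progression, stable, regression}."""
    thresholds = thresholds or ChangeThresholds()
    if math.isnan(pct):
        raise ValidationError("percent change is NaN")
    if pct > thresholds.progression_gt:
        return PROGRESSION
    if pct < thresholds.regression_lt:
        return REGRESSION
    return STABLE


def change_result(
    area1: int, area2: int, thresholds: ChangeThresholds | None = None
) -> ChangeResult:
    """Build the full ChangeResult for a visit pair, covering the edge cases.

    Incident drusen (zero baseline area, nonzero follow-up) has an undefined
    percentage; the category is forced to progression with a warning and the
    result flagged.
    """
    pct = percent_change(area1, area2)
    if math.isinf(pct):
        log.warning(
            "incident drusen: baseline area 0, follow-up %d px; "
            "percent change undefined, category forced to progression",
            area2,
        )
        return ChangeResult(area1, area2, math.inf, PROGRESSION, incident_drusen=True)
    return ChangeResult(area1, area2, pct, classify_change(pct, thresholds))
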