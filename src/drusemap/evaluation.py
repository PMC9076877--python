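"""Agreement statistics against expert grading.

Eyes carry a three-level categorical grading — drusen progression, stable,
drusen regression — from expert clinicians, and one category per automated
method. The summary statistics are:

* **agreement** — fraction of eyes where the method category equals the
  expert category (the trace of the 3×3 confusion matrix over n);
* **sensitivity** — among eyes the experts graded as *changed* (progression
  or regression), the fraction the method placed in the *same direction*.
  A regression eye called progression is a miss, not a detection: direction
  matters, because progression and regression carry different clinical
  implications. An expert-changed eye called in the opposite direction is
  additionally flagged, since its role in specificity is undefined (it is
  counted only as a sensitivity miss).
* **specificity** — among expert-stable eyes, the fraction the method also
  called stable; a stable eye pushed past ±5% either way is a false
  positive for that direction.

Paired continuous comparisons between two methods use Bland–Altman bias /
limits of agreement and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .quantify import CATEGORIES, PROGRESSION, REGRESSION, STABLE

__all__ = [
    "GradingRecord",
    "ConfusionSummary",
    "BlandAltmanResult",
    "confusion_matrix",
    "subgroup_agreement",
    "bland_altman",
    "pearson_correlation",
    "read_grading_csv",
    "bundled_grading_records",
    "evaluate_methods",
]

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class GradingRecord:
    """One eye: the expert category plus per-method category and percent."""

    eye_id: str
    expert_category: str
    method_categories: dict
    method_percents: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expert_category not in CATEGORIES:
            raise ValidationError(
                f"unknown expert category {self.expert_category!r} for {self.eye_id}"
            )
        for m, c in self.method_categories.items():
            if c not in CATEGORIES:
                raise ValidationError(f"unknown category {c!r} for method {m!r}")


@dataclass(frozen=True)
class ConfusionSummary:
    """3×3 expert-vs-method counts (rows: expert progression/stable/
    regression; columns: method, same order) plus derived fractions."""

    counts: np.ndarray
    n_total: int
    agreement: float
    sensitivity: float | None
    specificity: float | None
    n_change: int
    n_stable: int
    opposite_direction_flags: int


def confusion_matrix(records: list[GradingRecord], method: str) -> ConfusionSummary:
    """Tabulate expert vs method categories and derive the summary fractions.

    ``sensitivity`` is None when there are no expert-changed eyes and
    ``specificity`` is None when there are no expert-stable eyes — flagged
    as undefined rather than silently 0.
    """
    if not records:
        raise ValidationError("no grading records")
    counts = np.zeros((3, 3), dtype=int)
    opposite = 0
    for rec in records:
        if method not in rec.method_categories:
            raise ValidationError(f"record {rec.eye_id} lacks method {method!r}")
        i = _CAT_INDEX[rec.expert_category]
        j = _CAT_INDEX[rec.method_categories[method]]
        counts[i, j] += 1
        if {rec.expert_category, rec.method_categories[method]} == {
            PROGRESSION,
            REGRESSION,
        }:
            opposite += 1
    n = int(counts.sum())
    agreement = float(np.trace(counts)) / n
    change_rows = [_CAT_INDEX[PROGRESSION], _CAT_INDEX[REGRESSION]]
    n_change = int(counts[change_rows, :].sum())
    same_direction = int(sum(counts[i, i] for i in change_rows))
    sensitivity = same_direction / n_change if n_change else None
    s = _CAT_INDEX[STABLE]
    n_stable = int(counts[s, :].sum())
    specificity = counts[s, s] / n_stable if n_stable else None
    return ConfusionSummary(
        counts=counts,
        n_total=n,
        agreement=agreement,
        sensitivity=sensitivity,
        specificity=specificity,
        n_change=n_change,
        n_stable=n_stable,
        opposite_direction_flags=opposite,
    )


def subgroup_agreement(
    records: list[GradingRecord], method: str, subgroup: str
) -> float:
    """Fraction of eyes in one expert subgroup where the method agrees."""
    if subgroup not in CATEGORIES:
        raise ValidationError(f"unknown subgroup {subgroup!r}")
    members = [r for r in records if r.expert_category == subgroup]
    if not members:
        raise ValidationError(f"subgroup {subgroup!r} is empty")
    hits = sum(1 for r in members if r.method_categories[method] == subgroup)
    return hits / len(members)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r_diff_vs_mean: float
    degenerate: bool  # zero-variance difference: r reported as 0


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired percent-change measurements.

    bias = mean(x−y); limits of agreement = bias ± 1.96·sd(x−y); the
    reported r correlates the pairwise difference against the pairwise mean
    (a proportional-bias check).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bland_altman requires equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("bland_altman requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("bland_altman requires finite values")
    diff = x - y
    mean = (x + y) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    degenerate = sd == 0 or np.std(mean) == 0
    r = 0.0 if degenerate else pearson_correlation(diff, mean)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        r_diff_vs_mean=r,
        degenerate=degenerate,
    )


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; raises on degenerate (zero-variance) input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("pearson_correlation requires equal 1-D vectors, n >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("pearson_correlation requires finite values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def read_grading_csv(path: str | Path) -> list[GradingRecord]:
    """Load a cohort grading table.

    Columns: ``eye_id,expert,mspr_pct,mspr_cat,cirrus_pct,cirrus_cat``
    (method columns are discovered from the ``*_cat`` / ``*_pct`` pattern,
    so other method names work too). Lines starting with ``#`` are comments.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"cannot read grading CSV {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"grading CSV {path} contains no records")
    if "eye_id" not in df.columns or "expert" not in df.columns:
        raise ValidationError(f"grading CSV {path} must have eye_id and expert columns")
    methods = sorted(c[: -len("_cat")] for c in df.columns if c.endswith("_cat"))
    if not methods:
        raise ValidationError(f"grading CSV {path} has no *_cat method columns")
    records = []
    for _, row in df.iterrows():
        cats = {m: str(row[f"{m}_cat"]) for m in methods}
        pcts = {
            m: float(row[f"{m}_pct"]) for m in methods if f"{m}_pct" in df.columns
        }
        records.append(
            GradingRecord(
                eye_id=str(row["eye_id"]),
                expert_category=str(row["expert"]),
                method_categories=cats,
                method_percents=pcts,
            )
        )
    return records


def bundled_grading_records() -> list[GradingRecord]:
    """The packaged 33-eye intermediate-AMD cohort grading table (11 eyes per
    expert subgroup) comparing multispectral pattern recognition ("mspr")
    and an OCT-based RPE-elevation change analysis ("cirrus") to expert
    grading. Categories are the observed cohort counts; percent columns are
    synthetic illustrative values consistent with the categories."""
    from importlib.resources import files

    return read_grading_csv(files("drusemap.data").joinpath("cohort_gradings.csv"))


def evaluate_methods(records: list[GradingRecord]) -> dict:
    """Full evaluation report for every method present in the records."""
    methods = sorted({m for r in records for m in r.method_categories})
    report: dict = {"n_eyes": len(records), "methods": {}}
    for m in methods:
        cs = confusion_matrix(records, m)
        report["methods"][m] = {
            "counts": cs.counts.tolist(),
            "agreement": cs.agreement,
            "sensitivity": cs.sensitivity,
            "specificity": cs.specificity,
            "subgroup_agreement": {
                g: subgroup_agreement(records, m, g)
                for g in CATEGORIES
                if any(r.expert_category == g for r in records)
            },
        }
    if len(methods) == 2 and all(
        set(r.method_percents) == set(methods) for r in records
    ):
        a, b = methods
        x = np.array([r.method_percents[a] for r in records])
        y = np.array([r.method_percents[b] for r in records])
        ba = bland_altman(x, y)
        report["bland_altman"] = {
            "methods": [a, b],
            "bias": ba.bias,
            "loa": [ba.loa_low, ba.loa_high],
            "r_diff_vs_mean": ba.r_diff_vs_mean,
        }
    return report
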