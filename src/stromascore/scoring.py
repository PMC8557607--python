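"""Stroma-immune (and intraepithelial-immune) score computation.

A patient's CD3 and CD8 stromal densities are each converted to a
percentile of the development-group density distribution (mid-rank
empirical CDF, range 0–100); the stroma-immune score is the mean of the
two percentiles. Thresholds splitting the development group into three
near-equal categories are derived once (quantile grouping in the style of
Hmisc's cut2, thresholds reported as upper-group minima) and then frozen:
validation cohorts are always mapped through the stored reference and
thresholds, never re-derived.

The intraepithelial-immune score is the identical computation with the
tumor-epithelium ROI and its own reference and thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

CATEGORY3 = ("low", "intermediate", "high")


@dataclass(frozen=True)
class PercentileReference:
    """Frozen development-group density distribution for one stain + ROI."""

    values: tuple[float, ...]  # sorted ascending
    stain: str = ""
    roi: str = ""

    @property
    def n(self) -> int:
        return len(self.values)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"stain": self.stain, "roi": self.roi, "sorted_values": list(self.values)})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PercentileReference":
        d = json.loads(Path(path).read_text())
        return cls(values=tuple(d["sorted_values"]), stain=d["stain"], roi=d["roi"])


@dataclass(frozen=True)
class CategoryThresholds:
    """Two cut points splitting scores into low / intermediate / high."""

    t1: float
    t2: float
    n: int  # derivation cohort size

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError(f"need t1 < t2, got ({self.t1}, {self.t2})")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"t1": self.t1, "t2": self.t2, "n": self.n}))

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoryThresholds":
        d = json.loads(Path(path).read_text())
        return cls(t1=d["t1"], t2=d["t2"], n=d["n"])


@dataclass(frozen=True)
class StromaImmuneScore:
    p_cd3: float
    p_cd8: float
    score: float
    category3: str
    category2: str


def build_percentile_reference(
    dev_densities, stain: str = "", roi: str = ""
) -> PercentileReference:
    """Freeze the development-group density distribution.

    Requires at least two finite non-negative values; duplicates are kept
    with multiplicity (they matter for the mid-rank percentile).
    """
    arr = np.asarray(list(dev_densities), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 development densities")
    bad = np.flatnonzero(~np.isfinite(arr) | (arr < 0))
    if bad.size:
        raise ValueError(f"invalid density at index {bad[0]}: {arr[bad[0]]}")
    return PercentileReference(values=tuple(np.sort(arr)), stain=stain, roi=roi)


def to_percentile(ref: PercentileReference, density: float) -> float:
    """Mid-rank percentile of ``density`` in the reference distribution.

    ``100 * (#below + 0.5 * #equal) / n``, clamped to [0, 100].
    """
    if not np.isfinite(density) or density < 0:
        raise ValueError(f"density must be finite and non-negative, got {density}")
    vals = np.asarray(ref.values)
    below = int(np.sum(vals < density))
    equal = int(np.sum(vals == density))
    pct = 100.0 * (below + 0.5 * equal) / ref.n
    return float(np.clip(pct, 0.0, 100.0))


def stroma_immune_score(p_cd3: float, p_cd8: float) -> float:
    """Average of the CD3 and CD8 percentiles."""
    for name, p in (("p_cd3", p_cd3), ("p_cd8", p_cd8)):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {p}")
    return (p_cd3 + p_cd8) / 2.0


def derive_category_thresholds(dev_scores, n_groups: int = 3) -> CategoryThresholds:
    """Quantile-based three-way split of the development scores.

    Emulates cut2-style grouping: the k-th threshold is the smallest
    observed score of the k-th upper group, placed so group sizes are as
    equal as ties permit (sorted index ⌊k·n/3⌋). Deterministic; rejects
    inputs with fewer than ``n_groups`` distinct values.
    """
    if n_groups != 3:
        raise ValueError("only the 3-group split used by the scoring scheme is supported")
    arr = np.sort(np.asarray(list(dev_scores), dtype=float))
    distinct = np.unique(arr)
    if distinct.size < n_groups:
        raise ValueError(
            f"need at least {n_groups} distinct scores, got {distinct.size}"
        )
    n = arr.size
    t1 = float(arr[int(n // 3)])
    t2 = float(arr[int(2 * n // 3)])
    if t2 <= t1:  # ties collapsed the cut points; advance t2 to the next value
        higher = distinct[distinct > t1]
        t2 = float(higher[0])
    if t1 <= float(arr[0]):  # t1 must leave a non-empty low group
        t1 = float(distinct[distinct > arr[0]][0])
        if t2 <= t1:
            t2 = float(distinct[distinct > t1][0])
    return CategoryThresholds(t1=t1, t2=t2, n=n)


def assign_category(score: float, thresholds: CategoryThresholds) -> tuple[str, str]:
    """(3-level, 2-level) category of a score.

    Boundary scores belong to the upper group (cut2 minimum-of-group
    convention); the 2-level category collapses intermediate+high → high.
    """
    if score < thresholds.t1:
        cat3 = "low"
    elif score < thresholds.t2:
        cat3 = "intermediate"
    else:
        cat3 = "high"
    return cat3, ("low" if cat3 == "low" else "high")


def score_patient(
    cd3_density: float,
    cd8_density: float,
    ref_cd3: PercentileReference,
    ref_cd8: PercentileReference,
    thresholds: CategoryThresholds,
) -> StromaImmuneScore:
    """Full per-patient scoring against a frozen reference."""
    p3 = to_percentile(ref_cd3, cd3_density)
    p8 = to_percentile(ref_cd8, cd8_density)
    s = stroma_immune_score(p3, p8)
    cat3, cat2 = assign_category(s, thresholds)
    return StromaImmuneScore(p_cd3=p3, p_cd8=p8, score=s, category3=cat3, category2=cat2)
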