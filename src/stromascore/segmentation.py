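"""Whole-slide tissue segmentation by overlapping-tile classification.

A slide at 20× working magnification is covered with 224×224 px tiles on a
75 px overlapped grid (stride 149), each tile is assigned the tissue class
of maximum probability, and every pixel takes the majority class among the
tiles covering it. Majority ties resolve to the class of the covering tile
whose anchor comes earliest in row-major order, making the label image
independent of tile processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale

from .classifier import ClassifierModel, featurize
from .taxonomy import CLASS_NAMES, N_CLASSES, TileClass

DEFAULT_TILE_SIDE = 224
DEFAULT_OVERLAP = 75
#: mpp below this is treated as 40× source and downscaled ×2 to 20×
MPP_40X_CUTOFF = 0.35


@dataclass(frozen=True)
class TileGrid:
    tile_side: int
    overlap: int
    xs: tuple[int, ...]
    ys: tuple[int, ...]

    @property
    def stride(self) -> int:
        return self.tile_side - self.overlap

    @property
    def anchors(self) -> list[tuple[int, int]]:
        """Top-left tile positions in row-major order (y outer, x inner)."""
        return [(x, y) for y in self.ys for x in self.xs]

    def __len__(self) -> int:
        return len(self.xs) * len(self.ys)


@dataclass(frozen=True)
class TissueMap:
    """Per-pixel nine-class label image at working magnification."""

    labels: np.ndarray  # (H, W) uint8 of class indices
    mpp: float

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.labels.max(initial=0) >= N_CLASSES:
            raise ValueError("labels contain invalid class indices")

    @property
    def per_class_px(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=N_CLASSES)
        return {CLASS_NAMES[i]: int(c) for i, c in enumerate(counts)}

    def class_pixels(self, cls: TileClass) -> int:
        return int(np.sum(self.labels == int(cls)))


@dataclass(frozen=True)
class TsrResult:
    """Tumor–stroma ratio: stroma / (stroma + tumor epithelium) area."""

    tsr: float
    category: str  # stroma_low | stroma_high (>= 50% is stroma_high)


def _axis_anchors(dim: int, tile_side: int, stride: int) -> tuple[int, ...]:
    anchors = list(range(0, dim - tile_side + 1, stride))
    if anchors[-1] + tile_side < dim:
        anchors.append(dim - tile_side)  # snap final tile to the boundary
    return tuple(anchors)


def plan_tile_grid(
    width_px: int,
    height_px: int,
    tile_side: int = DEFAULT_TILE_SIDE,
    overlap: int = DEFAULT_OVERLAP,
) -> TileGrid:
    """Anchor grid guaranteeing full slide coverage.

    Regular anchors at multiples of ``stride = tile_side - overlap``; when
    the last regular tile leaves uncovered pixels, one extra anchor per
    axis is snapped to ``dim - tile_side`` so no pixel is padded.
    """
    if not 0 <= overlap < tile_side:
        raise ValueError(f"need 0 ≤ overlap < tile_side, got overlap={overlap}")
    if width_px < tile_side or height_px < tile_side:
        raise ValueError(
            f"slide {width_px}×{height_px} is smaller than the {tile_side} px tile; "
            "upscale the slide or use a smaller tile_side"
        )
    stride = tile_side - overlap
    return TileGrid(
        tile_side=tile_side,
        overlap=overlap,
        xs=_axis_anchors(width_px, tile_side, stride),
        ys=_axis_anchors(height_px, tile_side, stride),
    )


def to_working_resolution(rgb: np.ndarray, mpp: float) -> tuple[np.ndarray, float]:
    """Downscale 40× sources (mpp ≤ 0.35) by 2 to the 20× working scale."""
    if mpp <= MPP_40X_CUTOFF:
        rgb = (
            rescale(rgb, 0.5, channel_axis=-1, anti_aliasing=True, preserve_range=True)
            .round()
            .clip(0, 255)
            .astype(np.uint8)
        )
        mpp *= 2.0
    return rgb, mpp


def classify_slide(
    model: ClassifierModel, slide: np.ndarray, grid: TileGrid, mpp: float = 0.5
) -> TissueMap:
    """Tile-classify a slide and fuse tile labels into a per-pixel map."""
    h, w = slide.shape[:2]
    side = grid.tile_side
    anchors = grid.anchors
    feats = np.stack(
        [
            featurize(slide[y : y + side, x : x + side], model.config.feature_side)
            for x, y in anchors
        ]
    )
    proba = model.predict_proba(feats)
    tile_cls = np.argmax(proba, axis=1)  # per-tile max-probability class

    counts = np.zeros((h, w, N_CLASSES), dtype=np.uint16)
    for (x, y), c in zip(anchors, tile_cls):
        counts[y : y + side, x : x + side, c] += 1
    cover = counts.sum(axis=-1)
    if (cover == 0).any():
        raise AssertionError("tile grid failed to cover the slide")  # grid contract

    max_count = counts.max(axis=-1)
    labels = counts.argmax(axis=-1).astype(np.uint8)
    n_at_max = (counts == max_count[..., None]).sum(axis=-1)
    tied = n_at_max > 1
    if tied.any():
        # earliest covering tile (row-major anchor order) wins the tie
        resolved = ~tied
        for (x, y), c in zip(anchors, tile_cls):
            sl = (slice(y, y + side), slice(x, x + side))
            winner = (~resolved[sl]) & (counts[sl][..., c] == max_count[sl])
            labels[sl][winner] = c
            resolved[sl][winner] = True
            if resolved.all():
                break
    return TissueMap(labels=labels, mpp=mpp)


def extract_roi_mask(tissue_map: TissueMap, target: TileClass) -> tuple[np.ndarray, float]:
    """Binary mask of one tissue class and its area in mm²."""
    target = TileClass(target)
    mask = tissue_map.labels == int(target)
    area_mm2 = float(mask.sum()) * tissue_map.mpp**2 / 1e6
    return mask, area_mm2


def compute_tsr(tissue_map: TissueMap) -> TsrResult:
    """Tumor–stroma ratio with the fixed 50% stroma-high threshold."""
    stroma = tissue_map.class_pixels(TileClass.STROMA)
    epithelium = tissue_map.class_pixels(TileClass.TUMOR_EPITHELIUM)
    if stroma + epithelium == 0:
        raise ValueError(
            "TSR undefined: neither stroma nor tumor epithelium present in the map"
        )
    tsr = stroma / (stroma + epithelium)
    return TsrResult(tsr=tsr, category="stroma_high" if tsr >= 0.5 else "stroma_low")
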