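"""DAB-positive cell detection and density computation.

Positive (brown) cells are quantified in three steps: Ruifrok–Johnston
color deconvolution of the RGB image into optical-density stain channels,
threshold + morphology segmentation of the DAB channel inside a region of
interest, and conversion of the resulting count to a density in cells/mm².

Optical density of an 8-bit channel value I is defined as
``OD = -log10((I + 1) / 256)`` — the +1 offset keeps a pure black pixel
finite. The per-pixel OD vector is projected onto a stain basis
(hematoxylin, DAB, residual unit vectors); the DAB coefficient is the
chromogen signal used for detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

# Ruifrok & Johnston H-DAB stain vectors (rows: hematoxylin, DAB); the
# residual is the unit cross product completing the basis.
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainProfile:
    """Unit optical-density vectors spanning RGB stain space.

    Rows of :attr:`matrix` are hematoxylin, DAB, residual. The default is
    the canonical H-DAB basis used throughout brown-chromogen IHC work.
    """

    hematoxylin: np.ndarray = field(default_factory=lambda: _unit(_HEMATOXYLIN))
    dab: np.ndarray = field(default_factory=lambda: _unit(_DAB))
    residual: np.ndarray = field(
        default_factory=lambda: _unit(np.cross(_HEMATOXYLIN, _DAB))
    )

    def __post_init__(self) -> None:
        for name in ("hematoxylin", "dab", "residual"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError(f"stain vector {name!r} must be a unit 3-vector")
            object.__setattr__(self, name, v)
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain vectors are linearly dependent; cannot deconvolve")

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([self.hematoxylin, self.dab, self.residual])


@dataclass(frozen=True)
class CellDetectionParams:
    """Detector knobs, calibrated for 20× working resolution (~0.5 µm/px).

    ``min_area_px``/``max_area_px`` bracket a lymphocyte footprint
    (~7–10 µm diameter → roughly 150–300 px at 0.5 µm/px, with generous
    slack); components above ``max_area_px`` are split by a
    distance-transform watershed whose seeds are local maxima at least
    ``seed_min_distance_px`` apart.
    """

    od_threshold: float = 0.15
    min_area_px: int = 30
    max_area_px: int = 1500
    seed_min_distance_px: int = 5


@dataclass(frozen=True)
class CellQuantResult:
    """Positive-cell quantification for one stain on one slide."""

    n_cells: int
    centroids: tuple[tuple[float, float], ...]  # (x, y) pixel coordinates
    roi_area_mm2: float | None = None
    density: float | None = None  # cells per mm²


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical density."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    return -np.log10((rgb.astype(np.float64) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; clips to valid 8-bit values."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def deconvolve_dab(rgb: np.ndarray, profile: StainProfile | None = None) -> np.ndarray:
    """Return the DAB optical-density coefficient image, clipped at 0.

    The OD vector of every pixel is expressed in the stain basis by solving
    ``od = coeffs @ profile.matrix``; only the DAB coefficient is returned.
    """
    profile = profile or StainProfile()
    od = rgb_to_od(rgb)
    coeffs = od.reshape(-1, 3) @ np.linalg.inv(profile.matrix)
    dab = coeffs[:, 1].reshape(rgb.shape[:2])
    return np.clip(dab, 0.0, None)


def deconvolve(rgb: np.ndarray, profile: StainProfile | None = None) -> np.ndarray:
    """Full stain-coefficient image, shape (H, W, 3): H, DAB, residual."""
    profile = profile or StainProfile()
    od = rgb_to_od(rgb)
    return (od.reshape(-1, 3) @ np.linalg.inv(profile.matrix)).reshape(od.shape)


def _split_large_component(mask: np.ndarray, params: CellDetectionParams) -> np.ndarray:
    """Watershed-split one oversized binary component; returns a label image."""
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=params.seed_min_distance_px, labels=mask, exclude_border=False
    )
    if len(peaks) < 2:
        return mask.astype(np.int32)
    markers = np.zeros_like(mask, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=mask)


def segment_positive_cells(
    dab: np.ndarray,
    roi_mask: np.ndarray,
    params: CellDetectionParams | None = None,
) -> CellQuantResult:
    """Detect DAB-positive cells inside ``roi_mask``.

    Pipeline: threshold the DAB OD channel at ``od_threshold`` within the
    ROI, fill holes, drop components below ``min_area_px``, watershed-split
    components above ``max_area_px``, and count the resulting connected
    components. Centroids are reported in (x, y) pixel coordinates.
    """
    params = params or CellDetectionParams()
    dab = np.asarray(dab, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if dab.shape != roi_mask.shape:
        raise ValueError(
            f"DAB channel shape {dab.shape} != ROI mask shape {roi_mask.shape}"
        )
    if not roi_mask.any():
        logger.warning("empty ROI mask; reporting zero cells")
        return CellQuantResult(n_cells=0, centroids=())

    binary = (dab >= params.od_threshold) & roi_mask
    binary = ndi.binary_fill_holes(binary)

    labels = cc_label(binary, connectivity=2)
    centroids: list[tuple[float, float]] = []
    next_label_img_needed = False
    for region in regionprops(labels):
        if region.area < params.min_area_px:
            continue
        if region.area > params.max_area_px:
            sub = labels[region.slice] == region.label
            split = _split_large_component(sub, params)
            for part in regionprops(split):
                if part.area < params.min_area_px:
                    continue
                cy, cx = part.centroid
                centroids.append(
                    (cx + region.slice[1].start, cy + region.slice[0].start)
                )
            next_label_img_needed = True
            continue
        cy, cx = region.centroid
        centroids.append((cx, cy))
    if next_label_img_needed:
        logger.debug("watershed splitting applied to oversized components")

    return CellQuantResult(n_cells=len(centroids), centroids=tuple(centroids))


def compute_density(result: CellQuantResult, roi_area_mm2: float) -> CellQuantResult:
    """Attach a cells/mm² density to a quantification result."""
    if not np.isfinite(roi_area_mm2) or roi_area_mm2 <= 0:
        raise ValueError(f"ROI area must be positive, got {roi_area_mm2}")
    return replace(
        result,
        roi_area_mm2=float(roi_area_mm2),
        density=result.n_cells / float(roi_area_mm2),
    )
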