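"""Slide, mask and sidecar-metadata I/O.

Slides are plain RGB images: TIFF (microns-per-pixel stored in the
resolution tags) or PNG with a ``<name>.mpp.json`` sidecar holding
``{"mpp": float}``. Label masks are single-channel PNGs of class indices
with a JSON sidecar naming the classes. An optional openslide backend is
used for pyramidal sources when the library is importable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .taxonomy import CLASS_NAMES

_CM_PER_INCH = 2.54


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".mpp.json")


def write_slide(path: str | Path, rgb: np.ndarray, mpp: float) -> None:
    """Write an RGB slide; mpp goes to TIFF tags or a JSON sidecar."""
    path = Path(path)
    rgb = np.ascontiguousarray(rgb, dtype=np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px_per_cm = 1e4 / mpp
        tifffile.imwrite(
            path,
            rgb,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        Image.fromarray(rgb).save(path)
        _sidecar_path(path).write_text(json.dumps({"mpp": float(mpp)}))


def _mpp_from_tiff(path: Path) -> float | None:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None or unit is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        px_per_unit = num / den
        unit_val = getattr(unit.value, "value", unit.value)
        if unit_val == 3:  # centimeter
            return 1e4 / px_per_unit
        if unit_val == 2:  # inch
            return 1e4 * _CM_PER_INCH / px_per_unit
        return None


def read_slide(path: str | Path, mpp_override: float | None = None) -> tuple[np.ndarray, float]:
    """Read an RGB slide and resolve its microns-per-pixel.

    Resolution order: explicit override, TIFF resolution tags or PNG
    sidecar, else the documented default of 0.5 µm/px (20×).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        rgb = tifffile.imread(path)
        mpp = _mpp_from_tiff(path)
    else:
        rgb = np.asarray(Image.open(path).convert("RGB"))
        sidecar = _sidecar_path(path)
        mpp = json.loads(sidecar.read_text())["mpp"] if sidecar.exists() else None
    if rgb.ndim == 2:
        rgb = np.stack([rgb] * 3, axis=-1)
    if rgb.shape[-1] == 4:
        rgb = rgb[..., :3]
    if mpp_override is not None:
        mpp = float(mpp_override)
    if mpp is None:
        mpp = 0.5
    return np.ascontiguousarray(rgb, dtype=np.uint8), float(mpp)


def write_mask(path: str | Path, labels: np.ndarray, mpp: float) -> None:
    """Write a class-index mask as single-channel PNG + JSON sidecar."""
    path = Path(path)
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(path)
    counts = {
        CLASS_NAMES[i]: int(n)
        for i, n in enumerate(np.bincount(labels.ravel(), minlength=len(CLASS_NAMES)))
    }
    meta = {"class_names": list(CLASS_NAMES), "mpp": float(mpp), "per_class_px": counts}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_mask(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    labels = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    return labels, float(meta["mpp"])
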