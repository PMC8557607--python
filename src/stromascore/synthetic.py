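"""Synthetic fixtures: tissue tiles, pseudo-whole-slide images and cohorts.

Everything the scoring pipeline consumes can be generated here with known
ground truth: labeled tiles for the nine tissue classes, composite slides
with exact region masks and planted DAB-positive cells, and survival
cohorts with a known log-hazard effect of the immune score.

Randomness discipline: every generator derives its random state as
``numpy.random.default_rng(SeedSequence(seed, spawn_key=key))`` where the
spawn key names the fixture element (class index, stain, patient number).
Two calls with the same spec and seed are therefore bit-identical, and
individual elements are reproducible in isolation.

Tile appearance is an artifact convention, not a histology claim: each
class has a base color plus a class-specific texture (fibrous streaks for
stroma, dense dark nuclei for lymphocytes, near-white emptiness for
background, ...) chosen so that classes are statistically separable while
remaining non-constant images. Planted cells are rendered as brown disks
whose optical-density vector lies along the canonical DAB stain vector, so
the real color-deconvolution detector — not a shortcut — finds them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Polygon
import shapely
from skimage.draw import disk as disk_indices

from .quantify import od_to_rgb, StainProfile
from .taxonomy import TileClass

STAINS = ("CD3", "CD8")

Region = tuple[int, int, int, int] | Polygon  # (x0, y0, x1, y1) half-open, or polygon


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream of the master seed (documented splitting scheme)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# --------------------------------------------------------------------------
# tissue tile textures
# --------------------------------------------------------------------------

# Base RGB color and flat-noise SD per class; textures are added on top.
# IHC slides carry only a hematoxylin counterstain besides the chromogen,
# so tissue tones are blue-gray/lavender tints chosen with a near-zero
# projection onto the DAB deconvolution vector — only planted chromogen
# disks should light up the DAB channel.
_BASE: dict[TileClass, tuple[tuple[int, int, int], float]] = {
    TileClass.TUMOR_EPITHELIUM: ((168, 122, 196), 8.0),
    TileClass.STROMA: ((206, 202, 224), 6.0),
    TileClass.ADIPOSE: ((244, 242, 244), 3.0),
    TileClass.BACKGROUND: ((250, 250, 250), 2.0),
    TileClass.DEBRIS: ((134, 130, 164), 12.0),
    TileClass.LYMPHOCYTES: ((198, 188, 222), 6.0),
    TileClass.MUCUS: ((214, 228, 232), 4.0),
    TileClass.MUSCLE: ((172, 162, 204), 6.0),
    TileClass.NORMAL_MUCOSA: ((200, 178, 214), 6.0),
}


def _scatter_disks(
    img: np.ndarray,
    rng: np.random.Generator,
    n: int,
    radius: tuple[int, int],
    color: tuple[int, int, int],
) -> None:
    h, w = img.shape[:2]
    for _ in range(n):
        r = int(rng.integers(radius[0], radius[1] + 1))
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rr, cc = disk_indices((cy, cx), r, shape=(h, w))
        img[rr, cc] = color


# per-tile chromogen load when rendering training tiles: T-cell-bearing
# classes carry brown DAB disks at a class-specific density (per px²)
_CHROMOGEN_DENSITY: dict[TileClass, float] = {
    TileClass.STROMA: 1 / 1400,
    TileClass.LYMPHOCYTES: 1 / 2000,
    TileClass.TUMOR_EPITHELIUM: 1 / 8000,
}


def _render_texture(
    cls: TileClass,
    shape: tuple[int, int],
    rng: np.random.Generator,
    chromogen: bool = True,
) -> np.ndarray:
    """Class-specific RGB texture of the given (H, W) shape, uint8.

    ``chromogen=True`` (training tiles) scatters brown DAB-positive disks
    over the T-cell-bearing classes, as stained tissue would carry;
    composite slides render with ``chromogen=False`` so that the planted
    cell list remains the exact ground-truth count.
    """
    h, w = shape
    base, sd = _BASE[cls]
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = base
    area = h * w

    if cls is TileClass.TUMOR_EPITHELIUM:
        # crowded medium nuclei
        u8 = img.astype(np.uint8)
        _scatter_disks(u8, rng, max(1, area // 900), (3, 5), (118, 84, 178))
        img = u8.astype(np.float64)
    elif cls is TileClass.STROMA:
        # faint fibrous streaks: low-frequency sinusoid along a random direction
        yy, xx = np.mgrid[0:h, 0:w]
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin((xx * np.cos(theta) + yy * np.sin(theta)) / 6.0 + phase)
        img += (wave * 9.0)[..., None]  # lightness-only modulation
    elif cls is TileClass.ADIPOSE:
        # pale field densely broken by gray septa rings
        u8 = img.astype(np.uint8)
        for _ in range(max(3, area // 1800)):
            r = int(rng.integers(8, 16))
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            rr, cc = disk_indices((cy, cx), r, shape=(h, w))
            inner_rr, inner_cc = disk_indices((cy, cx), max(1, r - 3), shape=(h, w))
            u8[rr, cc] = (170, 170, 178)
            u8[inner_rr, inner_cc] = (246, 244, 246)
        img = u8.astype(np.float64)
    elif cls is TileClass.DEBRIS:
        img += rng.normal(0, 22, size=(h, w, 1))
    elif cls is TileClass.LYMPHOCYTES:
        # dense small dark-blue nuclei
        u8 = img.astype(np.uint8)
        _scatter_disks(u8, rng, max(1, area // 260), (2, 3), (62, 52, 134))
        img = u8.astype(np.float64)
    elif cls is TileClass.MUSCLE:
        yy = np.arange(h)[:, None]
        stripes = np.sin(yy / 3.5 + rng.uniform(0, 2 * np.pi))
        img += (stripes * 14.0)[..., None]
    elif cls is TileClass.NORMAL_MUCOSA:
        # sparse gland-like rings of darker epithelium
        u8 = img.astype(np.uint8)
        for _ in range(max(1, area // 3500)):
            r = int(rng.integers(6, 11))
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            rr, cc = disk_indices((cy, cx), r, shape=(h, w))
            inner_rr, inner_cc = disk_indices((cy, cx), max(1, r - 3), shape=(h, w))
            u8[rr, cc] = (152, 132, 186)
            u8[inner_rr, inner_cc] = (224, 210, 232)
        img = u8.astype(np.float64)
    # BACKGROUND and MUCUS: flat base + noise only

    img += rng.normal(0, sd, size=(h, w, 3))
    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if chromogen and cls in _CHROMOGEN_DENSITY:
        # zero-inflated load so unstained examples of each class are
        # well represented in a training corpus
        if rng.random() < 0.25:
            n = 0
        else:
            n = int(rng.integers(0, max(2, int(area * _CHROMOGEN_DENSITY[cls]))))
        for _ in range(n):
            r = rng.uniform(5, 8)
            cx = rng.uniform(r, w - r) if w > 2 * r else w / 2
            cy = rng.uniform(r, h - r) if h > 2 * r else h / 2
            _render_dab_disk(out, (cx, cy), r, rng)
    return out


def generate_tissue_tile(cls: TileClass | str, side_px: int, rng_seed: int) -> np.ndarray:
    """Deterministic RGB tile of one tissue class.

    Same (class, side, seed) → identical pixels. Raises for unknown class
    names or tiles smaller than 32 px.
    """
    if isinstance(cls, str):
        cls = TileClass.from_name(cls)
    if side_px < 32:
        raise ValueError(f"side_px must be ≥ 32, got {side_px}")
    rng = child_rng(rng_seed, 0, int(cls))
    return _render_texture(cls, (side_px, side_px), rng)


def generate_tile_corpus(
    tiles_per_class: int, side_px: int = 64, rng_seed: int = 0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Stack of labeled tiles covering all nine classes, for training runs."""
    tiles: list[np.ndarray] = []
    labels: list[int] = []
    for cls in TileClass:
        for i in range(tiles_per_class):
            rng = child_rng(rng_seed, 0, int(cls), i)
            tiles.append(_render_texture(cls, (side_px, side_px), rng))
            labels.append(int(cls))
    return tiles, np.asarray(labels)


# --------------------------------------------------------------------------
# composite slides
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Layout of one pseudo-WSI with known ground truth.

    ``region_layout`` is rasterized with the pixel-center rule (a pixel at
    integer (x, y) belongs to a region iff its center (x+0.5, y+0.5) is
    inside); later entries overwrite earlier ones; uncovered canvas is the
    background class. ``planted_cells`` maps stain → list of
    ((cx, cy), radius_px) disks that must be pairwise disjoint and lie
    fully inside ``planted_region``.
    """

    width_px: int
    height_px: int
    mpp: float
    region_layout: tuple[tuple[Region, TileClass], ...] = ()
    planted_cells: dict[str, tuple[tuple[tuple[float, float], float], ...]] = field(
        default_factory=dict
    )
    planted_region: TileClass = TileClass.STROMA
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.mpp <= 0:
            raise ValueError("slide dimensions and mpp must be positive")


def rasterize_layout(spec: SyntheticSlideSpec) -> np.ndarray:
    """Ground-truth class-index mask for a slide spec."""
    h, w = spec.height_px, spec.width_px
    mask = np.full((h, w), int(TileClass.BACKGROUND), dtype=np.uint8)
    for region, cls in spec.region_layout:
        if isinstance(region, Polygon):
            xs = np.arange(w) + 0.5
            ys = np.arange(h) + 0.5
            gx, gy = np.meshgrid(xs, ys)
            inside = shapely.contains_xy(region, gx.ravel(), gy.ravel()).reshape(h, w)
            mask[inside] = int(cls)
        else:
            x0, y0, x1, y1 = region
            mask[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)] = int(cls)
    return mask


def _validate_planted(spec: SyntheticSlideSpec, mask: np.ndarray) -> None:
    target = int(spec.planted_region)
    all_cells = [
        (stain, i, c, r)
        for stain, cells in spec.planted_cells.items()
        for i, (c, r) in enumerate(cells)
    ]
    for stain, i, (cx, cy), r in all_cells:
        if cx - r < 0 or cy - r < 0 or cx + r > spec.width_px or cy + r > spec.height_px:
            raise ValueError(
                f"planted cell {stain}[{i}] at ({cx}, {cy}) r={r} extends outside the canvas"
            )
        rr, cc = disk_indices((cy, cx), r, shape=mask.shape)
        if not np.all(mask[rr, cc] == target):
            raise ValueError(
                f"planted cell {stain}[{i}] at ({cx}, {cy}) is not fully inside "
                f"the {spec.planted_region.label} region"
            )
    for stain in spec.planted_cells:
        cells = spec.planted_cells[stain]
        for i in range(len(cells)):
            (x1, y1), r1 = cells[i]
            for j in range(i + 1, len(cells)):
                (x2, y2), r2 = cells[j]
                if np.hypot(x1 - x2, y1 - y2) < r1 + r2:
                    raise ValueError(f"planted cells {stain}[{i}] and {stain}[{j}] overlap")


def _render_dab_disk(
    img: np.ndarray, center: tuple[float, float], radius: float, rng: np.random.Generator
) -> None:
    """Draw one chromogen disk: DAB optical density highest at the center."""
    cx, cy = center
    rr, cc = disk_indices((cy, cx), radius, shape=img.shape[:2])
    dist = np.hypot(cc - cx, rr - cy)
    od_center = rng.uniform(0.75, 1.05)
    od = od_center * (1.0 - 0.6 * (dist / max(radius, 1.0)))
    dab_dir = StainProfile().dab
    rgb = od_to_rgb(od[:, None] * dab_dir[None, :])
    jitter = rng.integers(-4, 5, size=rgb.shape)
    img[rr, cc] = np.clip(rgb.astype(int) + jitter, 0, 255).astype(np.uint8)


def generate_slide(
    spec: SyntheticSlideSpec, stain: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one stain's slide: (RGB image, ground-truth mask, cell count).

    The regional background uses the same per-class texture recipes as
    :func:`generate_tissue_tile`, so tiles cropped from a slide are
    classifiable by a model trained on generated tiles.
    """
    if stain not in STAINS:
        raise ValueError(f"stain must be one of {STAINS}, got {stain!r}")
    mask = rasterize_layout(spec)
    _validate_planted(spec, mask)

    img = np.empty((spec.height_px, spec.width_px, 3), dtype=np.uint8)
    for cls_idx in np.unique(mask):
        cls = TileClass(int(cls_idx))
        rng = child_rng(spec.rng_seed, 1, int(cls))
        texture = _render_texture(cls, mask.shape, rng, chromogen=False)
        sel = mask == cls_idx
        img[sel] = texture[sel]

    cells = spec.planted_cells.get(stain, ())
    cell_rng = child_rng(spec.rng_seed, 2, STAINS.index(stain))
    for center, radius in cells:
        _render_dab_disk(img, center, radius, cell_rng)
    return img, mask, len(cells)


def plant_cells_in_rect(
    rect: tuple[int, int, int, int],
    n_cells: int,
    rng: np.random.Generator,
    radius_px: float = 7.0,
    min_gap_px: float = 4.0,
) -> tuple[tuple[tuple[float, float], float], ...]:
    """Dart-throw ``n_cells`` non-overlapping disks inside a rectangle.

    Raises if the rectangle cannot accommodate the requested count within a
    bounded number of attempts (the fixture must fail loudly, not thin out).
    """
    x0, y0, x1, y1 = rect
    margin = radius_px + 1
    placed: list[tuple[float, float]] = []
    min_dist = 2 * radius_px + min_gap_px
    attempts = 0
    max_attempts = 400 * max(n_cells, 1)
    while len(placed) < n_cells:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells of radius "
                f"{radius_px} in rectangle {rect}"
            )
        attempts += 1
        cx = rng.uniform(x0 + margin, x1 - margin)
        cy = rng.uniform(y0 + margin, y1 - margin)
        if all(np.hypot(cx - px, cy - py) >= min_dist for px, py in placed):
            placed.append((cx, cy))
    return tuple(((cx, cy), radius_px) for cx, cy in placed)


# --------------------------------------------------------------------------
# survival cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort with exponential event times driven by a standard-normal score.

    Hazard for patient i is ``baseline_hazard * exp(score_i * beta +
    covariates_i · effects)`` with ``beta = true_log_hr_per_score_sd``.
    Censoring is independent uniform administrative censoring on
    [0, T_max], with T_max solved so the expected censored fraction equals
    ``censor_rate``.
    """

    n_patients: int
    true_log_hr_per_score_sd: float = 0.0
    baseline_hazard: float = np.log(2) / 60.0  # per month; median OS 60 months
    censor_rate: float = 0.25
    covariate_effects: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        unknown = set(self.covariate_effects) - {"age", "sex", "stage", "site"}
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def _solve_censor_horizon(rates: np.ndarray, target: float) -> float:
    """T_max such that mean_i P(censor before event) equals ``target``.

    For exponential T with rate λ and C ~ U(0, M):
    P(C < T) = (1 - exp(-λM)) / (λM), decreasing in M from 1 to 0.
    """

    def frac(m: float) -> float:
        lm = rates * m
        return float(np.mean((1.0 - np.exp(-lm)) / lm))

    lo, hi = 1e-9, 1e9
    return brentq(lambda m: frac(m) - target, lo, hi, xtol=1e-10, rtol=1e-12)


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate one cohort table.

    Columns: patient_id, time_months, event, score, age, sex, stage, site.
    Covariate codings for the hazard: age enters per year centered at 63;
    sex as female=1; stage as III=1; site as rectum=1.
    """
    rng = child_rng(spec.rng_seed, 3)
    n = spec.n_patients
    score = rng.standard_normal(n)
    age = np.clip(rng.normal(63.0, 11.0, size=n), 30, 92)
    sex = rng.choice(["male", "female"], size=n)
    stage = rng.choice(["II", "III"], size=n)
    site = rng.choice(["colon", "rectum"], size=n)

    eff = spec.covariate_effects
    lin = spec.true_log_hr_per_score_sd * score
    lin = lin + eff.get("age", 0.0) * (age - 63.0)
    lin = lin + eff.get("sex", 0.0) * (sex == "female")
    lin = lin + eff.get("stage", 0.0) * (stage == "III")
    lin = lin + eff.get("site", 0.0) * (site == "rectum")
    rates = spec.baseline_hazard * np.exp(lin)

    t_event = rng.exponential(1.0 / rates)
    if spec.censor_rate >= 1.0:
        time = rng.uniform(0.0, 1.0 / spec.baseline_hazard, size=n)
        event = np.zeros(n, dtype=int)
    elif spec.censor_rate <= 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        t_max = _solve_censor_horizon(rates, spec.censor_rate)
        t_censor = rng.uniform(0.0, t_max, size=n)
        event = (t_event <= t_censor).astype(int)
        time = np.minimum(t_event, t_censor)
    time = np.maximum(time, 1e-6)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "score": score,
            "age": age,
            "sex": sex,
            "stage": stage,
            "site": site,
        }
    )


# --------------------------------------------------------------------------
# end-to-end synthetic study (slides + cohort on disk)
# --------------------------------------------------------------------------

# reference stromal T-cell density magnitudes (cells/mm²) used to scale fixtures
CD3_DENSITY_SCALE = 1304.0
CD8_DENSITY_SCALE = 472.0


def generate_study(
    out_dir: str | Path,
    n_patients: int,
    true_log_hr_per_score_sd: float = np.log(0.4),
    rng_seed: int = 0,
    slide_px: int = 560,
    mpp: float = 0.5,
    censor_rate: float = 0.25,
) -> pd.DataFrame:
    """Write a complete synthetic study cohort: slide pairs + cohort.csv.

    Per patient a latent immune level z ~ N(0, 1) sets correlated CD3/CD8
    stromal densities (log-normal around the 1304 / 472 cells/mm² scales)
    and the survival hazard via ``exp(z * beta)`` — higher infiltration is
    protective for beta < 0. Slides are written as ``<id>_CD3.png`` /
    ``<id>_CD8.png`` with an mpp sidecar; ground-truth planted counts and
    latent z are returned (and saved as truth.csv) for diagnostics.
    """
    from .io import write_slide  # local import to avoid a cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = child_rng(rng_seed, 4)

    radius = 7.0
    rows = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        z = rng.standard_normal()
        # the stroma band must stay wider than one 224-px tile so that at
        # least one grid tile is majority-stroma
        split = rng.uniform(0.42, 0.58)
        x_split = max(int(slide_px * split), 235)
        stroma_rect = (0, 0, x_split, slide_px)
        epi_rect = (x_split, 0, slide_px, slide_px)
        stroma_area_mm2 = x_split * slide_px * mpp**2 / 1e6

        counts = {}
        cells = {}
        for stain, scale in (("CD3", CD3_DENSITY_SCALE), ("CD8", CD8_DENSITY_SCALE)):
            dens = scale * np.exp(0.55 * z + 0.25 * rng.standard_normal())
            n_cells = max(1, int(round(dens * stroma_area_mm2)))
            n_cells = min(n_cells, int(0.5 * (x_split * slide_px) / (2 * radius + 4) ** 2))
            cells[stain] = plant_cells_in_rect(
                stroma_rect, n_cells, rng, radius_px=radius
            )
            counts[stain] = n_cells

        spec = SyntheticSlideSpec(
            width_px=slide_px,
            height_px=slide_px,
            mpp=mpp,
            region_layout=(
                (stroma_rect, TileClass.STROMA),
                (epi_rect, TileClass.TUMOR_EPITHELIUM),
            ),
            planted_cells=cells,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        for stain in STAINS:
            img, _, _ = generate_slide(spec, stain)
            write_slide(out_dir / f"{pid}_{stain}.png", img, mpp)
        rows.append(
            {
                "patient_id": pid,
                "z": z,
                "n_cd3": counts["CD3"],
                "n_cd8": counts["CD8"],
                "stroma_area_mm2": stroma_area_mm2,
            }
        )

    truth = pd.DataFrame(rows)
    z = truth["z"].to_numpy()
    cohort_rng = child_rng(rng_seed, 5)
    baseline = np.log(2) / 60.0
    rates = baseline * np.exp(true_log_hr_per_score_sd * z)
    t_event = cohort_rng.exponential(1.0 / rates)
    if censor_rate > 0:
        t_max = _solve_censor_horizon(rates, censor_rate)
        t_censor = cohort_rng.uniform(0.0, t_max, size=len(z))
        event = (t_event <= t_censor).astype(int)
        time = np.minimum(t_event, t_censor)
    else:
        event, time = np.ones(len(z), dtype=int), t_event

    cohort = pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "time_months": np.maximum(time, 1e-6),
            "event": event,
            "score": z,
            "age": np.clip(cohort_rng.normal(63.0, 11.0, size=len(z)), 30, 92),
            "sex": cohort_rng.choice(["male", "female"], size=len(z)),
            "stage": cohort_rng.choice(["II", "III"], size=len(z)),
            "site": cohort_rng.choice(["colon", "rectum"], size=len(z)),
        }
    )
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return cohort
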