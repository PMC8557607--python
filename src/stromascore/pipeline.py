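"""End-to-end orchestration: slide pair → tissue map → densities → score →
survival evaluation, as one reproducible run with provenance.

A study directory holds, per patient, ``<id>_CD3.<ext>`` and
``<id>_CD8.<ext>`` slides plus a ``cohort.csv`` with the survival table.
``run_study`` quantifies every patient, derives the percentile reference
and category thresholds on the development cohort only, scores every
cohort against those frozen artifacts, and emits Kaplan–Meier / Cox /
bootstrap-C results with the full configuration serialized alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import ClassifierModel
from .io import read_slide
from .quantify import (
    CellDetectionParams,
    CellQuantResult,
    compute_density,
    deconvolve_dab,
    segment_positive_cells,
)
from .scoring import (
    CategoryThresholds,
    PercentileReference,
    StromaImmuneScore,
    build_percentile_reference,
    derive_category_thresholds,
    score_patient,
    stroma_immune_score,
    to_percentile,
)
from .segmentation import (
    TsrResult,
    classify_slide,
    compute_tsr,
    extract_roi_mask,
    plan_tile_grid,
    to_working_resolution,
)
from .survival import (
    bootstrap_c_compare,
    cox_fit,
    km_estimate,
    logrank_test,
)
from .taxonomy import TileClass

logger = logging.getLogger(__name__)

STAINS = ("CD3", "CD8")
SLIDE_EXTS = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run needs; serialized verbatim for provenance."""

    model_path: str
    tile_side: int = 224
    overlap: int = 75
    mpp_override: float | None = None
    detector: CellDetectionParams = field(default_factory=CellDetectionParams)
    roi_targets: tuple[str, ...] = ("stroma",)
    bootstrap_B: int = 1000
    master_seed: int = 0
    tsr_stain: str = "CD3"  # which stain's map supplies the TSR

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=str)


@dataclass
class PatientImmuneRecord:
    patient_id: str
    quant: dict[str, CellQuantResult]  # stain → stroma quantification
    quant_epithelium: dict[str, CellQuantResult] = field(default_factory=dict)
    tsr: TsrResult | None = None
    score: StromaImmuneScore | None = None
    unscorable: bool = False
    note: str = ""


def _find_slide(directory: Path, patient_id: str, stain: str) -> Path:
    for ext in SLIDE_EXTS:
        p = directory / f"{patient_id}_{stain}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(
        f"missing {stain} slide for patient {patient_id} in {directory}"
    )


def quantify_patient(
    cd3_path: str | Path,
    cd8_path: str | Path,
    model: ClassifierModel,
    config: RunConfig,
    patient_id: str = "",
) -> PatientImmuneRecord:
    """Segment both stains' slides and quantify stromal (and optionally
    intraepithelial) positive-cell densities plus the TSR.

    Deterministic given the inputs and config. A patient whose maps
    contain no stroma on either slide is flagged unscorable rather than
    silently scored zero.
    """
    paths = {"CD3": Path(cd3_path), "CD8": Path(cd8_path)}
    for stain, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing {stain} slide: {p}")

    quant: dict[str, CellQuantResult] = {}
    quant_epi: dict[str, CellQuantResult] = {}
    tsr: TsrResult | None = None
    stains_missing_stroma: list[str] = []
    for stain, p in paths.items():
        rgb, mpp = read_slide(p, mpp_override=config.mpp_override)
        rgb, mpp = to_working_resolution(rgb, mpp)
        grid = plan_tile_grid(rgb.shape[1], rgb.shape[0], config.tile_side, config.overlap)
        tmap = classify_slide(model, rgb, grid, mpp=mpp)
        if stain == config.tsr_stain:
            try:
                tsr = compute_tsr(tmap)
            except ValueError:
                tsr = None
        dab = deconvolve_dab(rgb)
        mask, area = extract_roi_mask(tmap, TileClass.STROMA)
        if area > 0:
            res = segment_positive_cells(dab, mask, config.detector)
            quant[stain] = compute_density(res, area)
        else:
            stains_missing_stroma.append(stain)
            quant[stain] = CellQuantResult(n_cells=0, centroids=())
        if "tumor_epithelium" in config.roi_targets:
            emask, earea = extract_roi_mask(tmap, TileClass.TUMOR_EPITHELIUM)
            if earea > 0:
                eres = segment_positive_cells(dab, emask, config.detector)
                quant_epi[stain] = compute_density(eres, earea)

    rec = PatientImmuneRecord(
        patient_id=patient_id, quant=quant, quant_epithelium=quant_epi, tsr=tsr
    )
    if stains_missing_stroma:
        # a density is undefined for any stain whose map holds no stroma
        rec.unscorable = True
        rec.note = f"no stroma detected on: {', '.join(stains_missing_stroma)}"
        logger.warning("patient %s: %s", patient_id, rec.note)
    return rec


def _reconcile(directory: Path, cohort: pd.DataFrame) -> tuple[list[str], dict[str, list[str]]]:
    """Intersect slide pairs on disk with cohort rows; report mismatches."""
    csv_ids = set(cohort["patient_id"].astype(str))
    slide_ids = set()
    for p in directory.iterdir():
        for stain in STAINS:
            for ext in SLIDE_EXTS:
                if p.name.endswith(f"_{stain}{ext}"):
                    slide_ids.add(p.name[: -len(f"_{stain}{ext}")])
    paired = {
        pid
        for pid in slide_ids
        if all(
            any((directory / f"{pid}_{s}{e}").exists() for e in SLIDE_EXTS)
            for s in STAINS
        )
    }
    usable = sorted(csv_ids & paired)
    report = {
        "slides_without_cohort_row": sorted(paired - csv_ids),
        "cohort_rows_without_slides": sorted(csv_ids - paired),
    }
    return usable, report


def _quantify_cohort(
    directory: Path, cohort: pd.DataFrame, model: ClassifierModel, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    usable, reconciliation = _reconcile(directory, cohort)
    rows = []
    for pid in usable:
        rec = quantify_patient(
            _find_slide(directory, pid, "CD3"),
            _find_slide(directory, pid, "CD8"),
            model,
            config,
            patient_id=pid,
        )
        if rec.unscorable:
            reconciliation.setdefault("unscorable", []).append(pid)
            continue
        rows.append(
            {
                "patient_id": pid,
                "cd3_density": rec.quant["CD3"].density,
                "cd8_density": rec.quant["CD8"].density,
                "tsr": rec.tsr.tsr if rec.tsr else np.nan,
                "tsr_category": rec.tsr.category if rec.tsr else "",
            }
        )
    return pd.DataFrame(rows), reconciliation


def _score_cohort(
    quant: pd.DataFrame,
    ref_cd3: PercentileReference,
    ref_cd8: PercentileReference,
    thresholds: CategoryThresholds,
) -> pd.DataFrame:
    scored = quant.copy()
    results = [
        score_patient(row.cd3_density, row.cd8_density, ref_cd3, ref_cd8, thresholds)
        for row in quant.itertuples()
    ]
    scored["p_cd3"] = [r.p_cd3 for r in results]
    scored["p_cd8"] = [r.p_cd8 for r in results]
    scored["score"] = [r.score for r in results]
    scored["category3"] = [r.category3 for r in results]
    scored["category2"] = [r.category2 for r in results]
    return scored


def _evaluate_cohort(table: pd.DataFrame, config: RunConfig, seed: int) -> dict:
    """KM + log-rank + Cox + bootstrap-C battery on one scored cohort."""
    out: dict = {"n": len(table), "n_events": int(table["event"].sum())}
    for cat_col in ("category3", "category2"):
        block: dict = {}
        try:
            curves = km_estimate(table, cat_col)
            block["five_year_survival_pct"] = {
                lbl: round(100 * c.rate_at(60.0), 1) for lbl, c in curves.items()
            }
            stat, dof, p = logrank_test(table, cat_col)
            block["logrank"] = {"chi2": stat, "df": dof, "p": p}
        except ValueError as exc:
            block["error"] = str(exc)
        out[cat_col] = block

    # score categories are coded with "low" as reference: HR < 1 ⇒ protective
    table = table.copy()
    table["score_high"] = (table["category2"] == "high").astype(float)
    table["stage_iii"] = (table["stage"] == "III").astype(float)
    for name, covs in (
        ("cox_unadjusted", ["score_high"]),
        ("cox_multivariable", ["score_high", "stage_iii", "age"]),
    ):
        try:
            fit = cox_fit(table, covs)
            out[name] = {
                c: dataclasses.asdict(t) for c, t in fit.terms.items()
            }
        except (ValueError, RuntimeError) as exc:
            out[name] = {"error": str(exc)}

    try:
        comp = bootstrap_c_compare(
            table,
            {"stage": ["stage_iii"], "stage+score": ["stage_iii", "score_high"]},
            B=config.bootstrap_B,
            seed=seed,
        )
        out["c_index"] = {
            "means": comp.means,
            "p_adjusted": {f"{a} vs {b}": p for (a, b), p in comp.p_adjusted.items()},
            "B": comp.B,
        }
    except (ValueError, RuntimeError) as exc:
        out["c_index"] = {"error": str(exc)}
    return out


def _format_cox_table(results: dict) -> str:
    """Plain-text unadjusted/multivariable HR table for each cohort."""
    lines = []
    for cohort, res in results.items():
        lines.append(f"== {cohort} (n={res['n']}, events={res['n_events']}) ==")
        for model in ("cox_unadjusted", "cox_multivariable"):
            block = res.get(model, {})
            lines.append(f"  {model.replace('cox_', '').replace('_', ' ')} Cox model")
            if "error" in block:
                lines.append(f"    <{block['error']}>")
                continue
            lines.append(f"    {'term':<14}{'HR':>8}{'95% CI':>16}{'P':>10}")
            for term, t in block.items():
                ci = f"{t['ci_low']:.2f}-{t['ci_high']:.2f}"
                lines.append(f"    {term:<14}{t['hr']:>8.2f}{ci:>16}{t['p']:>10.3g}")
        lines.append("")
    return "\n".join(lines)


def run_study(
    dev_dir: str | Path,
    val_dirs: list[str | Path],
    config: RunConfig,
    out_dir: str | Path,
) -> dict:
    """Run the complete study: develop on one cohort, validate on others.

    The percentile references and category thresholds are derived on the
    development cohort only and frozen; every cohort (including the
    development one) is scored through them. Outputs land in ``out_dir``:
    per-cohort ``scores_<name>.csv``, ``reference_*.json``,
    ``thresholds.json``, ``results.json``, ``tables.txt``.
    """
    dev_dir = Path(dev_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = ClassifierModel.load(config.model_path)

    cohorts = {"development": dev_dir}
    for i, d in enumerate(val_dirs):
        cohorts[f"validation_{i + 1}" if len(val_dirs) > 1 else "validation"] = Path(d)

    tables = {name: pd.read_csv(d / "cohort.csv") for name, d in cohorts.items()}
    if len(tables["development"]) < 6:
        raise ValueError("development cohort must have at least 6 patients")

    quants: dict[str, pd.DataFrame] = {}
    reconciliation: dict[str, dict] = {}
    for name, d in cohorts.items():
        logger.info("quantifying cohort %s", name)
        quants[name], reconciliation[name] = _quantify_cohort(
            d, tables[name], model, config
        )
    if len(quants["development"]) < 6:
        raise ValueError("fewer than 6 scorable development patients")

    dev = quants["development"]
    ref_cd3 = build_percentile_reference(dev["cd3_density"], stain="CD3", roi="stroma")
    ref_cd8 = build_percentile_reference(dev["cd8_density"], stain="CD8", roi="stroma")
    dev_scores = [
        stroma_immune_score(
            to_percentile(ref_cd3, row.cd3_density), to_percentile(ref_cd8, row.cd8_density)
        )
        for row in dev.itertuples()
    ]
    thresholds = derive_category_thresholds(dev_scores)

    ref_cd3.to_json(out_dir / "reference_cd3.json")
    ref_cd8.to_json(out_dir / "reference_cd8.json")
    thresholds.to_json(out_dir / "thresholds.json")

    results: dict = {}
    seed_seq = np.random.SeedSequence(config.master_seed, spawn_key=(30,))
    cohort_seeds = seed_seq.generate_state(len(cohorts)) % (2**31 - 1)
    for (name, _), seed in zip(cohorts.items(), cohort_seeds):
        scored = _score_cohort(quants[name], ref_cd3, ref_cd8, thresholds)
        merged = scored.merge(tables[name], on="patient_id", how="inner")
        merged.to_csv(out_dir / f"scores_{name}.csv", index=False)
        results[name] = _evaluate_cohort(merged, config, int(seed))

    provenance = {
        "package_version": __version__,
        "config": json.loads(config.to_json()),
        "reconciliation": reconciliation,
        "thresholds": {"t1": thresholds.t1, "t2": thresholds.t2, "n": thresholds.n},
    }
    (out_dir / "results.json").write_text(
        json.dumps({"provenance": provenance, "results": results}, indent=1, default=str)
    )
    (out_dir / "tables.txt").write_text(_format_cox_table(results))
    return {"provenance": provenance, "results": results}
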