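# stromascore

Automated stroma-immune scoring of CD3/CD8 immunohistochemistry (IHC)
whole-slide images, with a survival-statistics battery to evaluate the
score's prognostic value.

Tumor-infiltrating T-cells in the *stroma* of colorectal cancers carry
prognostic information beyond TNM stage. This package implements the full
pipeline that quantifies them without any manual annotation:

1. **Tissue segmentation** — a nine-class tile classifier (tumor
   epithelium, stroma, adipose, background, debris, lymphocytes, mucus,
   smooth muscle, normal mucosa) is trained with a two-stage
   pretrain → fine-tune scheme and applied to overlapping 224×224 px
   tiles (75 px overlap); per-pixel labels come from a majority vote of
   covering tiles. The stroma mask is the region of interest; the same
   map yields the tumor–stroma ratio TSR = stroma / (stroma + epithelium).
2. **Cell quantification** — DAB-positive (brown) cells inside the ROI
   are found by Ruifrok–Johnston color deconvolution
   (OD = −log₁₀((I+1)/256) projected onto the H-DAB stain basis),
   thresholding, size filtering, and watershed splitting, giving a
   density in cells/mm².
3. **Scoring** — each patient's CD3 and CD8 stromal densities become
   percentiles of the development cohort's distribution (mid-rank
   empirical CDF, 0–100); the *stroma-immune score* is their mean
   S = (P_CD3 + P_CD8)/2. Two cut2-style quantile thresholds derived on
   the development cohort split patients into low/intermediate/high (and
   a collapsed low/high) — thresholds and references are frozen and
   reused verbatim for validation cohorts.
4. **Evaluation** — Kaplan–Meier curves with 5-year rates, log-rank
   tests, unadjusted and multivariable Cox models (Efron ties), Harrell's
   C-index, and a seeded bootstrap comparison of C between risk models
   (e.g. stage vs. stage + score) with Bonferroni correction.

Patient imaging data are not distributable, so the package ships a
first-class synthetic-fixtures module (`stromascore.synthetic`): labeled
tissue tiles, composite pseudo-slides with exact ground-truth masks and
planted chromogen cells, and survival cohorts with a known log-hazard
effect — everything needed to exercise and validate the pipeline offline.

## Worked example

Score a patient against a development cohort and check that a known
protective effect is recovered from a simulated cohort:

```python
import numpy as np
from stromascore import (
    build_percentile_reference, to_percentile, stroma_immune_score,
    derive_category_thresholds, assign_category, cox_fit,
    km_estimate, logrank_test,
)
from stromascore.synthetic import generate_cohort, SyntheticCohortSpec

rng = np.random.default_rng(0)
dev_cd3 = rng.gamma(2.0, 650.0, size=200)   # development densities, cells/mm²
dev_cd8 = rng.gamma(2.0, 240.0, size=200)
ref_cd3 = build_percentile_reference(dev_cd3, stain="CD3", roi="stroma")
ref_cd8 = build_percentile_reference(dev_cd8, stain="CD8", roi="stroma")

p3, p8 = to_percentile(ref_cd3, 1850.0), to_percentile(ref_cd8, 510.0)
score = stroma_immune_score(p3, p8)
thr = derive_category_thresholds(
    [stroma_immune_score(to_percentile(ref_cd3, a), to_percentile(ref_cd8, b))
     for a, b in zip(dev_cd3, dev_cd8)])
cat3, cat2 = assign_category(score, thr)
print(f"CD3 percentile {p3:.1f}, CD8 percentile {p8:.1f}, score {score:.1f}")
print(f"thresholds t1={thr.t1:.1f}, t2={thr.t2:.1f}  ->  category {cat3}/{cat2}")

cohort = generate_cohort(SyntheticCohortSpec(
    n_patients=400, true_log_hr_per_score_sd=np.log(0.4),
    censor_rate=0.25, rng_seed=7))
t = cox_fit(cohort, ["score"]).terms["score"]
print(f"Cox HR per score SD: {t.hr:.2f} (95% CI {t.ci_low:.2f}-{t.ci_high:.2f}, "
      f"p={t.p:.2g}; true 0.40)")
cohort["group"] = np.where(cohort["score"] > 0, "high", "low")
curves = km_estimate(cohort, "group")
_, _, p = logrank_test(cohort, "group")
print(f"5-year survival: low {100*curves['low'].rate_at(60):.1f}%, "
      f"high {100*curves['high'].rate_at(60):.1f}%  (log-rank p={p:.2g})")
```

prints

```
CD3 percentile 79.0, CD8 percentile 63.0, score 71.0
thresholds t1=40.2, t2=60.0  ->  category high/high
Cox HR per score SD: 0.42 (95% CI 0.36-0.48, p=4.1e-34; true 0.40)
5-year survival: low 30.4%, high 69.9%  (log-rank p=6e-23)
```

A patient at the 79th CD3 and 63rd CD8 percentile scores 71 and lands in
the high category; on the simulated cohort the fitted hazard ratio per
score standard deviation (0.42) recovers the planted protective effect
(0.40), and high-scoring patients show the expected survival advantage.

The image pipeline runs the same way from the shell:

```sh
stromascore synth --out study/dev --patients 30 --seed 1     # synthetic slides + cohort.csv
stromascore synth --out study/val --patients 12 --seed 2
stromascore train --pretrain tiles/he --finetune tiles/ihc --out model.bin
stromascore run --dev study/dev --val study/val --model model.bin \
    --out results/ --bootstrap 1000 --seed 1
```

`results/` then holds per-cohort `scores_*.csv`, the frozen
`reference_*.json` and `thresholds.json`, hazard-ratio tables
(`tables.txt`) and the full `results.json` with provenance.

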