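# ielscore

Intra-epithelial lymphocyte (IEL) scoring and prognostic evaluation for oral
epithelial dysplasia (OED).

OED is a premalignant change of the oral mucosa whose risk of transforming
into oral squamous cell carcinoma is currently judged by pathologist grading
(WHO mild/moderate/severe, or binary low/high risk) — systems with known
inter-observer variability and limited predictive power. A growing body of
evidence implicates lymphocytic infiltration of the epithelium in
transformation risk. `ielscore` turns nuclear detections from a digital
pathology pipeline (epithelial vs "other"/lymphocyte centroids, plus
dysplasia region polygons) into slide-level IEL scores and evaluates their
prognostic value against clinical grading. It is aimed at computational
pathology researchers who already have segmentation output (e.g. GeoJSON
annotation exports) and want reproducible scoring and survival statistics.

## The scores

All scores are computed from nuclei whose centroids lie inside the annotated
dysplasia, at a working resolution of 1.0 microns per pixel (mpp):

- **IEL-C** (IEL Count): `100 · n_IEL / n_epi` over the entire dysplastic
  region — IELs per 100 dysplastic epithelial cells, the convention used for
  duodenal IEL counts in coeliac histology.
- **IEL-PC** (IEL Peak Count): the maximum of the same ratio over 512×512 px
  sliding windows (default stride 256 px), i.e. the densest IEL *hotspot*.
  Windows with fewer than `min_epi` (default 20) epithelial cells are
  ineligible, suppressing spuriously high ratios from near-empty windows.
- **IEL-I** (IEL Index): `n_IEL / area` — IELs per mm² of dysplasia
  (shoelace polygon area, mpp²-converted).
- **IEL-PI** (IEL Peak Index): the windowed maximum of IELs per mm² of the
  dysplasia clipped to the window.

Downstream, slides are stratified low/high risk at the cohort **mean** score,
composite grades (`binary-IEL±`, `WHO-IEL±`) nudge the pathologist grade one
step by the IEL label, and prognostic value is measured by Kaplan–Meier /
log-rank, Cox proportional-hazards fits (hazard ratios per SD of score, 95%
Wald CIs), and Harrell's C-index, with transformation right-censored at 96
months. A clinicopathologic battery (chi-square/odds ratios, Mann–Whitney U
with point-biserial r_pb, Kruskal–Wallis with η², permutation Spearman) and
the 2-/6-point consensus-feature Cox models complete the evaluation. A
synthetic-data module generates annotations and survival cohorts with known
ground truth, so the full pipeline is testable end to end with no slide data.

## Worked example

```python
import pandas as pd
from ielscore import (SlideSimParams, simulate_slide, score_slide,
                      CohortSimParams, simulate_cohort, cox_fit)
from ielscore.survival import right_censor

# a synthetic slide with a planted IEL hotspot
ann, truth = simulate_slide(SlideSimParams(seed=7,
                            hotspots=[(1200.0, 1200.0, 250.0, 0.5)]))
s = score_slide(ann)
print(f"{s.n_epi} epithelial, {s.n_iel} IEL nuclei in "
      f"{s.dysplasia_area_mm2:.2f} mm2 of dysplasia")
print(f"IEL-C = {s.iel_c:.2f}  IEL-PC = {s.iel_pc:.2f}")

# a synthetic 219-slide cohort with a log-linear score effect on hazard
records, t = simulate_cohort(CohortSimParams(seed=11))
frame = pd.DataFrame({"months": [r.months for r in records],
                      "transformed": [r.transformed for r in records],
                      "iel_c": t["score"]})
fit = cox_fit(right_censor(frame), ["iel_c"])
row = fit.summary.loc["iel_c"]
print(f"IEL-C per-SD HR = {row['hr']:.2f} "
      f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}], C-index = {fit.c_index:.2f}")
```

prints

```
7928 epithelial, 864 IEL nuclei in 2.64 mm2 of dysplasia
IEL-C = 10.90  IEL-PC = 40.08
IEL-C per-SD HR = 1.69 [1.34-2.14], C-index = 0.66
```

The slide-level numbers say: 10.9 IELs per 100 dysplastic epithelial cells
globally, rising to 40.1 in the densest 512×512 window (the planted
hotspot). In the cohort, a one-SD increase in IEL-C multiplies the monthly
transformation hazard by 1.69, and the score alone ranks transformation
times with concordance 0.66.

The same pipeline is available from the shell:

```bash
iel simulate slide --seed 7 --out demo/
iel score --annotation demo/synthetic.geojson --out demo/scores.csv
iel stratify --scores demo/scores.csv --score iel_c --threshold 9.87 --out demo/labels.csv
iel survival --cohort cohort.csv --model binary+age+sex+site+iel_c --out fit.json
```

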