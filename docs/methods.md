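# Methods

## Scoring model

The object being scored is a *slide annotation*: nuclear centroids labelled
`epithelial` or `iel` plus dysplasia polygons, in pixel coordinates at a
stated resolution (microns per pixel, mpp). Upstream nuclear classifiers for
oral epithelium typically distinguish epithelial from "other" intra-epithelial
nuclei; in dysplastic oral epithelium the "other" class is overwhelmingly
lymphocytic, so those detections are treated as intra-epithelial lymphocytes
(IELs). The default class map therefore sends `other` and `lymphocyte` to
`iel`; any unmapped label is a hard error so that silent misclassification
cannot occur.

Scoring proceeds in three steps, all deterministic:

1. **Rescale** to the working resolution (1.0 mpp; coordinates multiply by
   `base_mpp / target_mpp`). Count-based quantities are unaffected;
   areas are converted with mpp², making IEL-C and IEL-I resolution-free.
2. **Restrict** to dysplasia: a nucleus counts if its centroid is inside or
   on the boundary of any region polygon (boundary-inclusive for
   determinism); overlapping regions are unioned, so no nucleus is counted
   twice and area is never double-counted.
3. **Score**: IEL-C = 100·n_IEL/n_epi and IEL-I = n_IEL/area(mm²) globally;
   IEL-PC and IEL-PI are maxima over square sliding windows.

### Windowing

Windows are axis-aligned squares of side `window_px` (default 512 px at
1.0 mpp) on a regular grid of pitch `stride_px` anchored at the bounding box
of the dysplastic nuclei, expanded one window to the top-left. Anchoring to
the data makes every score translation-invariant. Membership is the
half-open interval [x, x+w) × [y, y+w), which partitions points exactly
under non-overlapping tiling. Ties in the peak are broken by scan order
(row-major, top-left first), so reruns are bit-identical.

The stride default is 256 px (half-window overlap): ~4× the work of
non-overlapping tiling in exchange for a much smaller peak underestimate.
Eligibility floors guard the denominators: a window needs `min_epi`
epithelial cells (default 20) for IEL-PC, or `min_area_mm2` of clipped
dysplasia (default a quarter of the window area) for IEL-PI. Slides in
which no window is eligible report an absent peak with a warning rather
than a fabricated value; a slide with no epithelial cells in dysplasia has
an undefined IEL-C (the slide is excluded from score-based analyses), while
the area-based scores remain defined.

**Peak scores are extreme-value statistics.** The exhaustive supremum of
the window ratio over all placements is dominated by windows holding barely
`min_epi` cells at the tissue edge: a handful of IELs over a tiny
denominator outscores a genuine dense hotspot. This is the same mechanism
by which a few spurious IEL detections can corrupt a peak score in
production, and it is why the floor exists and is configurable. Empirically
(characterized on ~1,800-nucleus synthetic instances against a 1-px
exhaustive search): at `min_epi = 20` the half-overlap grid can
under-estimate the exhaustive supremum by up to ~60% because the supremum
itself is a near-floor noise artifact; at a floor of about half the
expected full-window count the grid is within 25% of the supremum, and at
stride 1 on integer coordinates the two agree exactly. The test suite
documents the 25% bound at the half-expected-count floor.

## Risk stratification and composite grades

Slides are labelled high risk when their score is *strictly greater* than
the cohort mean (ties go low; the mean rather than the median because
transformation events are a minority and a 50–50 split is not required).
The threshold is computed in-sample at slide level; a fixed external
threshold is accepted for deployment. Composite grades adjust a pathologist
grade by exactly one step: `plus` upgrades a low(-er) grade when the IEL
label is high and never downgrades; `minus` downgrades when the label is
low and never upgrades; the WHO ladder (mild < moderate < severe) clamps at
its ends. Consensus for pathologist-rated binary features is a 2-of-3
majority vote.

## Survival analysis

Time-to-event is transformation-free survival in months at slide level
(patients contributing several slides are not cluster-corrected — a
documented limitation). Administrative right-censoring at 96 months (8
years) converts later events to censorings at the horizon; the horizon
itself is inclusive.

Cox proportional-hazards models are fitted by partial-likelihood
maximization (statsmodels `PHReg`), Efron tie handling by default since
month-resolved times produce many ties and Efron is less biased than
Breslow (Breslow available). Hazard ratios are `exp(coef)` with 95% Wald
intervals from the observed information. Continuous covariates (IEL scores,
age) are z-standardized by default so HRs are per SD — the only scale-free
reading for a score without natural units; a raw-unit option exists and is
flagged prominently in the CLI. Categorical encodings: sex and binary grade
as 0/1; WHO grade ordinal 1/2/3, with the binary contrasts `who_g1` (mild
vs moderate+severe) and `who_g2` (mild+moderate vs severe); site and
scanner ordinal in single-covariate fits (one row per parameter) and
one-hot against the largest category in multi-covariate fits. Harrell's
C-index is computed on the linear predictor by the package's own
implementation: comparable pairs are those where the earlier time carries
an event; score ties count ½; the statistic is invariant under monotone
transforms of the risk score. Kaplan–Meier curves and the log-rank
chi-square come from lifelines.

The 2-point prognostic model uses the consensus features
{bulbous/drop-shaped rete pegs, loss of epithelial cohesion}; the 6-point
model adds {hyperchromatism, loss of stratification, suprabasal mitoses,
nuclear pleomorphism}. Features enter as unstandardized 0/1 indicators.
All C-indices are in-sample (no cross-validation), and every grid cell is
labelled with its exact covariate set to avoid ambiguity about which
clinical terms each row includes.

## Association battery

Nonparametric throughout, gated informally by a Shapiro–Wilk screen (IEL
scores are right-skewed). Chi-square tests are Pearson without Yates
correction — at cohort-scale counts the uncorrected test reproduces the
reconstructed contingency results; zero cells trigger the
Haldane–Anscombe +0.5 odds-ratio correction with a flag. Mann–Whitney U
uses the tie-corrected normal approximation (the exact-vs-asymptotic choice
is undocumented in comparable reports; asymptotic is standard at these n),
with the point-biserial correlation — Pearson between pooled values and the
0/1 group indicator — as effect size; the identity is asserted to 1e-12 in
tests. Kruskal–Wallis reports η² = (H − k + 1)/(n − k) unclamped (clamping
is a display concern), with post-hoc pairwise Mann–Whitney only when
p < 0.05. Spearman's ρ uses average ranks with a permutation p-value
(1 + #extreme)/(1 + n_perm), seed mandatory, bit-reproducible; an exact
enumeration mode exists for n ≤ 8. p-values are unadjusted, matching how
such batteries are conventionally reported; a Benjamini–Hochberg column is
available behind a flag.

## Synthetic data

`simulate_slide` draws epithelial nuclei as a homogeneous Poisson process
(default 3,000/mm², a realistic epithelial packing at 1.0 mpp) inside
dysplasia polygons (auto-generated irregular blobs, ~1 mm mean radius, by
default). Each epithelial nucleus spawns an IEL with probability
`iel_fraction` (default 0.08, putting the typical IEL-C near 8), boosted
inside planted circular hotspots; IELs are placed by Gaussian perturbation
(SD 8 px) around the parent, resampled into the region — Thomas-like
clustering that mimics lymphocytes in the paracellular space and gives
hotspot tests a real localized signal. Ground truth (exact coordinates,
counts, hotspot geometry) is returned alongside the annotation. An optional
label-flip noise models classifier error.

`simulate_cohort` draws slide-level IEL-C scores lognormally (median 8,
log-SD 0.6 → IQR ≈ 5–12) and peak scores as a noisy multiple (~6.8×) of the
global score, then survival times from a proportional-hazards model
T ~ Exponential(λ·exp(β·z + Σβ_f·x_f)) with z the cohort-standardized
score (β default 0.5/SD) and optional direct feature effects; censoring is
uniform on 60–120 months (five-to-ten-year follow-up) and λ is calibrated
by bisection so the expected event fraction hits the target (default 22%,
the minority-event regime that motivates mean-threshold stratification).
Grades couple to the score logistically (≈39% high-grade marginally); the
12 binary features get configurable logistic score-dependence —
immune-linked features (lymphocytic band strongest) track the score,
purely architectural ones do not — and each is reported as three rater
votes with 10% independent flip noise, so the 2-of-3 consensus machinery is
exercised. A Weibull baseline is available for non-constant hazards. Both
generators are byte-deterministic per seed.

### What the generators do not emulate

Real slides have anisotropic epithelium (basal-layer IEL enrichment in
ribbons, not discs), segmentation-correlated errors (missed nuclei near
stain artefacts), inter-scanner staining shifts, and patient-level
clustering of slides. Cohorts are generated with a *correctly specified*
proportional-hazards model. Passing tests therefore demonstrate that the
implementation computes its definitions correctly, recovers planted signal,
and is statistically calibrated — not that the scores carry the same
prognostic signal on real tissue, which requires real cohorts.

## Numerical and design notes

- Scores are stored unrounded; rounding to 2 decimals happens only at
  display/export layers.
- Polygon areas use the shoelace formula via shapely on the union of
  regions; 1 px² at m mpp = m²·10⁻⁶ mm².
- Mask input converts 4-connected foreground components to polygons whose
  interiors are exactly the union of pixel squares, so polygon area equals
  the filled-pixel count (a simple, exactly testable convention).
- Window counting sorts once on x and uses binary searches per grid column
  (O(G·n log n)); the exhaustive 1-px oracle in the tests uses an
  independent summed-area table.
- The baseline-rate bisection in the cohort generator runs 200 iterations
  on [1e-9, adaptively doubled upper bound] — exact to machine precision
  for practical purposes.
- Simulation sizes in the test suite (≤ ~2,000-nucleus instances for the
  exhaustive oracle, 200 slides for the mediant property, 500–1,000
  replicates for calibration, n = 2,000 cohorts for recovery) were chosen
  so each property is measured with comfortable statistical margin while
  the whole suite stays desk-scale.

## Known limitations

- Slide-level analysis without patient-level clustering or robust variance.
- No proportional-hazards diagnostics beyond what lifelines/statsmodels
  expose (a Schoenfeld-residual hook is a natural extension).
- The per-window table is exported, but no heatmap rendering.
- IEL subtype classification (CD4/CD8) is out of scope; the class label is
  binary epithelial/IEL.
- Whether peak-score denominators should use all epithelial nuclei in the
  window or only dysplastic ones is not uniquely determined by the scores'
  verbal definitions; this implementation restricts both numerator and
  denominator to dysplastic nuclei, consistent with counting "within the
  dysplasia regions alone", and exposes the windowing parameters so the
  alternative can be explored.
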