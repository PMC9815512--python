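# Methods

This note documents the statistical models, the synthetic-data generator
and the numerical choices behind `imdkit`, in the spirit of a package
methods appendix.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Reservoir-centred geometry

Each drug-release reservoir anchors a circular analysis region of
`max_extent` = 1,200 µm, divided into `max_extent / depth` = 4 concentric
annular sub-ROIs of `depth` = 300 µm.  Conventions:

- **Half-open rings** `[inner, outer)`: a cell at exactly 300 µm belongs to
  ring 1.  This makes boundary behaviour deterministic.
- **Exclusive nearest-reservoir assignment**, ties to the lowest reservoir
  id.  Neighbouring regions can never double-count a cell; the partition
  property (ring counts sum to the reservoir's assigned count) is tested
  directly against a brute-force oracle.
- **Distances from the reservoir centre**, not the device surface: the
  reservoirs are the release points and no surface-offset rule is better
  justified.
- **2-D only**: the analysis operates on single tissue sections.  Full
  annuli are used; a half-disc variant (for reservoirs at the device edge)
  is a possible extension but not implemented.
- Areas are analytic (`π(r₂²−r₁²)`), clipped to rectangular tissue bounds
  by polygonal approximation (shapely, 128 segments per quadrant; relative
  error < 1 %, verified against a 5 µm rasterisation oracle).  Fully
  interior annuli take the closed form directly.

## 2. Perturbation response model

For tumor *t*, condition *c*, marker *m*:

    log2FC(t,c,m) = log2( density_roi / density_ctrl ),
    density = (count + pseudocount) / area_mm²

- **Pooled 0–1,200 µm counts** give the headline effect (one value per
  condition, as the screen reports); per-ring densities are retained, and a
  ring deviating more than 3× from the median of the sibling rings is
  flagged as a QC warning but not excluded — the sub-ROI split exists to
  expose tissue damage, and silent exclusion would bias the effect.
- **Density (area-normalised) fold change** is the default because clipped
  ROIs at tissue borders would otherwise be incomparable; with equal areas
  it reduces to the raw count ratio.  Raw-count mode is obtained by passing
  equal areas.  Pseudocount defaults to 0 (counts in realistic regimes are
  in the hundreds); 0.5 is available for sparse data.
- **Control** = pooled density over all empty reservoirs of the same
  device.  The test's null sample is the per-tumor control-vs-control
  fold change (odd- vs even-indexed empty reservoirs), which is centred at
  zero by construction.
- **Student's t (equal variance), two-tailed, unpaired**, Welch optional.
  The null sample's fold changes have somewhat higher variance than the
  condition fold changes (single reservoirs on each side instead of pooled
  pairs); the pooled-variance test stays within the accepted 1–10 %
  rejection band under the null generator (verified over 1,000 simulated
  experiments in the test suite).
- With a single tumor the effect is reported and the p-value is NaN.
- Degenerate zero-variance comparisons with zero mean difference report
  t = 0, p = 1 rather than NaN.

Significance stars follow the screen's convention: `*` p < 0.05,
`**` p < 0.005.

## 3. Paired-ROI spatial metabolomics

1. **Density map**: marker-positive cells binned at the ion-image
   resolution (125 µm default) and smoothed with a Gaussian (bandwidth
   250 µm default ≈ 2 pixels).  Edge attenuation is corrected by dividing
   by the smoothed coverage mask, then the map is rescaled to integrate
   exactly to the marker count, making mass conservation exact rather than
   approximate.
2. **Hotspots**: pixels above the 0.95 map quantile, connected components
   (8-connectivity), components under 0.05 mm² dropped, each surviving
   component replaced by a **fixed-area disc (radius 400 µm)** at its
   density-weighted centroid.  Discs make "equivalent area" exact by
   construction; the detection method itself is a design choice, since
   cluster identification in the original workflow is manual/unspecified.
3. **Pairing**: hotspots processed by descending marker count; candidate
   equal-area discs are scanned outward on rings of increasing radius
   (step = one pixel, 16 angles), nearest first, and the first candidate
   that (a) overlaps no hotspot or accepted region, (b) lies on-grid within
   `max_separation` = 4,000 µm, and (c) satisfies
   `log2((n_high+0.5)/(n_low+0.5)) ≥ min_fold = 0.5` is accepted.  The
   greedy order plus the deterministic scan make pairing reproducible.
   "At least 0.5-fold change" is read as ≥ 0.5 log2 units (the scale the
   accompanying figures use); `min_fold` is a parameter, since other
   readings (ratio ≤ 0.5, 50 % difference) are defensible.
4. **Extraction**: a pixel belongs to a disc when its centre does; totals
   and means of raw ion counts per metabolite are reported.
5. **Statistics**: per-pair log2 fold change of mean counts (pseudocount
   0.5 to guard against sparse channels), paired two-tailed one-sample *t*
   against zero.  Per-metabolite significance uses **raw p < 0.05**
   (matching how single-metabolite panels are typically annotated);
   BH-adjusted p-values are reported alongside and drive the pathway-level
   list.  Whether the original univariate test was paired is not
   documented; the paired form mirrors the matched-ROI construction.
6. **Over-representation**: one-sided hypergeometric upper tail of the
   significant-list overlap with each user-supplied set (GMT format),
   sets intersected with the measured universe first, BH across sets.
   This is a deliberate generic replacement for web-service enrichment
   tools — no pathway database is bundled.
7. **Signatures**: Pearson correlation of log2 mean counts across the
   paired ROIs; metabolites categorised low/intermediate/high by tertiles
   of mean abundance (the original cutoffs are unpublished; tertiles are
   the neutral default and the rule is pluggable).  Constant metabolites
   yield missing correlations.
8. **Opposite trends**: metabolites significant in both of two marker
   analyses with strictly opposite fold-change signs.

## 4. ST classification

- Positive index = CD8⁺ count / nuclei; classes: high > 20 %, low < 5 %,
  boundaries (exactly 5 % or 20 %) fall in the intermediate class because
  the outer-class inequalities are strict.
- Geometric-mean normalisation per ROI over a **user-chosen target gene
  group** (the original target group is not public; the synthetic panel
  uses its housekeeping genes).  The operation is idempotent and leaves
  the target group's geometric mean at exactly 1.
- Class-vs-class DE: two-tailed unpaired *t* on log2 normalised values, BH
  across genes, ORA of the BH < 0.05 list.  This is a transparent stand-in
  for vendor DE statistics, not a reimplementation of them.

## 5. Synthetic-data generator

The generator defines the study conditions under which recovery is tested.

**Perturbation tumors.**  One device per tumor: 2 condition + 2 empty
control reservoirs on a 2,500 µm grid (≥ 2 × 1,200 µm, so regions of
distinct conditions cannot overlap), tissue bounds with a 1,300 µm margin
(≈ 26 mm²).  Tumor cells: homogeneous Poisson, 800 cells/mm².  T-cell
populations are three disjoint inhomogeneous Poisson processes — CD8⁺
(60 /mm²), FOXP3⁺ (40 /mm²), CD3-only (50 /mm², so total CD3⁺ = 150 /mm²)
— with intensity `baseline · (1 + effect · k(r))`, realised exactly by
thinning a dominating homogeneous process.  The kernel *k* is flat (1
inside 1,200 µm, 0 outside) by default so the planted fractional change is
directly recoverable as the pooled-ROI fold change; an exponential kernel
is available.  Baselines are round numbers in the range reported for
lymphocyte densities in immunocompetent murine mammary tumors, chosen once
for statistical testability (ROI counts in the hundreds), not fitted —
no within-group variance is published for the screen's effects.

Because CD8⁺ ⊂ CD3⁺ and FOXP3⁺ ⊂ CD3⁺, independent per-marker effects are
reconciled as follows: subset populations take their own planted effect
(inheriting the CD3 effect when none is given) and the CD3-only intensity
is solved so the **total** CD3⁺ density carries the planted CD3 effect
exactly.  Combinations implying a negative CD3-only intensity are rejected.

Presets (fractional changes at the reservoir): ARG_CD8 and CYS_CD8
CD8 +0.75; LAC_CD8 CD8 −0.50; PYR_FOXP3 FOXP3 +0.60; ATP_FOXP3 FOXP3
−0.70; GLN_CD3 and ITA_CD3 CD3 +0.75; GNE140_ALL all three −0.75; BSO
CD3 −0.50 / CD8 −0.75; NULL all zero.

**Ion images.**  Default 10 × 10 mm at 125 µm pixels (80 × 80).  Six
hotspot centres, rejection-sampled with pairwise separation ≥ 4 × radius
(guaranteeing pairable neighbourhoods) and a 2-radius margin; ~120 marker
cells per hotspot (Gaussian, σ = radius/2 = 200 µm) over a 5 /mm² sparse
background.  Per-pixel counts per channel are negative-binomial
(`var = µ + αµ²`, α = 0.05 — raw MALDI ion counts are overdispersed;
α = 0 recovers Poisson) with
`log2 µ = log2(200) + effect · hotspot_membership + smooth noise field`
(σ = 0.15 log2 units).  Planted log2 effects default to ±1 — large enough
to be recovered by ≥ 95 % sign accuracy at ≥ 20 pairs, small enough that
fillers stay null.  Metabolomics presets: CD8_HOTSPOT (glutathione,
N-acetyl-cysteine +1), FOXP3_HOTSPOT (citrate +1; myristic and oleic acid
−1), OPPOSITE7 (a CD8/FOXP3 section pair planting cystathionine,
d-Gluconate, dCMP, galacturonic acid, glucose 1-phosphate, mucic acid and
orotate with antagonistic signs, glutathione concordantly up in both).

**ST cohorts.**  Class counts (9, 12, 9) by default; positive indices are
drawn inside band interiors (e.g. high in [0.22, 0.45]) so that integer
rounding of CD8 counts against ~2,000 nuclei can never cross a class
boundary.  Expression: 50 genes in four blocks (12 amino-acid-metabolism,
10 glycolysis, 10 housekeeping = normalisation target, 18 other), log2
baselines uniform in [4, 8], per-ROI log2 noise σ = 0.4, and a +1 log2
shift of the amino-acid set in CD8-high ROIs.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue: diffusion–reaction pharmacokinetics of the
released compounds (the flat kernel is an idealisation), segmentation and
staining errors, cell–cell interaction (the processes are Poisson),
spatially varying tissue composition, mass-calibration artefacts in the
ion counts, and probe-level ST noise.  Recovery results demonstrate that
the pipeline's arithmetic and decision rules are correct, not that the
biological effect sizes are detectable at real-world noise levels.

## 6. Determinism and problem sizes

All randomness flows from a single integer seed per scenario
(`numpy.random.SeedSequence`; per-tumor streams are derived as
`SeedSequence([seed, tumor_index])`), and identical scenarios reproduce
byte-identical tables and grids.  The test suite's calibration checks use
1,000 simulated null experiments (perturbation rejection rate, accepted
band 1–10 % at α = 0.05), 500 null sections (metabolite flag rate, same
band) and 200 null ST cohorts (BH false-positive rate ≤ 10 %); the
acceptance script averages 20 seeds × 6 tumors per preset.  These sizes
were chosen so the binomial uncertainty of each rate is small relative to
its accepted band while the whole suite runs in minutes on one CPU.

## 7. Known limitations

- Hotspot detection is quantile-based and scale-fixed; very elongated or
  merging clusters become single discs.
- Greedy pairing is order-dependent by design (richest hotspot first) and
  can leave late hotspots unpaired in crowded fields; unpaired hotspots
  are logged and excluded from statistics.
- The control-split null sample needs ≥ 2 empty reservoirs per device;
  with exactly one, the test falls back to a one-sample t against zero.
- No spatial autocorrelation correction and no mixed-effects structure
  across devices — the screen's own analysis uses plain t tests, and the
  package mirrors it.
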