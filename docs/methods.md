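# Methods

This note documents the models, rules, and defaults implemented in `sedadna`,
in pipeline order, together with numerical choices and known limitations.

## Notation

A study comprises lakes \(l = 1..L\), sediment samples \(s\) with calibrated
ages (ka = thousand years before present) and depths (cm), and control samples
of types C1–C8. Every sample is amplified in \(R\) PCR replicates (default
\(R = 8\)). Raw data are counts \(c_{s,r,v}\): reads of sequence variant
\(v\) in replicate \(r\) of sample \(s\).

Control taxonomy: C1–C6 are negative controls eligible for the
control-enrichment screen and quality-threshold derivation; C7 is a post-PCR
negative control (counted in contamination-rate denominators, excluded from
screening); C8 is the positive control (excluded from both).

## Demultiplexing and pre-filters

Reads carry an 8-bp tag at each end; a read is assigned to a sample only on an
exact match of the ordered tag pair against the lookup table. Per sample,
identical sequences are collapsed to (variant, count). Variants shorter than
10 bp and dataset-wide singletons (total count 1) are removed before
assignment.

## Taxonomic assignment

**Plants (trnL P6 loop).** A variant is assigned only on a 100% exact match.
Reference libraries are ranked PhyloAlps (1) > ArctBorBryo (2) >
PhyloNorway (3) > EMBL (4); the hit from the highest-priority library with any
match wins. Multiple equally exact hits within one library resolve to the
lowest common taxonomic label; if no taxonomy is available to do so, the
variant is an error.

**Mammals (16S).** Global alignment (match +1, mismatch −1, gap −1;
Bio.Align.PairwiseAligner), identity = matches / alignment columns × 100,
assignment floor 95%. Because co-optimal alignments can give order-dependent
identity counts, identity is computed on the lexicographically ordered
sequence pair, making it symmetric (decision #11 in the ledger).

## Filter cascade

Order is fixed; each stage sees the previous stage's output.

1. **Homopolymer merge.** Variants whose run-length compression is identical
   are merged into the variant with the highest total count (ties: the
   lexicographically smaller sequence). This absorbs the dominant
   homopolymer-length sequencing error mode.
2. **Retention thresholds.** Cells with < 3 reads are zeroed; variants with
   < 10 total reads or < 3 positive replicates dataset-wide (after zeroing)
   are removed.
3. **Control-enrichment screen.** For each variant, the mean per-replicate
   relative frequency is computed over all performed replicates (zeros
   included) of eligible controls (C1–C6) and of sediments; variants with a
   strictly greater control mean are removed. Removal changes the relative
   frequencies of the survivors, so the screen iterates to a fixpoint
   (decision #12): the output is stable under re-application, which the
   one-pass rule is not.
4. **Known contaminants.** An explicit taxon list (laboratory/food taxa) is
   removed last.

An independent brute-force oracle (plain dicts and loops, no shared code)
re-implements the cascade in `tests/oracle.py`; equivalence on ≥ 1000 random
tables is acceptance criterion 1.

## Sample quality

MTQ = assigned reads / raw reads; MAQ = retained (post-cascade) reads / raw
reads, per sample. Thresholds are the maximum over eligible controls plus a
margin (defaults: MTQ margin 0.02, MAQ margin 0.01; control maxima of
0.50/0.24 give thresholds 0.52/0.25). A sediment sample is removed when
MTQ < threshold **and/or** MAQ < threshold (strict; samples exactly at the
threshold are kept). Controls are exempt from removal.

## Diversity and abundance indices

For taxon \(t\) in sample \(s\): wtRep\(_{t,s}\) = Σ over replicates of the
within-replicate read proportion of \(t\); wtRep_prop = wtRep / R ∈ [0, 1];
RAI = (sample-level read proportion) × wtRep_prop. Scaled RAI divides by the
per-sample sum within a plotted taxon group so each group sums to 1 per
sample (samples with zero group signal stay 0). Hill N0 is the count of taxa
with wtRep_prop > 0 — identical to the number of detected taxa, which is
property-tested.

## Mammal records

Detection records are per sediment sample × taxon with read totals and
positive-replicate counts. Contamination rate per taxon = fraction of
negative controls (C1–C7) with a detection. Exclusion rule: a detection is
excluded iff the taxon is a domesticate (Bos taurus, Ovis aries, Capra
hircus), its sample age is strictly > 8.0 ka, and it occurs in exactly one
replicate. First appearance = maximum age among non-excluded detections,
computable per study, region, or lake.

## Covariates

Age–depth conversion uses monotone linear interpolation (`np.interp`) and
refuses extrapolation. Climate matching picks the nearest grid time per lake
(argmin-first tie rule → the younger time on exact midpoints). Within/between
decomposition splits each covariate exactly into lake mean + within-lake
anomaly, optionally grand-mean centered.

## Attribution model

\(y_{s} = \beta_0 + X_s\beta + u_{l(s)} + \varepsilon_s\), with lake random
intercepts \(u_l \sim N(0, \sigma_u^2)\), fit by REML (statsmodels MixedLM).
Optional smooth terms use penalized cubic B-splines in the mixed-model
representation (spline wiggliness as an extra variance component). p-values
are two-sided t with residual degrees of freedom \(n - p\); significance
classes `****` < 0.0001, `***` < 0.001, `**` < 0.01 (strict cutoffs). When
the REML random-intercept variance lands on the zero boundary in a pure
linear fit, the model refits by OLS, because MixedLM's singular-covariance
path returns unreliable fixed effects there (decision #13); this also makes
the documented OLS-equivalence invariant hold exactly. Residual diagnostics:
per-lake lag-1 autocorrelation with a Bonferroni-adjusted normal critical
value plus the Durbin–Watson statistic.

## Simulator

`StudyConfig` drives six independent RNG streams (SeedSequence spawn keys:
references, reads/meta, climate, response, predictors, tag lookup), so
changing one generated artifact never perturbs another. Defaults: 14 lakes ×
50 samples, 60 plant taxa across 4 overlapping reference libraries, 11 mammal
taxa, R = 8 with 20% replicate dropout, homopolymer error variants for each
community taxon, planted control-enriched contaminants (control relative
frequency 0.10–0.48 vs. ≈ 0 in sediments, i.e. spike contrast ≥ 5×), 9.5%
planted low-quality samples, domesticate arrivals at 5.8/4.2/3.5/3.1 ka
(sheep/cattle/goat/horse) plus sporadic control-derived spikes, and a
Gaussian diversity response with intercept 40, residual SD 8, lake random
intercept SD 4, and a fixed default coefficient vector (temperature −5.99,
precipitation 0.03, deer 6.78, chamois 12.34, ibex 10.48, cattle 26.3, sheep
8.89, bank vole −7.37). `GroundTruth` records everything planted for
recovery checks.

Scope and limits of the generator: sequences are random (no phylogenetic
structure), errors are homopolymer-only, read depths are Poisson, and climate
is a smooth shared trend + lake offset + noise. It is built to exercise the
pipeline's decision rules, not to be a realistic sequencing simulator.

## Numerical choices

- Exact integer read accounting throughout the cascade; no floating-point
  reads.
- Relative-frequency comparisons in the control screen and the MTQ/MAQ rules
  are strict inequalities, so boundary cases are deterministic.
- REML default optimizer; spline random effects scaled by \(1/\sqrt{d}\) of
  the penalty eigenvalues for conditioning.
- `np.interp` for age–depth; nearest-neighbour (not interpolated) climate
  matching, preserving the actual simulated climate values.

## Known limitations

- Wald t-based p-values from mixed models are anticonservative for
  predictors whose variance is mostly between-lake when the number of lakes
  is small (≈ 3% at the nominal 1% level with 10 lakes for the precipitation
  predictor); calibration holds at the default 14-lake scale. Satterthwaite
  or Kenward–Roger corrections are not available in the backend (ledger #14).
- Mammal identity uses one co-optimal global alignment; the canonical-order
  rule makes it symmetric but other co-optimal alignments could differ by
  fractions of a percent near the 95% floor.
- First-appearance estimates for taxa with sporadic multi-replicate
  contamination inside the 5.8–8 ka window can predate the true arrival;
  the exclusion rule only removes single-replicate old detections, by design.
- The simulator's low-quality samples are separated from good samples by
  construction; quality-threshold recovery is exact only when that
  separation exceeds the margins.
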