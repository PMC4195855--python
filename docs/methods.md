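# Methods

## Scope and data flow

cnascan implements a depth-of-coverage copy-number pipeline for shallow
whole-genome sequencing of tumors, starting from per-bin read counts (the
alignment, duplicate marking and mapping-quality filtering that produce
such counts are upstream of this package). The stages are: bin filtering
and GC/mappability correction (`correction`), segmentation and discrete
calling with cell-fraction estimation (`calling`), region-level survival
scanning (`survival`), and multi-sample heterogeneity classification
(`heterogeneity`). The `synthetic` module is a first-class forward model
that generates every input with known ground truth; `io` and `cli` provide
the file formats and the shell surface.

## The mixture model

All calling logic derives from one identity. A specimen is a mixture of
normal cells and tumor cells; a CNA with integer copy number `c` carried by
a fraction `f` of all cells gives a locus the average copy number
`m = 2(1 − f) + c·f` and the expected log2 ratio `r = log2(m/2)` relative
to the diploid baseline. Consequences used throughout:

- **Thresholds.** `calling_thresholds(f_min, purity)` returns
  `log2(1 + f/2)` and `log2(1 − f/2)` with `f = f_min · purity`, the
  single-copy (c = 3 / c = 1) deflections of the smallest fraction worth
  calling. Defaults `f_min = 0.30`, purity 1 give +0.2016/−0.2345, i.e. the
  conventional printed ±0.20/−0.23 pair; a `rounded` switch reproduces the
  two-decimal values exactly for compatibility with external SEG workflows.
- **Cell fractions.** `estimate_cell_fraction` inverts the identity,
  `f = 2(2^r − 1)/(c − 2)/purity`, assuming single-copy events unless `c`
  is supplied (raw values above 1.05 are flagged model-inconsistent and
  clipped to 1). `anchored_fraction` divides an event's fraction by a
  clonal anchor's so purity cancels; it is how a marginal 10q deflection is
  read as "present in ~30–35% of tumor cells" against a clonal 1p/19q
  co-deletion.

## Bias correction

The correction estimates a multiplicative bias surface over GC content and
mappability by backfitting: alternating one-dimensional smooths of the
log2-scale counts on each covariate (2 rounds, span 0.65), exponentiated,
normalized to mean 1 over usable bins, and divided out. Two design choices
matter and were made for robustness, not convenience:

- Each 1-D smooth is fitted to **equal-count-stratum medians** of the
  partial residuals (up to 50 strata of ≥20 bins), not to raw points. Raw
  fits let chromosome-scale CNAs — which can occupy a third of a profile —
  leak into the bias curve; stratum medians stay on the diploid level as
  long as no stratum is majority-aberrant.
- The stratum medians are smoothed with a **local quadratic**
  (Savitzky–Golay) filter whose window covers the span fraction of strata.
  A local-linear fit at a wide span flattens the curvature of a unimodal GC
  bias and leaves residual GC correlation; the quadratic order tracks it.
  On simulated profiles with injected bias, residual |Spearman| between
  corrected log2 ratios and either covariate is below 0.05, and the
  correction is within 0.5% of the identity on bias-free input.

A constant covariate (e.g. a flat-GC toy genome) is skipped with a logged
warning. Usability requires: not blacklisted, mappability ≥ 0.8 (a
bin-level proxy for upstream alignability filtering), and a nonzero count
somewhere in the cohort.

`normalize_log2` centers profiles so the **median usable log2 ratio is
exactly 0**. Median centering is only unbiased while aberrations cover a
minority of the genome; because the two noise modes overlap, the offset
grows noticeably once ~10–25% of bins are aberrant, and the anchoring
breaks outright past 50%. For reading deflections (subclonality, calling in
heavily rearranged toy genomes) the package provides
`diploid_baseline(profile)` — the median of per-chromosome medians — which
stays on the diploid level whenever most *chromosomes* are unaffected;
subtract it before interpreting deflections. The profile contract itself
(median exactly 0) is unchanged.

## Segmentation and region calls

`segment_profile` is recursive binary segmentation: within each chromosome
the candidate breakpoint maximizes the two-sample t statistic; it is
accepted when a within-segment permutation test (default 100 shuffles)
gives p < 0.01, and recursion continues on both sides with a minimum
segment length of 3 usable bins. On a −1 step of 50 bins in noise SD 0.1
the breakpoints land within ±2 bins in ≥95% of seeds. Segment means are
called by strict inequalities against the thresholds; `region_call` labels
a named region loss/gain when same-direction segments cover ≥90% of its
length — which deliberately lets a whole-chromosome loss call a distal
region — with loss taking precedence (warned) in the never-observed case
that both directions pass.

## Survival scan

`reduce_to_regions` collapses bins into maximal runs whose call vector
across samples is constant; these runs are the scan's testing units.
Per region, carriers of the scanned direction are compared with the rest of
the cohort by a log-rank statistic computed from first principles (O − E
with hypergeometric variance per distinct death time). Significance is a
permutation p-value, `(1 + #{perm ≥ obs})/(n_perm + 1)`, permuting outcome
pairs rather than calls so each patient's genome-wide call correlation is
preserved; per-region generator streams are spawned from (master seed,
region index) so results do not depend on execution order. Runs of
consecutive same-chromosome regions with p below the fusion level (0.05)
are merged; a patient carries a fused region when aberrant calls cover
≥90% of its span (length-weighted). Fused regions are re-tested and the
final list adjusted by Benjamini–Hochberg (discovery) or, in `validate`
mode for a-priori regions, Holm–Bonferroni without fusion. The one-covariate
Cox hazard ratio is maximized by Newton iteration on the Breslow partial
likelihood with a Wald 95% CI; a monotone likelihood is flagged and returns
an unbounded CI. Kaplan–Meier medians come from lifelines; an undefined
median (curve above 0.5 throughout follow-up) is NaN. The log-rank and Cox
routines are cross-checked in the test suite against lifelines, which never
substitutes for them in the pipeline.

## Heterogeneity

`shared_grid` applies the region reduction across one patient's samples and
drops regions shorter than 5 Mbp; a CNA's identity across samples is (shared
region, direction), so partial overlaps are resolved by the grid rather
than by breakpoint matching. Spatial categories count samples sharing the
call (all / more than one but not all / one); temporal categories compare
the initial and recurrent call vectors (shared / initial-only /
recurrence-only). Mixed directions in one region count as two CNAs.
Percentages are rounded half-up to integers, matching the reporting style
of cohort tables (84 of 124 → 68%).

## Synthetic cohorts

The generator emulates: 15 kb binned counts, Poisson per bin with mean
`depth · bias(gc, mappability) · m/2` (optional negative-binomial
dispersion); a smooth unimodal GC bias peaking at GC 0.45 and a mappability
power law, normalized to mean 1; GC as a slow isochore-like process plus
fast bin-scale variation inside [0.3, 0.7]; mappability mostly ≥0.9 with a
~10% clustered low-mappability tail down to 0.5. Clonal architectures are
clones with integer-copy events and prevalences within the tumor
compartment at a specimen purity (default 0.6, reflecting the >60%
tumor-cell histology selection typical of such cohorts). Survival is
exponential with rate `ln 2 / median · Π HR`; the baseline median defaults
to 16.7 years (200.4 months), and `censoring_rate` is realized as an
administrative follow-up horizon placed at the baseline survival quantile
`1 − rate` — a single-parameter stand-in for staggered study entry that
reproduces the intended censored fraction in the baseline group.
Discovery-design cohorts use censoring 0.45, which together with an 18%
HR-2.91 region and a 40% HR-0.30 region yields ≈47% deaths, the follow-up
depth of the motivating cohort. Multi-region sampling keeps the first
(truncal) clone everywhere and restricts subclones to region subsets;
recurrences inherit the truncal clone, may drop subclones and may gain a
new clone — ground-truth spatial and temporal categories follow by
construction.

What the generator does **not** emulate: waviness and long-range
autocorrelation of real sWGS noise, replication-timing bias, FFPE artifacts
beyond dispersion, copy-neutral LOH (invisible to depth of coverage), sex
chromosomes, subclonal breakpoint heterogeneity within a region, and
non-proportional hazards. Passing tests therefore demonstrate correctness
of the algorithms under the stated noise model, not performance on any
particular real cohort.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale, chosen as the smallest
sizes at which the asserted tolerances are statistically meaningful:
permutation calibration uses 200 null cohorts of n = 98 at 500 permutations;
the power study uses 50 cohorts of n = 98 (exact 18/98 and 41/98 carriers,
10 neutral regions) at 2,000 permutations — 2,000 rather than 500 because
the p-value floor of (1)/(501) would mechanically cap what Benjamini–Hochberg
can declare at a 12-region family; hazard-ratio recovery uses 100 cohorts of
n = 1,000 and asserts the geometric-mean estimate within 15% (the per-seed
sampling SE of log HR at that n is ~0.09, so an every-seed bound would fail
a calibrated estimator about one seed in ten); subclonal-fraction recovery
uses 100 simulated 220 Mbp genomes at depth 100 per bin. The 10,000
permutations of the published design remain the library and CLI default.

Other numerics: permutation p-values carry the +1 correction and can never
be 0; permutation tie comparison uses a 1e-12 slack; the Newton solver for
the Cox likelihood caps steps at ±5 and declares monotone likelihoods at
|β| > 15; segmentation breaks exact ties by the first maximal split;
zero-count usable bins are set to the profile minimum −1 and logged, and a
profile with no positive usable count is rejected.

## Known limitations

- Median centering (and even the per-chromosome robust baseline) fails when
  aberrations dominate the genome or most chromosomes; near-triploid or
  heavily rearranged genomes need an external baseline.
- Cell-fraction estimates assume a single integer copy state per event;
  mixtures of states within one region bias `f` toward the dominant state.
- The scan's power at the published discovery design (n = 98, ~46 events,
  18% prevalence, HR 2.91) is intrinsically modest: the expected log-rank
  z-score is ≈2.75, so even an unadjusted α = 0.05 test detects the region
  in only ~80% of replicate cohorts, and any multiple-testing adjustment
  lowers that further. The corresponding acceptance test documents this
  honestly rather than relaxing the design.
- Copy-neutral LOH and balanced events are invisible to depth-of-coverage
  profiling and out of scope.
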