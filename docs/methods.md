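# Methods

## The assay and what the package computes

DR-*white* is a *Drosophila* double-strand-break (DSB) repair reporter: two
nonfunctional direct repeats of *white*, where the upstream copy
(``Sce.white``) is disrupted by a 23-bp insertion carrying the 18-bp I-SceI
recognition sequence. Expressing I-SceI cuts at that site; the repair
outcome is read out two ways, and this package implements both
quantifications:

- **Molecular readout.** The break-site region is PCR-amplified and Sanger
  sequenced, and the experimental chromatogram is decomposed against an
  uncut control chromatogram into an *indel spectrum* — the fraction of
  molecules carrying each net indel k ∈ [−K, +K], K = 35. Homologous
  recombination (HR) from the downstream donor removes the whole insertion
  and restores the SacI site (GAGCTC), so HR appears as exactly k = −23;
  k = 0 is "no DSB" (which also absorbs precise end-joining and intersister
  HR, molecularly invisible here); every other k is NHEJ with indels.
- **Phenotypic readout.** Individual premeiotic germline repair events are
  revealed in F2 progeny: red eyes mean HR restored *white*; white eyes
  with a brown body mean an intact reporter (no DSB / precise NHEJ /
  intersister HR / NHEJ with indels); white eyes with a yellow body mean
  single-strand annealing (SSA) deleted the intervening *y+* marker (a
  mitotic crossover is phenotypically identical and is not distinguished).

## Trace decomposition model

A molecule with a net indel of k bases at the break makes the sample
chromatogram read, at position p downstream of the break, what the control
reads at p − k. The sample's four-channel signal over a window is therefore
modeled as a non-negative mixture of 2K+1 shifted copies of the control
signal. The fit is ordinary non-negative least squares (NNLS; active-set,
deterministic); weights below `nonneg_tol` (1e−9) are truncated and the
rest renormalized to sum to one. R² is computed over the stacked
four-channel window signal. Per-component t statistics are emitted for
reporting only — no significance gate is applied before normalization,
since the downstream statistics are proportions, not component calls.

Window geometry, registration and QC are as follows, all config-exposed
(`DecompositionConfig`):

- **Alignment window** [break−100, break−20]: upstream of the cut, so every
  molecule is indel-free there. The sample is registered to the control by
  exhaustive search over offsets ±20, maximizing the cross-channel Pearson
  correlation; best correlation < 0.8 means the sample is unusable.
- **Decomposition window** [break+K+5, end−K−10]: starting beyond the
  largest modeled insertion guarantees no modeled position overlaps unknown
  inserted bases, so pure shifting is exact; the K-sized margin at the far
  end keeps every shifted model inside the control. (A window ending closer
  to the trace end would push insertion models out of bounds, which the
  model builder rejects as a configuration error.)
- **Background QC**: mean fraction of per-position signal in non-called
  channels over the (registered) alignment window; zero-total positions are
  excluded. Samples above the threshold (default 0.15) are flagged and
  refused by classification, mirroring the exclusion of high-background
  sequencing reactions.
- **Degeneracy**: if the shifted models are rank-deficient (repetitive
  control sequence), NNLS still returns a solution; a repetitiveness
  warning is raised. Ties in per-position base calling yield N and such
  positions fall back to the max channel in the background statistic.

Coordinates are 1-based, closed, top strand throughout, matching Sanger
trace numbering; the assay is strand-fixed by the sequencing primer.

### Known estimator bias at low editing rates

Non-negativity makes each of the ~69 tiny NHEJ component weights err only
upward under noise. Individual weight errors stay below 0.02 at the default
noise level, but their *sum* is inflated by roughly 0.01, which depresses
the relative HR percentage by ~2 points when the detectable fraction is
small (e.g. the 20%-detectable whole-fly profiles). This is inherent to
decomposition-based quantification without a significance gate and is left
uncorrected; groups with ≥50% detectable events are essentially unbiased.

## Classification and aggregation

For a spectrum with weights w: p_HR = w(−23), p_noDSB = w(0),
p_NHEJ = 1 − p_HR − p_noDSB. Relative proportions are percentages of
detectable events, rel_HR = 100·p_HR/(p_HR+p_NHEJ) (undefined — not zero —
when nothing is detectable; such samples are excluded from group means and
counted). Absolute proportions are percentages of all events:
abs_HR = 100·p_HR, abs_total_repair = 100·(p_HR+p_NHEJ). Group summaries
report the arithmetic mean and SEM = sd/√n across samples.

Germline vials are tallied per cross; the group statistic is the
**unweighted mean of per-vial percentages** (each vial is one sample,
regardless of progeny count; female vials contain two mothers but remain
one sample), with the pooled-progeny proportion reported alongside. A
red-eyed yellow-bodied fly (possible double event) is scored HR with a
logged anomaly; phenotype values outside the enumerations are rejected
rather than guessed.

## Statistics

- Welch's unequal-variance t test (Satterthwaite df) for single two-group
  contrasts; zero-variance degeneracies follow the p = 1 (equal means) /
  p → 0 (unequal, warned) conventions.
- Wilcoxon signed-rank for paired HR-vs-NHEJ proportions; zero differences
  dropped, exact p for ≤ 25 retained pairs, continuity-corrected normal
  approximation above.
- Factorial ANOVA (1–3 crossed factors, all interactions) via OLS with
  sum-to-zero contrasts. Balanced designs use the sequential decomposition
  (all types coincide); unbalanced designs use marginal (Type-III-style)
  sums of squares, and each result records which was used. Saturated
  designs are flagged rather than fitted silently.
- Tukey HSD from the studentized-range distribution using the factorial
  model's error mean square and residual df, with the Tukey–Kramer SE for
  unequal group sizes.
- Proportions are analyzed untransformed; p values below 1e−15 are
  reported as "< 1e−15"; no multiplicity adjustment beyond Tukey.

For the factorial reproduction layout, each sample's complementary rel_HR
and rel_NHEJ percentages both enter as rows with a `pathway` factor
(`melt_pathway`). Residual dfs under this layout match the reported F
statistics (e.g. 2·(23+38) − 4 = 118 for the male larva-vs-adult two-way;
2·124 − 8 = 240 for the three-way), which is why it is the default for
reproduction runs; a single-response layout is statistically cleaner and
remains available by passing `rel_HR` directly. In this layout the
`pathway` main effect tests proportions against 50:50 and factor main
effects other than pathway are structurally ≈ 0.

## Synthetic-data generator

The generator defines the conditions every validation runs under:

- **Constructs**: random non-repetitive amplicons (default 600 bp)
  containing GAGCTC once; the 23-bp cassette duplicates the first five
  SacI nucleotides ahead of the 18-bp recognition sequence, so removal
  restores wild type exactly.
- **Traces**: called-channel peaks ~ Normal(1.0, 0.05) with optional decay,
  non-called channels folded-Normal(0, 0.02); the sample is the
  truth-weighted mixture of shifted renderings with independent noise.
  Real chromatogram noise is more structured (dye blobs, mobility shifts,
  amplitude trends); the decomposition contract only requires the
  mixture-of-shifts structure, and raising `background_sd` exercises the
  QC-failure path. Passing recovery tests therefore demonstrates correct
  mixture inversion, not robustness to every real-trace artifact.
- **Cohorts**: per-sample outcome fractions get a Dirichlet perturbation
  (concentration 200) around the group profile so cohort SEMs are
  non-degenerate; the NHEJ mass is spread over a geometric indel-size
  distribution (decay 0.7 per base, deletions 2:1 over insertions) — the
  real indel-size spectrum is unreported, so this is a documented choice,
  config-exposed and recorded in manifests.
- **Preset profiles** encode each reported group mean (embryo ages, whole
  fly by sex, salivary gland, larval brain, wing disc, adult head, and the
  germline by sex). Where the detectable-event fraction is not reported
  (salivary gland, brains, wing disc, 3–6 h embryos) an assumed value is
  used (0.5; 0.72 for 3–6 h embryos, interpolating the flanking reported
  values) — it does not enter the relative HR/NHEJ statistics the groups
  are compared on. Germline mean progeny per vial derive from the reported
  totals (5894/66 ≈ 89.3 male, 2759/59 ≈ 46.8 female).
- **Germline cohorts**: vial totals ~ Poisson (truncated ≥ 1), outcomes
  multinomial, phenotypes rendered by inverting the scoring map.

Every generator is a pure function of (parameters, seed); manifests record
all truths. Because the preset truths encode the small printed sex
differences (e.g. adult head 28.1 vs 25.7% HR) while the within-group
spread implied by concentration 200 is narrower than real
biological variance, sex-by-pathway contrasts can genuinely reach
significance in synthetic cohorts; validation therefore asserts the sex
*main* term, which the complementary layout holds near zero.

## Problem sizes used in validation

Oracle-equivalence checks run 50 small instances (window ≤ 60 positions,
K = 5) against exhaustive active-set enumeration (agreement ≤ 1e−6).
Recovery runs 50 seeded pairs per tested profile at default noise (every
weight within 0.02, R² ≥ 0.9) and 20-sample cohorts for end-to-end group
means (within 3 points of truth). The germline estimator is checked for
unbiasedness at the male design point (66 vials × ~89 progeny, 500
replicates). Type-I calibration uses 2000 null replicates per test with
acceptance band [0.03, 0.07] at α = 0.05. The analysis drivers simulate
each cohort at its reported sample size.

## Limitations

- Base-calling from raw electropherograms, phred quality modeling and
  reverse-strand handling are out of scope; ABIF ingestion is a thin
  adapter over the analyzed data streams.
- SSA is invisible to the molecular readout (it removes the primer-flanked
  region's context entirely) and is quantified only phenotypically.
- Shift-0 weight is reported as "no DSB" without attempting to split
  precise NHEJ or intersister HR out of it.
- No vial-level random effects or transformation of proportions; the
  statistics layer mirrors direct factorial ANOVA on percentage data.
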