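# Methods

## Scope and model

`persisterprot` implements a label-free spectral-counting analysis for
bacterial persister proteomics. The observable is the number of
peptide-spectrum matches (PSMs) per protein and run; abundance is expressed
as the normalized spectral abundance factor

    NSAF_i = (SpC_i / L_i) / Σ_j (SpC_j / L_j)

per run, where `SpC_i` is the protein's spectral count and `L_i` its length
in amino acids. Dividing by length corrects for longer proteins yielding
more spectra per molecule; the run-wide normalization makes NSAF a *relative*
molar abundance that sums to 1 over the identified proteins of a run. NSAF
is therefore compositional: if some proteins truly rise, every other
protein's NSAF must fall. Consequences of this closure property are noted
below wherever they matter.

Two screens operate on NSAF values after shared quantification steps:

1. **Pairwise (before/after) screen.** Technical replicates are pooled by
   summing counts; proteins need a mean combined count ≥ 3 across runs and
   detection in ≥ 2 of 3 biological replicates of *both* conditions to be
   tested. Per protein, a two-sample t-test (Welch by default) compares the
   per-replicate NSAF values of the two conditions; Benjamini–Hochberg
   correction is applied across tested proteins and the FDR controlled at
   10%. A protein is called up (down) only if additionally its ratio of
   group-mean NSAFs is ≥ 1.5 (≤ 1/1.5). Proteins with zero counts in every
   baseline replicate whose *total* combined count in the test condition
   exceeds 5 are reported as **newly detected**: presumed upregulated, with
   no p-value, outside the BH family.
2. **Trend screen.** For each protein observed at the baseline and at every
   treatment time point, each biological replicate's NSAF at time t is
   divided by the *same replicate's* baseline NSAF; the log2 of these ratios
   is regressed on time in hours by ordinary least squares with a free
   intercept (3 time points × 3 replicates = 9 points; the 0-h baseline is
   not itself a point). The slope's two-sided t-test (n − 2 df) classifies
   proteins with p < 0.05 as increasing or decreasing by the slope's sign.
   The alternative formulation |log2 p| > 4.32 is the identical cut, since
   |log2 0.05| = 4.32; the implementation compares p to alpha directly. No
   multiple-testing correction is applied in this screen by design.

## Pipeline-order and eligibility decisions

Points where the procedure was genuinely open, and the choices made:

- **Technical replicates are summed**, not averaged: pooling search results
  is pooled spectral evidence, and sums preserve integer count semantics.
- **The average-count gate (≥ 3 across all runs)** is evaluated on combined
  per-biological-replicate counts over the runs handed to the screen, before
  NSAF. The NSAF denominator is computed over the proteins that survive this
  gate — "all identified proteins" is run-scoped.
- **The newly-detected rule is evaluated before the average-count gate.** A
  protein absent pre-treatment with, say, 7 total post PSMs would otherwise
  be silently discarded by the mean-count filter (mean 7/6 < 3) before the
  rule could see it. The gate therefore only restricts the *tested* set.
- **The > 5 spectral-count threshold is on the total over the test
  condition's biological replicates** (strict inequality; a total of exactly
  5 is not flagged). A per-replicate reading is stricter but not implied by
  the source procedure; the threshold is configurable
  (`newly_detected_min_psm`).
- **t-test eligibility** requires the presence filter in both conditions;
  proteins present only in the test condition route to the newly-detected
  rule; everything else is `excluded`. Every input protein lands in exactly
  one of {tested, newly detected, excluded}, and the stage counts in the run
  manifest verify this partition on every run.
- **Welch vs pooled:** Welch (Satterthwaite df) is the default because
  unequal variances are the norm for NSAF across conditions; the classic
  pooled-variance Student test is available as `test_variant="pooled"`.
- **Trend-screen gating** applies the average-count filter plus the
  common-protein gate (nonzero NSAF in ≥ 1 biological replicate of the
  baseline and of every time point). The 2-of-3 presence filter is specific
  to the pairwise comparison and is not applied here; per-replicate gaps are
  handled at the point level instead (next item).
- **Zero handling in trend points:** a replicate with a zero *baseline*
  NSAF contributes no points (the ratio is undefined); a zero at a single
  time point drops only that point. Both drops are logged. Fits require ≥ 3
  points spanning ≥ 2 distinct times; proteins below that are dropped with a
  logged reason rather than recorded.

## Numerical conventions

- Degenerate t-tests: two constant equal groups → t = 0, p = 1; constant
  unequal groups → p = 0 with the record flagged degenerate (volcano tables
  render these as infinite −log10 p rather than numbers). Groups of fewer
  than 2 values are errors.
- Degenerate OLS: an exact fit (residual sum of squares ≤ 1e-12 relative to
  the response scale) gives p = 0 for a nonzero slope and p = 1 for a flat
  line. These conventions are this package's own; other regression
  implementations may differ on such inputs.
- BH q-values are the standard monotone step-up transform
  (min over ranks ≥ own of m·p/rank, capped at 1); the rejection set equals
  the textbook largest-k rule, and `q ≤ alpha` is equivalent to rejection.
- Classification thresholds: fold-change gates are inclusive
  (≥ 1.5, ≤ 1/1.5); the trend p-threshold is strict (p < 0.05, so p = 0.05
  is not significant); the newly-detected count threshold is strict (> 5).
- NSAF columns are validated to sum to 1 within 1e-9; zeros in counts map to
  exact zeros in NSAF. A run with no identified protein has no defined
  normalization and is an error naming the run.

## Synthetic-data generator

The generator emulates the targeted study design: two technical × three
biological replicates per condition, either a two-condition before/after
layout or a 0/1/3/5-hour time course. Per protein, a relative abundance
`a_i` ~ LogNormal(0, 1.2) and a length `L_i` ~ LogNormal(5.6, 0.45) (≈ 290
aa median, clipped at 30) are drawn; the sampling weight is `a_i · L_i`, so
NSAF — which divides by length — recovers `a_i`, making the normalization's
purpose testable (its rank correlation with true abundance rises with depth).
Expected counts allocate each run's depth (default 20,000 PSMs, log-normal
run-to-run CV 0.1) proportionally to effect-modified weights; counts are
negative-binomial with variance μ + 0.2 μ² by default (Poisson at
dispersion 0), and a flat 5% dropout forces observed zeros. Class
assignment (null / up / down / trend-up / trend-down / newly-detected) is a
deterministic slice of a seeded permutation, so truth counts are exact.
Condition effects multiply the weight by the fold change (4-fold by default,
split evenly up and down); temporal trends multiply by `2^(slope · t)`
(±0.4 log2-units/h when enabled); newly-detected proteins have structural
zero weight in the baseline. All randomness derives from `numpy`'s PCG64
generator seeded from `SimParams.seed` (recorded in fixture metadata);
`generate_experiment(params, noise_seed=...)` optionally redraws only the
count noise so Monte-Carlo checks of `expected_counts` can hold the
structure fixed.

What the generator does *not* emulate: peptide-level identity and shared
peptides, abundance-dependent (MNAR) dropout, correlated protein modules,
batch effects, or chromatography drift. Passing tests therefore demonstrate
the screens' statistical behaviour under a clean count model, not robustness
to those real-data pathologies.

### Compositional coupling, made explicit

Because expected counts are renormalized within each run, injecting
one-sided effects changes every *other* protein's relative abundance by the
reciprocal of the total-weight shift — exactly as in a real experiment
where NSAF is closed. Two visible consequences: (1) with a heavy-tailed
abundance distribution, a strong effect on a dominant protein measurably
shifts all null proteins (the truth-recovery test fixtures therefore use a
moderated abundance spread, log-sd 0.6, so the injected effects rather than
the closure dominate); (2) in a time course, balanced up/down trends do not
cancel — `2^{st} + 2^{-st} > 2` — so null proteins acquire small negative
slopes. The screens report these as calls because they are real changes in
relative abundance; the test suite asserts false-call rates against what the
BH level controls rather than pretending closure away.

## Problem sizes and calibration checks

The statistical guarantees are checked at these sizes (chosen as the
package's standard verification workloads):

- FDR calibration: 200 simulated experiments of 1,000 proteins (10% true
  4-fold effects, dispersion 0.2, ~20,000 PSMs/run, 3 + 3 biological
  replicates); the mean realized false-discovery proportion among BH
  rejections must be ≤ 10%. Measured ≈ 2–5% depending on seed — conservative
  because the fold-change gate and overdispersion leave few borderline
  rejections.
- Slope-test type-I error: 10,000 null proteins with nine N(0, 0.5) points
  each; the fraction with p < 0.05 must be 0.05 ± 0.01.
- Power: on a 200-experiment batch at low noise (dispersion 0.01, no
  dropout, moderate abundance spread), the pairwise screen must call > 80%
  of 4-fold effects correctly (measured ≈ 0.90). With the default
  overdispersion (0.2) and three replicates, per-experiment power is low —
  an honest property of spectral counting at this design size.
- Oracle equivalence: BH against a brute-force largest-k scan on 1,000
  random p-vectors; t-test and OLS against closed-form arithmetic to 1e-10.

## Known limitations

- Fold changes are ratios of group-mean NSAFs; with two-to-three replicates
  these are noisy, and a ratio-of-means is not a mean-of-ratios.
- The pairwise screen tests NSAF values directly rather than count-model
  likelihoods; it inherits the t-test's small-sample behaviour at n = 3.
- The trend screen fits independent per-protein lines; no shrinkage across
  proteins, no correction for the compositional drift described above.
- Protein inference, peptide sharing, and spectrum-level processing are out
  of scope: the pipeline begins at a protein-by-run count table.
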