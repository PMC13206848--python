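# Methods

## The analysis chain

`petdesync` re-implements, as a tested pipeline, a regional PET analysis for
preclinical neuroinflammation studies: TSPO-PET (activated-microglia marker)
and amyloid-PET uptake in an atlas parcellation of the mouse brain, across
two genotypes (wild-type and an amyloidosis knock-in, "KI"), four treatment
arms (double placebo PL/PL, anti-amyloid antibody Ab/PL, pioglitazone
PL/Pio, combination Ab/Pio) and scans at 5, 7.5 and 10 months of age.

The chain is:

1. **%ID/cc** — regional activity as percent of injected dose per cc, the
   normalization-free uptake measure: `100 · concentration / injected_dose`.
2. **Pseudo-reference screen** — for each candidate VOI, Cohen's d (pooled
   n−1 SDs) between all pooled WT and all pooled KI %ID measurements; the
   VOI with the smallest |d| — the region least touched by genotype — becomes
   the SUVR reference. Ties break lexicographically. By default the screen
   pools all timepoints; a `timepoint` argument restricts it (the single-age
   variant is what the recovery experiment uses).
3. **SUVR** — each scan's VOI values divided by that scan's reference value;
   the reference maps to exactly 1; scans with a missing or non-positive
   reference are excluded *per scan* and itemized, never silently dropped.
4. **z-scores** — SUVR referenced to per-VOI control statistics (WT subjects
   at the latest timepoint, n−1 SD). Earlier ages reuse the late-age control
   statistics, so longitudinal z-profiles share one scale.
5. **Connectivity** — interregional correlation (Pearson r of two VOIs'
   SUVR across subjects; "ICC" in the molecular-connectivity sense, not
   intraclass correlation) with a Fisher r→z twin (`atanh`, |r| clipped to
   1−1e−7 with a warning).
6. **Desynchronization index (DI / connectivity deviation score)** — for
   every unordered VOI pair, B bootstrap resamples (subjects with
   replacement) of the control cohort each get an OLS line; the consensus
   fit is the replicate mean (median by flag). A subject's DI for VOI *i*
   is the sum over its V−1 pairs of the perpendicular distance
   |b·x₀ − y₀ + a| / √(b²+1) from the subject's pair point to the pair's
   consensus line. Composite regions (10-VOI cortex; entorhinal–
   hippocampus–amygdala, EHA) are summarized by PC1 of the constituents'
   standardized DI across the cohort, sign-oriented to correlate positively
   with mean constituent DI.
7. **Group statistics** — Shapiro–Wilk gate (α=0.05) for branch choice;
   Mann–Whitney U (exact enumeration when min(n)≤8 without ties, else
   tie-corrected normal approximation); Kruskal–Wallis with tie correction;
   Benjamini–Hochberg FDR within each result family; baseline-vs-%change
   OLS; pooled subject×region tracer-coupling OLS on z-scores (flagged
   descriptive — points are not independent); per-arm behavior regressions
   with no cross-arm slope test.

## Design choices where the procedure was genuinely open

* **Pair-fit orientation**: the lower-atlas-index VOI predicts the higher.
  Perpendicular distance makes DI nearly orientation-insensitive; the rule
  is recorded in ensemble metadata.
* **Consensus vs per-replicate distances**: distances are measured against
  the consensus line by default; a `per_replicate` flag averages over the B
  replicate lines instead. The two variants correlate strongly (≈0.96 at
  B≥200) but are not orderable — the distance is not convex in (slope,
  intercept), so neither dominates.
* **DI timepoint**: final age by default (where the control structure is
  defined); any age selectable.
* **DI normalization**: raw distance sums are primary; `DI/(V−1)` is
  emitted alongside for cross-atlas comparability.
* **PC1 basis**: correlation (standardized) matrix, since DI scale varies
  across VOIs; a raw-covariance variant sits behind a flag.
* **Control cohort**: pooled WT arms by default.
* **BH is not idempotent** ([1, .25] → [1, .5] → [1, 1]); re-adjustment can
  only increase values, which is the property we test.
* **Degenerate regressions** (zero predictor or response variance) return a
  flagged result, never NaN.
* **Reference VOI exclusion**: if the screen selects a VOI that is also a
  connectivity target, it is excluded from the pair set (it is constant 1
  after SUVR scaling).

## The synthetic cohort generator

No imaging data ships with the package; every downstream stage is validated
by parameter recovery on simulated cohorts with known truth. Per subject
*s*, VOI *v*, age *t*, the TSPO %ID value is

    y = base[v] + L[v]·(√(1−δ)·F + √δ·G[v]) + slope[v]·mult[arm]·(t−t₀)·[KI] + ε

with `F ~ N(0,1)` a shared per-subject-scan activation factor, `G[v]` iid
N(0,1), `ε ~ N(0, noise_sd[v])`. The desynchronization fraction δ (per arm,
in [0,1]) replaces shared-factor variance by idiosyncratic variance — the
√ weights keep the marginal variance constant, so rising δ destroys
interregional covariance without touching scale, which is exactly the
signature the DI is meant to detect.

Default parameterization (the study conditions, chosen once):

* **Cohort sizes** 8/6/8/12/10/18 across WT PL/PL … KI Ab/Pio, the
  emulated study's 10-month arms; timepoints 5, 7.5, 10 months; t₀ = 5.
* **Target VOIs** (20): ten bilateral neocortical subdivisions + ten
  bilateral subcortical regions; reference candidates brainstem and
  periaqueductal gray.
* **Variability**: target between-subject CoV 25% with 70% of variance on
  the shared factor → control interregional r ≈ 0.7, typical of
  molecular-connectivity matrices. A Gaussian model with the much larger
  CoV implied by the emulated study's pooled effect sizes would produce
  invalid (negative) uptake, so per-VOI genotype separation here is
  sharper (d ≈ 1.8–3 at 10 months) than pooled printed values — the model
  is homoskedastic and carries no susceptibility heterogeneity.
* **Reference regions** are disease-spared by construction: zero genotype
  slope, CoV 6%, weak factor loading. Two deliberate reasons: (i)
  low variability is the property that makes a region usable as a
  reference at all — a noisy reference multiplies every SUVR of the scan
  and injects signal-masking variance into DI and z-scores; (ii) if
  reference loadings were proportional to the targets', the shared factor
  would be a pure global scale that SUVR division cancels exactly,
  leaving no connectivity to measure.
* **Genotype effects** +45%…+90% of baseline by 10 months across target
  VOIs; treatment multipliers 1.0 / 0.45 / 0.70 / 0.50 (PL/PL, Ab/PL,
  PL/Pio, Ab/Pio) follow the emulated study's longitudinal SUVR
  attenuation pattern.
* **Desynchronization defaults** δ = 0 (WT), 0.5 / 0.6 / 0.35 / 0.35 for
  the KI arms.
* **Amyloid tracer**: pure noise around baseline in WT (amyloid-negative);
  in KI subjects the regional deviation is κ·(TSPO deviation in SD units)
  + √(1−κ²)·noise, so κ is on a correlation scale. Per-arm, per-age κ
  defaults are the square roots of the emulated study's printed coupling
  R² values.
* **Behavior** (water-maze target-quadrant time): genotype intercepts
  25 s (WT) / 18 s (KI), noise SD 5 s, floored at 0. The link
  `behavior_beta[arm]` (default −6 s/SD, Ab/PL arm only) multiplies the
  subject's *true cortical DI* — their deviation score against the
  analytic WT population lines, standardized within arm — so the
  population R² of the link is β²/(β²+σ²) ≈ 0.59, matching the emulated
  study's reported within-arm behavior correlations (R² 0.51–0.65).
* **Missingness** is completely at random per (subject, tracer, timepoint)
  with per-age rates (0 / 0.3 / 0.1 by default), never touches baseline
  scans, and rejects rates ≥ 0.9 where the coverage guarantee would be
  vacuous. Outcome-dependent missingness is deliberately not modeled.
* **Randomness**: one root seed; per-subject substreams via
  `SeedSequence(seed).spawn`, a separate stream for missingness. Identical
  config ⇒ bit-identical tables.

What the generator does *not* emulate — and hence what passing recovery
tests do not certify about real data: voxel-level structure and
partial-volume effects, skewed/heteroskedastic uptake distributions,
susceptibility heterogeneity between animals, outcome-dependent dropout,
scanner drift, and any treatment effect on connectivity other than the
variance-preserving δ mechanism (the emulated study reports DI outcomes but
no generative account; δ-replacement is one plausible mechanism among
several).

## Numerical choices

* Sample SDs and variances use n−1 divisors throughout.
* Pearson matrices are symmetrized, clipped to [−1, 1], unit diagonal;
  Fisher z clips |r| at 1−1e−7 with a warning.
* Bootstrap replicates with a zero-variance predictor are redrawn (bounded
  at 100 rounds); a constant control VOI raises instead.
* Uptake values are floored at 1% of the regional base mean (Gaussian tails
  would otherwise produce invalid non-positive %ID; at default CoV the
  clip probability is ~3·10⁻⁵ per value and the analytic-mean recovery
  tests are unaffected).
* CSV outputs are written in canonical row/column order with a fixed float
  format, making write→read→write byte-stable; the pipeline manifest
  records SHA-256 digests of every output.

## Experiment sizes

The recovery experiments run at: desynchronization ladder n=30/arm, V=20,
B=200, 10 seeds (monotonicity) and 20 seeds (δ=0.8 vs 0 separation);
pseudo-reference screen n=25/genotype, 40 seeds; null FDR calibration 200
datasets of n=10/genotype; coupling ladder and behavior detection
n=15/arm, 10 seeds each. These sizes give stable Monte-Carlo estimates
while keeping a full reproduction run around ten seconds on one CPU.

## Known limitations

* The per-replicate DI variant and the consensus variant are both offered
  because the published procedure does not disambiguate them; results
  correlate strongly but are not identical.
* The effect-size screen can select a disease-affected VOI in small
  cohorts by sampling noise; the pipeline tolerates this (reference
  exclusion) but the scientific interpretation of such a reference is the
  user's responsibility.
* Pooled regional coupling fits treat subject×region points as exchangeable
  and are reported as descriptive only; no mixed-effects correction is
  attempted (out of scope, as are linear mixed-effects models generally).
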