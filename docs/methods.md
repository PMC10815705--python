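# Methods

## Study design and differential expression

The pipeline assumes a four-genotype design — WT, N1KO (*NR1D1*-null),
N2KO (*NR1D2*-null), NDKO (double null) — with replicate TPM columns per
genotype (≥2 required for testing; the simulator defaults to 4). Analysis
starts at the TPM level; alignment and quantification are out of scope.

**Expression filter.** Genes are ranked by mean TPM across all samples and
exactly `floor(quantile · n_genes)` (default quantile 0.25) are retained.
Ties at the cutoff are broken by gene-id lexicographic order so the
retained set is a deterministic function of the matrix.

**Contrasts.** Per mutant genotype, fold change is the ratio of
untransformed mean TPM (mutant/WT) — independent of the pseudocount and
matching the conventional "fold change" of TPM pipelines — while the
p-value comes from a two-sided pooled (equal-variance) Student's *t* on
log2(TPM + pseudocount), df = n1 + n2 − 2. The log transform is the
variance stabilizer appropriate for TPM inputs; Welch's test is available
behind a flag, and the pseudocount (default 1.0) is configurable. DEG
flags use strict inequalities: `deg_up` iff FC > 1.5 and p < 0.05,
`deg_down` iff FC < 1/1.5 and p < 0.05. The down threshold is the
reciprocal, applying one FC criterion symmetrically. No multiple-testing
correction enters the flags (the calling rule is a raw-p rule); BH
*q*-values are emitted as an extra column for users who want them.

Degenerate cases are made explicit rather than left to float arithmetic:
0/0 fold changes carry an `fc_undefined` flag and never become DEGs; rows
with zero variance in both groups give p = 1 when the means agree and
p = 0 with a `degenerate` flag when they do not.

**qPCR.** The comparative-Ct method: ΔCt = Ct_target − Ct_reference per
sample, ΔΔCt = ΔCt − mean(ΔCt) over the control group, relative
expression = 2^(−ΔΔCt). Because the centring happens on the Ct (log)
scale, the control group's *geometric* mean is exactly 1; its arithmetic
mean exceeds 1 whenever the control replicates disagree. Samples with
missing Ct values are dropped with a warning.

## Isoform-dominance classification

Every NDKO DEG is assigned exactly one class per direction:

| class | criterion (up direction) |
|---|---|
| `alpha_dominant` | `deg_up` in N1KO **and** fc_N2KO < 1.3 |
| `beta_dominant` | `deg_up` in N2KO **and** fc_N1KO < 1.3 |
| `ndko_exclusive` | `deg_up` in neither single mutant |
| `shared` | everything else |
| `ambiguous` | qualifies as both dominants (only under conflicting thresholds) |

The down direction mirrors this with `deg_down` and the reciprocal
secondary bound fc > 1/1.3 — i.e. the other single mutant must show less
than a 1.3-fold *decrease*. The secondary criterion is a fold-change bound
only (no p requirement on the other single mutant). `shared` deliberately
absorbs every significant-in-a-single-mutant pattern that fails the
dominance criteria instead of inventing finer subclasses. All three
thresholds (1.5 primary FC, 0.05 p, 1.3 secondary FC) are configurable.

The Venn summary computes all seven intersection cells of the three
per-genotype DEG sets per direction, and the NDKO-exclusive percentage
100·|NDKO only|/|NDKO| rounded to two decimals (reported as NaN when the
NDKO set is empty).

## Gene-set overrepresentation

One-sided only: p = P(X ≥ k) for X ~ Hypergeom(N, K, n) after intersecting
both query and term with the universe, evaluated through the survival
function (stable for universes up to ~1e5 genes). The universe defaults to
the post-filter expressed-gene set, not the whole genome, because the DEG
lists are drawn from that background; it remains a configuration, not a
claim about any particular web tool's background. `overlap_pct` is
100·k/K (fraction of the term covered, the convention of enrichment
browsers); 100·k/n is also emitted. BH adjustment is applied within each
library separately since libraries are queried independently; terms
smaller than `min_term_size` (default 3) inside the universe are not
tested. Rows sort by ascending p, ties by descending overlap_pct then term
name, so output order is deterministic.

## Cosinor rhythmometry

The default fit is the single-component cosinor with a linear trend term:

    y(t) = M + b·t + β_c cos(2πt/τ) + β_s sin(2πt/τ)

solved by OLS; A = √(β_c² + β_s²), φ = (τ/2π)·atan2(β_s, β_c) mapped into
[0, τ). Fitting the trend inside the regression (rather than pre-detrending)
keeps the estimator a single linear projection with exact noiseless
recovery; the moving-average `detrend` op exists for plotting parity and
uses trapezoid end-weights so a full-period average of a periodic signal is
exactly zero. Rhythmicity is the F-test of (β_c, β_s) jointly zero (2
numerator df), with a machine-precision guard: residuals at round-off level
are treated as a perfect fit rather than fed to the F ratio. Relative
amplitude 100·A/M is reported only when the rhythm test is significant
(p < 0.05) and M > 0 — the operational meaning of an "N/A" amplitude —
otherwise NaN.

The period is fixed at 24 h by default; `free_period` grid-searches τ over
[20, 28] h in 0.1-h steps (bounded to avoid aliasing) by residual sum of
squares. A trace must cover at least two full periods.

**Damping.** The default fit is undamped. For traces with a decaying
envelope the package additionally offers `damped=True`, which profiles an
exponential envelope e^(−λt) on the oscillatory terms over a bounded λ grid
(default [0, 0.1] /h, step 0.002), solving the linear subproblem at each λ,
and reports the t = 0 amplitude. This option exists because the undamped
estimator's amplitude on a damped trace converges to the envelope-weighted
average ≈ A·(1−e^(−λT))/(λT) — about 0.64·A for λ = 0.01/h over 96 h — a
systematic bias no noise-level tolerance can absorb; the damped profile
fit removes it while remaining a sequence of closed-form OLS solves. The
undamped path stays the default because classical cosinor reporting is
undamped.

**Reporter assays.** Endpoint dual-luciferase wells are normalized
firefly/renilla per well, then scaled so the reference-group (default WT)
mean ratio is 1; wells with non-positive renilla are excluded with a
warning.

## Synthetic data

`simulate_expression` plants gene classes as log2 fold-change triples
(δ_N1, δ_N2, δ_ND): null (0,0,0); ndko_exclusive (0,0,±δ); additive
(±δ/2, ±δ/2, ±δ); alpha_dominant (±δ, 0, ±δ); beta_dominant (0, ±δ, ±δ).
Per gene, baseline log2 TPM ~ Normal(5, 2²) (a realistic spread for
expressed transcripts), and each sample draws
log2 TPM ~ Normal(baseline + δ_G, replicate_sd²) before exponentiation, so
planted fold changes are exact in expectation and direction-symmetric.
Defaults: 4 replicates/genotype, δ = log2(3) (a clearly detectable 3-fold
effect that satisfies the dominance-class bounds |δ_single| ≥ log2(1.5)
and |δ_other| < log2(1.3)), replicate_sd = 0.15 log2 units (a module
choice — replicate-level TPM dispersion is rarely published; 0.15
corresponds to ~11% CV, typical of good cell-line replicates), and a class
mixture of 70% null with the remainder split over the planted classes.
Class counts follow a deterministic largest-remainder allocation and are
assigned to gene indices in order (downstream stages are permutation-
invariant over genes); a class whose allocation rounds to zero genes is
dropped with a warning. Column rescaling to 1e6 (true TPM semantics) is
off by default because compositional renormalization perturbs the planted
fold changes; the flag exists to stress-test downstream robustness. A
single seed drives all randomness through deterministically spawned
sub-streams, so identical configs are bit-identical.

`simulate_bioluminescence` generates
y(t) = M + b·t + A·e^(−λt)·cos(2π(t−φ)/τ) + ε, ε ~ Normal(0, σ²), on an
inclusive grid from 0 to `duration` (default 96 h) at `sampling_interval`
(default 20 min, i.e. 289 points).

**What the simulators do and do not emulate.** The expression simulator
reproduces the *design* (genotypes, replicates, effect regimes) with
i.i.d. log-normal noise; it has no library-size, GC or count-overdispersion
structure, no gene-gene correlation, and its planted classes are cleanly
separated. Passing recovery tests therefore demonstrates that the
thresholds and classifier do what they claim under the stated noise model —
not that real knockout data will yield any particular class proportions.
The trace simulator likewise omits luminometer drift, phase jitter between
wells, and non-exponential damping.

## Problem sizes and numerical choices

The recovery suites use 2000 genes × 16 samples and 100 reporter
replicates of 289 points — sizes at which every behaviour under test is
already stable and the full suite runs in seconds. Table writers emit
shortest-round-trip float representations and readers parse with
round-trip precision, which is what makes byte-identical reruns and exact
write→read equality possible. The pipeline manifest records parameters,
seed, package version and SHA-256 checksums of inputs and outputs, and
deliberately contains no timestamps or absolute paths.

## Known limitations

- DEG calling is threshold-based on TPM by design; there is no
  count-model (negative-binomial) inference and no shrinkage.
- The raw-p DEG rule means the genome-wide false-positive count scales
  with the number of tested genes; the emitted q column is informative
  only.
- Fisher overrepresentation treats genes as exchangeable; correlated gene
  sets inflate significance as in any hypergeometric enrichment.
- The cosinor assumes a single dominant period; multi-component rhythms,
  non-sinusoidal waveforms and spectral methods (FFT, Lomb–Scargle) are
  out of scope.
- Genotype vocabulary is fixed to {WT, N1KO, N2KO, NDKO}; other naming
  schemes must be mapped on input, because the classifier's semantics are
  tied to the single/single/double structure.
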