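# Methods

This note documents the statistical models, numerical choices and known
limitations behind `peptiq`, in the spirit of the methods documentation
of packages like statsmodels or msprime. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

All analysis operates on a long-format table with one row per measured
feature intensity and the fixed columns
`sample, condition, replicate, protein, peptide, precursor,
intensity_log2, dose`. The single authoritative intensity scale is
log2: differences are log2 fold changes, and the linear scale is
recovered as 2^x where a metric demands it (CVs). Intensities ≤ 0 in
source exports are treated as missing, not as zeros — a zero in a
search-engine report records non-detection, not abundance. Precursors
are keyed as `peptide + "_" + charge`, independent of the source
dialect. Fragment-level data is supported only through the generic
dialect with a user-supplied feature column, since export formats do not
agree on a fragment key.

Run provenance is recorded in the pipeline manifest (`manifest.json`:
root seed, stage order, SHA-256 per artifact) rather than as comment
headers inside the TSVs, which some strict TSV consumers reject.

## Synthetic data generator

The generator is the package's offline test surface. Its model is
hierarchical and deliberately mirrors the assumptions of the downstream
statistics:

- protein mean log2 intensity ~ Normal(μ_pop = 20, σ_pop = 2);
- each peptide adds a fixed ionisation offset ~ Normal(0, 1.5);
- each replicate observation adds Normal(0, 0.3) measurement noise;
- differential proteins (default fraction 0.1, exactly
  round(frac × n) of them) add a per-condition effect to non-reference
  conditions; |effect| ~ Normal(1, 0.5) log2 units with random sign —
  around the 2-fold changes typical of perturbation experiments;
- each observation survives detection with probability
  sigmoid(slope × (intensity − midpoint)), midpoint 17, slope 1.

The logistic dropout is the standard smooth two-parameter surrogate for
missing-not-at-random detection failure; with the defaults above it
yields roughly 10–30% missingness, concentrated in low-abundance
proteins. In `lip_mode` only a random subset (half, at least one) of a
differential protein's peptides responds, emulating the local
conformational readout of LiP-MS.

In dose mode each responder protein's mean follows an LL.4 curve of the
dose with hill slope 1, amplitude |d − c| ~ Uniform(1, 4) log2 with
random sign, and EC50 log-uniform in [1e-7, 1e-5] — inside the default
dose series (0 plus 1e-8…3e-5), so the transition is observable. The
default series has 9 doses because four-parameter fits on fewer than 5
distinct doses are under-determined (the generator refuses them).

Protein sequences are synthetic: each protein's sequence is the
concatenation of its peptides, which are generated K/R-terminated and
internally K/R-free. Every simulated peptide is therefore fully tryptic
with a known position, giving the annotation stage exact ground truth.

What the generator does **not** emulate: correlated peptide noise,
batch/run-order effects, chromatographic or spectral artifacts,
interference, charge-state redundancy, shared (razor) peptides, and real
proteome sequence composition. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not
robustness to every pathology of real data.

## Quality control

CVs are computed on the linear scale, sd(raw)/mean(raw) with (n−1)
variance, per (feature, condition); a CV of log values would not be
scale-meaningful. Sample correlation uses pairwise-complete features
(minimum 3 shared) rather than imputation: QC must describe the data as
measured. For the same reason imputation is opt-in and never runs
before QC.

## Normalization and imputation

Median normalization shifts each sample by (reference − median(sample)),
with the reference being the median of the per-sample medians —
symmetric in the samples, no designated reference run. The operation is
idempotent and preserves within-sample differences exactly (a single
constant is added per sample). Samples without any observed intensity
are an error, not silently dropped.

MNAR imputation draws each missing cell of sample s from
Normal(mean_s − shift·sd_s, (width·sd_s)²) with defaults shift = 1.8 and
width = 0.3, the widely used down-shifted-Gaussian defaults
(e.g. Perseus-style workflows). Imputed cells are flagged; samples with
fewer than two observed values keep their missing cells with a logged
warning. This scheme is a declared stand-in for left-censored dropout,
not a model of the acquisition process.

## Protein inference (MaxLFQ-style)

For each protein, every ordered sample pair (j, k) sharing at least
`min_shared` features (default 1 — small matrices are common in
simulations and filtered data; canonical MaxLFQ uses 2) contributes the
ratio r_jk = median over shared features of (x_ij − x_ik). The profile
solves the least-squares problem min Σ (p_j − p_k − r_jk)² via the graph
Laplacian normal equations; the minimum-norm lstsq solution is then
anchored so the component mean equals the mean of the observed log2
intensities of its samples. The system is translation-invariant, so the
anchor is pure convention; it keeps profiles on the intensity scale.
Connected components of the sample-sharing graph are solved
independently and never mixed — pairwise ratios carry no information
between disconnected sample sets; singleton components fall back to the
median of their own observed features. The test suite checks this
solver against an independent dense least-squares construction of the
full pair system, exhaustively for small matrices.

## Differential testing

Three per-feature tests on log2 intensities:

- **Welch's t**: unequal-variance t with Welch–Satterthwaite df.
- **One-way ANOVA**: fixed-effects F = MSB/MSW as the omnibus test.
- **Moderated t**: empirical-Bayes variance shrinkage. Per comparison,
  pooled two-group variances s² (d = n₁+n₂−2 df) across all features
  are fitted with a scaled inverse chi-square prior (d₀, s₀²) by the
  method of moments on log s²: e = log s² − ψ(d/2) + log(d/2) has
  variance trigamma(d/2) + trigamma(d₀/2), so d₀ comes from monotone
  root-finding on the trigamma equation (Brent on [1e-8, 1e8]) and s₀²
  from the mean equation. When the spread of log variances falls at or
  below its theoretical sampling minimum the prior is a point mass:
  d₀ = ∞ and s₀² = mean of the variances. The moderated statistic uses
  s̃² = (d₀s₀² + d·s²)/(d₀ + d) with d₀ + d df (normal when d₀ = ∞).
  The fit refuses fewer than 10 usable variances. Both branches are
  cross-checked against `limma::fitFDist`/`squeezeVar` through Rscript
  when R is available.

The moderated test pools variance per comparison rather than through a
global design-matrix model: this keeps the contract simple (two groups
in, one result out) at the cost of not sharing information across
conditions; for multi-factor designs use a dedicated linear-model tool.
Features failing replicate minima are reported with missing statistics
and a reason instead of being dropped, so the tested/untestable
accounting is preserved. Missing values are never imputed inside the
tests. BH adjustment excludes missing p-values from the number of
tests.

## Dose–response

The model is drc's LL.4 parameterisation
f(x) = c + (d − c)/(1 + exp(b(ln x − ln e))); dose 0 enters through the
curve limit (f(0) = d for b > 0). Since (b, c, d) → (−b, d, c) leaves
the curve unchanged, fits are canonicalised to b ≥ 0.

Fitting is deterministic bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobian in (b, c, d, ln e),
ftol/xtol/gtol 1e-10, ≤ 500 evaluations) with multistart: c₀/d₀ from
the min/max of per-dose means, e₀ the dose whose mean is closest to the
half-response level, b₀ ∈ {−1, +1}; the smallest residual sum wins.
The bounds — asymptotes within 3 response-spans of the data, ln e within
2 decades of the tested dose range, |b| ≤ 20 — exist because a
dropout-censored plateau creates a flat ridge (asymptote → ∞ at
constant residual) on which an unbounded optimizer never terminates;
they are a stability device, not a prior.

Model relevance is the F-test of the 4-parameter fit against the
intercept-only model on the raw observations, df (3, n − 4). R² is
computed against the per-dose **mean** response: with replicates it
measures curve shape rather than replicate noise (a strong responder
with noisy replicates still scores high), and with one observation per
dose it coincides with the ordinary 1 − SSres/SStot. Hits are
converged fits with BH-adjusted p below α (default 0.05) and R² at
least `min_r2` (default 0.8), ranked by adjusted p, then descending R²,
then feature ID; α and min_r2 are artifact defaults, not literature
constants. Constant responses return a converged flat fit with p = 1
and the slope flagged unidentifiable.

Limitations: no confidence intervals on EC50 (profile likelihood is out
of scope), no 5PL/Weibull alternatives, and responders whose abundance
sits below the detection limit across the responsive dose range are
unrecoverable by any fit — the simulation-based sensitivity checks
include such proteins in their denominator.

## Peptide annotation

Coordinates are 1-based inclusive, matching UniProt numbering.
Peptides are matched after stripping `[bracket]`/`(parenthesis)`
modification annotations; the leftmost exact match wins, with a
`multi_mapped` flag instead of an error for repeat-containing proteins.
Trypsin specificity: an N-terminus is specific when the preceding
residue is K/R or the peptide starts the protein; a C-terminus when the
last residue is K/R or the peptide ends the protein; both ⇒
fully-tryptic, one ⇒ semi-tryptic, none ⇒ non-tryptic. The K/R-P
suppression rule is off by default and switchable — conventions differ
between search engines. Coverage is the union of covered residue
intervals over the protein length. Barcode profiles project per-peptide
statistics onto residues: minimum adjusted p and the signed log2 FC of
the overlapping peptide with the largest |FC|.

## Enrichment

One-sided upper-tail hypergeometric over-representation,
p = P(X ≥ k) with X ~ Hypergeom(N, K, n), evaluated through
`scipy.stats.hypergeom.sf` and verified in the tests against exact
integer tail summation. The background defaults to the proteins present
in the dataset, not the whole proteome — enrichment must be relative to
what was detectable. Odds ratios use a 0.5 continuity correction when
any 2×2 cell is zero. Terms with K < 2 or K > N/2 are reported but
flagged low-information. Depletion (lower tail) is available behind a
flag; the treatment-target variant tests a single set and applies no
multiplicity adjustment. Because the test is discrete, null p-values
are stochastically larger than uniform; the calibration check in the
test suite uses a table design (N = 1000, K = n = 200) whose exact
attainable size is 4.8%, so the nominal-5% premise holds.

## Reproducibility

All randomness flows from one root seed: pipeline stage i consumes the
i-th child of `numpy.random.SeedSequence(seed)`, so the chain is
bit-reproducible while stages stay independent. Simulation,
imputation and the acceptance script all derive their streams the same
way. The problem sizes used by the validation script (exhaustive 3×3
MaxLFQ sweep plus 500 random 4×5 matrices; 1000-feature null
calibrations; 200-feature EC50 recovery; N ≤ 60 hypergeometric sweep)
were chosen so the whole run completes in about a minute on one CPU
while keeping Monte-Carlo standard errors well inside the asserted
tolerances.
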