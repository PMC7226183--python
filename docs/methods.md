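# Methods

## Model

Every analysis rests on the single-harmonic cosinor model of circadian gene
expression: on a positive linear abundance scale,

    y_g(t) = M_g · (1 + r_g · cos(2π (t − φ_g)/24)) + noise,

with mesor M_g (rhythm-adjusted mean), relative amplitude r_g ∈ [0, 1] and
peak phase φ_g ∈ [0, 24) hours after synchronization. Fitting uses the
equivalent linear parameterisation M + a·cos(ωt) + b·sin(ωt) by ordinary
least squares; rhythmicity is the F test of the harmonic model against the
intercept-only model with (2, n−3) degrees of freedom. Replicate samples at
equal wall times (0 h vs 24 h, 12/15/18 h vs 36/39/42 h) are kept at their
wall times: a fixed 24-h period makes them effective replicates without any
relabelling. The model assumes stable (undamped) oscillation with stationary
mesor; damping and population desynchrony are out of scope. An iteratively
reweighted (Tukey bisquare) fit is available behind `fit(robust=True)` as an
opt-in; the documented, reproducible core is plain OLS, and its p-values are
validated against a brute-force normal-equation oracle rather than any
third-party rhythm package.

Significance combines statistical and biological criteria: Benjamini–
Hochberg q < 0.05 (strict inequality) *and* relative amplitude ≥ 0.1
(inclusive). A non-positive fitted mesor makes the relative amplitude
undefined; such genes are reported with `relamp = NaN` and can never be
significant.

## Harmonization

TDM (Training Distribution Matching) is fitted on the pooled values of each
dataset (not per sample): with reference quartiles Q1, Q3, extremes and
IQR, the spreads (Q1 − min)/IQR and (max − Q3)/IQR are transferred to the
target's quartiles to obtain clamp bounds; target values are clamped and
linearly mapped onto [ref_min, ref_max]. The transform is global and
monotone, so it preserves within-gene and within-sample rank order
("inter-observation dependencies"). Pooled-per-dataset fitting matches the
design of the published TDM method.

Shared-window normalization divides each gene by its mean over samples in
the (inclusive, configurable) 12–24 h window, **on the linear scale**.
Per-gene (not global) normalization is required to remove gene-specific
platform offsets, and ratio (not log-subtraction) normalization keeps the
data on the positive linear scale on which relative amplitude is defined.
After it, both platforms have per-gene window mean exactly 1, so
concatenation introduces no platform offset inside the window.

## Preprocessing

TMM follows the published definition: reference sample = the one whose
upper-quartile count/library-size is closest to the mean upper quartile;
M/A values on genes positive in both samples; 30% two-sided trim on M and
5% on A (rank-based, intersected); inverse-asymptotic-variance weighted
mean of retained M values; factors centred to geometric mean 1. The
implementation is cross-checked against Bioconductor edgeR in the test
suite. CPM uses the standard library-size-scaled prior convention (default
prior 0.5 for the log transform, 0 when only filter means are needed).
Expression filters are inclusive at the boundary ("at least"): mean CPM
≥ 0.5 for counts (then TMM and CPM are recomputed on the retained genes —
the mechanism chosen for "renormalized using only the selected genes") and
mean log2 intensity ≥ 3 for arrays. Feature-to-gene collapse keeps the
feature with the highest mean over all time points; ties break to the
lexicographically smallest feature id, which is deterministic and
platform-independent.

## Circular statistics and PSEA

Phase correlation uses the Jammalamadaka–SenGupta circular coefficient with
its asymptotic normal p-value (the definition implemented by the standard
circular-statistics packages); it is rotation-invariant and equals ±1 for
rotations/reflections. Our implementation is cross-checked against
pingouin's. The asymptotic p-value is well calibrated from a few hundred
phase pairs; calibration tests therefore use n = 200 pairs per draw.

PSEA uses the Kuiper statistic V = D⁺ + D⁻ on phases mapped to [0, 1),
with the Stephens small-sample correction λ = (√n + 0.155 + 0.24/√n)·V and
the asymptotic series p = 2·Σ (4j²λ² − 1)·exp(−2j²λ²) truncated at 1e-12.
The background is the uniform circle; the empirical-background mode of the
original PSEA is out of scope. Phases are rounded to the nearest full hour
(half away from zero, 24 → 0) before testing; the vector-average pathway
phase is computed from the *unrounded* phases, since rounding is a property
of the test input, not of the phase estimate. Sets with fewer than 5
rhythmic members are excluded, and BH adjustment runs across tested sets
only (untested sets contribute no p-values). The asymptotic series is
applied for all tested sets (n ≥ 5); exact small-n tables are not used.

## Synthetic data

The generator emulates the two study designs: a bounded log2-intensity
platform (9 samples, 0–24 h every 3 h, values clamped to [0, 13.5]) and a
count platform with a wider dynamic range (11 samples, 12–42 h every 3 h).
Intensity noise is additive Gaussian on log2 values (default sd 0.15 log2
units, a realistic array noise floor); counts are negative binomial with
mean s_g(t)·L_s/10⁶ (the noiseless signal read in CPM units, so library
size enters linearly) and dispersion 0.05, typical of cell-line RNA-seq
replicates. Baseline log2 abundance is Normal(7, 2): this keeps nearly all
genes inside the intensity envelope and above both expression cutoffs,
matching the moderately-to-highly expressed genes such filters retain in
real data. Library sizes ramp deterministically over ±10% of 5·10⁶ so TMM
has genuine composition/depth differences to remove. Default simulation:
10,000 genes, 20% rhythmic, relative amplitudes uniform on [0.2, 0.6],
phases uniform on the circle.

What the generator does *not* emulate: probe-level effects, mappability and
gene-length biases, batch effects beyond the platform shift, damped or
desynchronising oscillations, and correlated noise between genes. Passing
recovery tests therefore demonstrate correctness of the pipeline under the
stated noise model, not performance guarantees on real cross-platform data,
where platform disagreement is far larger (real microarray/RNA-seq phase
correlations are known to be weak even when both series are individually
credible).

Labelled gene sets for PSEA benchmarking draw "clustered" sets from
rhythmic genes whose true phase falls in a window (default 1 h) around a
random centre and "null" sets uniformly from all genes.

## Numerical choices and degenerate inputs

- Cosinor fits are vectorized over genes via a single least-squares solve
  of the shared 3-column design; constant series get F = 0, p = 1, and a
  numerically perfect harmonic fit gets p = 0.
- Fewer than 3 distinct sampling times modulo the period make the model
  unidentifiable and are rejected; at least 6 observations are required.
- TDM rejects degenerate (zero-IQR) distributions; shared-window
  normalization rejects genes with non-positive window means and windows
  containing no samples.
- Circular correlation returns NaN (not an error) when either phase vector
  has zero circular dispersion; the circular mean returns NaN for a
  vanishing resultant (e.g. antipodal pairs). Values within 1e-9 of the
  period wrap to exactly 0.
- All stochastic components consume a `numpy.random.default_rng` seed;
  identical configuration and seed reproduce outputs byte for byte.

## Problem sizes

The default test-suite and acceptance problem sizes — 10,000-gene single
runs, 2,000–4,000-gene multi-seed sweeps (20 seeds), 50-seed PSEA recovery
on truth-level phase tables, and 5,000-draw Monte-Carlo calibrations — were
chosen to give stable estimates of every reported rate (binomial standard
errors well below the tolerances asserted) while keeping a full run in the
order of seconds on one CPU.

## Known limitations

- The expression filter can remove genuinely rhythmic but low-expressed
  genes; recovery metrics count these as misses by design.
- The asymptotic Kuiper p-value is slightly conservative below n ≈ 8.
- The robust fitting mode reports a Wald-type p-value from the IRLS
  covariance, which is not exchangeable with the OLS F-test p-value.
- Candidate-list annotation matches on exact gene identifiers; synonym
  resolution is the caller's responsibility.
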