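# Methods

`nmrage` re-implements, as a tested and reusable pipeline, the analysis
chain used for 1D ¹H NMR metabonomic profiling of longitudinal rodent
cohorts: a synthetic spectra generator with complete ground truth,
spectral preprocessing, recursive segment-wise peak alignment,
multivariate pattern recognition with subject-level cross-validation,
FDR-controlled univariate biomarker detection, and line-width analysis
of ligand–protein binding. This note records the models, the parameter
choices that matter, and the places where the design was genuinely open.

## Synthetic cohorts

Because studies of this kind rarely deposit raw spectra, the generator
is a first-class component: every downstream claim in the test suite is
a recovery statement against what the generator planted.

Each metabolite template is a set of first-order multiplets (singlet to
quartet by binomial ratios; "m" from an explicit line list) rendered as
pure Lorentzians — the natural NMR line shape, and exponential
apodization upstream preserves it, so no pseudo-Voigt option is offered.
A multiplet with center δ, coupling J (Hz) and spectrometer frequency ν
(MHz) has lines at δ ± kJ/ν. A rendered multiplet integrates to its
concentration (rectangle rule, within 1% when the lines sit inside the
grid).

Per sample, the generator draws, in a fixed order from a substream keyed
by `(seed, sample_index)` (so extending a design never perturbs earlier
samples):

* concentration noise — lognormal with unit mean and coefficient of
  variation `mult_noise_cv` (default 0.15, a typical biological CV for
  urinary metabolites at these group sizes);
* chemical-shift jitter — one Gaussian offset per template applied to
  all its multiplets, with template-specific sd: 0.01 ppm for citrate
  and 0.008 ppm for taurine (the classically pH-/ionic-strength-
  sensitive urine signals), ~0.002 ppm or zero elsewhere;
* dilution — log-uniform in `dilution_log_range` (default [0.5, 2]),
  multiplying the whole spectrum, to exercise quotient normalization
  over a symmetric multiplicative range;
* additive Gaussian noise (default sd 0.2 intensity units), appended
  after dilution scaling because thermal noise does not scale with the
  sample.

Protein binding is modelled as fast exchange: the observed width of a
bound metabolite's lines is the population-weighted average
`(1-f)·free + f·bound`. The pheromone 6H6MH3O ships with f = 0.5 and a
bound width chosen so the free/observed pair is 1.36/1.94 Hz, the
ultrafiltration contrast the line-width analysis must detect. An
ultrafiltered variant of any design forces f = 0 everywhere.

Default grid: 0.5–10.0 ppm at 0.00025 ppm, stored descending, at
600.44 MHz. No concentration scale is meaningful for synthetic data;
the default template library carries typical *relative* urine
intensities (creatinine, citrate and taurine dominant), which matters
for alignment realism — the custom citrate interval is anchored by
citrate itself only if citrate actually dominates its region, as it
does in real urine. The library covers ~20 metabolites plus two
"unknown" singlets; it deliberately omits water-suppression artifacts,
baseline roll, ¹³C satellites and CPMG relaxation editing (CPMG exists
only as a fluid label with its own exclusion preset).

## Preprocessing

Stage order is fixed: calibrate (optional) → exclude regions → align →
PQN → log. Exclusion precedes normalization so water artifacts cannot
drive dilution factors; alignment sees unnormalized but water-free
spectra; normalization sees aligned variables.

*Calibration* shifts the axis so the tallest peak in a search window
(TSP → 0 ppm for urine; the anomeric α-D-glucose doublet → 5.233 ppm
for plasma) lands on target, failing if nothing rises 5 noise-sd above
the window median.

*Region exclusion* presets: urine retains [0.8, 4.7] ∪ [4.9, 10.0] ppm;
1D plasma removes below 0.2, water 4.2–5.2 and above 10; CPMG plasma
removes below 0.8, water 4.6–5.15 and above 10. Excluded intervals are
open, so the retained bands keep their endpoints.

*PQN*: reference = element-wise median spectrum (the canonical choice);
per-sample dilution factor = median of the quotients x/ref over
variables where the reference exceeds 1e−12 of its maximum; the sample
is divided by its factor. No prior total-area scaling — the factor
already absorbs scale. Renormalizing against the *same* reference
returns factors of exactly 1. One caveat the tests quantify: when
planted group effects change a substantial fraction of total signal
mass, the median quotient absorbs part of the change (Lorentzian tails
spread any mass change across the grid), shrinking apparent log fold
changes by roughly a quarter at the synthetic library's size. Real
spectra, with hundreds of mostly unchanged signals, sit closer to the
ideal; this is a known boundary of what passing tests show about real
data.

*Log transform*: y = ln(x + offset). The automatic offset is the
smallest positive entry, raised by |min| when thermal noise leaves
small negative values, so the transform is always defined. The
processing log enforces normalize-before-log (overridable).

## Alignment (RSPA)

Two passes, both rigid integer-grid shifts with edge-value padding —
at 0.00025 ppm ≈ 0.15 Hz the grid step is far below any line width, so
sub-grid interpolation buys nothing, and the insertion/deletion local
stretching of the original recursive scheme is deliberately not
implemented.

The reference is the sample with the highest mean Pearson correlation
to all others (ties → smallest sample id). The global pass aligns the
whole spectrum, then splits at the deepest local minimum of the
*reference* (shared segmentation across samples) and recurses while
segments stay above `min_segment_width` (default 0.01 ppm) and depth ≤
10. Split candidates are restricted to the central half of a segment so
the recursion stays balanced — an unrestricted "deepest minimum" tends
to shave slivers off segment edges and exhausts the depth budget before
isolating peaks. Segments whose reference range falls below
`peak_prominence_floor` (1% of the reference's global range) are never
shifted: aligning noise against noise just overfits the reference and
oscillates between passes. A candidate shift is accepted when the
correlation gain exceeds `acceptance`·(1 − corr_before), with shifts
bounded by `max_shift` (default 0.02 ppm global, 0.05 ppm for custom
intervals; none of these values is prescribed anywhere, all are
surfaced in config).

The custom-interval pass rigidly aligns researcher-chosen,
baseline-separated windows (citrate 2.50–2.75, taurine 3.20–3.50 by
default) with no recursion, leaving everything outside untouched, and
warns when an interval edge carries more than 5% of the interval's
maximum intensity.

Known limitation: when per-sample jitter approaches a multiplet's
splitting (citrate's 0.025 ppm at jitter sd 0.01), line ownership can
flip between reference-defined segments and rigid shifts cannot fully
repair the region; a second pass may then still find work to do.
Idempotence holds within the designed envelope (jitter small relative
to splittings), which is how the property is tested.

## Multivariate analysis

*PCA* is mean-centered SVD; loading signs are fixed by making each
column's largest-magnitude element positive.

*Rank selection* uses bi-cross-validation with row×column hold-outs:
the held block A is predicted from the complements as
Â_k = B·D_k⁺·C (blocks centered by training-row column means), and the
k minimizing mean squared prediction error is selected; k = 0
(column-mean prediction) is allowed and is the expected answer for
structureless data.

*MMC* maximizes tr(Wᵀ(S_b − S_w)W): S_b and S_w are the between- and
within-class scatter matrices (both divided by total n), and the
discriminant loadings are the top eigenvectors of S_b − S_w, by default
n_classes − 1 of them. Unlike Fisher LDA this needs no inversion of
S_w, which is why it suits p ≫ n spectra; it is still computed on PCA
scores (rank from BCV, capped at n − n_classes) so the within-class
covariances that the *classifier* needs stay well-conditioned at per-
group n of 4–10.

*Leave-mouse-out CV*: folds are animals, never spectra. Inside each
fold the full pipeline — optional ANOVA p < 0.05 feature selection,
PCA, MMC, per-class Gaussians — is refit on training mice only; the
held-out animal's spectra are projected and assigned to the class
minimizing the quadratic discriminant distance
(z−μ_c)ᵀΣ_c⁻¹(z−μ_c) + ln det Σ_c. Class covariances are shrunk toward
their diagonal, Σ ← (1−λ)Σ + λ·diag(Σ) with λ = 0.1, because per-class
n is tiny; a 1e−10 trace-scaled ridge keeps the log-determinant finite
in degenerate folds. "Predicted variance" — a term the field uses
loosely — is defined here as 1 − RSS/TSS of the held-out spectra after
projection onto the training discriminant subspace (which is
orthonormal, being a product of orthonormal PCA and MMC bases). Folds
whose training set loses a class are skipped and reported.

## Univariate analysis

Per-variable one-way ANOVA on the log scale (so direction calls are
log-mean differences, matching the ↑/↓ arrow semantics of biomarker
tables). The F statistic is computed directly so degenerate columns
follow an explicit convention: zero scatter everywhere → F = 0, p = 1,
flagged; zero within-group scatter with a real difference → p = 0.

Benjamini–Hochberg step-up controls the FDR: sort p, find the largest k
with p(k) ≤ kq/m, call everything at or below p(k); the attained
threshold is reported (0 when empty). Three tiers: `FDR_significant`
(in the BH mask at q = 0.05 or 0.10), `potential` (unadjusted p < 0.05
— the liberal screen used when multivariate models are built from
training profiles), `ns`.

Per-variable results collapse to metabolites via a shipped ppm-window
library (±0.015 ppm around standard urine assignments; unknowns as bare
windows). A metabolite's tier is the best tier among its windows; its
p_min is the smallest window p; each window votes a direction with the
sign of its *aggregate* log-difference (robust to residual
misalignment, where the single minimum-p variable can sit on a
dispersion dipole), and disagreeing windows flag a conflict rather than
resolve it.

## Line widths and identification scoring

FWHM is measured two ways: a least-squares Lorentzian fit (amplitude,
center, half-width, baseline offset; relative residual reported so
overlapping peaks can be rejected) and interpolated half-maximum
crossing after subtracting a baseline estimated from the outer 10% of
window points — the programmatic version of a manual half-band-width
measurement, exact on straight flanks and invariant to intensity
scaling and constant baseline. Widths convert ppm ↔ Hz through the
spectrometer frequency. Filtered/unfiltered width groups are compared
with a two-tailed Welch t-test (Welch–Satterthwaite df); equal constant
groups return p = 1 by convention.

MICE (metabolite identification carbon efficiency) is identification-
information bits divided by carbon count; the scorer applies no
threshold. The default rubric (one bit per matched item of evidence,
per kind) ships as an overridable data file; the bits are always
user-auditable in the tally.

## Pipeline, sizes and determinism

`run_study` executes the fixed stage order, records an append-only
provenance log (steps, parameters, package version, config hash), and
writes all tables with fixed float formatting so a rerun from the same
config and seed is byte-identical. Samples are sorted by id before
analysis, making every report independent of input order.

Test and acceptance simulations run on reduced grids chosen so peaks
stay well-resolved (≥5 grid points per line width): typically
0.5–4.0 ppm at 0.0005 ppm for cohort-level checks and 0.00025 ppm
windows for alignment and line-shape checks; cohort sizes mirror the
study design (4–5 mice per genotype × week cell, two batches of 10 for
the batch null). The full default grid (38,001 points) is exercised
through the exclusion-count and I/O tests.

## Limitations

* Rigid-shift alignment cannot repair jitter comparable to multiplet
  splittings (see above); warping methods are out of scope.
* PQN on small synthetic libraries absorbs part of large planted
  effects; reported fold changes are conservative.
* The synthetic generator omits baseline distortion, water-suppression
  residues and peak-shape heterogeneity, so passing recovery tests
  bound algorithmic correctness, not robustness to every acquisition
  artifact.
* The "predicted variance" definition is this package's own; published
  uses of the phrase may differ.
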