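# Methods

This note documents the models and procedures implemented in `ppaeeg`,
the choices made where the design was genuinely open, and what the
synthetic cohorts can and cannot demonstrate.

## Synthetic cohorts (`ppaeeg.synthdata`)

**What is emulated.** A four-group resting-state EEG cohort — controls
(CG) and the three PPA variants (nfvPPA, svPPA, lvPPA) with default group
sizes 20/18/10/12 — recorded on 32 channels (10/20 montage) at 500 Hz,
nominally 20 minutes per subject. Each recording is built from three
ingredients:

1. *Spectral structure.* Every latent source shares a group-specific
   one-sided PSD: a 1/f (pink) background (total power 5 µV², floor at
   1 Hz) plus flat band bumps calibrated so the power in each of
   delta/theta/alpha/beta/gamma equals the group's configured
   `10^(log-power)` exactly. Controls default to a plausible resting
   profile (log10 µV²: delta 1.4, theta 1.0, alpha 1.4, beta 0.9,
   gamma 0.4); patients shift theta up and alpha down (e.g. nfvPPA
   +0.5/−0.4), the slowing pattern reported clinically for these
   syndromes, with mild variant-specific differences so the four-class
   task is not degenerate. Effect sizes are configuration, not
   hard-coded. Band oscillators are realized as narrowband Gaussian
   processes (frequency-domain shaping of white noise); by the Rice
   representation these are randomly amplitude- and phase-modulated
   sinusoids, and the construction makes per-band power exactly
   calibrated, so planted log-power differences are recovered without
   bias by an aligned full-length DFT.
2. *Connectivity.* Cross-channel dependence is planted through a latent
   precision matrix P (unit diagonal, off-diagonal couplings 0.25):
   sources are mixed through the Cholesky factor of P⁻¹. Rows of the
   mixing matrix are unit-normalized — partial correlation is invariant
   under per-channel rescaling, so the partial-correlation ground truth
   `−P_ij/√(P_ii P_jj)` and the per-channel band powers hold
   simultaneously. Defaults: controls get a triangle-free ring lattice
   (low clustering), patients disjoint 4-cliques (maximal clustering),
   giving a planted, sign-testable group difference in graph metrics.
3. *Nuisance components*, added after mixing and meant to be removed by
   preprocessing: 50 Hz line noise (10 µV, common phase), slow sinusoidal
   drift (20 µV, 0.05–0.3 Hz), and stereotyped 300 ms biphasic blink
   transients (~120 µV, Poisson 10/min, weighted onto frontal channels).

**What is not emulated**, hence what passing tests do not show about real
data: non-stationarity and state changes (drowsiness), spatially
realistic volume conduction and electrode geometry, frequency-dependent
connectivity (the planted dependence is broadband), muscle/movement
artifacts, and between-subject heterogeneity beyond noise realizations
(all subjects of a group share one profile). Perfect benchmark scores on
strong-effect synthetic cohorts therefore validate the *pipeline
mechanics* (no leakage, correct estimators, recoverable effects), not
clinical performance.

Generation is deterministic given `(spec.seed, subject_seed)`. Cohorts
are written as one CSV per subject plus a manifest and a ground-truth
JSON; EDF input is read via MNE, but cohort output is CSV because no EDF
writer is available in the supported dependency set.

## Preprocessing (`ppaeeg.preprocess`)

Fixed order: time-range selection → 1 Hz high-pass → line-noise removal →
average re-reference → 40 Hz low-pass → ICA with component rejection →
1 s epoching → amplitude-based epoch rejection. Choices:

- **Filters** are zero-phase forward–backward 4th-order Butterworth
  (≈48 dB/octave effective). Zero phase avoids band-specific delays that
  would corrupt connectivity estimates.
- **Line-noise removal** follows the sliding-window regression idea: 4 s
  Hann-weighted windows with 50 % overlap; per window the dominant
  frequency within ±5 Hz of 50 Hz is located on a zero-padded spectrum,
  its complex amplitude fitted per channel by weighted least squares, and
  the synthesized sinusoid subtracted by overlap-add. Harmonics above
  40 Hz are left to the low-pass. On a pure tone this attenuates ≥20 dB
  at 50 Hz while moving out-of-band power by <1 dB.
- **Manual steps replaced.** Visual time-range selection becomes an
  explicit keep-list of intervals; visual epoch review becomes a
  peak-to-peak rule (default 100 µV, configurable) — no threshold is
  prescribed by the clinical workflow this mirrors, so both defaults are
  logged.
- **ICA** is scikit-learn FastICA on the continuous cleaned signal,
  seeded. Average-referenced data has rank n−1, so n−1 components are
  extracted by default (a full-rank request on rank-deficient data is
  degenerate and unstable). For long recordings the unmixing is fitted on
  ≤20 000 evenly-strided samples and applied to all. A component is
  rejected as blink-like when >40 % of its absolute mixing weight lies on
  frontal channels *and* its source kurtosis exceeds 5; the 40 % value
  reflects that average re-referencing pulls a pure frontal topography's
  frontal share to ≈0.5.

## Spectral features (`ppaeeg.spectral`)

Band power is a per-epoch Hann periodogram (density scaling), averaged
over the 1 s epochs — a Welch-style estimate in which the epochs are the
segments. Bands are half-open [lo, hi) so touching printed edges resolve
unambiguously (a 4 Hz bin is theta, not delta). Both relative power
(fraction of 1–45 Hz total) and log10 absolute power enter the feature
table; the >45 Hz remainder ("OoB") is computed as a diagnostic but
excluded from the classifier (the 40 Hz low-pass empties it). Known
limitation: with 1 s windows, Hann leakage across band edges biases
absolute band power when the true PSD is strongly stepped (as in the
synthetic sources); group *differences* keep their sign, and the
generator recovery test therefore measures calibration with an aligned
full-length DFT instead.

## Wavelet features (`ppaeeg.wavelet`)

Seven-level DWT with Daubechies-4 (common in EEG work; family
configurable). Boundary mode defaults to periodization, making the
transform exactly orthogonal — coefficient energy equals signal energy
and reconstruction is exact to rounding — at the cost of wrap-around
boundary coefficients; symmetric padding is available via `mode=`.
Nominal subband edges are the dyadic values [fs/2^(k+1), fs/2^k),
truncated (not rounded) to one decimal to match how such tables are
conventionally printed (500/64 = 7.8125 → 7.8). The per-subband feature
is log10(1 + mean coefficient energy), averaged over epochs; the +1
keeps the zero-signal feature at 0 and is monotone. Subbands 1–2
(>62.5 Hz at 500 Hz) are excluded: the 40 Hz low-pass leaves them empty.

## Autoencoder features (`ppaeeg.autoencoder`)

A mirrored fully-connected encoder–decoder (default 500→64→16→64→500,
tanh hidden layers, linear latent and output), MSE loss, Adam, trained on
1 s single-channel windows pooled across channels (shared weights keep
the parameter count desk-scale); windows are globally standardized and
subsampled to ≤20 000 for training. Implemented in NumPy with a seeded
RNG, so training is bit-deterministic. With linear activations, no
hidden layer and no biases the model is a linear map, which the tests
exploit (subspace recovery against a PCA oracle; homogeneity of the
encoder). Per subject the features are the mean and sd over epochs of
each latent unit per channel. The model records the subject ids it was
trained on; the study driver trains it on the training split only, and
the leakage audit asserts this.

## Network features (`ppaeeg.network`)

Per band (delta–gamma; OoB excluded) the retained epochs are
concatenated, band-pass filtered, and one partial-correlation matrix is
estimated per subject: Ledoit–Wolf shrinkage covariance, inverted, then
`pcorr_ij = −P_ij/√(P_ii P_jj)`. Shrinkage is on by default because 32
channels against a limited number of clean samples makes the plain
inverse unstable; the plain inverse is available (`shrinkage=None`) and
is used in the convergence tests. The adjacency is |pcorr| with zero
diagonal. Binary graphs come from proportional thresholding — keep the
top ⌈density·n(n−1)/2⌉ edges, default density 0.2, ties broken
lexicographically and a degenerate tie regime flagged — chosen so degree
counts are comparable across subjects; the definitions of the metrics
read as counts, so weighted variants are deliberately out of scope.
Metrics: node degree, mean shortest-path hop count over connected pairs
(disconnected pairs excluded and counted), and transitivity
3·triangles/connected-triples. networkx provides the graph algorithms;
the test suite checks them against a brute-force enumeration oracle on
all graphs up to 8 nodes.

## Classification (`ppaeeg.classify`)

Stratified 80/20 split with per-class round-half-up train counts (40/20
→ 32+16 train, 8+4 test); min-max scaling fitted on train (constant
columns map to 0 with a warning; test values may leave [0,1], and a clip
guard protects Multinomial NB, which requires non-negative input);
ANOVA-F selection of the top k = 50 columns, ties broken by name. The
hyperparameter search (`ppaeeg.bayesopt`) is sequential model-based
optimization: a Matern-kernel Gaussian-process surrogate over
[0,1]-encoded dimensions, expected-improvement acquisition over a seeded
finite candidate pool, budget 32 evaluations (8 random initial), fully
deterministic given the seed. Search spaces per model are documented in
`_search_space`; the kNN neighbor range is clamped to the smallest
CV-fold fit size, and a configuration whose CV fold fails scores 0. The
Elastic Net is used as a classifier: logistic regression with an
elastic-net penalty (saga). Cross-validation is stratified 10-fold on
F1 (PPA positive; macro-averaged for the four-class task), falling back
with a warning to the largest feasible fold count. Undefined metric
ratios (zero denominators) are reported as NaN, never silently as 0.
Tables 2–4-style outputs report both the CV tuning score and held-out
metrics, labeled, since either convention appears in practice.

## Reporting (`ppaeeg.report`)

PCA is computed on the min-max-scaled feature table (scaling makes
heterogeneous feature families commensurable); the embedding exposes
orthonormal loadings and explained-variance fractions. Feature
importance is the ANOVA F-score of the selected columns (the quantity
the selector actually used), with provenance-family percentages (Node
Degree / Clustering Coefficient / Path Length / qEEG / Wavelet /
Autoencoder). Decision trees are exported both as text and as a flat
rule table whose re-execution reproduces the fitted model's predictions
exactly (round-trip tested). Figures (PCA scatter, importance bars,
confusion heat-maps, ROC, schematic head-plot of the strongest
connections) use a schematic 2D 10/20 layout, not digitized electrode
positions.

## Problem sizes used in validation

The acceptance script runs the study-sized cohort (60 subjects, 32
channels) with 2-minute recordings — long enough for ~115 clean epochs
per subject, which stabilizes every estimator, while keeping a full run
in minutes on one CPU; its elapsed time is reported as a quantity. The
Monte-Carlo recovery experiments use deliberately small cohorts (2–3
subjects per group, 8–16 channels, 8–20 s) because the planted effects
are strong and only the *sign* of the recovered effect is scored across
20 cohorts (100 runs for the ANOVA selection rate). The unit-test suite
uses the same scales. Search budgets in the acceptance run are 12
evaluations per model (the full default is 32); on these synthetic
effect sizes the optimum is flat, and the choice is recorded here as the
package's own.

## Known limitations

- Line-noise removal fits a single sinusoid per window; heavily
  amplitude-modulated mains interference would need narrower windows.
- The blink-rejection rule is tuned to the stereotyped frontal transient
  the generator produces; real ocular/muscle artifacts are more varied
  and may need additional criteria (e.g. correlation with an EOG lead).
- Band-power absolute calibration is leakage-limited at 1 s windows (see
  above).
- Proportional thresholding guarantees equal edge counts, so degree
  *distributions*, not densities, differ between groups; metrics on the
  weighted graph are not implemented.
- The permutation sanity check compares the real held-out F1 to the
  permutation-null mean; with very small test sets individual permuted
  F1 values are coarsely quantized.
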