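# Methods

## Signal model and preprocessing

A recording is a channels × samples matrix in microvolts with a stated
sampling rate (256 or 500 Hz in the datasets this pipeline targets) and 19
electrodes in 10–20 order (Fp1, Fp2, F7, F3, Fz, F4, F8, T3, C3, Cz, C4,
T4, T5, P3, Pz, P4, T6, O1, O2); inputs with named channels are reordered
to this canonical list.  Filtering is FIR and zero-phase (forward–backward
application), so downstream features are not time-shifted: a band-pass with
default edges 0.5 and 45 Hz and a band-stop over 47–53 Hz for 50 Hz mains.
FIR length is ~3 periods of the low cutoff (3·fs/f_low), capped at 1023
taps and forced odd; `filtfilt` padding is clamped to the signal length.
Because a 0.5 Hz high-pass edge leaves a wide transition band relative to
DC, per-channel means are subtracted before band-pass filtering — this is
part of the high-pass behavior and makes constant offsets vanish exactly.
Recordings are cut into non-overlapping 15-s windows (19 × 3840 samples at
256 Hz, 19 × 7500 at 500 Hz); a trailing partial window is dropped so every
segment yields the same feature count.

## Multiscale PCA denoising

Each channel is wavelet-decomposed (default `sym4`, depth J = 5, symmetric
extension) and at every coefficient level the channels × coefficients
matrix is truncated by PCA: coefficient vectors across channels are the
observations, each channel is mean-centered, and components whose
eigenvalues strictly exceed the mean eigenvalue are retained (Kaiser rule;
ties drop).  A detail level whose retained set is empty is zeroed outright;
the approximation level keeps its retained components.  The channels are
rebuilt by the inverse transform and a final Kaiser-rule PCA pass is
applied to the reconstructed matrix.  Eigenvector signs are fixed (largest
loading positive) for bit-reproducibility.  The rationale: shared cortical
sources make the clean multichannel signal low-rank across channels while
noise is spatially incoherent, so sub-average eigendirections carry mostly
noise.  Limiting behavior verified by tests: on a noise-free low-rank
matrix the transform is the identity to ~1e-12 relative error, and on
rank-1 signal plus Gaussian noise it strictly reduces mean-squared error to
the clean signal for every tested seed.  The wavelet name, depth, and the
zero-or-keep treatment of empty detail levels are configuration, not claims
about any particular prior software's internals.

## Amplitude-polar map and BPFSL features

The APM uses the first difference a′ of a channel both as radius and as
radian angle: x = a′·sin a′, y = a′·cos a′.  Microvolt increments feed
sin/cos directly — no unit rescaling — because the construction is defined
on raw amplitudes; a `prescale` factor (default 1.0) exists for sensitivity
studies only.  Useful exact invariants: x² + y² = a′² pointwise, and under
input negation x is unchanged while y is negated.

The BPFSL descriptor slides a 5-wide window over the Euclidean distances
between consecutive APM points.  The window threshold is
γ = (population std of the 5 distances) / 16; bit i is 1 iff the i-th
distance is ≥ γ (so an all-equal window, γ = 0, ties to code 31), and the
bits pack little-endian into a code 0…31.  The per-channel feature vector
is the 32-bin histogram of codes: an N-sample channel gives N − 1 points,
N − 2 distances and N − 6 codes, so counts sum to N − 6 exactly.  Two
deliberately exposed knobs: `gamma_divisor` (default 16 = 2⁴; 24 supported
as an alternative reading of the threshold definition) and histogram
normalization (default off, raw counts; useful when mixing segment lengths
such as 3840- and 7500-sample windows).  Codes are indexed 0–31; there are
exactly 32 of them, one per bin.

Channel fusion is concatenation in montage order: 19 × 32 = 608 features
per segment, named `ch<electrode>_bin<code>` so per-channel contribution
summaries can be computed from names.  For a 256 Hz segment this is a
1 − 608/72960 = 99.17 % dimensionality reduction (99.57 % for 500 Hz
segments); the pipeline computes the ratio from the actual shapes at run
time and logs it in the manifest.

## NCA feature ranking

Feature selection uses neighborhood component analysis with a diagonal
metric: one weight per feature, learned by maximizing the regularized
expected leave-one-out accuracy

F(v) = Σᵢ Σ_{j: yⱼ=yᵢ, j≠i} p_ij − λ Σ_f v_f²,
p_ij ∝ exp(−Σ_f v_f² |x_if − x_jf|), p_ii = 0,

a soft nearest-neighbor objective over a weighted Manhattan distance.  The
raw parameters v are unconstrained and the reported weight is v_f², which
is nonnegative by construction.  Features are z-scored first (distance
kernels are scale-sensitive; switchable via `standardize`).  λ defaults to
1/n.  Optimization is L-BFGS-B with the analytic gradient; the pairwise
per-feature difference tensor is independent of v and is precomputed when
it fits in memory (~1.5 GB cap), else accumulated in 64-feature blocks.
Initialization is 1/√p plus a small seeded perturbation, so the fit is
deterministic per seed; the recorded objective history is non-decreasing
across accepted iterates.  Ranking sorts weights descending with ties
broken toward the lower feature index.  By default NCA is fit once on the
full feature matrix before cross-validation, mirroring a sequential
rank-then-classify protocol; this leaks selection information into the CV
estimate (see Limitations) and a per-fold refit is available to callers by
fitting inside their own fold loop.

## Classification and evaluation

The classifier is a single-hidden-layer feedforward network: 10 tanh units,
softmax-style two-class output (probability rows sum to 1), trained by
L-BFGS on standardized inputs with seeded initialization.  Evaluation is
stratified k-fold cross-validation (default k = 10, seeded shuffling;
folds are re-drawn a bounded number of times if a training split would miss
a class).  Confusion counts are pooled over all test folds — every segment
is tested exactly once — and ACC/SEN/SPE are computed from the pooled
totals in percent, with responders as positives.  SEN (or SPE) is reported
as NaN with a warning when no positives (negatives) were evaluated.  The
feature-count sweep evaluates increasing prefixes of the ranking and picks
the smallest k attaining the maximal accuracy.  A k-nearest-neighbor
baseline shares the fold protocol.  Fold grouping is per-segment by
default, matching the protocol this pipeline family reports; because
segments of one subject then appear on both sides of a split, a
`subject` grouping mode (StratifiedGroupKFold) is provided and is the
right choice whenever subjects have identifiable fingerprints.

## Synthetic study conditions

The generator emulates 19-channel resting EEG: per channel, band sinusoids
at 2 / 6 / 10 / 22 Hz (delta/theta/alpha/beta) with uniformly random
phases, plus 1/f^β background noise (spectrally shaped white noise, 10 µV
RMS), optional 50 Hz line interference, and 0.3-s raised-cosine blink
pulses (75 µV, Poisson arrivals, Fp1/Fp2 only) to give MSPCA a realistic
frontal transient to suppress.  Every channel and the blink train draw
from independent RNG streams keyed by (seed, class, subject, channel), so
records are bit-reproducible and toggling one noise source never perturbs
another.  Class structure comes solely from per-class band amplitudes and
the 1/f exponent.  The `separable` preset (defaults) gives responders an
alpha-dominant, steeper-spectrum profile (alpha 30 µV, beta 5 µV, β = 1.3)
and non-responders a beta-shifted, flatter one (alpha 10 µV, beta 18 µV,
β = 0.7) — a deliberately large gap whose purpose is to make the full
pipeline's discriminative path testable; the `null` preset copies one
class's parameters to both for chance-level checks.

What the generator does **not** emulate: subject-level heterogeneity
(within a class, subjects differ only in phase/noise/blink realizations),
non-stationarity, electrode artifacts other than blinks, volume-conduction
correlation structure between channels, and realistic alpha reactivity.
Consequently, passing the end-to-end tests shows the pipeline recovers a
large programmed spectral/complexity gap — it does not certify clinical
accuracy on real cohorts, where subject fingerprints also make per-segment
CV optimistic.

## Numerical choices and degenerate inputs

- Strict ">" in the Kaiser comparison; all-tied eigenvalues retain nothing
  (a zeroed detail level).
- Population (ddof = 0) standard deviation in the BPFSL threshold.
- All-zero segments map to all-zero MSPCA output; constant channels give
  the one-hot code-31 histogram; thresholds at γ tie upward.
- CSV round-trips are exact: writes use 17 significant digits and reads use
  round-trip float parsing.
- Filters validate band edges against Nyquist; too-short records segment to
  an empty list with a warning rather than an error.

## Limitations

- Global (pre-CV) NCA ranking inflates cross-validated accuracy estimates;
  on permuted labels the measured null sits a few points above 50 % for
  exactly this reason (within the tolerated band in the tests).  Use
  per-fold selection and subject grouping for unbiased real-data estimates.
- The FFNN is trained by a quasi-Newton full-batch method, appropriate for
  the small sample sizes here; very large cohorts would warrant a
  stochastic optimizer.
- MSPCA assumes channel-space low-rankness; it can attenuate genuinely
  focal activity confined to a single electrode.
- The amplitude-as-radians construction makes features sensitive to the
  input's physical units; inputs must be in microvolts (or use `prescale`).
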