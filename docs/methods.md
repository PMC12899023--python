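# Methods

This note documents the models, conventions and design choices behind
`ssvepclean`, in the spirit of a methods section: what is computed, why
these defaults, and what the synthetic benchmark does and does not
show.

## Per-window least-squares cleaning

Each occipital channel is cleaned independently in non-overlapping 1-s
windows (256 samples at 256 Hz).  The design matrix stacks a constant
bias column with the p auxiliary-channel windows; the ordinary
least-squares fit is solved by SVD-based `lstsq` (rank-revealing), and
the fitted projection is subtracted.  One-second windows trade off
local stationarity of the artifact projection against estimator
variance (n = 256 samples against p + 1 ≤ 7 coefficients).

Conventions and edge cases:

- **Rank deficiency** (e.g. electrically bridged electrodes producing
  duplicated auxiliaries) yields the minimum-norm solution plus a
  per-window degeneracy flag — never an exception, because real caps do
  this routinely.  Degenerate windows are excluded from β summaries.
- **Flat-lined target windows** have undefined variance explained;
  they are reported as NaN.
- **β statistics** pool |β| over windows and the three occipital
  targets (one row per auxiliary channel).  The SD is population
  (divide by N) by default, configurable to sample; CV = SD / mean|β|.
- Cleaning uses only the window itself — no labels, no cross-subject
  statistics — so it cannot leak training-subject information into a
  test subject under leave-one-subject-out (LOSO) evaluation.
- **Subset search** scores every non-empty auxiliary subset by the
  evaluated subject's own LOSO test accuracy and returns the argmax
  (ties: smaller subset, then enumeration order).  This mirrors the
  original study's procedure and therefore inherits its optimistic
  selection bias: the selected subset's accuracy is not an unbiased
  estimate of generalization.  Use it to characterize channel
  relevance, not to report headline accuracy.

## Preprocessing filters

The acquisition-stage filters are Butterworth designs in cascaded
second-order sections: a 48–52 Hz notch (overall order 4) and a
0.5–100 Hz band-pass (overall order 8).  The stated order is the
*overall* filter order; scipy's band designs double the prototype
order, so `butter(order // 2)` is used.  Filtering is causal
(single-pass) by default — the cleaning method is meant to be
online-capable and zero-phase filtering is non-causal — with a
`zero_phase` flag for forward–backward filtering where offline
analysis prefers it.  No samples are dropped automatically; edge
transients are the caller's concern (tests discard 1-s edges
explicitly).

## Spectral features

Amplitude spectra use a plain rectangular-window FFT with one-sided
2/N scaling (a unit sinusoid on a bin reads 1.0; DC and Nyquist are
not doubled).  With 1-s windows the bin grid is 1 Hz, so the
stimulation frequencies (7, 8, 9 Hz) and their second and third
harmonics sit exactly on bins and leak nothing; no taper or detrending
is applied for the same reason.  The scaling convention cancels in
classification but is fixed so spectra are physically interpretable
and testable (Parseval's identity holds per window).  Feature vectors
concatenate the amplitudes at {7, 8, 9, 14, 16, 18, 21, 24, 27} Hz
channel-major over O1, O2, Oz → 27 features.

## Classifiers

**Linear SVM** — one-vs-rest `LinearSVC` with hinge loss and C = 1 on
features standardized by training-set statistics.  The multi-class
scheme and C are exposed; defaults follow the package's reading of a
maximum-margin linear baseline.

**compact_net** — a deliberately small dense network: per-feature
z-score normalization (training statistics), one 64-unit ReLU layer,
dropout 0.5, softmax output.  Training: Adam (learning rate 1e-3,
default; unstated in the protocol this mirrors), batch 64, up to 40
epochs, early stopping with patience 3 on the validation loss of a
class-balanced split of ~12.5% of the training data (floor per class,
at least one sample).  The network is implemented directly in numpy —
forward pass, inverted dropout, analytic gradients and Adam are a few
dozen lines — keeping the package dependency-light and the training
loop fully deterministic given seeds.  Each variant is trained three
times with seeds `seed_base + {0,1,2}`; prediction returns one label
vector per run, and accuracy is reported as mean ± SD across runs
(never a majority-vote ensemble).  For window-level McNemar
comparisons the first run's decisions are used.

## Reference methods

**CCA** — for each candidate frequency a reference matrix of sines and
cosines at f, 2f, 3f is correlated with the 3-channel window; the
first canonical correlation is computed from SVD-orthonormalized,
column-centered bases (numerically stable, rank-deficiency tolerant),
and the argmax frequency wins, ties to the lowest frequency.  Sin+cos
pairs make the decision invariant to the unknown response phase.

**FBCCA** — five zero-phase band-pass filters (6/14/22/30/38–90 Hz,
overall order 4 before the forward–backward doubling) are applied per
window; per-band first canonical correlations are combined as
Σ w(n)·ρ(n) with the standard decreasing weights w(n) = n^(-1.25) +
0.25.  The weights are configurable and recorded in every report; a
squared-ρ combination mode exists for comparison.  With a single band
and unit weight FBCCA reduces exactly to CCA on the filtered signal.

## Evaluation metrics

- **Accuracy**: percentage of correctly classified 1-s windows under
  LOSO (all windows of one subject form the test set).
- **McNemar**: window-level paired comparison; exact two-sided binomial
  p for b + c ≤ 25 discordant windows, continuity-corrected χ²(1)
  above; b + c = 0 is degenerate (p = 1).
- **Group tests**: paired t and Wilcoxon signed-rank on per-subject
  accuracies, both reported.  Zero-variance nonzero differences return
  the t limit p = 0.
- **ITR (Wolpaw)**: (60/T)·[log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1))]
  bit/min, clamped to 0 at or below chance; the raw formula is exposed
  via `clamp=False`.
- **Spectral SNR**: 10·log₁₀ of the stimulation-bin power over the mean
  power of the six bins at ±1, 2, 3 Hz.  Per-window SNR in dB is
  averaged over windows, then over the three occipital channels
  (dB-domain averaging, matching per-window computation followed by
  averaging; linear-domain averaging is available).

## Synthetic data generator

The generator emulates the structure of the 12-subject study protocol
the package models: per subject three 60-s sessions at 256 Hz, one per
stimulation frequency (7, 8, 9 Hz), nine electrodes (O1, O2, Oz
targets; Cz, Fp1, HEOG, neck, cheek, jaw auxiliaries).

Signal model per session:

- **SSVEP**: three harmonics with amplitudes [1.0, 0.5, 0.25] µV.  One
  random phase per harmonic and session, plus a small ±0.4 rad
  per-channel spread.  The near-alignment matters: real SSVEPs at
  neighbouring occipital electrodes are strongly phase-coherent, which
  makes the response spatially near rank-1.  Fully independent
  per-channel phases would let a multichannel decoder cancel any
  rank-1 artifact projection in a spare spatial dimension at almost no
  cost, understating artifact harm.
- **Background**: 1/f (α = 1) noise at 4 µV RMS per occipital channel.
  This level was fixed so the raw-signal stimulation-bin SNR (~2–3 dB)
  and raw LOSO accuracies (~78–82%) sit in the regime the reference
  study reports, rather than the near-ceiling regime a quieter
  background produces.
- **Artifacts**: shared "events" (8/min, 1–2 s, non-overlapping,
  uniform random onsets via rejection sampling) model deliberate
  compound facial actions; each source joins an event with probability
  0.6 (the central-channel source always joins, playing its role as a
  global artifact reference).  Source shapes: EMG bursts = 20–90 Hz
  band-limited noise under a Tukey envelope with a small (<10% power)
  sub-4-Hz electrode-motion component; blinks = trains of ~0.3-s
  biphasic pulses; ocular/eyebrow drift = a slow ramp with abrupt
  release.  Amplitudes are deliberate-artifact sized (ocular 120 µV
  peak, facial EMG 100 µV RMS, central 50 µV RMS), so occipital
  projections exceed twice the SSVEP fundamental during episodes and
  ~30% of windows are contaminated.
- **Mixing**: fixed per subject (relative jitter 0.15 across subjects)
  with magnitudes shaped like the β gains observed on real caps
  (central ≈ 0.4 dominant; ocular/muscular 0.10–0.15).  Auxiliary
  channels record their source plus weak 1/f background (0.2 µV RMS)
  and white sensor noise (0.5 µV RMS), with no SSVEP leakage by
  default (`ssvep_leakage` exists to stress-test the known caveat of
  regressing out neural signal).
- **Determinism**: all randomness derives from one master seed through
  `(seed, subject, session)` generator streams; identical configs are
  bit-reproducible.
- **Ground truth**: recorded occipital = pristine SSVEP + background +
  mixing·sources, exactly, enabling direct checks of coefficient
  recovery (mean β̂ → true gain as auxiliary noise → 0; ~1%
  attenuation at 20 dB auxiliary SNR).

What the generator does **not** emulate: nonstationary electrode
impedance drift, head-movement cable artifacts uncorrelated with any
auxiliary channel, mutual EEG→EOG contamination, inter-subject
differences in SSVEP amplitude or background spectrum beyond the
mixing jitter, and volume-conduction physics (mixing is a free matrix,
not a head model).  Passing the synthetic end-to-end checks therefore
demonstrates that the pipeline removes *linearly mixed, auxiliary-
observable* artifacts and that the evaluation machinery is correct —
not that the same accuracy gains will materialize on any particular
real recording.

## Problem sizes used in the automated checks

The shipped test suite runs the full comparison on 12 synthetic
subjects × 3 × 60-s sessions (2160 windows) for five master seeds for
the effect-direction check, and on 3-subject, 20-s-session datasets
for unit-level pipeline tests.  These sizes were chosen to exercise
the complete protocol (including LOSO with 11-subject training pools)
while keeping the suite fast enough for routine development runs.

## Known limitations

- Per-window OLS subtracts any neural signal that is coherent with the
  auxiliaries within the window; with `ssvep_leakage > 0` the
  generator reproduces this attenuation for study.
- The regression assumes the projection is constant within 1 s; fast
  posture changes violate this (adaptive recursive variants are out of
  scope).
- EDF output quantizes to 16 bits over ±3276.8 µV (0.1 µV steps) and
  truncates to whole 1-s records.
- The compact network is CPU-only by design; its three runs are means
  to quantify initialization variance, not an ensemble.
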