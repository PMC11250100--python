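# Methods

This note records the modelling choices, numerical conventions and
known limitations behind `epochsift`. It documents what the code does
and why; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Signal conditioning

The canonical chain band-passes continuous recordings to 0.1–70 Hz and
band-stops 49–51 Hz against European mains, then cuts 1.5 s epochs
(−0.5 s to +1 s) around each stimulus, keeping only the first epoch per
(infant, stimulus) pair. Filters are linear-phase symmetric FIR
kernels designed with `scipy.signal.firwin` and applied centred, so an
in-band tone emerges with zero measured delay. The literature this
design follows does not fix kernel lengths or tapers; our conventions
are:

- Hamming taper; transition widths 0.1 Hz at the band-pass low edge,
  5 Hz at the high edge, 1 Hz for the band-stop. Kernel length is
  ⌈3.3·fs/Δf⌉, rounded up to odd.
- The band-pass is the convolution of a low-pass with a
  spectrally-inverted low-pass (the high-pass), which makes the DC gain
  exactly zero and lets the two edges have independent transitions.
- Zero-phase application uses reflection padding by half the kernel
  length (repeated reflection when the kernel outgrows the signal) and
  FFT convolution; output length equals input length.
- Event-to-sample mapping is half-open: the event maps to the first
  sample with time ≥ event time.

A 0.1 Hz edge demands a ~66 000-tap kernel at 2 kHz — far longer than
one 3000-sample epoch — so filtering is applied to the continuous
recording whenever one exists. For stand-alone epochs a relaxed
0.5 Hz low edge with reflection padding is offered and a warning is
logged; a compatibility band of 0.5–30 Hz is available for data that
was manually reviewed at that band. Mains suppression of ≥40 dB is
only claimed for continuous data, where the epoch core sits away from
the padded edges.

## The feature bank

31 scalars per epoch, in a frozen manifest order
(`feature_manifest.json`, version 1). Conventions that the sources of
these descriptors leave open:

- **Kurtosis** is Pearson's (normal → 3) everywhere; moments are
  population moments (ddof 0).
- **Degenerate inputs** (zero-variance series, empty bands, <3 usable
  fit bins) return 0, never NaN, so the ensemble downstream is a total
  function. A constant epoch yields the all-zero vector.
- **Amplitude change** is the sliding-window max − min (a superset of
  the alternative reading max |x(t+50 ms) − x(t)|).
- **Windowed derivative sums** telescope to the net change across the
  window, so they are implemented as sliding |x(i+w−1) − x(i)| over the
  epoch's amplitude-power variance; the brute-force tests confirm the
  equivalence.
- **Periodogram**: whole-epoch, rectangular window, one-sided, with the
  FFT zero-padded 8×. The native resolution of a 1.5 s epoch is
  0.67 Hz, which cannot resolve the sub-0.5 Hz band at all; padding
  refines the grid to 0.083 Hz. The signal mean is removed before
  padding and its power restored at the DC bin, so a DC offset cannot
  leak into the low-frequency bins. Parseval's identity
  (∫PSD df = mean x²) holds exactly and is asserted to 1e−9.
- **Spectral fit** regresses log₁₀ power on log₁₀ frequency (the
  power-law form the λ literature uses; the alternative linear-in-log-f
  form appears to be a typesetting artefact in the source material) and
  reports the slope λ and residual RMSE per band. Bands are half-open
  [lo, hi); the broadband fit starts at 2 Hz, below which infant EEG
  departs from a power law.
- **Fractal dimensions** are estimated in 100 ms windows with 50 %
  overlap (our convention; no window scheme is prescribed), with
  Higuchi's k_max = 8 and Katz's waveform-length/diameter form; a flat
  window scores exactly 1 by both. The features are the Pearson
  kurtosis of the resulting FD series.
- **Haar kurtosis** uses a full-depth decomposition (all detail levels
  concatenated). The series is padded to the next power of two with
  its edge value rather than zeros: zero-padding would introduce a
  boundary step whose detail coefficients dominate the kurtosis of
  every epoch and would make even a constant epoch score heavy-tailed.

Scale invariances are asserted in the tests: multiplying an epoch by
c > 0 leaves local skewness, kurtosis, λ, Higuchi-FD kurtosis and Haar
kurtosis unchanged (rel. err < 1e−9), scales amplitude change by c and
the amplitude-power variance by c⁴. Katz FD is not exactly
scale-invariant (it mixes time and amplitude units), which is inherent
to the estimator.

## Consensus and weighting

The ground truth for an epoch is the modal rating of the panel; its
certainty weight is the agreeing fraction (with seven raters, 4/7 to
7/7). These weights become per-observation `sample_weight`s when
fitting the forest — no additional class weighting is applied, since
the certainty weight is the stated mechanism. Cohen's κ uses the
contingency formula with marginal chance agreement; the degenerate case
p_e = 1 is defined as 1 when observed agreement is perfect and 0
otherwise. Leave-one-rater-out consensus re-votes among the remaining
six raters; 3–3 ties are excluded from that rater's scoring rather than
broken (exclusion avoids fabricating a label the panel never produced).

## Classifier

`sklearn.ensemble.RandomForestClassifier`, single-threaded and seeded;
the posterior is the tree-mean artefact probability and an epoch is
called artefactual when the posterior is ≥ the threshold (≥, not >,
favouring sensitivity at the boundary). The default search grid is
n_trees {100, 300}, max_depth {None, 5, 10}, min_samples_leaf
{1, 5, 10, 20}, max_features {sqrt, all}; min-samples-per-leaf gets the
widest range because it is the hyperparameter whose tuning most visibly
moves performance in this regime. Grid search scores the
class-support-weighted F1 averaged over leave-one-subject-out folds and
breaks ties towards the simpler model (fewer trees, shallower, larger
leaf), so the winner is independent of enumeration order. McNemar's
test on paired predictions is exact binomial on the discordant pairs,
switching to the continuity-corrected χ² above 25 discordant pairs.
Models serialize to a versioned joblib container embedding the feature
manifest, config, seed and a training-set fingerprint; prediction on a
mismatched manifest is refused by name.

The grouped stratified split assigns whole infants to the test side by
a seeded greedy pass minimising the total absolute deviation of
per-(age-group, stimulus) test counts from the target fraction;
deviations forced by group structure are logged, not fatal.

## Synthetic data: what it emulates, what it does not

The generator is the package's stand-in for non-public infant
recordings, and its defaults are the study conditions the detector
assumes: fs = 2000 Hz, 1.5 s epochs with the event at +0.5 s, 1/f
background at 20 µV RMS, a Gaussian-windowed half-sine evoked
deflection (peak 30 µV, latency 0.4 s, width 0.2 s) for stimulus
epochs, and a 410-epoch registry over three age groups × seven stimulus
types with 160 infants and at most one epoch per (infant, stimulus).
Artefact prevalence defaults to 21 % of epochs, split across six
classes — movement burst, step, 50 Hz mains, spike (high-variance) and
detachment flatline, slow drift (low-variance); severities default to
overtly visible amplitudes (e.g. 20×RMS steps) and scale continuously
down to an identity at severity 0. Flatline is modelled as detachment
collapsing the whole epoch to a ~2 % residual plus sensor noise: a
flat segment covering only a third of the epoch cannot reduce the
whole-epoch power variance by the order of magnitude that
distinguishes the class.

Raters flip the ground truth independently with per-rater error rates;
the defaults (three expert raters at 7.5 % error, four experienced at
14.5 %) were set by inverting the closed-form independent-flip κ so
that within-tier agreement sits near the levels reported for real
expert (κ ≈ 0.6) and experienced (κ ≈ 0.4) raters of such data at 21 %
prevalence. The closed form — and hence the calibration test — is only
valid under this independence assumption; real raters' errors
correlate (they look at the same waveform), real artefacts form a
difficulty continuum rather than a clean/overt dichotomy, and real
neonatal EEG has microstructure (sleep states, trace alternant) the
generator does not attempt. Passing tests therefore demonstrate that
the machinery is correct and recovers planted structure, not that the
detector reaches any particular accuracy on real infant EEG — at
default severities the synthetic classes are near-separable and
held-out balanced accuracy saturates near 1.0, degrading monotonically
as severity shrinks.

One consequence worth noting: on synthetic data the mean SNR
(max |post-stimulus amplitude| / SD of baseline) of detector-accepted
heel-lance epochs is *lower* than that of all epochs, because
high-variance artefacts inflate the numerator. On real data artefact
corrupts the baseline too and rejection tends to raise SNR; the sign of
this quantity is a property of the generator's artefact mix, not of the
detector. The ERP magnitude convention is max absolute post-stimulus
amplitude (peak-to-peak available via an option).

## Problem sizes

The test suite runs the full pipeline at 200 training / 100 test epochs
(balanced clean/artefact), the oracle sweep over 50 random epochs, the
rater calibration at 2000 epochs, and the severity-degradation check at
100 epochs per seed over five seeds; `scripts/acceptance.py` runs the
410-epoch registry workflow with ~130-fold leave-one-subject-out
cross-validation. These sizes were chosen to exercise every code path
at comfortably interactive runtimes.

## Known limitations

- Single-channel by design: no montages, re-referencing or
  inter-channel features.
- Detect-and-reject only; no artefact correction (ICA/ASR removal).
- The EDF+ writer supports one EEG channel plus an annotation track and
  16-bit quantisation over a configurable physical range; it exists to
  export synthetic recordings, not as a general EDF library.
- Alternative classifier families (SVM, boosting) are not implemented;
  the McNemar comparison operation is provided so a user can run that
  comparison against any paired predictions.
- The univariate logit screen reports p = 0 with a logged flag under
  complete separation rather than a finite Wald p.
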