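# epochsift

Automated artefact detection for single-channel, 1.5 s neonatal ERP EEG
epochs.

Event-related-potential studies in neonates often record from one
channel (Cz), capture very short epochs (−0.5 s to +1 s around a
stimulus at 2 kHz), and obtain at most one trial per stimulus per
infant. Artefact rejection in this setting is usually done by expert
visual review — slow, subjective and hard to reproduce — while the
standard automated tools (ICA, ASR) need many channels or long
recordings and cannot be applied at all to a single 1.5 s trace.
`epochsift` implements an automated detector designed for exactly this
niche: it is aimed at researchers and trialists who need reproducible,
rater-like rejection decisions on short single-channel infant epochs.

## Method

Each epoch is summarised by a bank of 31 scalar features:

- **time domain** — maximum amplitude change over any 50 ms window;
  mean absolute local skewness over 15 ms segments; Pearson kurtosis of
  the voltage series; the variance of the point-wise power
  Var[x²(t)]; and the maximum absolute windowed sum of derivatives
  (windows of 50/100/200/300/500 ms), normalised by that variance;
- **frequency domain** — total power below 0.5 Hz; and, for each band
  (δ 0.2–3.5, θ 4–7.5, α 8–13, β 14–30, γ 30–70 Hz, plus the broadband
  spectrum above 2 Hz): the band power, the power-law slope λ of the
  least-squares fit log₁₀P = λ log₁₀f + C to the epoch periodogram, and
  the RMSE of that fit;
- **complexity** — the kurtosis of sliding-window fractal-dimension
  series (Higuchi and Katz estimators, 100 ms windows, 50 % overlap) and
  the kurtosis of the full-depth Haar wavelet detail coefficients.

Ground truth comes from a panel of binary raters: the consensus label
is the majority vote and each epoch carries a certainty weight — the
fraction of raters agreeing (between a 4/3 split, w = 4/7, and
unanimity, w = 1). A random forest is trained on the feature vectors
with these observation weights; its posterior

&nbsp;&nbsp;&nbsp;&nbsp;p(artefact | x) = mean over trees of the tree's class probability

estimates the probability that the rater panel would reject the epoch,
and the decision threshold (default 0.5) can be moved along the ROC
curve to trade sensitivity for specificity. Model selection uses
exhaustive grid search scored by class-support-weighted F1 under
leave-one-subject-out cross-validation — folds are grouped by infant so
no subject ever straddles train/validation. Evaluation reports
confusion metrics, balanced accuracy ((sensitivity + specificity)/2),
Cohen's κ against the consensus, ROC/AUC, permutation feature
importance and subgroup accuracies with bootstrap intervals; a model
can be scored exactly like a human rater via leave-one-rater-out
consensus.

Because the infant recordings such detectors are trained on are not
public, the package includes a first-class synthetic module that
generates 1/f background EEG with Gaussian-windowed evoked deflections,
six artefact classes (movement burst, step, mains breakthrough, spike,
detachment flatline, slow drift) and simulated rater panels with
per-rater error rates — every part of the pipeline is testable without
any download.

## Worked example

`examples/simulate_and_detect.py` generates a 105-epoch synthetic
registry (three age groups × seven stimulus types, 36 infants), has a
simulated seven-rater panel label it, trains the consensus-weighted
forest on one side of a grouped stratified split and scores the
held-out infants:

```
105 epochs, 28 rated artefact by the panel (27%)
held-out: sensitivity 1.00, specificity 1.00, balanced accuracy 1.00, AUC 1.00
```

At the generator's default severities the synthetic artefacts are
overt, so the held-out epochs separate perfectly; the sensitivity /
specificity trade-off becomes visible with milder artefacts, as in
`examples/threshold_tuning.py` (severity 0.25):

```
 threshold  sensitivity  specificity  rejected
      0.20         0.97         0.60        55
      0.35         0.97         0.88        44
      0.50         0.78         0.97        32
      0.65         0.65         1.00        26
      0.80         0.62         1.00        25

ROC AUC 0.97.
```

Raising the threshold rejects fewer epochs (higher specificity, lower
sensitivity); lowering it catches more artefact at the cost of
discarding clean data. The other examples tour the feature bank
(`feature_tour.py`), the EDF → filter → epoch chain
(`filter_and_epoch.py`) and the rater-agreement model
(`rater_agreement.py`).

A thin CLI mirrors the same stages for shell use:

```sh
epochsift simulate --n-infants 40 --seed 7 --out run/
epochsift extract-features run/epochs.csv --out run/features.csv
epochsift consensus run/raters.csv --out run/consensus.json
epochsift train run/features.csv run/consensus.json --out run/model.joblib
epochsift classify run/model.joblib run/features.csv --out run/pred.csv
epochsift evaluate run/pred.csv run/consensus.json --out run/report.json
```

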