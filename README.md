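# wavesleep

Automatic sleep-stage scoring from a **single channel of EEG**.

Overnight polysomnograms are scored by experts into 30-s epochs of wake
(W), three non-REM depths (N1, N2, N3) and REM (R).  `wavesleep`
automates this for single-channel EEG — the setting relevant to
wearable, at-home sleep monitoring — with three components:

1. **Time-frequency features.** Each epoch is described by 557 features
   built from complex Morlet wavelets: band-power at 22 peak
   frequencies chosen to track the stage-defining rhythms (slow waves,
   K-complexes, theta, alpha, spindles, beta, gamma), summarized over
   the whole epoch and over eleven 5-s sliding windows, plus the
   time-domain signal power, all pairwise Pearson correlations between
   band-power series, and the first 50 autocorrelation lags.  A Morlet
   wavelet at peak frequency *f* with *n* cycles has Gaussian envelope
   width σ = n/(2πf); few cycles favor temporal precision (transients),
   many cycles frequency precision (sustained rhythms).  Features from
   the two preceding and two succeeding epochs are stacked on, giving
   5 × 557 = 2785 inputs per epoch, which lets the classifier exploit
   stage-transition context without hand-written smoothing rules.

2. **A class-balanced ensemble of stacked sparse autoencoders (SSAEs).**
   Sleep data are heavily imbalanced (N2 abounds, N1 is rare), so each
   of the 20 ensemble members trains on a subsample holding, per
   recording, equally many epochs of every stage (the count of the
   rarest stage present).  Each member is a 2-layer sigmoid
   autoencoder stack pre-trained layer-wise with an L2-weight-decay
   (λ = 10⁻⁵) and KL-sparsity penalty (weight β = 2.0, target mean
   activation ρ = 0.2, 20 hidden units), then fine-tuned end-to-end
   with a softmax head; every phase runs L-BFGS for r = 60 iterations.
   Epochs are scored by the argmax of the members' mean class
   probabilities, optionally reweighted per stage.

3. **Class-balanced evaluation.** Metrics derive from the
   row-normalized confusion matrix M, scoring each stage one-vs-all
   against the *average* of the other stages: sensitivity sᵢ = Mᵢᵢ,
   false-positive mass fᵢ = mean over j ≠ i of Mⱼᵢ, precision
   pᵢ = sᵢ/(sᵢ+fᵢ), F1ᵢ = 2pᵢsᵢ/(pᵢ+sᵢ), per-stage accuracy
   (sᵢ+1−fᵢ)/2, overall accuracy = mean sᵢ.  Cross-validation is
   leave-one-subject-out; summaries come with percentile-bootstrap
   confidence intervals, and sleep-efficiency / transitional-epoch
   statistics support performance-vs-covariate regressions.

A synthetic-EEG generator produces stage-labelled recordings with
stage-typical spectra (alpha for W, theta for N1/R, spindles +
K-complexes for N2, >75 µV slow waves for N3) and Markov-chain
hypnograms, so the entire pipeline runs and is tested without any
external data.

## Worked example

Score the pooled cross-validation confusion counts of a 39-recording
overnight dataset (rows = expert, columns = algorithm, order
N1 N2 N3 R W):

```sh
$ cat counts.csv
1654,262,8,366,472
1270,13696,1231,760,621
7,469,4966,6,143
899,340,0,6164,308
441,34,23,138,2744
$ wavesleep metrics-from-counts counts.csv --text
stage      precision  sensitivity  specificity           f1     accuracy
N1             0.882        0.599        0.920        0.713        0.759
N2             0.930        0.779        0.942        0.848        0.860
N3             0.978        0.888        0.980        0.931        0.934
R              0.936        0.799        0.946        0.862        0.872
W              0.923        0.812        0.932        0.864        0.872
mean           0.930        0.775        0.944        0.844        0.860
overall accuracy: 0.775
```

Reading: N3 is the best-recognized stage (89% of N3 epochs correct),
N1 the hardest (60%); because every stage is weighted equally, the
overall accuracy (77.5%) is the mean per-stage sensitivity, and mean
F1 is 84% with the worst-stage F1 at 71%.

The full synthetic pipeline — simulate six subjects, extract features,
train the ensemble, LOSO-evaluate — in one command:

```sh
wavesleep evaluate --simulate --out-dir results/ --seed 0 --members 5 --iters 30
```

which writes `metrics.json` (pooled and per-recording-averaged reports,
bootstrap CI, per-recording sleep efficiency and transitional-epoch
percentages) and `pooled_confusion.csv`.  Individual steps are also
exposed: `simulate`, `extract`, `train`, `predict` (see `--help`).

## Layout

- `wavesleep.synthetic` — stage-typical synthetic EEG + Markov hypnograms
- `wavesleep.data_io` — EDF and hypnogram I/O, stage mapping (3/4 → N3,
  drop movement/unscored), in-bed segmentation
- `wavesleep.features` — Morlet band power, feature blocks, transforms,
  per-recording scaling, context stacking
- `wavesleep.ssae` — sparse-autoencoder objective/gradients, stacking,
  fine-tuning, prediction
- `wavesleep.ensemble` — class-balanced sampling, ensemble training and
  decision rule
- `wavesleep.evaluation` — LOSO CV, class-balanced metrics, bootstrap,
  sleep statistics
- `wavesleep.cli` — the `wavesleep` command

See `docs/methods.md` for modelling choices and limitations.
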