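# Methods

This note records the scientific and numerical choices behind
`wavesleep`, in the spirit of a model-description document: what is
computed, under which assumptions, and where the design was genuinely
open.

## Signal model and feature extraction

Scoring operates on one EEG channel sampled at 100 Hz (any integer rate
works; autocorrelation lags are always 50 *samples*, i.e. 0.5 s at
100 Hz), segmented into 30-s epochs indexed 0-based and half-open over
samples.

**Morlet band power.** For each band (peak frequency f, cycle count n)
the kernel is `exp(2πift)·exp(−t²/2σ²)` with σ = n/(2πf), truncated at
±4σ (>99.99% of the Gaussian mass) and normalized to unit energy
(Σ|w|²Δt = 1) so band powers are comparable across bands.  The
band-power series is the squared magnitude of the complex convolution.
Convolution runs once over the whole recording and is then segmented
into epochs: per-epoch convolution would create an edge artifact at
every epoch boundary, whereas this way only the recording's ends see
the (zero-padded) boundary.

**Band table.** 22 bands: slow (0.5, 0.7, 1, 1.5, 2 Hz; 3 cycles),
K-complex (2, 3.2 Hz; 3), delta/theta (3–6 Hz; 5), alpha (8, 10, 12 Hz;
10), spindle (12–15 Hz; 3), beta (16, 18 Hz; 3; 20 Hz; 5) and gamma
(40 Hz; 5).  The table is configurable (`label freq cycles` per line);
the feature count B + 11B + 1 + 11 + B(B−1)/2 + 50 holds for any B and
equals 557 at B = 22.

**Power summaries.** "Power" of a series over an interval is the mean
of its squared values.  Applied to the band-power series — itself a
squared magnitude — this makes band-power features scale as amplitude⁴
while signal-power features scale as amplitude²; both definitions are
defensible, so the plain-mean alternative (amplitude² scaling) is
available via `band_power_stat="mean"`.  The default follows the strict
reading of "power of the band-power signal".

**Degenerate values.** Pearson correlation of a zero-variance pair is
defined as 0 (the correlation block must stay bounded and finite, and
receives no transform); autocorrelation of an all-zero epoch is 0;
`log` transforms use a floor of 1e-12 to guard exact zeros from
synthetic inputs.  Negative powers raise — they indicate an upstream
bug, not data.

**Transform → scale → context.** Powers are log-transformed and
autocorrelations squared to roughly center their distributions for the
sigmoid units; then each feature is min-max mapped to [0, 1] separately
per recording (constant features map to 0.5, single-epoch recordings
are rejected).  The transform-then-scale order is a choice; the reverse
order would let the log floor dominate.  Context stacking concatenates
the features of epochs e−2…e+2; recording boundaries use replication
padding (keeps the design matrix rectangular without discarding
epochs), and context never crosses recordings.

## Classifier

Each member is a stack of 2 sigmoid sparse-autoencoder layers (depth is
configurable; the stack depth is not dictated by the method) with 20
units each, pre-trained greedily on unlabelled activations under the
objective

    (1/m) Σ ½‖x̂−x‖² + (λ/2)Σ W² + β Σⱼ KL(ρ ‖ ρ̂ⱼ),

λ = 10⁻⁵, β = 2.0, ρ = 0.2, with exact analytic gradients
(finite-difference-verified in the tests).  A softmax head is fitted on
the top activations and the whole network fine-tuned on softmax
cross-entropy plus the same weight decay — the standard supervised loss
for this construction, and it yields the calibrated probabilities the
ensemble mean needs.  Every phase (each layer, head, fine-tune) runs
L-BFGS for r = 60 iterations; we read the iteration budget as
per-phase.  The optimizer contract is: any quasi-Newton minimizer
honoring the cap and returning the best iterate seen.  Initialization
is uniform(−ε, ε) with ε = √(6/(fan_in+fan_out)), biases zero, fully
seeded; mean activations ρ̂ are clipped to [1e-8, 1−1e-8] inside the KL
term.

**Balanced sampling.** Per recording, m = the minimum epoch count over
the stages *present* there; m epochs per present stage are drawn
without replacement.  Generalizing from "the least-represented stage"
to "present stages" keeps the sampler well-defined on short or atypical
recordings; stages absent from a recording simply contribute nothing
from it.  Ensembles default to 20 members; member seeds derive from
(master seed, member index).

**Decision rule.** Mean of member probabilities, elementwise multiplied
by optional positive stage weights (all 1 by default), argmax; ties
break deterministically by canonical class order (N1, N2, N3, R, W).
Stage weights let a user bias scoring toward stages that matter for a
given application without retraining.

## Evaluation

Cross-validation is leave-one-subject-out: all recordings of one
subject form the test fold.  Two summary modes exist: pooling the
per-fold confusion counts before normalizing (used for headline
numbers — a summed cross-validation matrix), and averaging
per-recording metrics (used for bootstrap CIs and covariate
regressions).  For per-recording metrics, stages absent from that
recording are skipped.  The bootstrap is the percentile method over
recordings (B = 1000, 95% by default).  Sleep efficiency is the
percentage of non-W epochs within time in bed (lights-out through the
last non-W epoch; the data carry a lights-out marker but no lights-on).
A transitional epoch differs in stage from its previous or next epoch;
its percentage is taken over time in bed.  Performance-vs-covariate
tests use simple linear regression (R², two-sided slope p — identical
to the F-test in the simple case).  Printed-percentage comparisons
round half away from zero.

## Synthetic data

The generator emulates exactly what the feature extractor measures:
stage-typical spectral content.  Components are band-pass-filtered
white noise scaled to an RMS amplitude — filtered noise rather than
sinusoids so that correlation and autocorrelation features are
non-degenerate.  Defaults: W = alpha (10 Hz, 30 µV RMS) over mixed
activity; N1 = theta (5 Hz, 25 µV) with weak alpha; N2 = theta plus
spindles (13.5 Hz bursts, ~4 per epoch) and K-complexes (0.7-s biphasic
pulses, 80 µV, ~1.5 per epoch); N3 = 1 Hz slow waves at 80 µV RMS
(high-voltage, <2 Hz); R = theta with sawtooth-range (3 Hz) and faster
(20 Hz) admixtures.  Hypnograms come from a first-order Markov chain
starting in W with self-transitions near 0.8, which places the
transitional-epoch fraction in the 10–30% range of real nights.

What the generator does **not** emulate: artifacts and movement,
inter-subject variability, EOG/EMG leakage, non-stationarity within a
stage, scorer disagreement, and realistic stage-bout durations (the
Markov chain is memoryless).  Passing end-to-end tests therefore shows
the pipeline is correctly wired and can recover stages from spectral
structure — not that real-data accuracy would match; synthetic stages
are far more separable than real ones.

## Problem sizes and numerical choices

The end-to-end test suite uses 6 subjects × 120 epochs with 5-member
ensembles and r = 30, a scale at which LOSO completes in well under a
minute per seed while exercising every code path; the published-scale
configuration (20 members, r = 60, 39 overnight recordings) is the
default of the library and CLI.  EDF output quantizes to 16 bits over
the symmetric integer range just covering the signal (error ≤ half a
quantization step, verified round-trip against the `mne` reader).
Partial epochs at the end of a recording or annotation are dropped.

## Known limitations

* Real-data accuracy claims require the external overnight dataset and
  hours of training; they are out of scope for the test suite.
* Only single-channel EEG; no EOG/EMG features, which bounds
  performance on N1/R discrimination.
* No post-hoc hypnogram smoothing — transition context enters only
  through feature stacking, by design.
* The EDF writer emits minimal single-channel EDF (enough for
  round-tripping synthetic data), not full EDF+ with annotations.
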