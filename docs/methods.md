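# Methods

`eegconsensus` implements an analysis pipeline for decoding *action
concepts* from multi-subject EEG: hand-crafted spectral encodings of
62-channel epochs, per-subject classifiers, a subjects'-consensus ensemble,
EEG/video fusion baselines, and privileged-information distillation of the
EEG consensus into a video-only student.  The recordings such a study uses
are not publicly distributable, so the package ships a synthetic
multi-subject generator that reproduces the statistical structure the
analysis depends on; every stage is exercised end to end against it.

## The synthetic study

The default configuration mirrors a typical acquisition of this kind: 10
action classes, 24 video stimuli per class (240 total), 50 subjects each
responding to one disjoint half of the classes (so every stimulus is watched
by 25 subjects), one epoch per (subject, stimulus) pair, 62 channels x 3 s
at 250 Hz plus a 1 s pre-stimulus (inter-stimulus interval) segment.

Generative model, from concept to signal:

* **Class concepts.** Each class `k` has a latent vector `c_k` in R^16.
  Classes are drawn in correlated pairs (`class_correlation`, default 0.5):
  siblings share a group factor, so some actions are genuinely confusable.
  This matters for distillation: with mutually orthogonal class concepts the
  teacher's graded predictions carry no transferable structure beyond the
  hard label, and no distillation scheme can add information.
* **Stimuli.** Stimulus `j` of class `k` has latent
  `v_j = c_k + stimulus_noise_scale * noise` (default 1.2).  This noise is
  *shared by every viewer* of `j`: it models footage whose action is
  implicit or ambiguous, and no amount of subject averaging can remove it.
* **Subjects.** Subject `s` perceives through a fixed bias transform
  `B_s = I + subject_bias_scale * R_s` (default 1.0, `R_s` zero-mean).  The
  epoch latent is `u = B_s v_j + trial noise`, with trial noise scaled by
  `subject_bias_scale` as well (it models the subject's idiosyncratic
  per-trial response).  Zero-mean subject effects are the mechanism the
  consensus analysis exploits: averaging over n subjects shrinks them as
  1/sqrt(n).  Setting `subject_bias_scale = 0` removes every
  subject-varying corruption except white measurement noise, and the
  consensus curve flattens.
* **Signal synthesis.** Per-channel, per-band carrier amplitudes are an
  affine readout `A = a0 + G u` (a0 = 3, readout scale 0.45/sqrt(16); the
  offset keeps amplitudes positive).  The stimulus-on window is a sum of
  four band-limited sinusoids — one representative carrier per band: theta
  6 Hz, alpha 10 Hz, beta 22 Hz, gamma 45 Hz, configurable — weighted by
  those amplitudes, plus white noise at `eeg_noise_scale` (default 0.5;
  after band-pass filtering and 750-sample energy integration its effect on
  the features is small).  The pre-stimulus second contains noise only.
  Carrier phase is drawn per (stimulus, band) and shared across channels.
* **Video modality.** `video_features = V v_j + video_noise_scale * noise`
  with `video_dim = 1000` and noise 6.0 by default: a high-dimensional,
  heavily noised view of the same concept, emulating bag-of-words or CNN
  video descriptors.  The video modality is deliberately the weaker one —
  the premise of the whole design — and its dimensionality makes the
  video student variance-limited, which is the regime in which soft-label
  supervision is worth something.

All randomness flows from one seed through named `SeedSequence` streams
(concepts / stimuli / readout / subjects / trials / video), so a config
reproduces its dataset bit for bit, and changing only the video noise level
leaves the EEG side untouched.

What the generator does **not** model: 1/f background spectra, artifacts,
volume conduction, channel covariance, non-stationarity.  Passing tests
therefore demonstrate the *pipeline's* correctness and the *relative*
directions of its effects under the stated assumptions, not performance on
real recordings.

## Preprocessing and encodings

* **Normalisation** scales each channel's range linearly onto [-1, 1];
  constant channels map to zeros.  The pipeline normalises before band-pass
  filtering (the order is configurable).
* **Band tables.**  Two named tables are kept deliberately: the
  hand-crafted path uses theta 5-7, alpha 8-13, beta 14-30, gamma 31-60 Hz;
  the EEG-image path uses theta 4-7, alpha 8-13, beta 13-30 Hz.
* **Band-pass** is a zero-phase Butterworth (order 4, applied
  forward-backward); the contract is attenuation >= 20 dB one octave
  outside the passband, not a specific realisation.
* **FFT features** keep the magnitudes of DFT bins inside a band,
  concatenated channel-major; with N = 750 at 250 Hz, frequency f lands in
  bin 3f.  Magnitudes (not complex parts) feed downstream classifiers.
* **Differential entropy (DE)**: per channel and band,
  `h = 1/2 log(P) + 1/2 log(2 pi e / N)` in nats, with `P` the band-passed
  energy over the N-sample window — the Gaussian entropy closed form with
  variance estimated as P/N.  Zero band power raises an error naming the
  channels rather than emitting -inf.
* **Morlet wavelet power** uses cycle counts linear in frequency (3.5 at
  2 Hz to 18 at 60 Hz), temporal decimation by 3 before the transform,
  0.2 s zero-padding, and absolute baseline subtraction over [-900, -300] ms.
  Decimation bounds the analysable frequencies by the decimated Nyquist
  (~41.7 Hz), so the gamma band is covered only up to ~40 Hz on this path.
* **EEG images**: per-band channel powers (sum of squared in-band FFT
  magnitudes) are scattered at the azimuthal-equidistant projection of the
  electrode positions and interpolated onto a 32 x 32 mesh
  (Clough-Tocher piecewise cubic; 0 outside the electrode hull), stacked
  theta/alpha/beta as three planes.

## Classifiers and the consensus

The teacher is an MLP with one hidden layer of 248 rectified units and
dropout 0.5 on DE features (248 = 62 channels x 4 bands inputs), trained
per subject with Adam (lr 5e-3, full batch, up to 200 epochs, early
stopping on the validation split); a linear SVM (C = 1) is available as a
baseline.  Features are standardised with training-split statistics, per
subject.  Inference is deterministic; argmax ties break to the lowest class
index.

**Consensus** averages the per-subject logit vectors for a stimulus
arithmetically and applies a softmax (probability averaging is available as
a flag for comparison).  The accuracy-vs-subjects curve draws seeded random
subject subsets (20 resamples per point by default); the ROC analysis
reports per-class one-vs-rest AUC and the macro average.

**Cross-fitted teacher logits.**  Logits reported for training-split
stimuli come from 4-fold cross-fitting within each subject's training
epochs: a memorising network emits near-one-hot scores for its own training
data, which would strip the soft labels of the class-similarity information
distillation feeds on.  Validation- and test-split logits always come from
the full per-subject model.

## Distillation

Teacher soft labels are `s_i = softmax(mean-logits / T)`; the student
minimises `(1-lambda) CE(y_i, p_i) + lambda CE(s_i, p_i)` averaged over
training stimuli, where `p_i` is the student's softmax at temperature 1
(applying T to the student side as well is available behind a flag).  The
grid is T in {1, 2, 5, 10, 20, 50} x lambda in {0.25, 0.5, 0.75, 1.0},
5 runs per cell; the reported cell is selected on validation accuracy.
Students are a linear softmax model by default (an MLP is available),
trained for a fixed epoch budget with decoupled weight decay 1e-3 —
validation is reserved for cell selection and never drives student early
stopping, so the two uses of the split cannot feed each other.

## Fusion and protocol

Stimuli split 140-40-60 (train/validation/test), stratified by class with
largest-remainder allocation (per-class deviation from proportionality at
most one); epoch splits are induced by stimulus membership, so no stimulus
leaks.  Kernel fusion standardises each modality block with training
statistics, averages the per-block linear Gram matrices and trains an SVM on
the fused kernel (averaging linear Grams equals the half-scaled
concatenation kernel).  Logit fusion averages two models' logits
elementwise.  The fusion study pairs each stimulus's subject-averaged DE
vector with its video features; the complementary-noise condition evaluated
in the acceptance runs sets `video_noise_scale = 4.0` so the two modalities
are of comparable strength — with the default video noise the EEG modality
dominates and plain logit averaging tracks it rather than improving on it.

## Problem sizes and numerical choices

The acceptance computations run the full default study (6000 epochs of
62 x 1000 samples) for five generator seeds; directional claims
(consensus gain, AUC gain, distillation gain, fusion margins) are asserted
on means over those five replications, which is the scale at which the
per-seed fluctuation of a few percentage points averages out.  The
consensus and AUC gains are large relative to that fluctuation (about +6
and +5 to +7 points respectively, every replication); the distillation gain
is small — a couple of points, comparable to run-to-run noise — which is
consistent with the modest gains this kind of privileged-information
transfer yields in general.  A teacher variant scoring each training
stimulus with the other subjects' full models was evaluated and rejected:
although more accurate, its nearly one-hot soft labels embed per-instance
EEG noise in their small non-target masses, and the high-dimensional
student overfits exactly that.  Epoch signals
are synthesised and stored in float32; feature extraction filters stacked
epochs in chunks of 40 to bound memory.  Filter edge effects are avoided in
tests by measuring away from window boundaries; DE error flags, empty-band
errors and constant-channel conventions are covered by unit tests.

Known limitations: no real-data reader beyond the optional recording-chain
helpers (downsample / notch / baseline); the wavelet path computes total
("mixed") power only; per-subject classifiers see only that subject's five
classes, as in the emulated design, so their logits for never-seen classes
are uninformative (the consensus still ranks all ten because every stimulus
is scored by the half of the subjects that trained on its class).
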