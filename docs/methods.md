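# Methods

## Problem setting

Motor-imagery (MI) brain–computer interfaces decode which movement a
user imagines from multi-channel EEG. The physiological signal is
event-related desynchronization (ERD): imagining a movement attenuates
mu-band (8–12 Hz) and beta-band power over the corresponding
sensorimotor area. Decoders must cope with single-trial noise and with
distribution shift between recording sessions.

The decoder implemented here combines three ideas:

1. a **multi-scale CNN front-end** (three parallel temporal filter banks
   with short/medium/long kernels, a depthwise spatial convolution over
   the electrode axis, two average-pooling stages with a depthwise
   temporal refinement convolution between them, and a 1×1 fusion),
2. a **local–global attention encoder** whose keys come from either a
   plain linear projection (global path) or two short 1-D convolutions
   along the sequence (local path), fused by element-wise addition, and
3. **group-rational Kolmogorov–Arnold (GR-KAN) layers** replacing both
   the MLP sublayers of the encoder and the classifier head.

## GR-KAN layers

A GR-KAN layer applies a learnable rational ("safe Padé") activation

φ(x) = w · P(x) / (1 + |Q(x)|),  P of degree m = 5, Q of degree n = 4
with no constant term,

elementwise to its input and then mixes with a dense linear map. The
input's `din` dimensions are split into `g` contiguous groups of width
`din/g`; all dimensions of a group share one rational function. The
denominator is structurally ≥ 1, so the activation has no poles. The
learnable count is exactly `dout·din + dout·[bias] + g·(m+1+n)`; the
scale w is kept as a fixed per-group buffer because it is redundant with
the numerator coefficients (w·P reparameterizes P).

**Initialization.** The rational coefficients start from a least-squares
fit of the safe Padé form to SiLU on [−3, 3] (max fit error ≈ 1.1e−6;
constants frozen in `grkan.py`), so training starts from a known-good
activation shape. Mixing weights follow a variance-preserving rule: the
second moment E[F(x)²] of each group's activation is estimated by Monte
Carlo under x ~ N(0, 1) (100 000 samples by default, giving well under
1% relative error for smooth activations) and weights are drawn i.i.d.
from N(0, 1/(din·E[F(x)²])). This is the unique i.i.d. scaling for which
Var[output] = Var[input] on independent standard-normal inputs. The
printed formula for this initialization in the source literature is
typographically garbled; the implementation follows the stated goal
(variance preservation), which pins the formula down uniquely. Groups
may in principle have different gains, so the weight std is applied per
column group; the recorded `InitGain` stores the across-group mean.

## Front-end details and defaults

| name | default | meaning |
|------|---------|---------|
| F1 | 8 | temporal filters per branch |
| D | 2 | depth multiplier of the spatial convolution |
| K1 | (32, 64, 96) | kernel triple, 4-class preset; (16, 32, 64) for the binary preset |
| P1, P2 | 8, 8 | average-pooling sizes |
| K2 | 16 | depthwise temporal refinement kernel |
| E | 16 | post-fusion embedding width (= F1·D) |
| dropout | 0.25 | after each pooling stage |

Temporal convolutions use "same" zero padding; pooling windows are
non-overlapping with floor division, so the sequence length is
L = ⌊⌊T/P1⌋/P2⌋ (15 for T = 1000) regardless of data values. Batch
normalization + ELU follow each convolution stage, the standard
convention in this family of EEG decoders; convolutions are bias-free
since the following normalization absorbs offsets. The refinement
convolution is depthwise (one kernel per feature map); a full
convolution would also be defensible, but depthwise keeps the stage a
pure temporal smoother.

Because the temporal filter bank and the depthwise spatial convolution
are linear maps along different axes, they commute; the implementation
applies the spatial mix first, which shrinks the array the FFT-based
temporal convolution touches (electrode axis collapsed before
filtering) at bit-identical output semantics. The unit tests check the
FFT convolutions against direct sliding-window oracles.

## Encoder details

- Heads h = 4, head width E/h = 4.
- Local-key kernels (3, 5), each branch emitting E/2 channels so the
  concatenation preserves width E and needs no extra projection. The
  value path is not convolved — only the keys are enriched.
- Attention projections are bias-free, so both attention paths are
  exactly linear in the value matrix; the two per-head outputs are
  summed and pass through a single output projection.
- Channel mixer: two GR-KAN layers forming an expansion/projection pair
  E → 4E → E (expansion ratio 4), group count 8.
- Sinusoidal positional encoding is added once before the first layer.
- Residuals use pre-norm ordering by default (post-norm is available via
  a flag); pre-norm trains stably at the depth-5 binary preset.
- Encoder depth: 1 layer for the 4-class preset, 5 for the binary preset.
- Dropout 0.5 on attention output and mixer output.

**Input standardization.** Each trial is z-scored per channel before the
front-end (flag `standardize_input`, on by default). Cross-session drift
in electrode impedance and amplifier gain appears as per-channel
multiplicative and additive offsets; trial-wise standardization cancels
both exactly while preserving within-channel spectral structure (the
class signal is the *fraction* of variance in the mu band, which
standardization leaves intact). Without it, the decoder was measurably
sensitive to the generator's session-shift perturbation — within-session
test accuracy was near-perfect while shifted-session accuracy dropped —
which is precisely the failure mode this step is standard practice
against in EEG decoding pipelines.

The classifier head is a single GR-KAN layer (activation first, then
linear) from the flattened L·E fused features to the N class logits,
with 8 groups. Softmax lives inside the cross-entropy loss; the model
returns raw logits.

## Training protocol

Adam with fixed learning rate 0.001, β1 = 0.5, β2 = 0.999; batch size
72; cross-entropy loss; no schedule, weight decay, early stopping, or
validation-based model selection (final-epoch weights are used). The
reference epoch budget is 2000; desk-scale runs in the test suite and
acceptance script use up to 200 epochs, which suffices on the bundled
synthetic task. Slice-and-recombine augmentation is on by default: each
epoch, one fresh synthetic copy of the training set is generated with a
per-epoch seed (trials cut into 8 chronological segments; each segment
slot filled from a random same-class donor, with replacement) and
concatenated to the real batch stream. Training runs in float32 by
default for speed; the numerical contracts in the test suite run the
engine in float64.

## Numerical engine

No deep-learning framework is used: the network runs on a small
reverse-mode autodiff engine over numpy arrays written for this package
(`autodiff.py`, ~20 operations). Temporal convolutions are computed by
real FFTs (correlation via the convolution theorem), which on CPU is far
cheaper than explicit sliding windows for 32–96-tap kernels on
1000-sample trials; their gradients are likewise FFT-based and verified
against central differences. Softmax uses the max-subtraction trick with
an analytic Jacobian-vector product; the loss uses log-sum-exp.

## Synthetic data generator

Each trial is broadband Gaussian noise (σ = 1 per sample) plus
unit-variance band-limited mu (8–12 Hz) and beta (18–26 Hz) processes
per channel (white noise through a zero-phase 4th-order Butterworth
band-pass, rescaled). Class k multiplies the mu-band *amplitude* on its
designated channels by √(1 − erd_depth) (so power drops by `erd_depth`,
0.5 by default). Designated channels are contiguous blocks: class k owns
channels [k·C/N, (k+1)·C/N). The test split models a later session:
per-channel gains 1 + 0.1·z and offsets 0.1·z′ drawn once per split.
Rhythm amplitude 1.0 relative to noise σ = 1 makes single-trial mu power
on a designated block differ by roughly a factor 2 between its own class
and the others — large enough that band-power logistic regression
separates the classes, which is what real ERD looks like on good
subjects and what makes the task a meaningful end-to-end check.

What the generator does **not** emulate: volume conduction and realistic
spatial mixing (channels are independent), 1/f background spectra,
artifacts (EOG/EMG), inter-trial nonstationarity beyond the session
shift, and subject variability. Passing the end-to-end test therefore
shows that the architecture, gradients, and training loop can extract
class-dependent band-power structure under session shift — not that the
model reaches any particular accuracy on real recordings.

## Problem sizes used by the automated checks

The end-to-end check trains the 4-class preset (22 channels, 1000
samples) on 200 synthetic trials for 200 epochs with augmentation and
evaluates on 100 shifted-session trials; a null configuration
(erd_depth = 0, session shift 0) is trained briefly to confirm
chance-level behavior. The kernel-ablation comparison pits the
three-branch multi-scale front-end against a single-scale variant —
one branch with one kernel (64), the closest analogue of removing the
multi-scale structure — on the same generated task over 3 training
seeds at a shortened budget (80 epochs in the test suite, 60 in the
acceptance script), sizes chosen so the whole suite runs comfortably on
one CPU while leaving the qualitative comparison intact. At full
convergence (200 epochs) the same comparison was measured during
development at mean 90.3% (multi-scale) vs 87.3% (single-branch) over
three seeds.

## Known limitations

- The GDF ingestion path applies a light 0.5–100 Hz band-pass and 50 Hz
  notch (zero-phase 4th-order IIR) before epoching; competition files
  are already hardware-filtered, so this is a touch-up, and the path is
  exercised only on synthetic in-memory recordings in the tests.
- Whether positional encoding belongs in this architecture at all is
  ambiguous in the source description; it is included (and removable by
  setting encoder depth 0 plus reading the embedded features directly).
- The per-position channel mixer treats sequence positions
  independently by construction; no cross-position mixing happens
  outside attention.
- Training at float32 with FFT convolutions is deterministic for a
  fixed seed on a fixed BLAS/FFT build, but bit-level reproducibility
  across different numpy/scipy builds is not guaranteed.
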