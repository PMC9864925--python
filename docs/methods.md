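# Methods

## Scope and intent

`dmflsim` is a deterministic, single-process simulator of a
communication-efficient federated-learning (FL) protocol — conditional
client upload plus deadline-based client selection over FedAvg — for
multi-class image classification. It replaces three things that made the
original setting GPU- and network-bound with desk-scale counterparts:

* real multi-source chest-X-ray corpora → a synthetic class-templated image
  generator with the same bookkeeping structure (6 imbalanced classes,
  SMOTE balancing, 80/10/10 stratified split, per-client partitions);
* large CNN backbones → a linear-softmax model and a small NumPy CNN, with
  "sized" registry entries that pad the parameter vector so communication
  accounting can reflect larger backbones;
* wall-clock training and network transfer → a simulated clock
  (deterministic per-epoch times with seeded jitter) and a byte/bandwidth
  ledger.

The protocol logic itself — the upload decision, the waiting-time rule,
straggler exclusion, weighted aggregation, global assessment and dispatch —
is implemented in full.

## The protocol

Per global round *i*, every client:

1. loads the dispatched global parameter vector (always — never its own
   previous local state),
2. runs E epochs of mini-batch SGD on its local training split, minimising
   the multi-class cross-entropy `C_LOSS(W) = -(1/|D|) Σ_X Σ_a B_{X,a} log
   Q_{X,a}` with the plain update `W ← W - a ∇C_LOSS(W)` (no momentum, no
   weight decay: the update rule is the protocol's contract),
3. measures its validation accuracy `A_ACC` and reports its simulated
   training time `T_TIME`,
4. uploads its parameters only if `A_ACC` strictly exceeds its running best
   `A_MAX` (which is then raised to `A_ACC`); ties skip.

The server sets the round deadline to the arithmetic mean of the previous
round's reported training times (round 1 uses a configurable initial waiting
time; a slack multiplier, default 1.0, is available). Messages arriving
after the deadline are `timed_out` and excluded from aggregation; on-time
messages without payload are `skipped`. Arrival time equals training time —
serialization/transfer latency is accounted in the communication ledger, not
in deadline comparisons, since the deadline rule is defined on training
times. Accepted updates are combined by FedAvg weighted by client
training-set size (uniform weights available). An empty round keeps the
global parameters and logs the event rather than deadlocking. The
aggregated model is scored on a held-out server test set and dispatched to
*all* clients, including stragglers and skippers.

`default_fl` mode is the baseline: synchronous FedAvg where every client
uploads every round and every arrival is accepted. The two modes share every
random stream (data generation, initialization, batch order, clock jitter),
so they differ only at the decision points; with `force_upload=True` and the
deadline slack set very large, a dmfl run is bit-identical to its default_fl
twin — the central correctness oracle of the test suite.

### Decision conventions

Points the protocol statement leaves open, resolved here as package policy:

* `A_MAX` is **per-client**, the running maximum of that client's own
  validation accuracy, initialized to 0 (so round 1 uploads unless accuracy
  is exactly 0). Validation — not training — accuracy is used to avoid
  overfitting inflation.
* The deadline is **global** (one `W_TIME` per round from all reported
  times), not per-client; arrival exactly at the deadline is accepted (≤).
* Skipping and timed-out clients still report training times, and those
  times enter the next round's mean.
* The communication ledger counts every payload actually sent, including a
  straggler's (it consumed bandwidth even though the aggregate ignored it);
  round records track acceptance separately.
* In forced-upload mode `A_MAX` updates as `max(A_MAX, A_ACC)`, preserving
  monotonicity; under normal operation uploads only happen on strict
  improvement, where the two rules coincide.

## Synthetic data generator

Class k of K is a Gaussian blob whose centre moves around a ring and whose
width cycles through three scales — classes differ in blob location and
extent. A sample is `clip(0.25 + separability·σ·template_k + ε, 0, 1)` with
i.i.d. pixel noise `ε ~ N(0, σ²)`, `σ = 0.15`. `separability` is therefore a
signal-to-noise ratio: at 0 all classes share one distribution (a 1-NN
classifier sits at chance — property-tested against the binomial null), at
3–5 classes are cleanly separable. Default image size is 32×32 (configurable;
the full-scale corpus bookkeeping is validated at 8×8, since per-class counts
do not depend on pixel dimensions).

What the generator does **not** emulate: anatomical structure, acquisition
variation between hospitals, label noise, or feature-level covariate shift
between clients. Passing tests show the protocol machinery is correct and
communication-efficient on separable data; they say nothing about diagnostic
accuracy on real radiographs.

The default per-class counts mirror an imbalanced 6-class corpus
(3301/5000/700/2793/3867/1349); SMOTE balances every class to a common
target (7000 at full scale). Protocol scenarios use balanced per-class
counts, since the protocol trains on the balanced corpus.

## SMOTE

On flattened pixel vectors with the Euclidean metric: a synthetic sample is
`x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`, `x_nn` among the k = 5 nearest
same-class neighbours (the canonical SMOTE default), clipped to [0, 1].
Originals are preserved unchanged and synthetic samples are flagged
`synthetic_smote`. The geometric contract — every synthetic point lies on a
segment between two original same-class points within 1e−6 — is verified by
exhaustive search at test scale. A class with a single sample is an error
(no neighbour to interpolate toward).

## Splitting and partitioning

Stratified splits allocate `floor(fraction·n)` per class to validation and
test, remainder to train — so 7000 per class at 0.8/0.1/0.1 gives exactly
5600/700/700. A nonzero fraction that would receive zero samples for some
class is an error in the public splitter; inside client partitions a lenient
variant applies (tiny classes stay in train) so that heavily skewed
(Dirichlet-partitioned) clients remain constructible. Client partitioning is
IID (uniform without replacement) or non-IID via symmetric Dirichlet class
proportions with configurable concentration (smaller = more skewed).

## Models and numerics

* **linear** — softmax regression on flattened pixels. Also serves, at 3×3
  input and 5 classes, as the 50-parameter model for exhaustive
  finite-difference gradient checks.
* **small-cnn** — conv(4@3×3)/ReLU/maxpool2 → conv(8@3×3)/ReLU/maxpool2 →
  dense 64/ReLU → softmax head; 19,222 parameters at 32×32 with 6 classes.
  Forward and backward passes are NumPy (im2col convolutions); analytic
  gradients agree with central finite differences to better than 1e−6
  relative error in the shipped tests.
* **vgg16-sized / vgg19-sized / densenet169-sized** — the small CNN with
  the parameter vector zero-padded to 138k/144k/172k entries (inert padding,
  zero gradient). They exist solely so upload-size accounting preserves the
  size ordering the communication comparisons assume.

Probabilities are clipped to [1e−12, 1] before logs. Parameter vectors are
float64; serialization is little-endian (magic, architecture id, dimension,
payload, CRC32 trailer), so upload size is `18 + len(id) + 8d` bytes and a
corrupted payload raises. Weight init is Gaussian (He-scaled for the CNN,
0.01 for linear), biases zero; zero parameters give the uniform predictor
with loss exactly ln K.

Default hyperparameters: learning rate 0.1, batch 16, 1 epoch/round for
scenario runs — standard plain-SGD values for normalized inputs at these
data sizes. All randomness flows from one master seed through named child
seeds (`numpy.random.SeedSequence`), making whole runs byte-reproducible and
the two protocol modes stream-aligned.

## Simulated time and communication

Per-round training time is `E · base_seconds_per_epoch · (1 + jitter)`,
jitter uniform in ±`jitter_fraction`, seeded per client and round; jitter 0
makes deadline behaviour exactly predictable for tests. Upload seconds are
`bytes / bandwidth` at a configurable link rate (default 12 MB/s). Absolute
wall-clock minutes of any real deployment are out of scope; only simulated
quantities are reported.

## Problem sizes used in shipped checks

Chosen as desk-scale defaults: corpus bookkeeping runs at the full printed
counts (17,010 raw → 42,000 balanced) with 8×8 images; protocol scenarios
use the smallest experimental group scaled 1:10 (clients 50/100/200,
20 rounds, small CNN, separability 4.0); communication-dominance sweeps use
20 seeded 3-client, 5-round linear-model scenarios plus one 100-round pair.

## Known limitations

* The baseline ("default FL") is synchronous FedAvg with universal upload —
  the natural reading, but other baselines (async, partial participation)
  are not modelled.
* Per-client deadlines (each client judged against its own history) are a
  plausible alternative reading of the waiting-time rule; only the
  global-mean deadline is implemented.
* No real networking, encryption, or multi-process execution; the transport
  is an in-process message list under a simulated clock.
* Training-set-size FedAvg weights assume honest size reports; there is no
  robustness or poisoning model.
* The accuracy levels reached on synthetic data do not transfer to real
  medical imagery; only relative protocol behaviour (uploads saved, rounds
  to converge, straggler handling) is meaningful.
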