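# dmflsim

A desk-scale, fully deterministic simulator for **decision-making federated
learning (DMFL)** — a communication-efficient federated-learning protocol for
multi-class medical-image classification — together with the synchronous
FedAvg baseline it is compared against.

## Who this is for

Researchers and students studying communication efficiency in federated
learning (FL) who want to experiment with conditional-upload and
deadline-based client-selection rules without GPUs, real chest-X-ray
repositories, or networked deployments. Everything runs on one CPU in
seconds to minutes, and every run is reproducible bit-for-bit from its
configuration and seed.

## The protocol

In FL, clients train a shared model on local data and exchange only
parameters with a central server, which aggregates them by federated
averaging (FedAvg): the global parameter vector is the sample-count-weighted
mean of the client vectors. Each client minimises the multi-class
cross-entropy loss

$$C_\mathrm{LOSS}(W) = -\frac{1}{|D|}\sum_{X \in D}\sum_{a=1}^{K} B_{X,a}\,\log Q_{X,a}$$

over its local training set $D$ ($B$ one-hot true labels, $Q$ predicted
class probabilities) by plain mini-batch gradient descent,
$W_{i,j+1} = W_{i,j} - a\,\nabla C_\mathrm{LOSS}(W_{i,j})$, where $i$ indexes
global rounds, $j$ local steps and $a$ is the learning rate.

DMFL adds two decision points on top of synchronous FedAvg:

1. **Client participation** — after local training, a client uploads its
   parameters only if the new local validation accuracy $A_\mathrm{ACC}$
   *strictly* exceeds its running best $A_\mathrm{MAX}$; otherwise it asks to
   skip the round (and sends only its training time).
2. **Client selection** — the server sets each round's waiting time
   $W_\mathrm{TIME}$ to the arithmetic mean of the previous round's reported
   training times; a straggler whose update arrives later is excluded from
   that round's aggregate (but still receives the new global model).

A communication ledger counts every upload, its bytes and its simulated
transfer time at a fixed link rate (default 12 MB/s), so matched DMFL vs
default-FL runs quantify the communication saved.

Because the real protocol ran on imbalanced multi-source chest-X-ray
corpora, the package ships a synthetic generator emulating a 6-class
imbalanced image corpus (class-specific blob templates plus noise, with a
separability knob), SMOTE oversampling to balance classes, stratified
80/10/10 splitting, and IID or Dirichlet-skewed client partitioning.

## Worked example

```python
import dataclasses
from dmflsim import compare_runs, run_federated_job, benchmark_scenario

cfg = benchmark_scenario(scale=0.1, mode="dmfl", rounds=20, seed=1, separability=4.0)
dmfl = run_federated_job(cfg)
default = run_federated_job(dataclasses.replace(cfg, mode="default_fl"))
c = compare_runs(dmfl, default)
print(f"final accuracy: dmfl={c.final_accuracy_dmfl:.3f} default={c.final_accuracy_default:.3f}")
print(f"uploads:        dmfl={c.dmfl_upload_count} default={c.default_upload_count}")
```

prints

```
final accuracy: dmfl=1.000 default=1.000
uploads:        dmfl=8 default=60
```

Three clients holding 50/100/200 well-separated 6-class images both reach
the same test accuracy after 20 rounds, but the decision-making protocol
uploads parameters only 8 times against the baseline's 60 (3 clients × 20
rounds): once clients stop improving on their own validation data, they stop
uploading. More examples live in `examples/` (dataset generation, SMOTE
balancing and splitting, a single client's round, the metric formulas, and
the full comparison).

A thin CLI wraps the same functions:

```bash
dmflsim simulate --mode dmfl --rounds 20 --seed 1 --out run_dmfl
dmflsim simulate --mode default_fl --rounds 20 --seed 1 --out run_def
dmflsim compare run_dmfl run_def
dmflsim report run_dmfl          # accuracy and upload curves as PNG
dmflsim make-data --out imgs     # synthetic corpus as per-class PNG folders
```

## Metrics

Model quality is reported from the K×K confusion matrix, reduced
one-vs-rest per class: ACC = (TP+TN)/(TP+TN+FP+FN), PRE = TP/(TP+FP),
REC = TP/(TP+FN), SPF = TN/(TN+FP), F1 = 2·PRE·REC/(PRE+REC), macro-averaged
by default; the plain overall accuracy (trace/total) is reported alongside
the macro one-vs-rest accuracy since both readings are common.

See `docs/methods.md` for the full model description, defaults, numerical
choices and limitations.
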