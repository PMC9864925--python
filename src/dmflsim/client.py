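"""Client-side process of the federated protocol.

Each round a client (1) loads the dispatched global parameters, (2) trains
locally for E epochs of mini-batch SGD on its own training subset, (3)
evaluates the new local model on its validation subset, and (4) decides
whether to upload: the update is sent only when the new local accuracy
A_ACC strictly exceeds the client's running best A_MAX (client-participation
decision).  The report message always carries the simulated training time;
the parameter payload travels only on upload.  No raw sample ever leaves
the client.

Wall-clock training time is replaced by a deterministic simulated clock
(per-round time = E * base_seconds_per_epoch * (1 + jitter)) so that the
server's deadline-based client selection can be exercised reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_rng
from .data import ClientPartition, LabeledDataset
from .models import (
    ClassifierModel,
    HyperParams,
    ParameterVector,
    accuracy,
    loss_gradient,
    model_size_bytes,
    serialize_parameters,
    sgd_step,
)

__all__ = [
    "TrainingClock",
    "ClientState",
    "LocalTrainingResult",
    "ClientRoundMessage",
    "local_train",
    "decide_upload",
    "submit_report",
]


@dataclass(frozen=True)
class TrainingClock:
    """Deterministic stand-in for measured wall-clock training time."""

    base_seconds_per_epoch: float = 60.0
    jitter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_seconds_per_epoch <= 0:
            raise ValueError("base_seconds_per_epoch must be positive")
        if not 0 <= self.jitter_fraction < 1:
            raise ValueError("jitter_fraction must lie in [0, 1)")

    def training_time(self, epochs: int, round_index: int) -> float:
        """Simulated seconds for ``epochs`` epochs in a given round."""
        if epochs == 0:
            return 0.0
        rng = child_rng(self.seed, "clock", round_index)
        jitter = rng.uniform(-self.jitter_fraction, self.jitter_fraction)
        return epochs * self.base_seconds_per_epoch * (1.0 + jitter)


@dataclass
class ClientState:
    """Everything one client carries across rounds."""

    client_id: str
    partition: ClientPartition
    hyperparams: HyperParams
    clock: TrainingClock
    architecture_id: str
    seed: int = 0
    best_accuracy: float = 0.0  # A_MAX: running max of own validation accuracy

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_accuracy <= 1.0:
            raise ValueError("best_accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class LocalTrainingResult:
    trained_params: ParameterVector
    training_time: float  # T_TIME, simulated seconds
    local_accuracy: float  # A_ACC, on the client's validation subset
    epochs_completed: int

    def __post_init__(self) -> None:
        if self.training_time < 0:
            raise ValueError("training time must be nonnegative")
        if not 0.0 <= self.local_accuracy <= 1.0:
            raise ValueError("local accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class ClientRoundMessage:
    """What a client sends the server after a round of local training.

    The envelope always carries identity, the simulated training time (which
    is also the message arrival time — training dominates the round) and both
    accuracy figures; the serialized parameter payload is attached only on
    upload.
    """

    client_id: str
    round_index: int
    training_time: float
    local_accuracy: float
    best_accuracy: float
    arrival_time: float
    payload: bytes | None = None
    train_size: int = 0

    @property
    def payload_bytes(self) -> int:
        return len(self.payload) if self.payload is not None else 0

    @property
    def uploaded(self) -> bool:
        return self.payload is not None


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def local_train(
    state: ClientState, global_params: ParameterVector, round_index: int
) -> LocalTrainingResult:
    """E epochs of mini-batch SGD from the dispatched global parameters.

    The global parameters are always the starting point (never the client's
    previous local state).  Deterministic given (state, global_params,
    round_index).
    """
    if global_params.architecture_id != state.architecture_id:
        raise ValueError(
            f"global parameters are for architecture {global_params.architecture_id!r}, "
            f"client {state.client_id} expects {state.architecture_id!r}"
        )
    train = state.partition.train
    if len(train) == 0:
        raise ValueError(f"client {state.client_id} has an empty training subset")
    hp = state.hyperparams
    from .models import get_architecture

    sample_shape = train.samples[0].pixels.shape
    arch = get_architecture(state.architecture_id, sample_shape, train.num_classes)
    model = ClassifierModel(arch, global_params)

    params = global_params
    if hp.epochs > 0:
        rng = child_rng(state.seed, "train", round_index)
        for _ in range(hp.epochs):
            for batch_idx in _minibatches(len(train), hp.batch_size, rng):
                batch = train.subset([int(i) for i in batch_idx])
                grad = loss_gradient(model.with_parameters(params), batch)
                params = sgd_step(params, grad, hp.learning_rate)
    eval_set = state.partition.validation if len(state.partition.validation) else train
    acc = accuracy(model.with_parameters(params), eval_set)
    return LocalTrainingResult(
        trained_params=params,
        training_time=state.clock.training_time(hp.epochs, round_index),
        local_accuracy=acc,
        epochs_completed=hp.epochs,
    )


def decide_upload(local_accuracy: float, best_accuracy: float) -> str:
    """Client-participation rule: upload iff A_ACC strictly exceeds A_MAX."""
    if not (0.0 <= local_accuracy <= 1.0 and 0.0 <= best_accuracy <= 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    return "upload" if local_accuracy > best_accuracy else "skip"


def submit_report(
    state: ClientState,
    result: LocalTrainingResult,
    decision: str,
    round_index: int,
) -> ClientRoundMessage:
    """Build the round message and apply the A_MAX update.

    On upload, A_MAX is raised to A_ACC (the rule only uploads on strict
    improvement, so this is the running maximum); on skip it is unchanged.
    """
    if decision not in ("upload", "skip"):
        raise ValueError(f"decision must be 'upload' or 'skip', got {decision!r}")
    payload = None
    if decision == "upload":
        payload = serialize_parameters(result.trained_params)
        state.best_accuracy = max(state.best_accuracy, result.local_accuracy)
    return ClientRoundMessage(
        client_id=state.client_id,
        round_index=round_index,
        training_time=result.training_time,
        local_accuracy=result.local_accuracy,
        best_accuracy=state.best_accuracy,
        arrival_time=result.training_time,
        payload=payload,
        train_size=len(state.partition.train),
    )
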