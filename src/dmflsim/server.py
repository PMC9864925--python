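"""Server-side process of the federated protocol.

The server schedules each round's deadline (waiting time) as the arithmetic
mean of the previous round's reported client training times — the
client-selection decision: a client whose message arrives after the deadline
is a straggler and is excluded from that round's aggregate.  Received updates
are combined by federated averaging (weights proportional to client
training-set size), the aggregated global model is assessed on a held-out
server test set, and the new global parameters are dispatched to every
client, including the skipped and timed-out ones.  A communication ledger
accumulates upload counts, bytes and simulated transfer seconds at a fixed
link rate (default 12 MB/s).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .client import ClientRoundMessage
from .data import LabeledDataset
from .metrics import compute_metrics, confusion_matrix
from .models import (
    ClassifierModel,
    HyperParams,
    ParameterVector,
    get_architecture,
    predict_labels,
)

__all__ = [
    "JobSpec",
    "ServerState",
    "RoundRecord",
    "CommLedger",
    "compute_waiting_time",
    "collect_round",
    "fedavg_aggregate",
    "assess_and_dispatch",
    "record_upload",
]

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 12_000_000.0  # bytes/second: the 12 MB/s link rate


@dataclass(frozen=True)
class JobSpec:
    """The job the server publishes: how many global rounds, the starting
    deadline, the architecture and training hyperparameters, and the link
    bandwidth used for upload-time accounting."""

    total_rounds: int  # D_T, number of global iterations
    initial_waiting_time: float = 600.0  # W0 seconds, used in round 1
    architecture_id: str = "small-cnn"
    hyperparam_defaults: HyperParams = field(default_factory=HyperParams)
    bandwidth_bytes_per_second: float = DEFAULT_BANDWIDTH
    deadline_slack: float = 1.0  # multiplier on the mean previous training time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_rounds <= 0:
            raise ValueError("total_rounds must be positive")
        if self.initial_waiting_time <= 0:
            raise ValueError("initial_waiting_time must be positive")
        if self.bandwidth_bytes_per_second <= 0:
            raise ValueError("bandwidth must be positive")
        if self.deadline_slack <= 0:
            raise ValueError("deadline_slack must be positive")


@dataclass
class ServerState:
    global_params: ParameterVector
    server_test_set: LabeledDataset
    round_index: int = 0
    waiting_time: float = math.inf
    global_best_accuracy: float = 0.0  # server-side A_MAX: running max global accuracy


@dataclass(frozen=True)
class ClientOutcome:
    """One client's line in a round record."""

    client_id: str
    training_time: float
    local_accuracy: float
    decision: str  # uploaded | skipped | timed_out


@dataclass(frozen=True)
class RoundRecord:
    """Ledger of one global iteration: who trained, who uploaded, who was
    excluded, and what the global model scored afterwards."""

    round_index: int
    waiting_time_used: float
    outcomes: tuple[ClientOutcome, ...]
    participant_ids: tuple[str, ...]  # uploaded AND arrived in time
    global_accuracy_after: float

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "waiting_time_used": self.waiting_time_used,
            "outcomes": [vars(o) for o in self.outcomes],
            "participant_ids": list(self.participant_ids),
            "global_accuracy_after": self.global_accuracy_after,
        }


@dataclass
class CommLedger:
    """Cumulative upload accounting for a run: counts, bytes and simulated
    upload seconds (= bytes / bandwidth, exactly)."""

    bandwidth_bytes_per_second: float = DEFAULT_BANDWIDTH
    upload_count: int = 0
    upload_bytes: int = 0
    upload_seconds: float = 0.0
    per_client: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bandwidth_bytes_per_second": self.bandwidth_bytes_per_second,
            "upload_count": self.upload_count,
            "upload_bytes": self.upload_bytes,
            "upload_seconds": self.upload_seconds,
            "per_client": self.per_client,
        }


def compute_waiting_time(
    previous_round_training_times: list[float],
    initial_waiting_time: float,
    slack: float = 1.0,
) -> float:
    """Deadline for the current round: mean of the previous round's reported
    training times (times a slack multiplier); the configured initial waiting
    time when there is no previous round to average."""
    if any(t < 0 for t in previous_round_training_times):
        raise ValueError("training times must be nonnegative")
    if not previous_round_training_times:
        return initial_waiting_time
    return slack * float(np.mean(previous_round_training_times))


def collect_round(
    messages: list[ClientRoundMessage], waiting_time: float
) -> tuple[list[ClientRoundMessage], list[ClientRoundMessage], list[ClientRoundMessage]]:
    """Partition the round's messages into (accepted, timed_out, skipped).

    accepted: carried a payload and arrived at or before the deadline;
    timed_out: arrived after the deadline (payload or not);
    skipped: arrived in time but declined to upload.
    """
    accepted, timed_out, skipped = [], [], []
    for m in messages:
        if m.arrival_time > waiting_time:
            timed_out.append(m)
        elif m.uploaded:
            accepted.append(m)
        else:
            skipped.append(m)
    return accepted, timed_out, skipped


def fedavg_aggregate(
    updates: list[tuple[ParameterVector, int]],
    current_global: ParameterVector | None = None,
) -> ParameterVector:
    """Federated averaging: element-wise mean weighted by sample counts.

    An empty update list keeps the current global parameters unchanged (the
    round still advances); this requires ``current_global``.
    """
    if not updates:
        if current_global is None:
            raise ValueError("no updates and no current global parameters to fall back on")
        logger.info("no participants this round; global parameters unchanged")
        return current_global
    arch_ids = {p.architecture_id for p, _ in updates}
    dims = {p.dimensionality for p, _ in updates}
    if len(arch_ids) > 1 or len(dims) > 1:
        raise ValueError(f"mixed architectures/dimensions in aggregate: {arch_ids}, {dims}")
    weights = np.array([float(n) for _, n in updates])
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("sample counts must be nonnegative with a positive total")
    weights /= weights.sum()
    stacked = np.stack([p.values for p, _ in updates])
    return ParameterVector(weights @ stacked, updates[0][0].architecture_id)


def assess_and_dispatch(state: ServerState, new_global: ParameterVector) -> float:
    """Score the aggregated model on the server's held-out test set, update the
    running best, and install the parameters as the next round's dispatch."""
    if len(state.server_test_set) == 0:
        raise ValueError("server test set is empty")
    sample_shape = state.server_test_set.samples[0].pixels.shape
    arch = get_architecture(
        new_global.architecture_id, sample_shape, state.server_test_set.num_classes
    )
    model = ClassifierModel(arch, new_global)
    pred = predict_labels(model, state.server_test_set)
    truth = state.server_test_set.labels_array()
    acc = float(np.mean(pred == truth))
    state.global_params = new_global
    state.global_best_accuracy = max(state.global_best_accuracy, acc)
    return acc


def evaluate_global(state: ServerState):
    """Full metric report of the current global model on the server test set."""
    sample_shape = state.server_test_set.samples[0].pixels.shape
    arch = get_architecture(
        state.global_params.architecture_id, sample_shape, state.server_test_set.num_classes
    )
    model = ClassifierModel(arch, state.global_params)
    pred = predict_labels(model, state.server_test_set)
    cm = confusion_matrix(
        state.server_test_set.labels_array(),
        pred,
        state.server_test_set.num_classes,
        state.server_test_set.class_names,
    )
    return compute_metrics(cm), cm


def record_upload(
    ledger: CommLedger, client_id: str, payload_bytes: int, bandwidth: float | None = None
) -> CommLedger:
    """Account one (possibly empty) upload: bytes > 0 adds one upload, its
    bytes, and bytes/bandwidth simulated seconds."""
    bw = ledger.bandwidth_bytes_per_second if bandwidth is None else bandwidth
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    if payload_bytes < 0:
        raise ValueError("payload bytes must be nonnegative")
    if payload_bytes == 0:
        return ledger
    entry = ledger.per_client.setdefault(
        client_id, {"upload_count": 0, "upload_bytes": 0, "upload_seconds": 0.0}
    )
    seconds = payload_bytes / bw
    entry["upload_count"] += 1
    entry["upload_bytes"] += payload_bytes
    entry["upload_seconds"] += seconds
    ledger.upload_count += 1
    ledger.upload_bytes += payload_bytes
    ledger.upload_seconds += seconds
    return ledger
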