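"""Full federated runs under a simulated clock, in two protocol modes.

``dmfl`` mode runs the decision-making protocol: clients upload only on
strict validation-accuracy improvement, and the server excludes stragglers
whose arrival exceeds the round deadline (mean of the previous round's
training times).  ``default_fl`` mode is the synchronous FedAvg baseline:
every client uploads every round and every arrival is accepted.  The two
modes differ ONLY in those decision points — data, initialization, batch
order and clock draws all flow from the same master seed — so matched runs
are directly comparable, and with forced uploads and no timeouts a dmfl run
is bit-identical to its default_fl twin.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import child_seed
from .client import ClientRoundMessage, ClientState, TrainingClock, decide_upload, local_train, submit_report
from .data import (
    ClientPartition,
    LabeledDataset,
    SplitSpec,
    generate_synthetic_dataset,
    partition_clients,
    stratified_split,
)
from .metrics import MetricReport
from .models import HyperParams, ParameterVector, get_architecture
from .server import (
    ClientOutcome,
    CommLedger,
    JobSpec,
    RoundRecord,
    ServerState,
    assess_and_dispatch,
    collect_round,
    compute_waiting_time,
    evaluate_global,
    fedavg_aggregate,
    record_upload,
)

__all__ = [
    "ClientConfig",
    "RunConfig",
    "RunReport",
    "ComparisonReport",
    "run_federated_job",
    "compare_runs",
    "benchmark_scenario",
    "CLIENT_SIZE_GROUPS",
]

MODES = ("dmfl", "default_fl")

# per-client dataset sizes of the six experimental groups (three clients each)
CLIENT_SIZE_GROUPS = {
    1: (500, 1000, 2000),
    2: (800, 1600, 3000),
    3: (1200, 2400, 3200),
    4: (1500, 3000, 3500),
    5: (1000, 4000, 3800),
    6: (2000, 4200, 4200),
}


@dataclass(frozen=True)
class ClientConfig:
    size: int
    base_seconds_per_epoch: float = 60.0
    jitter_fraction: float = 0.0
    hyperparams: HyperParams | None = None  # None: use the job defaults


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one federated run; a run is reproducible
    bit-for-bit from this object alone."""

    mode: str
    job: JobSpec
    clients: tuple[ClientConfig, ...]
    num_classes: int = 6
    class_counts: tuple[int, ...] | None = None  # None: balanced to cover the demand
    image_size: tuple[int, int] = (32, 32)
    separability: float = 3.0
    partition_mode: str = "iid"
    dirichlet_concentration: float = 0.5
    server_test_fraction: float = 0.1
    client_split: SplitSpec = field(default_factory=SplitSpec)
    force_upload: bool = False  # dmfl only: bypass the participation decision
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.clients:
            raise ValueError("at least one client is required")
        if not 0 < self.server_test_fraction < 1:
            raise ValueError("server_test_fraction must lie in (0, 1)")

    def resolved_class_counts(self) -> tuple[int, ...]:
        if self.class_counts is not None:
            return self.class_counts
        demand = sum(c.size for c in self.clients)
        per_class = math.ceil(demand / (1.0 - self.server_test_fraction) / self.num_classes) + 1
        return tuple([per_class] * self.num_classes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["client_split"] = dataclasses.asdict(self.client_split)
        return d


@dataclass
class RunReport:
    """Everything one run produced: per-round records, the final metric
    report on the server test set, the communication ledger, and the final
    global parameters."""

    config: RunConfig
    rounds: list[RoundRecord]
    final_metrics: MetricReport
    comm: CommLedger
    final_params: ParameterVector
    accuracy_per_round: list[float]

    @property
    def final_accuracy(self) -> float:
        return self.final_metrics.accuracy

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "rounds": [r.to_dict() for r in self.rounds],
            "final_metrics": self.final_metrics.to_dict(),
            "comm": self.comm.to_dict(),
            "accuracy_per_round": self.accuracy_per_round,
        }

    def save(self, out_dir: str | Path) -> Path:
        """Write report.json, rounds.csv, comm.csv and the final parameter
        checkpoint into a directory."""
        import pandas as pd

        from .models import save_checkpoint

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        rows = []
        for r in self.rounds:
            for o in r.outcomes:
                rows.append(
                    {
                        "round": r.round_index,
                        "client_id": o.client_id,
                        "training_time": o.training_time,
                        "local_accuracy": o.local_accuracy,
                        "decision": o.decision,
                        "waiting_time_used": r.waiting_time_used,
                        "global_accuracy_after": r.global_accuracy_after,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "rounds.csv", index=False)
        pd.DataFrame([self.comm.to_dict() | {"mode": self.config.mode}]).drop(
            columns=["per_client"]
        ).to_csv(out / "comm.csv", index=False)
        save_checkpoint(self.final_params, out / "global_params.bin")
        return out


def _build_world(config: RunConfig):
    """Generate the corpus, carve out the server test set, and partition the
    rest across clients."""
    counts = config.resolved_class_counts()
    full = generate_synthetic_dataset(
        counts,
        image_size=config.image_size,
        separability=config.separability,
        seed=child_seed(config.seed, "data"),
    )
    pool, _, server_test = stratified_split(
        full,
        SplitSpec(1.0 - config.server_test_fraction, 0.0, config.server_test_fraction),
        seed=child_seed(config.seed, "server-split"),
    )
    partitions = partition_clients(
        pool,
        [c.size for c in config.clients],
        mode=config.partition_mode,
        seed=child_seed(config.seed, "partition"),
        concentration=config.dirichlet_concentration,
        split=config.client_split,
    )
    return partitions, server_test


def run_federated_job(config: RunConfig) -> RunReport:
    """Execute all global rounds of one federated job under the simulated
    clock and return the full run report."""
    job = config.job
    partitions, server_test = _build_world(config)

    clients: list[ClientState] = []
    for cc, part in zip(config.clients, partitions):
        clients.append(
            ClientState(
                client_id=part.client_id,
                partition=part,
                hyperparams=cc.hyperparams or job.hyperparam_defaults,
                clock=TrainingClock(
                    base_seconds_per_epoch=cc.base_seconds_per_epoch,
                    jitter_fraction=cc.jitter_fraction,
                    seed=child_seed(config.seed, "clock", part.client_id),
                ),
                architecture_id=job.architecture_id,
                seed=child_seed(config.seed, "client", part.client_id),
            )
        )

    arch = get_architecture(job.architecture_id, config.image_size, config.num_classes)
    state = ServerState(
        global_params=arch.init_params(child_seed(config.seed, "init")),
        server_test_set=server_test,
    )
    ledger = CommLedger(bandwidth_bytes_per_second=job.bandwidth_bytes_per_second)

    rounds: list[RoundRecord] = []
    acc_series: list[float] = []
    prev_times: list[float] = []
    for round_index in range(1, job.total_rounds + 1):
        waiting = compute_waiting_time(prev_times, job.initial_waiting_time, job.deadline_slack)

        messages: list[ClientRoundMessage] = []
        for cs in clients:
            result = local_train(cs, state.global_params, round_index)
            if config.mode == "default_fl" or config.force_upload:
                decision = "upload"
                # keep A_MAX a running maximum even when the decision is bypassed
                cs.best_accuracy = max(cs.best_accuracy, result.local_accuracy)
                msg = submit_report(cs, dataclasses.replace(result), "upload", round_index)
            else:
                decision = decide_upload(result.local_accuracy, cs.best_accuracy)
                msg = submit_report(cs, result, decision, round_index)
            messages.append(msg)

        if config.mode == "default_fl":
            deadline = math.inf  # the baseline accepts every arrival
        else:
            deadline = waiting
        accepted, timed_out, skipped = collect_round(messages, deadline)

        for m in messages:  # every sent payload consumed bandwidth
            record_upload(ledger, m.client_id, m.payload_bytes)

        from .models import deserialize_parameters

        updates = [(deserialize_parameters(m.payload), m.train_size) for m in accepted]
        new_global = fedavg_aggregate(updates, current_global=state.global_params)
        acc = assess_and_dispatch(state, new_global)
        acc_series.append(acc)

        outcome_by_id = {}
        for m in accepted:
            outcome_by_id[m.client_id] = "uploaded"
        for m in timed_out:
            outcome_by_id[m.client_id] = "timed_out"
        for m in skipped:
            outcome_by_id[m.client_id] = "skipped"
        outcomes = tuple(
            ClientOutcome(m.client_id, m.training_time, m.local_accuracy, outcome_by_id[m.client_id])
            for m in messages
        )
        rounds.append(
            RoundRecord(
                round_index=round_index,
                waiting_time_used=deadline,
                outcomes=outcomes,
                participant_ids=tuple(m.client_id for m in accepted),
                global_accuracy_after=acc,
            )
        )
        state.round_index = round_index
        # all reported times (including stragglers') enter the next deadline
        prev_times = [m.training_time for m in messages]

    final_metrics, _ = evaluate_global(state)
    return RunReport(
        config=config,
        rounds=rounds,
        final_metrics=final_metrics,
        comm=ledger,
        final_params=state.global_params,
        accuracy_per_round=acc_series,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side communication and accuracy comparison of a dmfl run
    against its default-FL twin."""

    dmfl_upload_count: int
    default_upload_count: int
    upload_count_difference: int  # default - dmfl (>= 0 by construction)
    upload_seconds_dmfl: float
    upload_seconds_default: float
    upload_seconds_ratio: float  # dmfl / default
    accuracy_per_round_dmfl: list[float]
    accuracy_per_round_default: list[float]
    final_accuracy_dmfl: float
    final_accuracy_default: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_runs(dmfl: RunReport, default: RunReport) -> ComparisonReport:
    """Compare two matched runs (identical configs except mode)."""
    ca = dataclasses.asdict(dmfl.config)
    cb = dataclasses.asdict(default.config)
    for skip in ("mode", "force_upload"):
        ca.pop(skip), cb.pop(skip)
    if ca != cb:
        raise ValueError("runs are not comparable: configs differ beyond mode")
    ratio = (
        dmfl.comm.upload_seconds / default.comm.upload_seconds
        if default.comm.upload_seconds > 0
        else float("nan") if dmfl.comm.upload_seconds > 0 else 1.0
    )
    return ComparisonReport(
        dmfl_upload_count=dmfl.comm.upload_count,
        default_upload_count=default.comm.upload_count,
        upload_count_difference=default.comm.upload_count - dmfl.comm.upload_count,
        upload_seconds_dmfl=dmfl.comm.upload_seconds,
        upload_seconds_default=default.comm.upload_seconds,
        upload_seconds_ratio=ratio,
        accuracy_per_round_dmfl=list(dmfl.accuracy_per_round),
        accuracy_per_round_default=list(default.accuracy_per_round),
        final_accuracy_dmfl=dmfl.final_accuracy,
        final_accuracy_default=default.final_accuracy,
    )


def benchmark_scenario(
    scale: float = 1.0,
    row: int = 1,
    mode: str = "dmfl",
    rounds: int = 100,
    architecture_id: str = "small-cnn",
    image_size: tuple[int, int] = (32, 32),
    separability: float = 3.0,
    seed: int = 0,
    hyperparams: HyperParams | None = None,
    base_seconds_per_epoch: Sequence[float] = (60.0, 80.0, 120.0),
    jitter_fraction: float = 0.0,
) -> RunConfig:
    """Build a 3-client scenario with per-client dataset sizes from one of the
    six experimental groups (row 1 = 500/1000/2000), scaled by ``scale``.

    The synthetic corpus is balanced across the 6 classes (the protocol runs
    on the oversampling-balanced corpus).  ``scale`` must leave every client
    at least 3 samples per class.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    if row not in CLIENT_SIZE_GROUPS:
        raise ValueError(f"row must be one of {sorted(CLIENT_SIZE_GROUPS)}")
    sizes = [int(round(s * scale)) for s in CLIENT_SIZE_GROUPS[row]]
    K = 6
    if min(sizes) < 3 * K:
        raise ValueError(
            f"scale {scale} gives client sizes {sizes}; need >= 3 samples per class per client"
        )
    hp = hyperparams or HyperParams(learning_rate=0.1, batch_size=16, epochs=1)
    clients = tuple(
        ClientConfig(size=s, base_seconds_per_epoch=b, jitter_fraction=jitter_fraction)
        for s, b in zip(sizes, base_seconds_per_epoch)
    )
    return RunConfig(
        mode=mode,
        job=JobSpec(total_rounds=rounds, architecture_id=architecture_id, hyperparam_defaults=hp, seed=seed),
        clients=clients,
        num_classes=K,
        image_size=image_size,
        separability=separability,
        seed=seed,
    )
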