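"""One client's round: local SGD from the global parameters, then the
participation decision (upload only on strict validation-accuracy improvement).
"""

from dmflsim import (
    ClientPartition,
    ClientState,
    HyperParams,
    SplitSpec,
    TrainingClock,
    decide_upload,
    generate_synthetic_dataset,
    get_architecture,
    local_train,
    stratified_split,
    submit_report,
)

ds = generate_synthetic_dataset([200, 200], image_size=(16, 16), separability=0.8, seed=1)
train, val, test = stratified_split(ds, SplitSpec(0.8, 0.1, 0.1), seed=1)
state = ClientState(
    client_id="client1",
    partition=ClientPartition("client1", train, val, test),
    hyperparams=HyperParams(learning_rate=0.02, batch_size=8, epochs=1),
    clock=TrainingClock(base_seconds_per_epoch=60.0, jitter_fraction=0.1, seed=1),
    architecture_id="linear",
    seed=1,
)

global_params = get_architecture("linear", (16, 16), 2).init_params(0)
for round_index in (1, 2, 3, 4, 5):
    result = local_train(state, global_params, round_index)
    decision = decide_upload(result.local_accuracy, state.best_accuracy)
    msg = submit_report(state, result, decision, round_index)
    print(
        f"round {round_index}: A_ACC={result.local_accuracy:.3f} "
        f"A_MAX={state.best_accuracy:.3f} decision={decision} "
        f"T_TIME={result.training_time:.1f}s payload={msg.payload_bytes} bytes"
    )
    global_params = result.trained_params
# Once validation accuracy stops strictly improving, the client skips the
# upload and the round message carries a zero-byte payload.
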