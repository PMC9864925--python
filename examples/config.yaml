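# Example run configuration for `dmflsim simulate --config examples/config.yaml --out DIR`
mode: dmfl
job:
  total_rounds: 10
  initial_waiting_time: 600.0
  architecture_id: small-cnn
  bandwidth_bytes_per_second: 12000000.0   # 12 MB/s link rate
  deadline_slack: 1.0
  seed: 0
  hyperparams:
    learning_rate: 0.1
    batch_size: 16
    epochs: 1
clients:
  - {size: 50,  base_seconds_per_epoch: 60.0,  jitter_fraction: 0.1}
  - {size: 100, base_seconds_per_epoch: 80.0,  jitter_fraction: 0.1}
  - {size: 200, base_seconds_per_epoch: 120.0, jitter_fraction: 0.1}
num_classes: 6
image_size: [32, 32]
separability: 4.0
partition_mode: iid
server_test_fraction: 0.1
seed: 1
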