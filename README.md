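# cmdsim

A desk-scale simulator for **privacy-preserving collaborative medical
diagnosis**: several healthcare institutions jointly train a diagnostic
classifier by federated averaging, exchanging only **Paillier-encrypted model
updates** — the coordinator aggregates ciphertexts it cannot read, and a
separate key authority decrypts the single aggregate. The classifier is a
**residual deep belief network (RDBN)**: stacked RBMs, optionally pre-trained
with CD-1 contrastive divergence, with residual skips
`h^l = σ(W^l h^{l−1} + b^l) + h^{l−s}` and a softmax head fine-tuned under
cross-entropy.

Who this is for: people studying encrypted federated learning pipelines who
need a fully inspectable, reproducible, pure-Python reference — every stage
(local SGD, fixed-point encoding, homomorphic aggregation, confusion-matrix
metrics) is a plain function with tests, not a framework.

The core update rule per communication round, with N institutions:

```
θᵢ ← local SGD on Dᵢ from θ          (deltas Δθᵢ = θᵢ − θ)
cᵢ = Enc_pk(encode(Δθᵢ))             (fixed-point + Paillier)
C  = c₁ ⊕ … ⊕ c_N                    (ciphertext product = plaintext sum)
θ  ← θ + (1/N) · decode(Dec_sk(C))   (decryption by the key authority only)
```

## Worked example

```bash
cmdsim train-federated --seed 1 --out run/
```

runs the default desk-scale profile — 3 institutions × 200 synthetic patients
(binary-symptom "diabetes-like" preset, strong class separation), a 2×16-unit
RDBN, 10 encrypted rounds under a 128-bit key — and prints the held-out
metric block:

```json
{
  "TP": 120,
  "TN": 120,
  "FP": 0,
  "FN": 0,
  "accuracy": 1.0,
  "precision": 1.0,
  "recall": 1.0,
  "fpr": 0.0,
  "f_measure": 1.0
}
```

On this well-separated synthetic task the global model classifies the 120-row
test split perfectly (micro-averaged one-vs-rest counts, hence 240 cells for
2 classes). `run/rounds.csv` logs the round-by-round global loss and the exact
serialized payload bytes in each direction:

```
round,global_loss,bytes_up,bytes_down,wall_time
0,0.7320771130818544,144423,38634,0.2047...
1,0.7336610225326977,144378,40548,0.2335...
2,0.6988033926200181,144366,40578,0.2814...
```

(~144 kB of ciphertext upstream per round for 594 parameters × 3 institutions
at 128-bit keys — the ciphertext blow-up is the price of the privacy
boundary.) Other subcommands: `cmdsim keygen`, `cmdsim simulate-data`,
`cmdsim evaluate`; `--help` on each. Configuration is YAML over the same keys
as the defaults, echoed verbatim to `run/resolved_config.yaml`.

As a library:

```python
from cmdsim import make_spec, generate, partition, PartitionSpec
from cmdsim import TrainConfig, build_model, FLConfig, run_federated

X, y = generate(make_spec("diabetes_like", n_samples=600,
                          class_separation=5.0, seed=1))
shards = partition(X, y, PartitionSpec(n_institutions=3, seed=1))
cfg = TrainConfig(hidden_layers=2, hidden_units=16, learning_rate=0.1,
                  optimizer="sgd", dropout=0.0, seed=1)
model = build_model(X.shape[1], 2, cfg)
state = run_federated(FLConfig(n_institutions=3, rounds=10, key_bits=128,
                               seed=1), shards, model, train_cfg=cfg)
```

See `docs/methods.md` for the model, the protocol, what the synthetic world
does and does not establish, and all numerical choices.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch —
simulate data, shard it, train the encrypted federation, evaluate the global
model — and writes its results map as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
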