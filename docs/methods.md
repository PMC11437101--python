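# Methods

`cmdsim` simulates privacy-preserving collaborative medical diagnosis: several
healthcare institutions jointly train one classifier without ever exchanging
patient rows, by sharing only Paillier-encrypted model updates that a central
coordinator can aggregate but not read. This note records the model, the
protocol, the synthetic-data world the tests run in, and the numerical and
design choices that were genuinely open.

## The classifier: residual deep belief network (RDBN)

Each hidden layer is a restricted Boltzmann machine (RBM) over visible units
`v` and hidden units `h` with energy

```
E(v, h) = - a·v - b·h - vᵀ W h,          P(v, h) = e^{-E(v,h)} / Z.
```

Layers can be pre-trained greedily: the first RBM models the (min-max scaled)
inputs, each later RBM models the previous layer's hidden activation
probabilities, all via CD-1 contrastive divergence (one Gibbs alternation;
mean-field visible reconstructions, sampled hidden states driving the chain).
`rbm_joint_probability` computes P(v, h) exactly by enumeration for models of
at most 16 total units and exists purely as a verification surface.

The supervised network adds residual skips. The default placement is the
canonical `y = F(x) + x` form,

```
h^l = σ(W^l h^{l-1} + b^l) + h^{l-s},
```

with the alternative placement (skip inside the nonlinearity,
`h^l = σ(W^l h^{l-1} + b^l + h^{l-s})`) available as
`residual_mode="pre_activation"`. Both appear in the literature; we default to
post-activation because it preserves the identity path exactly. A skip is taken
only when the source activation exists and matches the target width — with the
default span s = 1 and equal hidden widths that means every hidden layer except
(usually) the first. A softmax head produces class probabilities; prediction is
argmax with lowest-index tie-break.

Sigmoid is mandatory inside RBM sampling (Bernoulli probabilities require it);
the fine-tuning forward pass is configurable sigmoid/ReLU and defaults to
sigmoid for consistency with pre-training, even though large-scale runs of
this kind of network often quote ReLU. Fine-tuning minimizes mean
cross-entropy by backpropagation through the residual graph (skips route
gradient both through the nonlinearity and directly to the source layer), with
inverted dropout at the configured rate during training only. The centralized
fine-tuner defaults to Adam; the *federated local step is plain SGD*, matching
the protocol's update rule below. Weights initialize Gaussian(0, 0.01), biases
zero, when not pre-trained.

The federated parameter vector flattens, in order: each hidden layer's W
(row-major) then hidden bias b, then the output head W and b. RBM visible
biases are pre-training-only (they carry no supervised gradient) and are
excluded from federation.

## The protocol

Per communication round t:

1. the coordinator distributes the global vector θ;
2. institution i runs `local_epochs` of minibatch SGD on its shard D_i from θ
   and forms Δθ_i = θ_i − θ (deltas, not raw parameters, are sent: this
   matches the averaging rule and keeps fixed-point magnitudes small);
3. optionally, i.i.d. Laplace(0, noise_level·sensitivity) noise is added to
   each coordinate (off by default; level 1.0 when enabled; calibrating the
   sensitivity to a real clipping bound is out of scope);
4. the delta is fixed-point encoded and Paillier-encrypted under the single
   system public key;
5. the coordinator multiplies ciphertexts coordinate-wise (homomorphic
   addition) — it holds no private key, structurally;
6. a separate key authority decrypts the one aggregate ciphertext vector and
   applies unweighted federated averaging, θ_new = θ_old + (1/N) Σ Δθ_i,
   with the division performed after decryption (Paillier has no exact
   ciphertext division).

All N institutions participate every round. The loop stops at the round budget
or when ‖θ_new − θ_old‖∞ < 1e−5 (a value we fixed; "convergence" is otherwise
unquantified in this setting). Transport is in-process, but every payload is
serialized to its JSON wire form so the per-round byte log is exact.

Unweighted 1/N averaging is deliberate even when shards differ in size; the
weighted variant would be a one-line change but is not what the aggregation
rule we follow prescribes.

## The cryptosystem

Paillier with the simplified generator g = n + 1, so encryption is
`c = (1 + m·n) · rⁿ mod n²` (one modular multiplication plus one
exponentiation) and decryption uses λ = lcm(p−1, q−1), µ = λ⁻¹ mod n. Primes
come from a seeded candidate search (odd candidates of exactly half the key
width, BPSW primality test), making keypairs reproducible for tests. Key sizes:
2048 bits in the full-scale profile, 128–512 in tests — 128-bit keys are
cryptographically worthless and exist purely to keep desk-scale runs fast; the
homomorphic algebra is identical at every size.

Real-valued weights are mapped to the plaintext ring by fixed-point encoding:
`m = round(x · scale) mod n`, negatives occupying the upper residue half, so
additive homomorphism carries over to signed reals exactly up to rounding
(≤ 0.5/scale per element, ≤ K/scale for a K-term homomorphic sum). Defaults:
scale 2^32, |x| ≤ 1e6, with the constructor enforcing max_abs·scale < n/3 so
small sums cannot wrap.

A textbook unpadded-RSA path demonstrates the multiplicative counterpart
(product of ciphertexts decrypts to product of plaintexts). It is flagged
insecure-demo and never touches the federated pipeline.

## The synthetic world

The generator draws from a class-conditional model: continuous features are
per-class Gaussians (unit variance, means scaled by `class_separation`),
binary features per-class Bernoullis with logits scaled the same way, ordinal
features per-class multinomials from scaled softmax logits. Separation 0
collapses all classes onto one distribution (a strong baseline scores at
chance); separation 5 makes a linear model nearly perfect. Labels may be
flipped with probability `label_noise`. Three presets copy only the *shape*
(feature counts and kinds, class counts) of well-known public tabular
diagnosis datasets — 34 mostly-ordinal features / 6 classes, 12 continuous /
5 classes, 16 binary + age / 2 classes — not their distributions. A green test
on this world therefore establishes that the pipeline's mechanics (training,
encryption, aggregation, metrics) are correct, not that any real-data accuracy
figure is reproduced: the generator has no missing data, no feature
correlations beyond class structure, and balanced classes by construction.

Partitioning is iid (random equal split) or Dirichlet non-iid (per-institution
class proportions from Dirichlet(α); empty shards are refilled from the
largest one so every institution keeps ≥ 1 row). CSV I/O is headered, with
column-median imputation of blanks at read time, and min-max scaling to [0, 1]
applied before training to satisfy the RBM visible-unit convention.

## Profiles and parameters

Full-scale profile (the configuration the method is described at): 10
institutions × 1000 patients, 50 communication rounds, 5 local epochs, batch
64, learning rate 0.001, Adam (centralized), 5 hidden layers × 256 units,
dropout 0.5, cross-entropy, 2048-bit keys, DP noise level 1.0 (off unless
enabled).

Test profile (the `DEFAULT_CONFIG` the CLI and the acceptance checks run): 3
institutions × 200 patients, 10 rounds, 2 layers × 16 units, 128-bit keys,
dropout 0, SGD with learning rate 0.1. The learning rate is the one knob the
full-scale profile cannot supply (0.001 belongs to a 100-round Adam schedule);
0.1 is a standard plain-SGD scale for a few-hundred-sample, near-separable
task and was fixed when the profile was written. The full-scale profile is
exercised nowhere in the default suite — it would take hours on one CPU — but
every mechanism it uses is identical at desk scale.

## Numerical choices and limitations

- Softmax/cross-entropy via log-sum-exp; piecewise-stable sigmoid.
- Gradient checks compare analytic backprop to central finite differences
  with step 1e−6 and relative tolerance 1e−4.
- Prediction ties break toward the lowest class index.
- Zero-denominator metric cells raise a typed `UndefinedMetricError` rather
  than reporting 0; in per-class tables the offending cell is `None` and the
  rest stay filled. Multiclass reduction is micro-averaged one-vs-rest (counts
  summed before ratios), with per-class tables attached, because single
  confusion tables for multiclass tasks are otherwise ambiguous.
- Encrypted and plaintext federated averaging agree to T·N/scale per
  coordinate after T rounds with N institutions — pure quantization error;
  training amplification is negligible at the learning rates used.
- Not implemented: Gaussian-Bernoulli RBMs (continuous features are scaled to
  [0, 1] and treated as visible probabilities), persistent CD, client
  sampling, asynchronous or Byzantine-robust aggregation, threshold Paillier,
  and any side-channel hardening.
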