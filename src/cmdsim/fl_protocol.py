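"""Federated training loop with encrypted aggregation.

One communication round: the coordinator distributes the global parameter
vector theta; each institution runs local minibatch SGD on its private
shard and forms a delta Delta_i = theta_i - theta; deltas are (optionally)
perturbed with Laplace noise, fixed-point encoded and Paillier-encrypted;
the coordinator folds the ciphertext vectors with homomorphic addition —
it never sees a private key — and hands the single aggregate to a key
authority, which decrypts once and applies unweighted federated averaging::

    theta_new = theta_old + (1/N) * sum_i Delta_i

The round repeats until the configured round budget or until the max-norm
parameter change falls below the convergence tolerance. Transport is
in-process, but every payload is serialized to its wire form (JSON decimal
strings) so byte accounting is exact.

Role separation is structural: :class:`Coordinator` holds only the public
key; :class:`KeyAuthority` is the only object holding private material, and
``aggregate_encrypted`` accepts no key argument other than the public one.
"""

from __future__ import annotations

import json
import random
import time
from dataclasses import dataclass, field

import numpy as np

from . import phc_crypto as phc
from . import rdbn_model as rdbn
from .phc_crypto import Ciphertext, FixedPointEncoding, PaillierPublicKey
from .synthetic_data import InstitutionDataset

__all__ = [
    "ParameterUpdate",
    "EncryptedUpdate",
    "CoordinatorState",
    "FLConfig",
    "KeyAuthority",
    "Coordinator",
    "local_train",
    "local_loss",
    "add_dp_noise",
    "encrypt_update",
    "serialize_encrypted_update",
    "aggregate_encrypted",
    "decrypt_and_average",
    "run_federated",
]

CONVERGENCE_TOL = 1e-5  # max-norm of the global parameter change


@dataclass
class ParameterUpdate:
    """Plaintext model delta Delta_theta_i for one institution and round."""

    flat_delta: np.ndarray
    round_index: int
    institution_id: int

    def __post_init__(self) -> None:
        self.flat_delta = np.asarray(self.flat_delta, dtype=float)
        if not np.isfinite(self.flat_delta).all():
            raise ValueError("parameter update contains non-finite entries")


@dataclass
class EncryptedUpdate:
    """Ciphertext form of a ParameterUpdate."""

    ciphertexts: list[Ciphertext]
    key_id: str
    scale: int
    round_index: int
    institution_id: int


@dataclass
class FLConfig:
    """Federation-level settings; defaults mirror the full-scale profile."""

    n_institutions: int = 10
    patients_per_institution: int = 1000
    rounds: int = 50
    local_epochs: int = 5
    aggregation: str = "federated_averaging"
    dp_enabled: bool = False
    dp_noise_level: float = 1.0
    key_bits: int = 2048
    seed: int = 0
    convergence_tol: float = CONVERGENCE_TOL

    def __post_init__(self) -> None:
        if self.n_institutions < 1 or self.rounds < 1 or self.local_epochs < 0:
            raise ValueError("counts must be positive")
        if self.aggregation != "federated_averaging":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.dp_noise_level < 0:
            raise ValueError("dp_noise_level must be >= 0")


@dataclass
class CoordinatorState:
    """Global model parameters plus per-round bookkeeping."""

    global_params: np.ndarray
    round_index: int
    n_institutions: int
    history: list[dict] = field(default_factory=list)
    converged: bool = False


class KeyAuthority:
    """Trusted entity: generates and holds the system keypair.

    The coordinator receives only the public key; decryption of the
    ciphertext aggregate happens here and nowhere else.
    """

    def __init__(self, key_bits: int, seed: int):
        self._keypair = phc.generate_keypair(key_bits, seed)

    @property
    def public_key(self) -> PaillierPublicKey:
        return self._keypair.public

    def decrypt_aggregate(self, agg: EncryptedUpdate,
                          enc: FixedPointEncoding) -> np.ndarray:
        return np.array(phc.decrypt_vector(self._keypair, agg.ciphertexts, enc))


class Coordinator:
    """Central server: aggregates ciphertexts; holds no private key."""

    def __init__(self, public_key: PaillierPublicKey):
        self.public_key = public_key

    def aggregate(self, updates: list[EncryptedUpdate]) -> EncryptedUpdate:
        return aggregate_encrypted(updates, self.public_key)


# --------------------------------------------------------------------------
# Client-side operations
# --------------------------------------------------------------------------

def local_train(client: InstitutionDataset, global_params: np.ndarray,
                model_template: rdbn.RDBNModel, cfg: rdbn.TrainConfig,
                round_index: int = 0) -> ParameterUpdate:
    """Local minibatch SGD from the global parameters; returns the delta.

    Runs cfg.local_epochs epochs of plain gradient descent (the federated
    local step is SGD by design; Adam is reserved for centralized
    fine-tuning). Raw rows never leave this function.
    """
    global_params = np.asarray(global_params, dtype=float)
    model = rdbn.set_flat_params(model_template, global_params)
    if client.X.shape[1] != model.n_features:
        raise ValueError(
            f"institution {client.institution_id}: feature width "
            f"{client.X.shape[1]} does not match model {model.n_features}"
        )
    # per-(seed, round, institution) stream keeps runs reproducible
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, round_index, client.institution_id])
    )
    theta = global_params.copy()
    for _ in range(cfg.local_epochs):
        perm = rng.permutation(client.n_i)
        for start in range(0, client.n_i, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            work = rdbn.set_flat_params(model, theta)
            drop_rng = rng if cfg.dropout > 0 else None
            loss, grad = rdbn.loss_and_grads(
                work, client.X[idx], client.y[idx], dropout_rng=drop_rng)
            if not np.isfinite(loss):
                raise rdbn.TrainingDivergedError(
                    f"institution {client.institution_id} diverged in "
                    f"round {round_index}"
                )
            theta = theta - cfg.learning_rate * grad
    return ParameterUpdate(
        flat_delta=theta - global_params,
        round_index=round_index,
        institution_id=client.institution_id,
    )


def local_loss(params: np.ndarray, client: InstitutionDataset,
               model_template: rdbn.RDBNModel) -> float:
    """Mean cross-entropy of the parameterized model on one shard."""
    if client.n_i == 0:
        raise ValueError("empty dataset")
    model = rdbn.set_flat_params(model_template, np.asarray(params, dtype=float))
    return rdbn.cross_entropy_loss(model, client.X, client.y)


def add_dp_noise(update: ParameterUpdate, noise_level: float,
                 rng: np.random.Generator,
                 sensitivity: float = 1.0) -> ParameterUpdate:
    """Perturb a delta with i.i.d. Laplace(0, noise_level * sensitivity).

    noise_level = 0 is the identity. Calibrating `sensitivity` to a real
    clipping bound is the caller's responsibility; default 1.0 matches the
    nominal unit-sensitivity convention.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if noise_level == 0:
        return update
    b = noise_level * sensitivity
    noisy = update.flat_delta + rng.laplace(0.0, b, size=update.flat_delta.shape)
    return ParameterUpdate(noisy, update.round_index, update.institution_id)


def encrypt_update(update: ParameterUpdate, pk: PaillierPublicKey,
                   enc: FixedPointEncoding,
                   rng: random.Random) -> EncryptedUpdate:
    """Fixed-point encode and Paillier-encrypt a delta, element-wise."""
    cts = phc.encrypt_vector(pk, update.flat_delta.tolist(), enc, rng=rng)
    return EncryptedUpdate(
        ciphertexts=cts,
        key_id=pk.key_id,
        scale=enc.scale,
        round_index=update.round_index,
        institution_id=update.institution_id,
    )


def serialize_encrypted_update(eu: EncryptedUpdate) -> bytes:
    """Wire form: JSON with decimal-string ciphertexts. Used for byte
    accounting; transport itself is in-process."""
    return json.dumps({
        "key_id": eu.key_id,
        "scale": eu.scale,
        "round": eu.round_index,
        "institution": eu.institution_id,
        "ciphertexts": [str(c.value) for c in eu.ciphertexts],
    }).encode()


# --------------------------------------------------------------------------
# Server-side operations
# --------------------------------------------------------------------------

def aggregate_encrypted(updates: list[EncryptedUpdate],
                        pk: PaillierPublicKey) -> EncryptedUpdate:
    """Fold encrypted deltas by homomorphic addition — no decryption.

    The aggregate decrypts to sum_i Delta_i. Mixing keys, rounds, or
    lengths is a protocol error.
    """
    if not updates:
        raise ValueError("no updates to aggregate")
    first = updates[0]
    for u in updates[1:]:
        if u.key_id != first.key_id:
            raise ValueError("updates encrypted under different keys")
        if u.round_index != first.round_index:
            raise ValueError("updates from different rounds")
        if len(u.ciphertexts) != len(first.ciphertexts):
            raise ValueError("updates of different lengths")
        if u.scale != first.scale:
            raise ValueError("updates with different fixed-point scales")
    acc = list(first.ciphertexts)
    for u in updates[1:]:
        acc = [phc.homomorphic_add(a, c, pk)
               for a, c in zip(acc, u.ciphertexts)]
    return EncryptedUpdate(
        ciphertexts=acc,
        key_id=first.key_id,
        scale=first.scale,
        round_index=first.round_index,
        institution_id=-1,  # aggregate has no single owner
    )


def decrypt_and_average(agg: EncryptedUpdate, authority: KeyAuthority,
                        enc: FixedPointEncoding, n_institutions: int,
                        old_params: np.ndarray) -> np.ndarray:
    """theta_new = theta_old + (1/N) * decode(decrypt(aggregate)).

    Division by N happens after decryption (Paillier offers no exact
    ciphertext division); averaging is unweighted.
    """
    if n_institutions < 1:
        raise ValueError("n_institutions must be >= 1")
    total = authority.decrypt_aggregate(agg, enc)
    return np.asarray(old_params, dtype=float) + total / n_institutions


# --------------------------------------------------------------------------
# The full loop
# --------------------------------------------------------------------------

def run_federated(cfg: FLConfig, datasets: list[InstitutionDataset],
                  model_template: rdbn.RDBNModel,
                  train_cfg: rdbn.TrainConfig | None = None,
                  encoding: FixedPointEncoding | None = None,
                  log_path=None) -> CoordinatorState:
    """Execute the encrypted federated-averaging loop.

    Per round: distribute theta -> local SGD per institution -> optional
    Laplace noise -> encrypt -> ciphertext aggregation -> single decryption
    and averaging by the key authority. Logs per-round global loss and
    exact serialized byte counts. Stops at cfg.rounds or when the global
    parameter change drops below cfg.convergence_tol in max-norm.
    """
    if len(datasets) != cfg.n_institutions:
        raise ValueError(
            f"cfg.n_institutions={cfg.n_institutions} but "
            f"{len(datasets)} datasets supplied"
        )
    if train_cfg is None:
        train_cfg = rdbn.TrainConfig(local_epochs=cfg.local_epochs,
                                     seed=cfg.seed)
    enc = encoding or FixedPointEncoding()

    authority = KeyAuthority(cfg.key_bits, cfg.seed)
    enc.validate(authority.public_key)
    coordinator = Coordinator(authority.public_key)
    nonce_rng = random.Random(cfg.seed + 1)
    dp_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0xD9]))

    theta = rdbn.get_flat_params(model_template)
    state = CoordinatorState(global_params=theta, round_index=0,
                             n_institutions=cfg.n_institutions)

    for t in range(cfg.rounds):
        t0 = time.perf_counter()
        bytes_down = cfg.n_institutions * len(
            json.dumps(theta.tolist()).encode())
        encrypted, bytes_up = [], 0
        for client in datasets:
            upd = local_train(client, theta, model_template, train_cfg,
                              round_index=t)
            if cfg.dp_enabled:
                upd = add_dp_noise(upd, cfg.dp_noise_level, dp_rng)
            eu = encrypt_update(upd, coordinator.public_key, enc, nonce_rng)
            bytes_up += len(serialize_encrypted_update(eu))
            encrypted.append(eu)
        agg = coordinator.aggregate(encrypted)
        theta_new = decrypt_and_average(agg, authority, enc,
                                        cfg.n_institutions, theta)
        delta_norm = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        g_loss = float(np.mean([
            local_loss(theta, c, model_template) for c in datasets]))
        state.history.append({
            "round": t,
            "global_loss": g_loss,
            "bytes_up": bytes_up,
            "bytes_down": bytes_down,
            "wall_time": time.perf_counter() - t0,
        })
        state.global_params = theta
        state.round_index = t + 1
        if delta_norm < cfg.convergence_tol:
            state.converged = True
            break

    if log_path is not None:
        import csv as _csv
        with open(log_path, "w", newline="") as fh:
            w = _csv.DictWriter(fh, fieldnames=[
                "round", "global_loss", "bytes_up", "bytes_down", "wall_time"])
            w.writeheader()
            w.writerows(state.history)
    return state
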