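"""Partially homomorphic cryptosystems for encrypted federated aggregation.

Implements the Paillier cryptosystem (additively homomorphic: the product of
two ciphertexts decrypts to the sum of the plaintexts) with the simplified
generator g = n + 1, a fixed-point encoding that maps signed real model
weights onto the plaintext ring Z_n so that homomorphic addition acts on
reals, and a textbook-RSA multiplicative demonstration.

Security scope: this is a simulator. Keys down to 128 bits are allowed for
tests, prime search is seeded for reproducibility, and the RSA path is
unpadded. None of this is hardened against side channels or chosen
ciphertexts; do not reuse outside desk-scale experiments.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import dataclass
from typing import Sequence

import sympy

MIN_KEY_BITS = 128

__all__ = [
    "PaillierPublicKey",
    "PaillierKeypair",
    "Ciphertext",
    "FixedPointEncoding",
    "KeyMismatchError",
    "generate_keypair",
    "encrypt",
    "decrypt",
    "homomorphic_add",
    "scalar_multiply",
    "encode_real",
    "decode_real",
    "encrypt_vector",
    "decrypt_vector",
    "RSAKeypair",
    "generate_rsa_keypair",
    "rsa_encrypt",
    "rsa_decrypt",
    "rsa_homomorphic_multiply",
]


class KeyMismatchError(ValueError):
    """Operation mixed ciphertexts or keys with different key identities."""


def _key_id(n: int) -> str:
    return hashlib.sha256(str(n).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PaillierPublicKey:
    """Public half of a Paillier keypair: modulus n and generator g = n + 1."""

    n: int
    g: int
    key_bits: int

    @property
    def n_sq(self) -> int:
        return self.n * self.n

    @property
    def key_id(self) -> str:
        return _key_id(self.n)


@dataclass(frozen=True)
class PaillierKeypair:
    """Paillier public/private material.

    n = p*q for distinct primes p, q of key_bits/2 bits each;
    lam = lcm(p-1, q-1); mu = lam^{-1} mod n (valid because g = n + 1).
    """

    public: PaillierPublicKey
    lam: int
    mu: int

    @property
    def key_id(self) -> str:
        return self.public.key_id

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": str(self.public.n),
                "g": str(self.public.g),
                "lambda": str(self.lam),
                "mu": str(self.mu),
                "key_bits": self.public.key_bits,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PaillierKeypair":
        d = json.loads(payload)
        pub = PaillierPublicKey(int(d["n"]), int(d["g"]), int(d["key_bits"]))
        return cls(public=pub, lam=int(d["lambda"]), mu=int(d["mu"]))


@dataclass(frozen=True)
class Ciphertext:
    """A Paillier ciphertext: an integer in [0, n^2) tagged with its key."""

    value: int
    key_id: str


def _seeded_prime(bits: int, rng: random.Random) -> int:
    """Draw odd candidates of exactly `bits` bits until one is prime."""
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        if sympy.isprime(cand):
            return cand


def generate_keypair(key_bits: int, seed: int) -> PaillierKeypair:
    """Generate a Paillier keypair deterministically from `seed`.

    Parameters
    ----------
    key_bits : size of the modulus n in bits; at least 128. The full-scale
        profile uses 2048; tests use 128-512 to stay fast.
    seed : seeds the prime search so keypairs are reproducible.
    """
    if key_bits < MIN_KEY_BITS:
        raise ValueError(
            f"key_bits must be >= {MIN_KEY_BITS}, got {key_bits}"
        )
    rng = random.Random(seed)
    half = key_bits // 2
    while True:
        p = _seeded_prime(half, rng)
        q = _seeded_prime(half, rng)
        if p == q:
            continue
        n = p * q
        if n.bit_length() == key_bits:
            break
    lam = math.lcm(p - 1, q - 1)
    mu = pow(lam, -1, n)  # L(g^lam mod n^2) = lam when g = n + 1
    pub = PaillierPublicKey(n=n, g=n + 1, key_bits=key_bits)
    return PaillierKeypair(public=pub, lam=lam, mu=mu)


def encrypt(pk: PaillierPublicKey, m: int, nonce_seed: int | None = None,
            rng: random.Random | None = None) -> Ciphertext:
    """Encrypt plaintext m in [0, n): c = (1 + m*n) * r^n mod n^2.

    Probabilistic: a fresh nonce r makes repeated encryptions of one
    plaintext distinct. Pass `nonce_seed` (or a shared `rng`) to make the
    nonce reproducible.
    """
    n = pk.n
    if not 0 <= m < n:
        raise ValueError(f"plaintext out of range [0, n): {m}")
    if rng is None:
        rng = random.Random(nonce_seed)
    while True:
        r = rng.randrange(1, n)
        if math.gcd(r, n) == 1:
            break
    n_sq = pk.n_sq
    # g = n+1 collapses g^m mod n^2 to 1 + m*n
    c = ((1 + m * n) % n_sq) * pow(r, n, n_sq) % n_sq
    return Ciphertext(value=c, key_id=pk.key_id)


def decrypt(kp: PaillierKeypair, c: Ciphertext) -> int:
    """Recover the plaintext: m = L(c^lam mod n^2) * mu mod n."""
    if c.key_id != kp.key_id:
        raise KeyMismatchError(
            f"ciphertext key {c.key_id} does not match keypair {kp.key_id}"
        )
    n = kp.public.n
    u = pow(c.value, kp.lam, kp.public.n_sq)
    ell = (u - 1) // n
    return ell * kp.mu % n


def homomorphic_add(c1: Ciphertext, c2: Ciphertext, pk: PaillierPublicKey) -> Ciphertext:
    """Ciphertext addition: c1*c2 mod n^2 decrypts to (m1 + m2) mod n."""
    if c1.key_id != c2.key_id or c1.key_id != pk.key_id:
        raise KeyMismatchError("cannot add ciphertexts under different keys")
    return Ciphertext(value=c1.value * c2.value % pk.n_sq, key_id=pk.key_id)


def scalar_multiply(c: Ciphertext, k: int, pk: PaillierPublicKey) -> Ciphertext:
    """Plaintext scaling: c^k mod n^2 decrypts to (k*m) mod n; k >= 0."""
    if k < 0:
        raise ValueError(
            "negative scalar not supported; encode negation at the "
            "fixed-point layer"
        )
    if c.key_id != pk.key_id:
        raise KeyMismatchError("ciphertext/key mismatch")
    return Ciphertext(value=pow(c.value, k, pk.n_sq), key_id=pk.key_id)


@dataclass(frozen=True)
class FixedPointEncoding:
    """Signed-real <-> Z_n codec with resolution 1/scale.

    Nonnegative x maps to round(x*scale); negative x to n - round(|x|*scale),
    i.e. the upper half of the residue ring, so Paillier's additive
    homomorphism carries over to signed reals exactly (up to rounding).
    max_abs bounds |x| so that sums of a few encodings never wrap: the
    constructor enforces max_abs * scale < n/3.
    """

    scale: int = 2 ** 32
    max_abs: float = 1e6

    def validate(self, pk: PaillierPublicKey) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.max_abs * self.scale >= pk.n / 3:
            raise ValueError(
                "max_abs * scale must stay below n/3 to leave headroom "
                "for homomorphic sums"
            )


def encode_real(x: float, enc: FixedPointEncoding, pk: PaillierPublicKey) -> int:
    if not math.isfinite(x) or abs(x) > enc.max_abs:
        raise ValueError(f"value {x} exceeds encoding bound {enc.max_abs}")
    m = round(x * enc.scale)
    return m % pk.n


def decode_real(m: int, enc: FixedPointEncoding, pk: PaillierPublicKey) -> float:
    n = pk.n
    if m >= (n + 1) // 2:
        m -= n
    return m / enc.scale


def encrypt_vector(pk: PaillierPublicKey, xs: Sequence[float],
                   enc: FixedPointEncoding,
                   rng: random.Random | None = None,
                   nonce_seed: int | None = None) -> list[Ciphertext]:
    """Element-wise fixed-point encrypt; errors carry the offending index."""
    if rng is None:
        rng = random.Random(nonce_seed)
    out = []
    for i, x in enumerate(xs):
        try:
            out.append(encrypt(pk, encode_real(x, enc, pk), rng=rng))
        except ValueError as exc:
            raise ValueError(f"element {i}: {exc}") from exc
    return out


def decrypt_vector(kp: PaillierKeypair, cs: Sequence[Ciphertext],
                   enc: FixedPointEncoding) -> list[float]:
    out = []
    for i, c in enumerate(cs):
        try:
            out.append(decode_real(decrypt(kp, c), enc, kp.public))
        except KeyMismatchError as exc:
            raise KeyMismatchError(f"element {i}: {exc}") from exc
    return out


# --- textbook RSA: multiplicative homomorphism demonstration only ----------
#
# Unpadded RSA so that E(m1)*E(m2) mod n = E(m1*m2). Insecure by design;
# exists to exhibit the multiplicative counterpart of Paillier's additive
# law and is never used in the federated pipeline.

@dataclass(frozen=True)
class RSAKeypair:
    n: int
    e: int
    d: int

    @property
    def key_id(self) -> str:
        return _key_id(self.n)


def generate_rsa_keypair(key_bits: int = 512, seed: int = 0) -> RSAKeypair:
    rng = random.Random(seed)
    e = 65537
    while True:
        p = _seeded_prime(key_bits // 2, rng)
        q = _seeded_prime(key_bits // 2, rng)
        if p == q:
            continue
        phi = (p - 1) * (q - 1)
        if math.gcd(e, phi) == 1:
            break
    return RSAKeypair(n=p * q, e=e, d=pow(e, -1, phi))


def rsa_encrypt(kp: RSAKeypair, m: int) -> Ciphertext:
    if not 0 <= m < kp.n:
        raise ValueError("plaintext out of range")
    return Ciphertext(value=pow(m, kp.e, kp.n), key_id=kp.key_id)


def rsa_decrypt(kp: RSAKeypair, c: Ciphertext) -> int:
    if c.key_id != kp.key_id:
        raise KeyMismatchError("ciphertext/key mismatch")
    return pow(c.value, kp.d, kp.n)


def rsa_homomorphic_multiply(c1: Ciphertext, c2: Ciphertext,
                             kp: RSAKeypair) -> Ciphertext:
    """c1*c2 mod n decrypts to (m1*m2) mod n under unpadded RSA."""
    if c1.key_id != c2.key_id or c1.key_id != kp.key_id:
        raise KeyMismatchError("cannot multiply ciphertexts under different keys")
    return Ciphertext(value=c1.value * c2.value % kp.n, key_id=kp.key_id)
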