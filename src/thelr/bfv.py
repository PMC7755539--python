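"""Threshold-variant BFV scheme.

One combined public key corresponds to additive ternary secret shares held
by z parties; decryption requires a partial share from every party (full
threshold).  On top of the textbook Fan-Vercauteren operations this module
implements the multi-round combined relinearization-key generation protocol:
the parties encrypt their param1 secret shares under a second parameter set
(param2) whose per-ciphertext plaintext moduli are the primes of param1's
coefficient modulus, the service provider assembles the key homomorphically,
and a threshold decryption reveals nothing but the key itself.

Sign conventions: pk_i = -(a·s_i + e_i), c = (pk0·u + e1 + Δm, pk1·u + e2),
relin level l holds (-(a_l·s + e_l) + B^l·s², a_l) with digit base B = 2^T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ring import (
    ConfigurationError,
    ModulusChain,
    RingElement,
    SamplerSpec,
    derive_rng,
    ntt_friendly_primes,
    ring_add,
    ring_mul,
    ring_neg,
    ring_sub,
    sample_gaussian_coeffs,
    sample_ternary_coeffs,
    sample_uniform_element,
    scale_round_ints,
)

SMUDGE_SECURITY_BITS = 40   # statistical security of smudging / masking noise


class ProtocolError(RuntimeError):
    pass


class DecryptionIntegrityError(RuntimeError):
    """Noise overflow detected in a debug-mode decryption."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class EncryptionParams:
    label: str                 # "param1" | "param2" (+ profile suffix)
    n: int
    q: ModulusChain
    t_chain: ModulusChain      # param1: batching chain; param2: param1's q
    key_dist: SamplerSpec
    err_dist: SamplerSpec
    decomp_bits_T: int = 60
    security_bits: int = 0     # claimed level; 0 = not for production
    production: bool = False

    @property
    def t(self) -> int:
        return self.t_chain.modulus

    @property
    def relin_size_L(self) -> int:
        return (self.q.total_bits - 1) // self.decomp_bits_T

    @property
    def delta(self) -> int:
        return self.q.modulus // self.t

    def __post_init__(self):
        if self.n != self.q.n:
            raise ConfigurationError("ring degree mismatch: n != q.n")
        # aux primes for the extended tensor basis (exact multiplication)
        need = 2 * self.q.total_bits + self.n.bit_length() + 4
        aux_bits = []
        have = self.q.total_bits
        while have < need:
            aux_bits.append(30 if self.n <= (1 << 24) else 40)
            have += aux_bits[-1]
        aux = ntt_friendly_primes(self.n, aux_bits, exclude=self.q.primes)
        self._ext = ModulusChain(tuple(self.q.primes) + tuple(aux), self.n)
        self._fresh_noise_bits = math.log2(
            4 * self.n * 6 * self.err_dist.sigma + self.t + 1)

    def to_dict(self) -> dict:
        return {
            "label": self.label, "n": self.n,
            "q_primes": list(self.q.primes),
            "t_primes": list(self.t_chain.primes),
            "t_n": self.t_chain.n,
            "sigma": self.err_dist.sigma,
            "decomp_bits_T": self.decomp_bits_T,
            "security_bits": self.security_bits,
            "production": self.production,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncryptionParams":
        return cls(label=d["label"], n=d["n"],
                   q=ModulusChain(d["q_primes"], d["n"]),
                   t_chain=ModulusChain(d["t_primes"], d["t_n"]),
                   key_dist=SamplerSpec("ternary"),
                   err_dist=SamplerSpec("gaussian", d["sigma"]),
                   decomp_bits_T=d["decomp_bits_T"],
                   security_bits=d["security_bits"],
                   production=d["production"])

    def __eq__(self, other):
        return isinstance(other, EncryptionParams) and self.to_dict() == other.to_dict()


_PROFILES = {
    # Reference parameter set: n=16384; q1 a 438-bit product of 8 primes,
    # q2 a 300-bit product of 5 primes (each ≤ 60 bits, ≡ 1 mod 2n);
    # t1 the 50-bit batching prime 1125899904679937.
    "reference": dict(n=16384, q1_bits=[55] * 6 + [54] * 2, t1=1125899904679937,
                      q2_bits=[60] * 5, T=60, sec1=128, sec2=192,
                      production=True),
    # Desk-scale profile (NOT for production): same structural constraints,
    # 30-bit primes so residue arithmetic stays in int64.  t1 is a product of
    # two 28-bit NTT-friendly primes (the congruence condition allows a
    # squarefree composite), large enough to carry the integerized gradients.
    "test": dict(n=4096, q1_bits=[30] * 15, t1_bits=[28, 28],
                 q2_bits=[30] * 7, T=60, sec1=0, sec2=0, production=False),
    # Minimal profile for unit tests and the relin-noise study.
    "tiny": dict(n=1024, q1_bits=[28] * 6, t1_bits=[22],
                 q2_bits=[28] * 7, T=28, sec1=0, sec2=0, production=False),
    # Reduced-degree profile that still carries the full training plaintext
    # scale (t ≈ 2^56): quick end-to-end protocol runs.
    "mini": dict(n=1024, q1_bits=[30] * 15, t1_bits=[28, 28],
                 q2_bits=[30] * 7, T=60, sec1=0, sec2=0, production=False),
}
_PARAM_CACHE: dict[str, tuple] = {}


def setup_params(profile: str = "test") -> tuple[EncryptionParams, EncryptionParams]:
    """Build (param1, param2).

    param1 carries the batched logistic-regression arithmetic; param2 exists
    solely to generate param1's relinearization key, so its per-ciphertext
    plaintext moduli are the primes of param1's coefficient modulus and the
    two rings share one degree.
    """
    if profile in _PARAM_CACHE:
        return _PARAM_CACHE[profile]
    if profile not in _PROFILES:
        raise ConfigurationError(f"unknown parameter profile {profile!r}")
    cfg = _PROFILES[profile]
    n = cfg["n"]
    q1 = ModulusChain(ntt_friendly_primes(n, cfg["q1_bits"]), n)
    if "t1" in cfg:
        t1 = ModulusChain([cfg["t1"]], n)
    else:
        t1 = ModulusChain(
            ntt_friendly_primes(n, cfg["t1_bits"], exclude=q1.primes), n)
    q2 = ModulusChain(
        ntt_friendly_primes(n, cfg["q2_bits"],
                            exclude=q1.primes + t1.primes), n)
    key = SamplerSpec("ternary")
    err = SamplerSpec("gaussian", 3.2)
    p1 = EncryptionParams(f"param1-{profile}", n, q1, t1, key, err,
                          cfg["T"], cfg["sec1"], cfg["production"])
    p2 = EncryptionParams(f"param2-{profile}", n, q2, q1, key, err,
                          cfg["T"], cfg["sec2"], cfg["production"])
    validate_param_pair(p1, p2)
    _PARAM_CACHE[profile] = (p1, p2)
    return p1, p2


def validate_param_pair(p1: EncryptionParams, p2: EncryptionParams) -> None:
    if p1.n != p2.n:
        raise ConfigurationError("param1/param2 polynomial moduli must share one degree")
    if p2.t_chain != p1.q:
        raise ConfigurationError(
            "param2 plaintext modulus must equal param1 coefficient modulus")
    if p1.t % (2 * p1.n) != 1:
        raise ConfigurationError("param1 plaintext modulus violates t ≡ 1 (mod 2n)")


# ---------------------------------------------------------------------------
# keys
# ---------------------------------------------------------------------------

@dataclass
class CommonReference:
    a: RingElement             # uniform in R_q, NTT domain
    seed: int
    label: str


@dataclass
class PartyKeyMaterial:
    party_id: str
    s: RingElement             # ternary secret share (coef domain)
    s_ntt: RingElement
    pk_share: RingElement      # -(a·s + e), NTT domain
    label: str


@dataclass
class CombinedPublicKey:
    pk0: RingElement           # Σ pk_shares, NTT domain
    pk1: RingElement           # the common a, NTT domain
    z: int
    label: str


@dataclass
class RelinKey:
    levels: list               # [(r0, r1)] of NTT-domain RingElements, L+1 entries
    decomp_bits_T: int
    label: str


def keygen_common(params: EncryptionParams, seed: int) -> CommonReference:
    rng = derive_rng(seed, "crs", params.label)
    a = sample_uniform_element(params.q, rng).to_ntt()
    return CommonReference(a, seed, params.label)


def keygen_party(params: EncryptionParams, common: CommonReference,
                 party_id: str, rng: np.random.Generator) -> PartyKeyMaterial:
    s = RingElement.from_signed(sample_ternary_coeffs(params.n, rng), params.q)
    e = RingElement.from_signed(
        sample_gaussian_coeffs(params.n, rng, params.err_dist.sigma), params.q)
    s_ntt = s.to_ntt()
    prod = RingElement((common.a.residues * s_ntt.residues) % params.q._p_arr,
                       params.q, "ntt")
    pk_share = ring_neg(ring_add(prod, e.to_ntt()))
    return PartyKeyMaterial(party_id, s, s_ntt, pk_share, params.label)


def combine_public_keys(shares: Sequence[PartyKeyMaterial],
                        common: CommonReference) -> CombinedPublicKey:
    pk0 = shares[0].pk_share
    for sh in shares[1:]:
        pk0 = ring_add(pk0, sh.pk_share)
    return CombinedPublicKey(pk0, common.a, len(shares), common.label)


def combined_secret(shares: Sequence[PartyKeyMaterial]) -> RingElement:
    """Debug-only: s_co = Σ s_i (never materialized by any protocol party)."""
    s = shares[0].s
    for sh in shares[1:]:
        s = ring_add(s, sh.s)
    return s


# ---------------------------------------------------------------------------
# ciphertexts
# ---------------------------------------------------------------------------

@dataclass
class Ciphertext:
    parts: list                # RingElements on params.q, coef domain
    params: EncryptionParams
    t: int                     # plaintext modulus of this ciphertext
    noise_bits: float          # running upper-bound estimate, log2

    @property
    def size(self) -> int:
        return len(self.parts)

    def copy(self) -> "Ciphertext":
        return Ciphertext([p.copy() for p in self.parts], self.params,
                          self.t, self.noise_bits)


def _scalar_poly_rns(scalar: int, coeffs: np.ndarray,
                     chain: ModulusChain) -> np.ndarray:
    """(scalar · coeffs) reduced per prime; coeffs signed ints (any size)."""
    rows = chain.decompose(np.asarray(coeffs, dtype=object))
    out = np.empty_like(rows)
    for i, p in enumerate(chain.primes):
        out[i] = (rows[i] * (scalar % p)) % p
    return out


def encrypt(m_coeffs, pk: CombinedPublicKey, params: EncryptionParams,
            rng: np.random.Generator, t: int | None = None,
            extra_noise_bits: float = 0.0) -> Ciphertext:
    """THE.encrypt: c = (pk0·u + e1 + Δ·m, pk1·u + e2), fresh size 2.

    ``m_coeffs``: signed plaintext coefficients mod t (array of ints), or a
    plaintext RingElement on params.t_chain.  ``t`` overrides the plaintext
    modulus (one prime of param1's q during relinearization keygen).
    ``extra_noise_bits`` adds centered-uniform noise of that bit size to e1
    (function-privacy encryptions of zero).
    """
    if isinstance(m_coeffs, RingElement):
        m_coeffs = m_coeffs.centered()
    else:
        m_coeffs = np.asarray(m_coeffs, dtype=object)
    tval = int(t if t is not None else params.t)
    half = (tval - 1) // 2
    if np.any(np.abs(m_coeffs) > half + 1):
        raise ConfigurationError("plaintext not reduced mod t")
    q = params.q
    delta = q.modulus // tval
    u = RingElement.from_signed(sample_ternary_coeffs(params.n, rng), q).to_ntt()
    sigma = params.err_dist.sigma
    e1 = q.decompose(sample_gaussian_coeffs(params.n, rng, sigma))
    e2 = q.decompose(sample_gaussian_coeffs(params.n, rng, sigma))
    if extra_noise_bits > 0:
        e1 = (e1 + _sample_bounded_rns(q, extra_noise_bits, rng)) % q._p_arr
    dm = _scalar_poly_rns(delta, m_coeffs, q)
    c0 = (q.ntt_inverse((pk.pk0.residues * u.residues) % q._p_arr)
          + e1 + dm) % q._p_arr
    c1 = (q.ntt_inverse((pk.pk1.residues * u.residues) % q._p_arr)
          + e2) % q._p_arr
    noise = math.log2(4 * params.n * 6 * sigma * max(pk.z, 1) + tval + 1)
    if extra_noise_bits > 0:
        noise = float(np.logaddexp2(noise, extra_noise_bits + 1))
    return Ciphertext([RingElement(c0, q, "coef"), RingElement(c1, q, "coef")],
                      params, tval, noise)


def encrypt_zero(pk: CombinedPublicKey, params: EncryptionParams,
                 rng: np.random.Generator, t: int | None = None,
                 extra_noise_bits: float = 0.0) -> Ciphertext:
    return encrypt(np.zeros(params.n, dtype=object), pk, params, rng,
                   t=t, extra_noise_bits=extra_noise_bits)


def _sample_bounded_rns(chain: ModulusChain, bits: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Centered uniform noise over [-2^b, 2^b), sampled directly in RNS from
    32-bit words (a power-of-two span needs no big-int reduction)."""
    m = int(bits) + 1                      # raw value uniform in [0, 2^m)
    words = (m + 31) // 32
    draws = rng.integers(0, 1 << 32, size=(words, chain.n), dtype=np.int64)
    top = m - 32 * (words - 1)
    draws[-1] &= (1 << top) - 1
    offset = 1 << (m - 1)
    out = np.zeros((len(chain.primes), chain.n), dtype=chain.dtype)
    for i, p in enumerate(chain.primes):
        acc = np.zeros(chain.n, dtype=np.int64 if chain.dtype is not object else object)
        for w in range(words):
            acc = (acc + (draws[w] % p) * pow(2, 32 * w, p)) % p
        out[i] = (acc - offset % p) % p
    return out


# -- homomorphic evaluation -------------------------------------------------

def _compat(c1: Ciphertext, c2: Ciphertext):
    if c1.params.label != c2.params.label or c1.t != c2.t:
        raise ConfigurationError("ciphertext parameter mismatch")


def he_add(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    _compat(c1, c2)
    n = max(c1.size, c2.size)
    parts = []
    for i in range(n):
        if i < c1.size and i < c2.size:
            parts.append(ring_add(c1.parts[i], c2.parts[i]))
        else:
            parts.append((c1.parts[i] if i < c1.size else c2.parts[i]).copy())
    return Ciphertext(parts, c1.params, c1.t,
                      float(np.logaddexp2(c1.noise_bits, c2.noise_bits)))


def he_sub(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    _compat(c1, c2)
    parts = [ring_sub(c1.parts[i], c2.parts[i]) for i in range(c1.size)]
    return Ciphertext(parts, c1.params, c1.t,
                      float(np.logaddexp2(c1.noise_bits, c2.noise_bits)))


def he_neg(c: Ciphertext) -> Ciphertext:
    return Ciphertext([ring_neg(p) for p in c.parts], c.params, c.t, c.noise_bits)


def he_add_plain(c: Ciphertext, m_coeffs) -> Ciphertext:
    """c + Δ·m for a plaintext polynomial m (signed coefficients mod t)."""
    q = c.params.q
    delta = q.modulus // c.t
    dm = _scalar_poly_rns(delta, m_coeffs, q)
    c0 = RingElement((c.parts[0].to_coef().residues + dm) % q._p_arr, q, "coef")
    return Ciphertext([c0] + [p.copy() for p in c.parts[1:]], c.params, c.t,
                      c.noise_bits + 0.1)


def he_mul_plain(c: Ciphertext, plain_coeffs) -> Ciphertext:
    """Multiply by a plaintext polynomial (ring product mod t slot-free, or
    slot-wise product when both are CRT-batched)."""
    q = c.params.q
    plain = np.asarray(plain_coeffs, dtype=object)
    norm = int(np.max(np.abs(plain))) if plain.size else 0
    pe = RingElement(q.decompose(plain), q, "coef").to_ntt()
    parts = [RingElement((p.to_ntt().residues * pe.residues) % q._p_arr,
                         q, "ntt") for p in c.parts]
    extra = math.log2(c.params.n * max(norm, 1) + 1)
    return Ciphertext(parts, c.params, c.t, c.noise_bits + extra)


def he_scalar_mul(c: Ciphertext, scalar: int) -> Ciphertext:
    """Multiply every slot/coefficient by an integer constant mod t."""
    q = c.params.q
    sc = int(scalar) % c.t
    if sc > c.t // 2:
        sc -= c.t
    parts = []
    for p in c.parts:
        res = np.empty_like(p.residues)
        for i, pr in enumerate(q.primes):
            res[i] = (p.residues[i] * (sc % pr)) % pr
        parts.append(RingElement(res, q, p.domain))
    return Ciphertext(parts, c.params, c.t,
                      c.noise_bits + math.log2(abs(sc) + 2))


def _lift_to_ext(elem: RingElement, params: EncryptionParams) -> np.ndarray:
    """Centered lift of a mod-q element into the extended tensor basis."""
    ext = params._ext
    k = len(params.q.primes)
    big = elem.centered()
    out = np.empty((len(ext.primes), params.n), dtype=ext.dtype)
    out[:k] = elem.to_coef().residues
    for i in range(k, len(ext.primes)):
        out[i] = (big % ext.primes[i]).astype(ext.dtype)
    return out


def he_mul(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    """Homomorphic multiplication (size-2 × size-2 → size-3).

    The (t/q)-scaled tensor product is evaluated exactly: operands are
    centered-lifted into an extended RNS basis large enough to hold the
    integer tensor, multiplied with NTTs, CRT-composed, scaled by t/q with
    exact rational rounding, and reduced back into the base chain.
    """
    _compat(c1, c2)
    if c1.size != 2 or c2.size != 2:
        raise ConfigurationError("he_mul expects size-2 ciphertexts")
    params = c1.params
    ext, q = params._ext, params.q
    a = [RingElement(_lift_to_ext(p, params), ext, "coef").to_ntt()
         for p in c1.parts]
    b = [RingElement(_lift_to_ext(p, params), ext, "coef").to_ntt()
         for p in c2.parts]
    pa = ext._p_arr
    t00 = (a[0].residues * b[0].residues) % pa
    t01 = (a[0].residues * b[1].residues + a[1].residues * b[0].residues) % pa
    t11 = (a[1].residues * b[1].residues) % pa
    parts = []
    for tens in (t00, t01, t11):
        coef = RingElement(tens, ext, "ntt").to_coef()
        big = ext.compose(coef.residues, centered=True)
        scaled = scale_round_ints(big, c1.t, q.modulus)
        parts.append(RingElement.from_signed(scaled, q))
    noise = (math.log2(params.n) + math.log2(c1.t)
             + max(c1.noise_bits, c2.noise_bits) + 2)
    return Ciphertext(parts, params, c1.t, noise)


# -- relinearization --------------------------------------------------------

def relin_keygen_single(params: EncryptionParams, s: RingElement,
                        rng: np.random.Generator) -> RelinKey:
    """Single-key reference path: rlk_l = (-(a_l·s + e_l) + B^l·s², a_l)."""
    q = params.q
    s_ntt = s.to_ntt()
    s2_ntt = RingElement((s_ntt.residues * s_ntt.residues) % q._p_arr, q, "ntt")
    B = 1 << params.decomp_bits_T
    levels = []
    for l in range(params.relin_size_L + 1):
        a_l = sample_uniform_element(q, rng).to_ntt()
        e_l = RingElement.from_signed(
            sample_gaussian_coeffs(params.n, rng, params.err_dist.sigma),
            q).to_ntt()
        bl = pow(B, l, q.modulus)
        bl_s2 = np.empty_like(s2_ntt.residues)
        for i, p in enumerate(q.primes):
            bl_s2[i] = (s2_ntt.residues[i] * (bl % p)) % p
        r0 = ring_sub(RingElement(bl_s2, q, "ntt"),
                      ring_add(RingElement((a_l.residues * s_ntt.residues)
                                           % q._p_arr, q, "ntt"), e_l))
        levels.append((r0, a_l))
    return RelinKey(levels, params.decomp_bits_T, params.label)


def _digit_decompose(elem: RingElement, params: EncryptionParams) -> list[np.ndarray]:
    """Base-2^T digits of the unsigned lift, each digit in RNS form (k, n)."""
    q = params.q
    T, L = params.decomp_bits_T, params.relin_size_L
    big = q.compose(elem.to_coef().residues, centered=False)
    # 30-bit words keep the per-prime reduction in int64
    nwords = (q.total_bits + 29) // 30
    words = np.empty((nwords, params.n), dtype=np.int64)
    mask = (1 << 30) - 1
    cur = big
    for w in range(nwords):
        words[w] = (cur & mask).astype(np.int64)
        cur = cur >> 30
    wt = T // 30 if T % 30 == 0 else None
    digits = []
    for l in range(L + 1):
        if wt is not None:
            chunk = words[l * wt:(l + 1) * wt]
            rows = np.empty((len(q.primes), params.n), dtype=q.dtype)
            for i, p in enumerate(q.primes):
                acc = np.zeros(params.n, dtype=np.int64)
                for w in range(chunk.shape[0]):
                    acc = (acc + (chunk[w] % p) * pow(2, 30 * w, p)) % p
                rows[i] = acc
            digits.append(rows)
        else:
            dig = (big >> (T * l)) & ((1 << T) - 1)
            digits.append(q.decompose(dig))
    return digits


def relinearize(c: Ciphertext, rlk: RelinKey) -> Ciphertext:
    """Reduce a size-3 ciphertext to size 2 decrypting to the same plaintext."""
    if rlk is None:
        raise ProtocolError("relinearization key missing")
    if c.size != 3:
        raise ProtocolError("relinearize expects a size-3 ciphertext")
    params = c.params
    q = params.q
    digits = _digit_decompose(c.parts[2], params)
    acc0 = np.zeros((len(q.primes), params.n), dtype=q.dtype)
    acc1 = np.zeros_like(acc0)
    for l, (r0, r1) in enumerate(rlk.levels):
        d_ntt = q.ntt_forward(digits[l])
        acc0 = (acc0 + d_ntt * r0.residues) % q._p_arr
        acc1 = (acc1 + d_ntt * r1.residues) % q._p_arr
    c0 = RingElement((c.parts[0].to_coef().residues
                      + q.ntt_inverse(acc0)) % q._p_arr, q, "coef")
    c1 = RingElement((c.parts[1].to_coef().residues
                      + q.ntt_inverse(acc1)) % q._p_arr, q, "coef")
    added = (rlk.decomp_bits_T + math.log2(params.n)
             + math.log2(len(rlk.levels)) + 6)
    return Ciphertext([c0, c1], params, c.t,
                      float(np.logaddexp2(c.noise_bits, added)))


def he_mul_relin(c1: Ciphertext, c2: Ciphertext, rlk: RelinKey) -> Ciphertext:
    return relinearize(he_mul(c1, c2), rlk)


def encrypt_many(m_list, pk: CombinedPublicKey, params: EncryptionParams,
                 rng: np.random.Generator, t: int | None = None) -> list:
    """Encrypt a batch of plaintexts under one key (NTTs amortized)."""
    q = params.q
    b = len(m_list)
    tval = int(t if t is not None else params.t)
    delta = q.modulus // tval
    ms = []
    for m in m_list:
        mc = m.centered() if isinstance(m, RingElement) else np.asarray(m, dtype=object)
        ms.append(mc)
    p_col = np.array(q.primes, dtype=np.int64).reshape(-1, 1, 1)
    u = rng.integers(-1, 2, size=(b, params.n))
    u_rns = u[None, :, :] % p_col
    u_ntt = q.ntt_forward(u_rns)
    sigma = params.err_dist.sigma
    e1 = sample_gaussian_coeffs(b * params.n, rng, sigma).reshape(b, params.n)
    e2 = sample_gaussian_coeffs(b * params.n, rng, sigma).reshape(b, params.n)
    c0 = (q.ntt_inverse((pk.pk0.residues[:, None, :] * u_ntt) % p_col)
          + e1[None, :, :]) % p_col
    c1 = (q.ntt_inverse((pk.pk1.residues[:, None, :] * u_ntt) % p_col)
          + e2[None, :, :]) % p_col
    noise = math.log2(4 * params.n * 6 * sigma * max(pk.z, 1) + tval + 1)
    out = []
    for j in range(b):
        dm = _scalar_poly_rns(delta, ms[j], q)
        cj0 = RingElement((c0[:, j, :] + dm) % q._p_arr, q, "coef")
        cj1 = RingElement(c1[:, j, :].copy(), q, "coef")
        out.append(Ciphertext([cj0, cj1], params, tval, noise))
    return out


# -- threshold decryption ---------------------------------------------------

@dataclass
class PartialDecryption:
    party_id: str
    mu: RingElement            # c1·s_i + e_smudge (coef domain)
    smudge_bits: float


def smudge_bits_for(c: Ciphertext) -> float:
    """Smudging size: ciphertext-noise bound plus the statistical margin, so
    var_c / var_smg ≤ 2^-2·SMUDGE_SECURITY_BITS."""
    return c.noise_bits + SMUDGE_SECURITY_BITS


def partial_decrypt(c: Ciphertext, key: PartyKeyMaterial,
                    rng: np.random.Generator,
                    smudge_bits: float | None = None) -> PartialDecryption:
    if c.size != 2:
        raise ProtocolError("threshold decryption requires a size-2 ciphertext")
    q = c.params.q
    sb = smudge_bits if smudge_bits is not None else smudge_bits_for(c)
    c1_ntt = c.parts[1].to_ntt()
    mu = q.ntt_inverse((c1_ntt.residues * key.s_ntt.residues) % q._p_arr)
    mu = (mu + _sample_bounded_rns(q, sb, rng)) % q._p_arr
    return PartialDecryption(key.party_id, RingElement(mu, q, "coef"), sb)


_DEC_TABLE_CACHE: dict = {}


def _dec_tables(q: ModulusChain, t_primes: tuple[int, ...]):
    """Per-prime tables for the int64 scale-round ⌊t·w/q⌉ mod t.

    With w = Σ w_i·(q/q_i)·inv_i − αq and t·inv_i = A_i·q_i + R_i:
    ⌊t·w/q⌉ ≡ Σ w_i·A_i + ⌊Σ w_i·R_i/q_i⌉ (mod t); the fractional sum fits
    comfortably in float64 because w_i < 2^31 and rounding-boundary distance
    is governed by the (much larger) noise margin.
    """
    key = (q.primes, t_primes)
    if key in _DEC_TABLE_CACHE:
        return _DEC_TABLE_CACHE[key]
    t = 1
    for tp in t_primes:
        t *= tp
    A = []
    Rfrac = np.empty(len(q.primes), dtype=np.float64)
    for i, qi in enumerate(q.primes):
        inv = pow(q.modulus // qi, -1, qi)
        A.append(t * inv // qi)
        Rfrac[i] = float(t * inv % qi) / qi
    A_mod = np.array([[a % tp for a in A] for tp in t_primes], dtype=np.int64)
    _DEC_TABLE_CACHE[key] = (A_mod, Rfrac, t)
    return _DEC_TABLE_CACHE[key]


def _t_prime_factors(c: Ciphertext) -> tuple[int, ...] | None:
    if c.t == c.params.t:
        return c.params.t_chain.primes
    if c.t in c.params.t_chain.primes:
        return (c.t,)
    return None


def _fast_scale_round(acc: np.ndarray, q: ModulusChain,
                      t_primes: tuple[int, ...]) -> np.ndarray:
    A_mod, Rfrac, t = _dec_tables(q, t_primes)
    v = np.rint(Rfrac @ acc.astype(np.float64)).astype(np.int64)
    res = []
    for j, tp in enumerate(t_primes):
        m = v % tp
        for i in range(len(q.primes)):
            m = (m + acc[i] * A_mod[j, i]) % tp
        res.append(m)
    # Garner recombination (t < 2^62 in every int64 profile)
    x = res[0].astype(np.int64)
    mod = t_primes[0]
    for j in range(1, len(t_primes)):
        tp = t_primes[j]
        inv = pow(mod % tp, -1, tp)
        diff = ((res[j] - x % tp) * inv) % tp
        x = x + mod * diff
        mod *= tp
    half = t >> 1
    return np.where(x > half, x - t, x)


def combine_decrypt(c: Ciphertext, shares: Sequence[PartialDecryption],
                    expected_parties: int | None = None,
                    exact: bool = False) -> np.ndarray:
    """⌊(t/q)·(c0 + Σ μ_i)⌉ mod t, centered.  Requires all z shares.

    ``exact=True`` forces the multiprecision reference path; the default
    uses the int64 RNS path when the parameter profile allows it.
    """
    if expected_parties is not None and len(shares) != expected_parties:
        raise ProtocolError(
            f"full-threshold decryption needs {expected_parties} shares, "
            f"got {len(shares)}")
    q = c.params.q
    acc = c.parts[0].to_coef().residues
    for sh in shares:
        acc = (acc + sh.mu.residues) % q._p_arr
    tp = _t_prime_factors(c)
    if not exact and q.dtype is not object and tp is not None \
            and max(tp) < (1 << 31) and c.t < (1 << 62):
        return _fast_scale_round(acc, q, tp)
    big = q.compose(acc, centered=True)
    m = scale_round_ints(big, c.t, q.modulus) % c.t
    half = c.t >> 1
    return np.where(m > half, m - c.t, m)


def partial_decrypt_many(cts: Sequence[Ciphertext], key: PartyKeyMaterial,
                         rng: np.random.Generator) -> list[PartialDecryption]:
    """Batched partial decryption of several size-2 ciphertexts."""
    q = cts[0].params.q
    stack = np.stack([c.parts[1].to_ntt().residues for c in cts], axis=1)
    prod = (stack * key.s_ntt.residues[:, None, :]) % \
        np.array(q.primes, dtype=np.int64).reshape(-1, 1, 1)
    mu = q.ntt_inverse(prod)
    out = []
    for j, c in enumerate(cts):
        sb = smudge_bits_for(c)
        res = (mu[:, j, :] + _sample_bounded_rns(q, sb, rng)) % q._p_arr
        out.append(PartialDecryption(key.party_id,
                                     RingElement(res, q, "coef"), sb))
    return out


def decrypt_with_secret(c: Ciphertext, s: RingElement) -> np.ndarray:
    """Debug path: decrypt any-size ciphertext directly under s (= s_co)."""
    q = c.params.q
    s_ntt = s.to_ntt()
    acc = c.parts[0].to_coef().residues.copy()
    spow = None
    for i, part in enumerate(c.parts[1:], start=1):
        spow = s_ntt if spow is None else RingElement(
            (spow.residues * s_ntt.residues) % q._p_arr, q, "ntt")
        acc = (acc + q.ntt_inverse((part.to_ntt().residues * spow.residues)
                                   % q._p_arr)) % q._p_arr
    big = q.compose(acc, centered=True)
    m = scale_round_ints(big, c.t, q.modulus) % c.t
    half = c.t >> 1
    return np.where(m > half, m - c.t, m)


def measure_invariant_noise(c: Ciphertext, s: RingElement) -> float:
    """Remaining noise headroom in bits (debug; needs the combined secret).

    Positive budget ⇒ decryption succeeds; the budget shrinks along a
    multiplication chain.
    """
    q = c.params.q
    s_ntt = s.to_ntt()
    acc = c.parts[0].to_coef().residues.copy()
    spow = None
    for part in c.parts[1:]:
        spow = s_ntt if spow is None else RingElement(
            (spow.residues * s_ntt.residues) % q._p_arr, q, "ntt")
        acc = (acc + q.ntt_inverse((part.to_ntt().residues * spow.residues)
                                   % q._p_arr)) % q._p_arr
    w = q.compose(acc, centered=True)
    t, Q = c.t, q.modulus
    m = scale_round_ints(w, t, Q)
    frac = t * w - Q * m                     # |frac| ≤ Q/2; noise = frac/(t·q) rel.
    worst = int(np.max(np.abs(frac)))
    if worst == 0:
        return float(Q.bit_length() - math.log2(2 * t))
    # integer-noise magnitude e with w = Δm + e  ->  e ≈ frac / t
    noise_mag = max(worst // t, 1)
    return math.log2(Q / (2 * t)) - math.log2(noise_mag)


# ---------------------------------------------------------------------------
# combined relinearization-key generation protocol
# ---------------------------------------------------------------------------

def relin_keygen_protocol(parties1: Sequence[PartyKeyMaterial],
                          parties2: Sequence[PartyKeyMaterial],
                          params1: EncryptionParams,
                          params2: EncryptionParams,
                          pk2_co: CombinedPublicKey,
                          master_seed: int) -> RelinKey:
    """Multi-round generation of the combined relinearization key.

    Per prime p_j of param1's coefficient modulus (j = 1..k):
      1. each party encrypts its param1 secret share s1_i mod p_j under
         pk2_co (plain polynomial plaintexts, not batched);
      2. the service provider sums them into c_j(s1_co);
      3. each party multiplies c_j(s1_co) by its own s1_i in plaintext and
         adds an encryption of zero with large noise (function privacy);
         the service provider sums the returns into c_j(s1_co²);
      4. per level l the service provider forms
         c_j(rlk_l0) = B^l·c_j(s1_co²) − a_l·c_j(s1_co) − Σ_i c_j(e_il);
      5. all parties threshold-decrypt under their param2 shares; the
         per-prime plaintexts are the RNS rows of rlk_l0 ∈ R_q1.
    """
    validate_param_pair(params1, params2)
    z = len(parties1)
    if len(parties2) != z:
        raise ProtocolError("every party needs key material under both parameter sets")
    k = len(params1.q.primes)
    L = params1.relin_size_L
    B = 1 << params1.decomp_bits_T
    sp_rng = derive_rng(master_seed, "relin", "sp")

    # step 1-2: ciphertexts of the combined secret, one per param1 prime
    c_s = []
    for j, pj in enumerate(params1.q.primes):
        acc = None
        for i, pkm in enumerate(parties1):
            rng = derive_rng(master_seed, "relin", "enc-s", i, j)
            ct = encrypt(pkm.s.centered(), pk2_co, params2, rng, t=pj)
            acc = ct if acc is None else he_add(acc, ct)
        c_s.append(acc)

    # step 3: shares of the encrypted square, function-privacy noise included
    c_sq = []
    for j, pj in enumerate(params1.q.primes):
        acc = None
        for i, pkm in enumerate(parties1):
            rng = derive_rng(master_seed, "relin", "sq", i, j)
            prod = he_mul_plain(c_s[j], pkm.s.centered())
            fp_bits = prod.noise_bits + SMUDGE_SECURITY_BITS
            prod = he_add(prod, encrypt_zero(pk2_co, params2, rng, t=pj,
                                             extra_noise_bits=fp_bits))
            acc = prod if acc is None else he_add(acc, prod)
        c_sq.append(acc)

    # step 4: assemble each level under encryption
    a_ls = [sample_uniform_element(params1.q, sp_rng) for _ in range(L + 1)]
    e_cts = {}  # (i, l, j) -> ciphertext of party i's level-l noise mod p_j
    e_polys = {}
    for i in range(z):
        for l in range(L + 1):
            rng = derive_rng(master_seed, "relin", "noise", i, l)
            e_il = sample_gaussian_coeffs(params1.n, rng,
                                          params1.err_dist.sigma)
            e_polys[(i, l)] = e_il
            for j, pj in enumerate(params1.q.primes):
                e_cts[(i, l, j)] = encrypt(e_il, pk2_co, params2,
                                           derive_rng(master_seed, "relin",
                                                      "noise-enc", i, l, j),
                                           t=pj)

    levels = []
    q1 = params1.q
    for l in range(L + 1):
        rows = np.empty((k, params1.n), dtype=q1.dtype)
        for j, pj in enumerate(params1.q.primes):
            bl = pow(B, l, pj)
            term = he_scalar_mul(c_sq[j], bl)
            a_plain = a_ls[l].residues[j].astype(object)
            a_plain = np.where(a_plain > pj // 2, a_plain - pj, a_plain)
            term = he_sub(term, he_mul_plain(c_s[j], a_plain))
            for i in range(z):
                term = he_sub(term, e_cts[(i, l, j)])
            # step 5: threshold decryption under the param2 shares
            shares = [partial_decrypt(term, pkm,
                                      derive_rng(master_seed, "relin", "dec",
                                                 l, j, pkm.party_id))
                      for pkm in parties2]
            rows[j] = (combine_decrypt(term, shares, expected_parties=z)
                       % pj).astype(q1.dtype)
        r0 = RingElement(rows, q1, "coef").to_ntt()
        levels.append((r0, a_ls[l].to_ntt()))
    return RelinKey(levels, params1.decomp_bits_T, params1.label)


def relin_key_noise_bits(rlk: RelinKey, s_co: RingElement,
                         params: EncryptionParams) -> float:
    """log2 ∞-norm of the key error e_l = -(rlk_l0 + a_l·s_co - B^l·s_co²),
    maximized over levels (debug instrumentation)."""
    q = params.q
    s_ntt = s_co.to_ntt()
    s2_ntt = RingElement((s_ntt.residues * s_ntt.residues) % q._p_arr, q, "ntt")
    B = 1 << params.decomp_bits_T
    worst = 0
    for l, (r0, a_l) in enumerate(rlk.levels):
        bl = pow(B, l, q.modulus)
        bl_s2 = np.empty_like(s2_ntt.residues)
        for i, p in enumerate(q.primes):
            bl_s2[i] = (s2_ntt.residues[i] * (bl % p)) % p
        err = ring_sub(ring_add(r0, RingElement(
            (a_l.residues * s_ntt.residues) % q._p_arr, q, "ntt")),
            RingElement(bl_s2, q, "ntt"))
        mag = int(np.max(np.abs(err.centered())))
        worst = max(worst, mag)
    return math.log2(max(worst, 1))
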