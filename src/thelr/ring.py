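"""Arithmetic in the polynomial ring R_q = Z_q[x]/(x^n + 1).

Elements are stored in residue-number-system (RNS) form: one coefficient
vector per prime of the modulus chain.  Every prime P in a chain satisfies
P ≡ 1 (mod 2n), so the negacyclic number-theoretic transform (NTT) is
available and polynomial products cost O(n log n) per prime.

Two coefficient dtypes are used transparently: int64 when every prime is
below 2^31 (so a product of two residues fits in a machine word), and
Python-int object arrays otherwise (exact, slower; used for 55-60 bit
reference chains where no heavy arithmetic is performed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import sympy

try:  # JIT butterfly kernel; the numpy path below is the portable fallback
    import numba

    @numba.njit(cache=True)
    def _butterfly_jit(a, tw, p):  # a: (k, b, n) int64, tw: (k, n-1), p: (k,)
        k, b, n = a.shape
        for i in range(k):
            pi = p[i]
            for bb in range(b):
                off = 0
                m = 2
                while m <= n:
                    half = m >> 1
                    for g in range(0, n, m):
                        base = g
                        for j in range(half):
                            w = tw[i, off + j]
                            lo = a[i, bb, base + j]
                            hi = a[i, bb, base + j + half] * w % pi
                            s = lo + hi
                            if s >= pi:
                                s -= pi
                            d = lo - hi
                            if d < 0:
                                d += pi
                            a[i, bb, base + j] = s
                            a[i, bb, base + j + half] = d
                    off += half
                    m <<= 1
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ModulusChain",
    "RingElement",
    "SamplerSpec",
    "ntt_friendly_primes",
    "ntt_transform",
    "ring_add",
    "ring_sub",
    "ring_mul",
    "ring_scale_round",
    "sample",
    "batch_encode",
    "batch_decode",
    "crt_compose",
    "crt_decompose",
    "derive_rng",
]

_INT64_LIMIT = 1 << 31  # residue products must fit in int64


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a structural constraint."""


# ---------------------------------------------------------------------------
# prime search
# ---------------------------------------------------------------------------

def ntt_friendly_primes(n: int, bit_lengths: Sequence[int],
                        exclude: Iterable[int] = ()) -> list[int]:
    """Largest primes P ≡ 1 (mod 2n) of the requested bit lengths.

    Scans downward from 2^b in steps of 2n; primes are pairwise distinct and
    distinct from ``exclude``.  Deterministic, so a chain is reproducible
    from (n, bit_lengths) alone.
    """
    if n & (n - 1):
        raise ConfigurationError("ring degree n must be a power of 2")
    found: list[int] = []
    taken = set(exclude)
    for b in bit_lengths:
        step = 2 * n
        p = ((1 << b) - 1) // step * step + 1
        while p > (1 << (b - 1)):
            if p not in taken and sympy.isprime(p):
                found.append(p)
                taken.add(p)
                break
            p -= step
        else:  # pragma: no cover - never hit for sane (n, b)
            raise ConfigurationError(f"no {b}-bit prime ≡ 1 mod {2*n}")
    return found


# ---------------------------------------------------------------------------
# modulus chain + NTT tables
# ---------------------------------------------------------------------------

def _bit_reverse_perm(n: int) -> np.ndarray:
    bits = n.bit_length() - 1
    idx = np.arange(n)
    rev = np.zeros(n, dtype=np.int64)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev


def _smallest_primitive_2n_root(p: int, n: int) -> int:
    """Smallest primitive 2n-th root of unity mod p (fixed for fingerprints)."""
    g = sympy.primitive_root(p)
    psi0 = pow(g, (p - 1) // (2 * n), p)
    if pow(psi0, n, p) != p - 1:  # pragma: no cover - sanity
        raise ConfigurationError("root-of-unity construction failed")
    # primitive 2n-th roots are psi0^j for odd j (2n is a power of two)
    step = psi0 * psi0 % p
    cur, best = psi0, psi0
    for _ in range(n - 1):
        cur = cur * step % p
        if cur < best:
            best = cur
    return best


class ModulusChain:
    """An ordered set of distinct NTT-friendly primes sharing ring degree n."""

    def __init__(self, primes: Sequence[int], n: int):
        primes = tuple(int(p) for p in primes)
        if n & (n - 1) or n < 2:
            raise ConfigurationError("ring degree n must be a power of 2 (>=2)")
        if len(set(primes)) != len(primes):
            raise ConfigurationError("chain primes must be pairwise distinct")
        for p in primes:
            if p % (2 * n) != 1:
                raise ConfigurationError(
                    f"prime {p} violates P ≡ 1 (mod 2n) for n={n}")
        self.primes = primes
        self.n = n
        self.dtype = np.int64 if max(primes) < _INT64_LIMIT else object
        self._p_arr = np.array(primes, dtype=self.dtype).reshape(-1, 1)
        self._ntt: dict | None = None
        Q = 1
        for p in primes:
            Q *= p
        self.modulus = Q
        # CRT weights: w_i = (Q/p_i) * (Q/p_i)^{-1} mod p_i
        self._crt_w = np.array(
            [(Q // p) * pow(Q // p, -1, p) % Q for p in primes], dtype=object)

    @property
    def total_bits(self) -> int:
        return self.modulus.bit_length()

    def fingerprint(self) -> dict:
        """Stable description (primes, degree, NTT roots) for manifests."""
        self._ensure_ntt()
        return {
            "n": self.n,
            "primes": list(self.primes),
            "roots": [int(r) for r in self._ntt["psi"]],
        }

    def __eq__(self, other):
        return (isinstance(other, ModulusChain)
                and self.primes == other.primes and self.n == other.n)

    def __hash__(self):
        return hash((self.primes, self.n))

    # -- NTT machinery -----------------------------------------------------

    def _ensure_ntt(self):
        if self._ntt is not None:
            return
        n, k = self.n, len(self.primes)
        dt = self.dtype
        psi = [_smallest_primitive_2n_root(p, n) for p in self.primes]
        psi_pows = np.empty((k, n), dtype=dt)
        inv_psi_pows = np.empty((k, n), dtype=dt)
        for i, p in enumerate(self.primes):
            ps, ipsi = psi[i], pow(psi[i], -1, p)
            row, irow = [1], [1]
            for _ in range(n - 1):
                row.append(row[-1] * ps % p)
                irow.append(irow[-1] * ipsi % p)
            psi_pows[i] = row
            inv_psi_pows[i] = irow
        n_inv = np.array([pow(n, -1, p) for p in self.primes],
                         dtype=dt).reshape(-1, 1)
        brev = _bit_reverse_perm(n)
        # per-stage twiddle tables for w = psi^2 (primitive n-th root)
        fwd_tw, inv_tw = [], []
        m = 2
        while m <= n:
            half = m // 2
            tf = np.empty((k, half), dtype=dt)
            ti = np.empty((k, half), dtype=dt)
            for i, p in enumerate(self.primes):
                w = pow(psi[i], 2, p)
                wm = pow(w, n // m, p)
                iwm = pow(wm, -1, p)
                cf, ci = 1, 1
                for j in range(half):
                    tf[i, j] = cf
                    ti[i, j] = ci
                    cf = cf * wm % p
                    ci = ci * iwm % p
            fwd_tw.append(tf)
            inv_tw.append(ti)
            m *= 2
        self._ntt = {
            "psi": psi, "psi_pows": psi_pows, "inv_psi_pows": inv_psi_pows,
            "n_inv": n_inv, "brev": brev, "fwd": fwd_tw, "inv": inv_tw,
        }
        if dt is not object and _HAVE_NUMBA:
            self._ntt["fwd_flat"] = np.concatenate(fwd_tw, axis=1)
            self._ntt["inv_flat"] = np.concatenate(inv_tw, axis=1)
            self._ntt["p_flat"] = np.array(self.primes, dtype=np.int64)

    def _butterflies(self, a: np.ndarray, tables: list[np.ndarray]) -> np.ndarray:
        """Iterative radix-2 butterflies on shape (k, b, n) (batch dim b)."""
        n, k = self.n, len(self.primes)
        b = a.shape[1]
        p = self._p_arr.reshape(k, 1, 1, 1)
        a = np.ascontiguousarray(a[..., self._ntt["brev"]])
        if "fwd_flat" in self._ntt:
            flat = (self._ntt["fwd_flat"] if tables is self._ntt["fwd"]
                    else self._ntt["inv_flat"])
            _butterfly_jit(a, flat, self._ntt["p_flat"])
            return a
        m, s = 2, 0
        while m <= n:
            half = m // 2
            tw = tables[s].reshape(k, 1, 1, half)
            v = a.reshape(k, b, n // m, m)
            hi = (v[..., half:] * tw) % p
            lo = v[..., :half].copy()
            add = lo + hi
            sub = lo - hi
            np.subtract(add, p, out=add, where=add >= p)
            np.add(sub, p, out=sub, where=sub < 0)
            v[..., :half] = add
            v[..., half:] = sub
            m, s = m * 2, s + 1
        return a

    def ntt_forward(self, coeffs: np.ndarray) -> np.ndarray:
        """Negacyclic forward NTT; accepts (k, n) or batched (k, b, n)."""
        self._ensure_ntt()
        batched = coeffs.ndim == 3
        x = coeffs if batched else coeffs[:, None, :]
        x = (x * self._ntt["psi_pows"][:, None, :]) % self._p_arr[:, None]
        out = self._butterflies(x, self._ntt["fwd"])
        return out if batched else out[:, 0, :]

    def ntt_inverse(self, values: np.ndarray) -> np.ndarray:
        self._ensure_ntt()
        batched = values.ndim == 3
        x = values if batched else values[:, None, :]
        x = self._butterflies(x.copy(), self._ntt["inv"])
        x = (x * self._ntt["n_inv"][:, None]) % self._p_arr[:, None]
        out = (x * self._ntt["inv_psi_pows"][:, None, :]) % self._p_arr[:, None]
        return out if batched else out[:, 0, :]

    # -- CRT ---------------------------------------------------------------

    def compose(self, residues: np.ndarray, centered: bool = False) -> np.ndarray:
        """Per-coefficient CRT reconstruction to Python ints (object array)."""
        obj = residues.astype(object)
        acc = (obj * self._crt_w[:, None]).sum(axis=0) % self.modulus
        if centered:
            half = self.modulus >> 1
            acc = np.where(acc > half, acc - self.modulus, acc)
        return acc

    def decompose(self, values) -> np.ndarray:
        """Reduce arbitrary (possibly signed, big) integers into RNS form."""
        vals = np.asarray(values)
        if vals.dtype == object and self.dtype is not object:
            # int64 fast path whenever the values fit a machine word
            mx = max((int(abs(v)) for v in vals.flat), default=0)
            if mx < (1 << 62):
                vals = vals.astype(np.int64)
        if vals.dtype != object and self.dtype is not object:
            p = np.array(self.primes, dtype=np.int64).reshape(-1, 1)
            return vals.astype(np.int64)[None, :] % p
        vals = vals.astype(object)
        out = np.empty((len(self.primes), vals.size), dtype=self.dtype)
        for i, p in enumerate(self.primes):
            out[i] = (vals % p).astype(self.dtype)
        return out


def crt_compose(residues, chain: ModulusChain, centered: bool = False):
    return chain.compose(np.asarray(residues), centered=centered)


def crt_decompose(values, chain: ModulusChain):
    return chain.decompose(values)


# ---------------------------------------------------------------------------
# ring elements
# ---------------------------------------------------------------------------

@dataclass
class RingElement:
    residues: np.ndarray          # shape (k, n)
    chain: ModulusChain
    domain: str = "coef"          # "coef" | "ntt"

    def __post_init__(self):
        if self.residues.shape != (len(self.chain.primes), self.chain.n):
            raise ConfigurationError("residue matrix shape mismatch")

    @classmethod
    def zeros(cls, chain: ModulusChain, domain: str = "coef") -> "RingElement":
        return cls(np.zeros((len(chain.primes), chain.n), dtype=chain.dtype),
                   chain, domain)

    @classmethod
    def from_signed(cls, coeffs, chain: ModulusChain) -> "RingElement":
        """Embed signed integer coefficients (any magnitude) into RNS form."""
        return cls(chain.decompose(coeffs), chain, "coef")

    def copy(self) -> "RingElement":
        return RingElement(self.residues.copy(), self.chain, self.domain)

    def to_ntt(self) -> "RingElement":
        if self.domain == "ntt":
            return self
        return RingElement(self.chain.ntt_forward(self.residues), self.chain, "ntt")

    def to_coef(self) -> "RingElement":
        if self.domain == "coef":
            return self
        return RingElement(self.chain.ntt_inverse(self.residues), self.chain, "coef")

    def centered(self) -> np.ndarray:
        """Coefficients composed to centered Python ints in [-Q/2, Q/2)."""
        return self.chain.compose(self.to_coef().residues, centered=True)

    def _check(self, other: "RingElement"):
        if self.chain != other.chain:
            raise ConfigurationError("modulus chain mismatch")

    def __eq__(self, other):
        if not isinstance(other, RingElement) or self.chain != other.chain:
            return False
        a, b = self.to_coef(), other.to_coef()
        return bool(np.all(a.residues == b.residues))


def ntt_transform(elem: RingElement, direction: str) -> RingElement:
    if direction == "forward":
        return elem.to_ntt()
    if direction == "inverse":
        return elem.to_coef()
    raise ValueError(f"unknown direction {direction!r}")


def ring_add(a: RingElement, b: RingElement) -> RingElement:
    a._check(b)
    if a.domain != b.domain:
        a, b = a.to_coef(), b.to_coef()
    return RingElement((a.residues + b.residues) % a.chain._p_arr,
                       a.chain, a.domain)


def ring_sub(a: RingElement, b: RingElement) -> RingElement:
    a._check(b)
    if a.domain != b.domain:
        a, b = a.to_coef(), b.to_coef()
    return RingElement((a.residues - b.residues) % a.chain._p_arr,
                       a.chain, a.domain)


def ring_neg(a: RingElement) -> RingElement:
    return RingElement((-a.residues) % a.chain._p_arr, a.chain, a.domain)


def ring_mul(a: RingElement, b: RingElement) -> RingElement:
    """Negacyclic product, NTT-accelerated, result in coefficient domain."""
    a._check(b)
    fa, fb = a.to_ntt(), b.to_ntt()
    prod = (fa.residues * fb.residues) % a.chain._p_arr
    return RingElement(prod, a.chain, "ntt").to_coef()


def ring_mul_ntt(a: RingElement, b: RingElement) -> RingElement:
    """Pointwise product of two NTT-domain elements (stays in NTT domain)."""
    a._check(b)
    return RingElement((a.to_ntt().residues * b.to_ntt().residues)
                       % a.chain._p_arr, a.chain, "ntt")


def ring_scale_scalar(a: RingElement, c: int) -> RingElement:
    res = np.empty_like(a.residues)
    for i, p in enumerate(a.chain.primes):
        res[i] = (a.residues[i] * (c % p)) % p
    return RingElement(res, a.chain, a.domain)


def ring_scale_round(a: RingElement, num: int, den: int,
                     out_chain: ModulusChain | None = None) -> RingElement:
    """⌊num·x/den⌉ applied per coefficient on the centered lift of ``a``.

    The exact multiprecision path: coefficients are CRT-composed to Python
    ints, scaled by the rational num/den with round-half-up, and re-embedded
    into ``out_chain`` (default: the chain of ``a``).
    """
    if den == 0:
        raise ZeroDivisionError("scale_round denominator is zero")
    x = a.centered()
    scaled = scale_round_ints(x, num, den)
    return RingElement.from_signed(scaled, out_chain or a.chain)


def scale_round_ints(x: np.ndarray, num: int, den: int) -> np.ndarray:
    """⌊num·x/den⌉ (round half up) on an object array of Python ints."""
    num, den = int(num), int(den)
    if den < 0:
        num, den = -num, -den
    return (2 * num * x + den) // (2 * den)


# ---------------------------------------------------------------------------
# randomness
# ---------------------------------------------------------------------------

def derive_rng(master_seed: int, *labels) -> np.random.Generator:
    """Counter/label-based subseed derivation: one master seed per run expands
    to independent per-party, per-round streams."""
    ints = [int(master_seed) & 0x7FFFFFFF]
    for lab in labels:
        h = hashlib.sha256(repr(lab).encode()).digest()
        ints.append(int.from_bytes(h[:4], "little"))
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class SamplerSpec:
    kind: str                     # "ternary" | "gaussian" | "uniform"
    sigma: float = 3.2
    seed: int | None = None
    tail_sigmas: float = 6.0      # gaussian tail cut

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ConfigurationError("SamplerSpec without seed is not samplable")
        return np.random.default_rng(self.seed)


def _gaussian_table(sigma: float, tail: float):
    cut = int(np.floor(tail * sigma))
    xs = np.arange(-cut, cut + 1)
    w = np.exp(-xs.astype(float) ** 2 / (2 * sigma ** 2))
    cdf = np.cumsum(w) / w.sum()
    return xs, cdf


def sample_ternary_coeffs(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(-1, 2, size=n)


def sample_gaussian_coeffs(n: int, rng: np.random.Generator,
                           sigma: float = 3.2, tail: float = 6.0) -> np.ndarray:
    """Discrete Gaussian via inverse-CDF table, truncated at ``tail``·sigma."""
    xs, cdf = _gaussian_table(sigma, tail)
    u = rng.random(n)
    return xs[np.searchsorted(cdf, u)]

def sample_uniform_element(chain: ModulusChain,
                           rng: np.random.Generator) -> RingElement:
    res = np.empty((len(chain.primes), chain.n), dtype=chain.dtype)
    for i, p in enumerate(chain.primes):
        draw = rng.integers(0, p, size=chain.n, dtype=np.uint64)
        res[i] = draw.astype(object) if chain.dtype is object else draw.astype(np.int64)
    return RingElement(res, chain, "coef")


def sample(spec: SamplerSpec, chain: ModulusChain,
           rng: np.random.Generator | None = None) -> RingElement:
    """Sample a ring element; deterministic under a fixed seed."""
    rng = rng if rng is not None else spec.rng()
    if spec.kind == "ternary":
        return RingElement.from_signed(sample_ternary_coeffs(chain.n, rng), chain)
    if spec.kind == "gaussian":
        return RingElement.from_signed(
            sample_gaussian_coeffs(chain.n, rng, spec.sigma, spec.tail_sigmas),
            chain)
    if spec.kind == "uniform":
        return sample_uniform_element(chain, rng)
    raise ConfigurationError(f"unknown sampler kind {spec.kind!r}")


def sample_uniform_bounded_coeffs(n: int, bound: int,
                                  rng: np.random.Generator) -> np.ndarray:
    """Centered uniform integers in [-bound, bound] as Python ints.

    Arbitrary-size bounds are assembled from 32-bit words so no big-int RNG
    is needed; used for smudging and function-privacy noise.
    """
    span = 2 * int(bound) + 1
    words = (span.bit_length() + 31) // 32 or 1
    draws = rng.integers(0, 1 << 32, size=(n, words), dtype=np.uint64)
    weights = np.array([1 << (32 * w) for w in range(words)], dtype=object)
    vals = (draws.astype(object) * weights).sum(axis=1) % span
    return vals - bound


# ---------------------------------------------------------------------------
# CRT batching (SIMD slots)
# ---------------------------------------------------------------------------

@dataclass
class BatchedVector:
    """Length-n slot vector of integers mod t (t = chain modulus)."""
    slots: np.ndarray             # object array of Python ints (centered or raw)
    t: int

    def __len__(self):
        return len(self.slots)


def batch_encode(values, t_chain: ModulusChain) -> RingElement:
    """Encode up to n slot values (signed ints) into a plaintext polynomial.

    Slot-wise sums/products of encodings correspond to ring add/mul mod t;
    requires every prime of ``t_chain`` ≡ 1 (mod 2n) (checked at chain
    construction).  Short inputs are zero-padded.
    """
    vals = list(int(v) for v in values)
    if len(vals) > t_chain.n:
        raise ConfigurationError("more slot values than ring degree")
    vals = vals + [0] * (t_chain.n - len(vals))
    arr = np.array(vals, dtype=object)
    res = t_chain.decompose(arr)
    return RingElement(t_chain.ntt_inverse(res), t_chain, "coef")


def batch_decode(poly: RingElement, centered: bool = True) -> np.ndarray:
    """Slot values of a plaintext polynomial (centered lift by default)."""
    vals = poly.chain.ntt_forward(poly.to_coef().residues)
    return poly.chain.compose(vals, centered=centered)
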