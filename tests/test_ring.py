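"""Polynomial-ring core: NTT vs schoolbook oracle, CRT batching
homomorphism, CRT bijection, exact scale-and-round, samplers."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thelr import ring


def schoolbook_negacyclic(a, b, n, q):
    out = [0] * n
    for i in range(n):
        for j in range(n):
            s = a[i] * b[j]
            if i + j >= n:
                out[i + j - n] -= s
            else:
                out[i + j] += s
    return [v % q for v in out]


@pytest.fixture(scope="module")
def chain8():
    return ring.ModulusChain(ring.ntt_friendly_primes(8, [12, 20]), 8)


@pytest.fixture(scope="module")
def tchain():
    n = 64
    return ring.ModulusChain(ring.ntt_friendly_primes(n, [20, 21]), n)


class TestChainConstruction:
    def test_rejects_non_power_of_two_degree(self):
        p = ring.ntt_friendly_primes(8, [12])[0]
        with pytest.raises(ring.ConfigurationError):
            ring.ModulusChain([p], 12)

    def test_rejects_non_ntt_friendly_prime(self):
        with pytest.raises(ring.ConfigurationError, match="P ≡ 1"):
            ring.ModulusChain([7], 8)

    def test_rejects_duplicate_primes(self):
        p = ring.ntt_friendly_primes(8, [12])[0]
        with pytest.raises(ring.ConfigurationError):
            ring.ModulusChain([p, p], 8)

    def test_prime_search_properties(self):
        primes = ring.ntt_friendly_primes(16, [14, 14, 15])
        assert len(set(primes)) == 3
        for p, b in zip(primes, [14, 14, 15]):
            assert p % 32 == 1 and p.bit_length() == b


class TestNTT:
    def test_roundtrip_identity(self, chain8):
        rng = np.random.default_rng(0)
        a = ring.RingElement.from_signed(rng.integers(-100, 100, 8), chain8)
        back = ring.ntt_transform(ring.ntt_transform(a, "forward"), "inverse")
        assert back == a

    def test_constant_polynomial_has_constant_slots(self, chain8):
        coeffs = np.zeros(8, dtype=np.int64)
        coeffs[0] = 5
        e = ring.RingElement.from_signed(coeffs, chain8).to_ntt()
        for row in e.residues:
            assert len(set(int(v) for v in row)) == 1 and int(row[0]) == 5

    def test_unknown_direction(self, chain8):
        a = ring.RingElement.zeros(chain8)
        with pytest.raises(ValueError):
            ring.ntt_transform(a, "sideways")

    def test_mul_by_one_is_identity(self, chain8):
        rng = np.random.default_rng(1)
        a = ring.RingElement.from_signed(rng.integers(-50, 50, 8), chain8)
        one = np.zeros(8, dtype=np.int64)
        one[0] = 1
        b = ring.RingElement.from_signed(one, chain8)
        assert ring.ring_mul(a, b) == a

    def test_x_half_squared_wraps_to_minus_one(self, chain8):
        mono = np.zeros(8, dtype=np.int64)
        mono[4] = 1
        x4 = ring.RingElement.from_signed(mono, chain8)
        prod = ring.ring_mul(x4, x4)
        cent = prod.centered()
        assert int(cent[0]) == -1 and all(int(v) == 0 for v in cent[1:])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_ntt_mul_equals_schoolbook(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.choice([4, 8, 16]))
        ch = ring.ModulusChain(ring.ntt_friendly_primes(n, [13, 17]), n)
        a = rng.integers(-200, 200, n)
        b = rng.integers(-200, 200, n)
        got = ring.ring_mul(ring.RingElement.from_signed(a, ch),
                            ring.RingElement.from_signed(b, ch))
        for i, p in enumerate(ch.primes):
            assert list(got.residues[i]) == schoolbook_negacyclic(
                list(a), list(b), n, p)

    def test_chain_mismatch_raises(self, chain8, tchain):
        a = ring.RingElement.zeros(chain8)
        b = ring.RingElement.zeros(tchain)
        with pytest.raises(ring.ConfigurationError):
            ring.ring_mul(a, b)


class TestScaleRound:
    def test_add_zero_identity(self, chain8):
        rng = np.random.default_rng(2)
        a = ring.RingElement.from_signed(rng.integers(-50, 50, 8), chain8)
        assert ring.ring_add(a, ring.RingElement.zeros(chain8)) == a

    def test_minus_one_rounds_to_zero_for_small_t(self, chain8):
        coeffs = np.zeros(8, dtype=object)
        coeffs[0] = chain8.modulus - 1          # ≡ −1 on the centered lift
        a = ring.RingElement.from_signed(coeffs, chain8)
        out = ring.ring_scale_round(a, 17, chain8.modulus)
        assert all(int(v) == 0 for v in out.centered())

    def test_zero_denominator(self, chain8):
        with pytest.raises(ZeroDivisionError):
            ring.ring_scale_round(ring.RingElement.zeros(chain8), 1, 0)

    def test_matches_exact_rational_rounding(self, chain8):
        rng = np.random.default_rng(3)
        vals = rng.integers(-10 ** 6, 10 ** 6, 8)
        num, den = 12345, 98765
        got = ring.scale_round_ints(np.array(list(vals), dtype=object), num, den)
        for v, g in zip(vals, got):
            exact = Fraction(num * int(v), den)
            floor = exact.numerator // exact.denominator
            expect = floor + (1 if Fraction(num * int(v), den) - floor >= Fraction(1, 2) else 0)
            assert int(g) == expect


class TestCRT:
    def test_two_prime_toy_vs_brute_force(self):
        # smallest NTT-friendly two-prime toy: residues (2, 3) mod (5, 13)
        ch = ring.ModulusChain([5, 13], 2)
        brute = [x for x in range(65) if x % 5 == 2 and x % 13 == 3]
        res = np.array([[2, 0], [3, 0]], dtype=np.int64)
        got = ring.crt_compose(res, ch)
        assert brute == [int(got[0])]

    def test_compose_decompose_bijection(self, chain8):
        rng = np.random.default_rng(4)
        xs = np.array([int(rng.integers(0, 1 << 30)) for _ in range(8)],
                      dtype=object) % chain8.modulus
        res = ring.crt_decompose(xs, chain8)
        back = ring.crt_compose(res, chain8)
        assert [int(v) for v in back] == [int(v) for v in xs]

    def test_decompose_zero(self, chain8):
        res = ring.crt_decompose(np.zeros(8, dtype=object), chain8)
        assert np.all(res == 0)


class TestBatching:
    def test_encode_decode_identity(self, tchain):
        rng = np.random.default_rng(5)
        vals = rng.integers(-1000, 1000, tchain.n)
        dec = ring.batch_decode(ring.batch_encode(vals, tchain))
        assert [int(v) for v in dec] == [int(v) for v in vals]

    def test_short_input_zero_padded(self, tchain):
        dec = ring.batch_decode(ring.batch_encode([3, -2], tchain))
        assert [int(v) for v in dec[:2]] == [3, -2]
        assert all(int(v) == 0 for v in dec[2:])

    def test_ring_homomorphism_add_and_mul(self, tchain):
        rng = np.random.default_rng(6)
        t = tchain.modulus
        u = rng.integers(-10 ** 5, 10 ** 5, tchain.n)
        v = rng.integers(-10 ** 5, 10 ** 5, tchain.n)
        eu, ev = ring.batch_encode(u, tchain), ring.batch_encode(v, tchain)
        dmul = ring.batch_decode(ring.ring_mul(eu, ev))
        dadd = ring.batch_decode(ring.ring_add(eu, ev))

        def cent(x):
            x %= t
            return x - t if x > t // 2 else x
        assert [int(a) for a in dmul] == [cent(int(x) * int(y))
                                          for x, y in zip(u, v)]
        assert [int(a) for a in dadd] == [cent(int(x) + int(y))
                                          for x, y in zip(u, v)]

    def test_all_ones_is_multiplicative_identity(self, tchain):
        rng = np.random.default_rng(7)
        u = rng.integers(-99, 99, tchain.n)
        ones = ring.batch_encode(np.ones(tchain.n, dtype=np.int64), tchain)
        dec = ring.batch_decode(ring.ring_mul(ring.batch_encode(u, tchain), ones))
        assert [int(v) for v in dec] == [int(v) for v in u]

    def test_too_many_values(self, tchain):
        with pytest.raises(ring.ConfigurationError):
            ring.batch_encode(np.ones(tchain.n + 1), tchain)


class TestSamplers:
    def test_ternary_range_and_determinism(self, chain8):
        spec = ring.SamplerSpec("ternary", seed=11)
        a = ring.sample(spec, chain8)
        b = ring.sample(ring.SamplerSpec("ternary", seed=11), chain8)
        assert a == b
        assert set(int(v) for v in a.centered()) <= {-1, 0, 1}

    def test_distinct_seeds_distinct_draws(self, chain8):
        a = ring.sample(ring.SamplerSpec("ternary", seed=1), chain8)
        b = ring.sample(ring.SamplerSpec("ternary", seed=2), chain8)
        assert a != b

    def test_gaussian_sd_matches_sigma(self):
        draws = ring.sample_gaussian_coeffs(10 ** 5,
                                            np.random.default_rng(0), 3.2)
        assert abs(draws.std() - 3.2) / 3.2 < 0.05
        assert np.max(np.abs(draws)) <= 19   # 6-sigma truncation

    def test_uniform_histogram(self, chain8):
        rng = np.random.default_rng(8)
        from scipy import stats
        p = chain8.primes[0]
        draws = np.concatenate([
            ring.sample_uniform_element(chain8, rng).residues[0]
            for _ in range(200)])
        hist, _ = np.histogram(draws, bins=16, range=(0, p))
        assert stats.chisquare(hist).pvalue > 1e-4

    def test_unknown_kind(self, chain8):
        with pytest.raises(ring.ConfigurationError):
            ring.sample(ring.SamplerSpec("laplace", seed=0), chain8)

    def test_derive_rng_reproducible_and_label_sensitive(self):
        a = ring.derive_rng(5, "x", 1).integers(0, 1 << 30, 4)
        b = ring.derive_rng(5, "x", 1).integers(0, 1 << 30, 4)
        c = ring.derive_rng(5, "x", 2).integers(0, 1 << 30, 4)
        assert np.array_equal(a, b) and not np.array_equal(a, c)
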