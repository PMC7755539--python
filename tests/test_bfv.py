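"""Threshold BFV: parameter constraints, end-to-end correctness against
slot-wise plaintext oracles, the relinearization-key protocol, threshold
decryption routing and smudging."""

import numpy as np
import pytest
from scipy import stats

from thelr import bfv, ring
from thelr.ring import ConfigurationError, batch_decode, batch_encode, derive_rng


def cent(x, t):
    x %= t
    return x - t if x > t // 2 else x


def enc_slots(ctx, vals, rng):
    return bfv.encrypt(batch_encode(vals, ctx.p1.t_chain), ctx.pk1, ctx.p1, rng)


def dec_slots(ctx, ct, rng=None):
    m = ctx.decrypt(ct, rng)
    return [int(v) for v in
            batch_decode(ring.RingElement.from_signed(m, ctx.p1.t_chain))]


class TestParams:
    def test_unknown_profile(self):
        with pytest.raises(ConfigurationError):
            bfv.setup_params("galactic")

    def test_param2_plaintext_must_match_param1_coefficient_modulus(self):
        p1, p2 = bfv.setup_params("tiny")
        bad = bfv.EncryptionParams(
            p2.label, p2.n, p2.q, p2.q, p2.key_dist, p2.err_dist,
            p2.decomp_bits_T)
        with pytest.raises(ConfigurationError, match="plaintext modulus"):
            bfv.validate_param_pair(p1, bad)

    def test_degree_mismatch_rejected(self):
        p1, _ = bfv.setup_params("tiny")
        q2 = ring.ModulusChain(ring.ntt_friendly_primes(512, [25, 25]), 512)
        bad = bfv.EncryptionParams("param2-x", 512, q2, p1.q,
                                   p1.key_dist, p1.err_dist)
        with pytest.raises(ConfigurationError, match="degree"):
            bfv.validate_param_pair(p1, bad)

    def test_relin_size_derived_from_modulus_bits(self):
        p1, _ = bfv.setup_params("tiny")
        assert p1.relin_size_L == (p1.q.total_bits - 1) // p1.decomp_bits_T

    def test_serialization_roundtrip(self):
        p1, p2 = bfv.setup_params("tiny")
        for p in (p1, p2):
            assert bfv.EncryptionParams.from_dict(p.to_dict()) == p
            assert not p.production


class TestEncryptDecrypt:
    @pytest.mark.parametrize("z", [1, 3])
    def test_threshold_roundtrip(self, tiny3, z):
        ctx = tiny3 if z == 3 else __import__(
            "conftest", fromlist=["KeyContext"]).KeyContext("tiny", z=1)
        rng = np.random.default_rng(z)
        vals = rng.integers(-500, 500, ctx.p1.n)
        assert dec_slots(ctx, enc_slots(ctx, vals, rng)) == [int(v) for v in vals]

    def test_encrypt_zero(self, tiny3):
        rng = np.random.default_rng(0)
        ct = bfv.encrypt_zero(tiny3.pk1, tiny3.p1, rng)
        assert all(v == 0 for v in dec_slots(tiny3, ct))

    def test_probabilistic_encryption(self, tiny3):
        rng = np.random.default_rng(1)
        m = batch_encode([7] * 4, tiny3.p1.t_chain)
        c1 = bfv.encrypt(m, tiny3.pk1, tiny3.p1, rng)
        c2 = bfv.encrypt(m, tiny3.pk1, tiny3.p1, rng)
        assert not np.array_equal(c1.parts[0].residues, c2.parts[0].residues)

    def test_unreduced_plaintext_rejected(self, tiny3):
        big = np.full(tiny3.p1.n, tiny3.p1.t, dtype=object)
        with pytest.raises(ConfigurationError, match="reduced"):
            bfv.encrypt(big, tiny3.pk1, tiny3.p1, np.random.default_rng(0))

    def test_missing_share_rejected(self, tiny3):
        rng = np.random.default_rng(2)
        ct = enc_slots(tiny3, [1, 2, 3], rng)
        shares = [bfv.partial_decrypt(ct, k, rng) for k in tiny3.keys1[:2]]
        with pytest.raises(bfv.ProtocolError, match="full-threshold"):
            bfv.combine_decrypt(ct, shares, expected_parties=3)

    def test_share_order_irrelevant(self, tiny3):
        rng = np.random.default_rng(3)
        ct = enc_slots(tiny3, [9, -9], rng)
        shares = [bfv.partial_decrypt(ct, k, np.random.default_rng(i))
                  for i, k in enumerate(tiny3.keys1)]
        a = bfv.combine_decrypt(ct, shares, 3)
        b = bfv.combine_decrypt(ct, shares[::-1], 3)
        assert np.array_equal(a, b)

    def test_combined_key_equivalence(self, tiny3):
        """Decryption under the z shares equals direct decryption under
        s_co = Σ s_i (debug path)."""
        rng = np.random.default_rng(4)
        vals = rng.integers(-100, 100, tiny3.p1.n)
        ct = enc_slots(tiny3, vals, rng)
        assert np.array_equal(tiny3.decrypt(ct),
                              bfv.decrypt_with_secret(ct, tiny3.s_co))

    def test_smudging_randomizes_shares_not_plaintext(self, tiny3):
        rng = np.random.default_rng(5)
        ct = enc_slots(tiny3, [4, 5, 6], rng)
        k = tiny3.keys1[0]
        mu1 = bfv.partial_decrypt(ct, k, np.random.default_rng(10))
        mu2 = bfv.partial_decrypt(ct, k, np.random.default_rng(11))
        assert not np.array_equal(mu1.mu.residues, mu2.mu.residues)
        rest = [bfv.partial_decrypt(ct, kk, np.random.default_rng(i))
                for i, kk in enumerate(tiny3.keys1[1:])]
        a = bfv.combine_decrypt(ct, [mu1] + rest, 3)
        b = bfv.combine_decrypt(ct, [mu2] + rest, 3)
        assert np.array_equal(a, b)

    def test_fast_and_exact_scale_round_agree(self, tiny3):
        rng = np.random.default_rng(6)
        ct = enc_slots(tiny3, rng.integers(-900, 900, tiny3.p1.n), rng)
        shares = [bfv.partial_decrypt(ct, k, rng) for k in tiny3.keys1]
        assert np.array_equal(bfv.combine_decrypt(ct, shares, 3),
                              bfv.combine_decrypt(ct, shares, 3, exact=True))


class TestHomomorphicOps:
    def test_add_matches_slot_oracle(self, tiny3):
        rng = np.random.default_rng(0)
        t = tiny3.p1.t
        u = rng.integers(-10 ** 5, 10 ** 5, tiny3.p1.n)
        v = rng.integers(-10 ** 5, 10 ** 5, tiny3.p1.n)
        got = dec_slots(tiny3, bfv.he_add(enc_slots(tiny3, u, rng),
                                          enc_slots(tiny3, v, rng)))
        assert got == [cent(int(x) + int(y), t) for x, y in zip(u, v)]

    def test_mul_relin_matches_slot_oracle(self, tiny3):
        rng = np.random.default_rng(1)
        t = tiny3.p1.t
        u = rng.integers(-300, 300, tiny3.p1.n)
        v = rng.integers(-300, 300, tiny3.p1.n)
        prod = bfv.he_mul(enc_slots(tiny3, u, rng), enc_slots(tiny3, v, rng))
        assert prod.size == 3
        rel = bfv.relinearize(prod, tiny3.rlk)
        assert rel.size == 2
        # extended (s_co²) decryption of the size-3 input is the oracle here
        direct = bfv.decrypt_with_secret(prod, tiny3.s_co)
        assert np.array_equal(bfv.decrypt_with_secret(rel, tiny3.s_co), direct)
        got = dec_slots(tiny3, rel)
        assert got == [cent(int(x) * int(y), t) for x, y in zip(u, v)]

    def test_mul_plain_all_ones_identity(self, tiny3):
        rng = np.random.default_rng(2)
        u = rng.integers(-50, 50, tiny3.p1.n)
        ones = batch_encode(np.ones(tiny3.p1.n, dtype=np.int64),
                            tiny3.p1.t_chain).centered()
        got = dec_slots(tiny3, bfv.he_mul_plain(enc_slots(tiny3, u, rng), ones))
        assert got == [int(v) for v in u]

    def test_scalar_mul_and_add_plain(self, tiny3):
        rng = np.random.default_rng(3)
        t = tiny3.p1.t
        u = rng.integers(-40, 40, tiny3.p1.n)
        ct = bfv.he_scalar_mul(enc_slots(tiny3, u, rng), 7)
        const = np.zeros(tiny3.p1.n, dtype=object)
        const[0] = 11                       # +11 in every slot
        ct = bfv.he_add_plain(ct, const)
        assert dec_slots(tiny3, ct) == [cent(7 * int(v) + 11, t) for v in u]

    def test_relinearize_size2_is_error(self, tiny3):
        rng = np.random.default_rng(4)
        ct = enc_slots(tiny3, [1], rng)
        with pytest.raises(bfv.ProtocolError, match="size-3"):
            bfv.relinearize(ct, tiny3.rlk)

    def test_missing_relin_key_is_error(self, tiny3):
        rng = np.random.default_rng(5)
        prod = bfv.he_mul(enc_slots(tiny3, [2], rng), enc_slots(tiny3, [3], rng))
        with pytest.raises(bfv.ProtocolError, match="missing"):
            bfv.relinearize(prod, None)

    def test_params_mismatch_rejected(self, tiny3, mini3):
        rng = np.random.default_rng(6)
        a = enc_slots(tiny3, [1], rng)
        b = enc_slots(mini3, [1], rng)
        with pytest.raises(ConfigurationError):
            bfv.he_add(a, b)

    def test_noise_budget_positive_and_monotone(self, tiny3):
        rng = np.random.default_rng(7)
        u = rng.integers(-100, 100, tiny3.p1.n)
        c = enc_slots(tiny3, u, rng)
        b0 = bfv.measure_invariant_noise(c, tiny3.s_co)
        c1 = bfv.relinearize(bfv.he_mul(c, c), tiny3.rlk)
        b1 = bfv.measure_invariant_noise(c1, tiny3.s_co)
        c2 = bfv.relinearize(bfv.he_mul(c1, c), tiny3.rlk)
        b2 = bfv.measure_invariant_noise(c2, tiny3.s_co)
        assert b0 > b1 > b2 > 0


class TestRelinKeygenProtocol:
    def test_protocol_key_relinearizes_product(self, mini3, mini3_protocol_rlk):
        rng = np.random.default_rng(0)
        t = mini3.p1.t
        u = rng.integers(-7000, 7000, mini3.p1.n)
        v = rng.integers(-7000, 7000, mini3.p1.n)
        prod = bfv.he_mul(enc_slots(mini3, u, rng), enc_slots(mini3, v, rng))
        rel = bfv.relinearize(prod, mini3_protocol_rlk)
        assert dec_slots(mini3, rel) == [cent(int(x) * int(y), t)
                                         for x, y in zip(u, v)]

    def test_single_party_protocol_matches_single_key_path(self):
        from conftest import KeyContext
        ctx = KeyContext("tiny", z=1)
        rlk_p = bfv.relin_keygen_protocol(ctx.keys1, ctx.keys2, ctx.p1,
                                          ctx.p2, ctx.pk2, 5)
        rlk_s = ctx.rlk
        rng = np.random.default_rng(1)
        u = rng.integers(-200, 200, ctx.p1.n)
        prod = bfv.he_mul(enc_slots(ctx, u, rng), enc_slots(ctx, u, rng))
        a = bfv.decrypt_with_secret(bfv.relinearize(prod, rlk_p), ctx.s_co)
        b = bfv.decrypt_with_secret(bfv.relinearize(prod, rlk_s), ctx.s_co)
        assert np.array_equal(a, b)

    def test_incomplete_key_breaks_relinearization(self, tiny3):
        """A key generated without one party's contribution fails to
        relinearize ciphertexts under the full combined key."""
        partial_rlk = bfv.relin_keygen_protocol(
            tiny3.keys1[:2], tiny3.keys2[:2], tiny3.p1, tiny3.p2,
            bfv.combine_public_keys(tiny3.keys2[:2], tiny3.crs2), 9)
        rng = np.random.default_rng(2)
        u = rng.integers(1, 50, tiny3.p1.n)
        prod = bfv.he_mul(enc_slots(tiny3, u, rng), enc_slots(tiny3, u, rng))
        oracle = bfv.decrypt_with_secret(prod, tiny3.s_co)
        got = bfv.decrypt_with_secret(bfv.relinearize(prod, partial_rlk),
                                      tiny3.s_co)
        assert not np.array_equal(got, oracle)

    def test_protocol_key_noise_small_and_measurable(self, mini3,
                                                     mini3_protocol_rlk):
        bits = bfv.relin_key_noise_bits(mini3_protocol_rlk, mini3.s_co,
                                        mini3.p1)
        assert 0 < bits < 20   # a few summed gaussians, far below q


class TestSmudging:
    def test_smudged_distributions_indistinguishable(self):
        """e_smg vs e_smg + e_ct pass a two-sample KS test at α=0.01 when
        var_c/var_smg ≤ 2^-40."""
        rng = np.random.default_rng(0)
        n = 20000
        e_ct = ring.sample_gaussian_coeffs(n, rng, 3.2)
        bound = 1 << 45                       # |e_ct| ≤ 19 → ratio ≪ 2^-40
        smg = rng.integers(-bound, bound, n)
        smg2 = rng.integers(-bound, bound, n)
        assert stats.ks_2samp(smg, smg2 + e_ct).pvalue > 0.01

    def test_masked_slots_uniform_over_t(self, tiny3):
        """Adding a uniform mod-t mask makes slot values uniform on Z_t."""
        rng = np.random.default_rng(1)
        t = tiny3.p1.t
        vals = rng.integers(0, 1000, tiny3.p1.n)       # highly non-uniform
        mask = rng.integers(0, t, tiny3.p1.n)
        masked = (vals + mask) % t
        hist, _ = np.histogram(masked, bins=16, range=(0, t))
        assert stats.chisquare(hist).pvalue > 1e-4
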