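"""Privacy-preserving model training (minibatch gradient descent).

Ten logistic models — one per cross-validation fold — are trained
simultaneously inside one set of CRT-batched ciphertexts.  Per cv-step the
researcher assigns model ((fold_i + cv − 1) mod 10) + 1 to slot i, so over
cv = 1..9 each model sees the nine folds that are not its own.  The service
provider evaluates the encrypted gradient

    gra^j = (G₃(x^Tβ) − label_const·y) · x^j         (x^0 = 1)

providers add removable uniform mod-t masks (one-time pads whose per-model
sums E are disclosed to the researcher only), and threshold decryption is
routed so that only the researcher reconstructs the plaintext slots.

``IntegerOracleTrainer`` is the exact plaintext mirror of the encrypted
pipeline (same G₃, same mod-t arithmetic, same researcher-side rounding):
its parameter snapshots are bit-identical to the secure run's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bfv
from .ring import ConfigurationError, RingElement, batch_encode, batch_decode, derive_rng
from .sigmoid import IntegerizedSigmoid, g3_eval_encrypted


@dataclass
class TrainingConfig:
    epoch: int = 45            # total cv-steps; outer loops = epoch // 9
    alpha: float = 0.1
    epsilon: float = 0.05
    b: int | None = None       # samples per fold (minibatch divisor)
    sf: int = 1000

    def __post_init__(self):
        if self.epoch % 9 != 0:
            raise ConfigurationError("epoch must be divisible by 9")
        if self.alpha <= 0 or self.epsilon <= 0:
            raise ConfigurationError("alpha and epsilon must be positive")


@dataclass
class TrainingResult:
    bank: np.ndarray                   # (10, d+1) final parameters
    snapshots: list                    # bank copy after every cv-step
    converged: bool
    ratios: list                       # convergence ratio per outer loop
    interval_violations: int           # slots with |SF·x^Tβ| ≥ 8000
    diverged: bool = False


# ---------------------------------------------------------------------------
# researcher-side arithmetic (shared verbatim by oracle and secure paths)
# ---------------------------------------------------------------------------

def model_for_slot(fold_vec: np.ndarray, cv: int) -> np.ndarray:
    """Model index (1..10) receiving slot i at rotation cv."""
    if np.any((fold_vec < 1) | (fold_vec > 10)):
        raise ConfigurationError("fold ids must lie in 1..10")
    return ((fold_vec + cv - 1) % 10) + 1


def slot_assign_params(bank: np.ndarray, fold_vec: np.ndarray, cv: int,
                       scales: np.ndarray, sf: int, t: int) -> np.ndarray:
    """SF-scaled integer parameter slots B^0..B^d (shape (d+1, N)), reduced
    into the centered mod-t range."""
    m = model_for_slot(fold_vec, cv) - 1
    picked = bank[m, :]                       # (N, d+1)
    if not np.all(np.isfinite(picked)):
        raise FloatingPointError("model parameters diverged to non-finite values")
    scaled = picked * (sf / scales[None, :])
    B = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    B = np.array([[int(v) for v in row] for row in B.T], dtype=object)
    half = t // 2
    return (B + half) % t - half


def accumulate_slots(decoded: np.ndarray, fold_vec: np.ndarray, cv: int,
                     t: int) -> np.ndarray:
    """Box-3 accumulation: gra(model)(j) += slot values, mod t.  ``decoded``
    is (d+1, N) integers (any representatives mod t)."""
    m = model_for_slot(fold_vec, cv)
    d1 = decoded.shape[0]
    gra = np.zeros((10, d1), dtype=object)
    for model in range(1, 11):
        idx = np.flatnonzero(m == model)
        if idx.size:
            for j in range(d1):
                gra[model - 1, j] = int(sum(int(v) for v in decoded[j, idx]) % t)
    return gra


def center_mod_t(x, t: int):
    x = np.asarray(x, dtype=object) % t
    half = t // 2
    return np.where(x > half, x - t, x)


def unmask_aggregate(gra: np.ndarray, E_total: np.ndarray, t: int) -> np.ndarray:
    """Subtract the disclosed per-model noise sums, then center."""
    return center_mod_t((gra - E_total) % t, t)


def rescale_and_update(bank: np.ndarray, gra_centered: np.ndarray,
                       scales: np.ndarray, label_const: int,
                       alpha: float, b: int) -> np.ndarray:
    """β(m) ← β(m) − α·gra(m)/b on the real scale: a slot carries
    label_const·(σ̃−y)·scale_j·x_j, so dividing by label_const·scale_j
    recovers the real gradient coordinate."""
    real = gra_centered.astype(np.float64) / (label_const * scales[None, :])
    return bank - alpha * real / b


def convergence_ratio(bank_new: np.ndarray, bank_old: np.ndarray) -> float:
    denom = float(np.linalg.norm(bank_new))
    if denom == 0.0:
        return 0.0
    return float(np.linalg.norm(bank_new - bank_old)) / denom


# ---------------------------------------------------------------------------
# plaintext integer engine (exact mirror of the encrypted arithmetic)
# ---------------------------------------------------------------------------

class PlainGradientEngine:
    """Computes, per provider, the exact slot values the service provider's
    encrypted circuit produces (Python-int arithmetic mod t)."""

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 g3: IntegerizedSigmoid, t: int):
        self.x = features.astype(object)       # (N, d)
        self.y = labels.astype(object)
        self.g3 = g3
        self.t = t

    def slot_gradients(self, B: np.ndarray) -> tuple[np.ndarray, int]:
        """B: (d+1, N) centered ints.  Returns ((d+1, N) mod-t slot values,
        #interval violations)."""
        g3, t = self.g3, self.t
        N, d = self.x.shape
        xlin = B[0, :N].copy()
        for j in range(d):
            xlin = xlin + B[j + 1, :N] * self.x[:, j]
        violations = int(np.sum(np.abs(xlin) >= g3.int_bound))
        G = (g3.A + g3.B * xlin + g3.C * xlin * xlin * xlin) % t
        diff = (G - g3.label_const * self.y) % t
        out = np.empty((d + 1, N), dtype=object)
        out[0] = diff
        for j in range(d):
            out[j + 1] = (diff * self.x[:, j]) % t
        return out, violations


class IntegerOracleTrainer:
    """Plaintext reference run of the full training schedule."""

    def __init__(self, provider_data: list[tuple[np.ndarray, np.ndarray]],
                 fold_vec: np.ndarray, scales: np.ndarray,
                 g3: IntegerizedSigmoid, cfg: TrainingConfig, t: int):
        self.engines = [PlainGradientEngine(x, y, g3, t) for x, y in provider_data]
        self.fold_vec = np.asarray(fold_vec)
        self.scales = np.concatenate(([1.0], np.asarray(scales, dtype=float)))
        self.g3 = g3
        self.cfg = cfg
        self.t = t
        self.N = len(fold_vec)
        total = self.N * len(provider_data)
        self.b = cfg.b if cfg.b is not None else max(total // 10, 1)

    def run(self, d: int, init_bank: np.ndarray | None = None) -> TrainingResult:
        cfg, t = self.cfg, self.t
        bank = (np.zeros((10, d + 1)) if init_bank is None
                else init_bank.astype(float).copy())
        snapshots, ratios = [], []
        violations = 0
        converged = diverged = False
        for it in range(cfg.epoch // 9):
            bank_old = bank.copy()
            for cv in range(1, 10):
                try:
                    B = slot_assign_params(bank, self.fold_vec, cv,
                                           self.scales, cfg.sf, t)
                except FloatingPointError:
                    diverged = True
                    break
                slot_sum = None
                for eng in self.engines:
                    vals, viol = eng.slot_gradients(B)
                    violations += viol
                    slot_sum = vals if slot_sum is None else (slot_sum + vals) % t
                gra = accumulate_slots(slot_sum, self.fold_vec, cv, t)
                gra = center_mod_t(gra, t)
                bank = rescale_and_update(bank, gra, self.scales,
                                          self.g3.label_const, cfg.alpha, self.b)
                snapshots.append(bank.copy())
            if diverged:
                break
            r = convergence_ratio(bank, bank_old)
            ratios.append(r)
            if r < cfg.epsilon:
                converged = True
                break
        return TrainingResult(bank, snapshots, converged, ratios,
                              violations, diverged)


# ---------------------------------------------------------------------------
# secure protocol session
# ---------------------------------------------------------------------------

def sp_aggregate_partials(shares: list) -> "bfv.PartialDecryption":
    """Service provider sums the data providers' partial decryption shares
    so the researcher receives one aggregate (plus its own share)."""
    q = shares[0].mu.chain
    acc = shares[0].mu.residues
    for sh in shares[1:]:
        acc = (acc + sh.mu.residues) % q._p_arr
    return bfv.PartialDecryption("sp-aggregate",
                                 RingElement(acc, q, "coef"),
                                 max(s.smudge_bits for s in shares))


class SecureTrainingSession:
    """Boxes 1–3 end to end over encrypted provider data.

    ``providers`` aligns packed training sets with provider key material;
    the researcher holds its own share; the service provider holds only
    public material (rlk, ciphertexts).
    """

    def __init__(self, packed: list, provider_keys: list,
                 researcher_key, fold_vec: np.ndarray, scales: np.ndarray,
                 g3: IntegerizedSigmoid, rlk, pk,
                 params: "bfv.EncryptionParams", cfg: TrainingConfig,
                 master_seed: int, transcript=None):
        if len({p.n_samples for p in packed}) != 1:
            raise ConfigurationError(
                "all providers must share the fold-vector layout")
        self.packed = packed
        self.provider_keys = provider_keys
        self.researcher_key = researcher_key
        self.fold_vec = np.asarray(fold_vec)
        self.scales = np.concatenate(([1.0], np.asarray(scales, dtype=float)))
        self.g3 = g3
        self.rlk = rlk
        self.pk = pk
        self.params = params
        self.cfg = cfg
        self.seed = master_seed
        self.transcript = transcript
        self.N = len(fold_vec)
        total = self.N * len(packed)
        self.b = cfg.b if cfg.b is not None else max(total // 10, 1)

    def _log(self, **kw):
        if self.transcript is not None:
            self.transcript.log(**kw)

    def _ct_bytes(self, ct) -> int:
        return ct.size * len(ct.params.q.primes) * ct.params.n * 8

    def _encrypted_gradient(self, c_B: list, pset) -> list:
        """Box 2 for one provider: returns d+1 gradient ciphertexts."""
        g3, rlk = self.g3, self.rlk
        xlin = c_B[0]
        for j, cx in enumerate(pset.x_cts):
            xlin = bfv.he_add(xlin, bfv.relinearize(
                bfv.he_mul(c_B[j + 1], cx), rlk))
        G = g3_eval_encrypted(xlin, g3, rlk)
        diff = bfv.he_sub(G, bfv.he_scalar_mul(pset.y_ct, g3.label_const))
        grads = [diff]
        for cx in pset.x_cts:
            grads.append(bfv.relinearize(bfv.he_mul(diff, cx), rlk))
        return grads

    def _mask_and_decrypt(self, c_gra: list, cv: int, step: int):
        """Box 3: provider masking, share routing, researcher-side decode.

        Returns (decoded slot values (d+1, N) centered ints, E_total)."""
        t = self.params.t
        d1 = len(c_gra)
        E_total = np.zeros((10, d1), dtype=object)
        for pi, pset in enumerate(self.packed):
            rng = derive_rng(self.seed, "mask", step, pi)
            noise = rng.integers(0, t, size=(d1, self.params.n), dtype=np.int64)
            noise[:, self.N:] = 0
            E = accumulate_slots(noise[:, :self.N].astype(object),
                                 self.fold_vec, cv, t)
            E_total = (E_total + E) % t
            polys = [batch_encode(noise[j], self.params.t_chain)
                     for j in range(d1)]
            n_cts = bfv.encrypt_many(polys, self.pk, self.params,
                                     derive_rng(self.seed, "mask-enc", step, pi))
            for j in range(d1):
                c_gra[j] = bfv.he_add(c_gra[j], n_cts[j])
                self._log(step="training", round=step, sender=pset.provider_id,
                          receiver="sp", payload="masked-noise-ct",
                          nbytes=self._ct_bytes(n_cts[j]))
        decoded = np.empty((d1, self.N), dtype=object)
        for j in range(d1):
            prov_shares = [
                bfv.partial_decrypt(c_gra[j], key,
                                    derive_rng(self.seed, "pd", step, j, key.party_id))
                for key in self.provider_keys]
            agg = sp_aggregate_partials(prov_shares)
            own = bfv.partial_decrypt(c_gra[j], self.researcher_key,
                                      derive_rng(self.seed, "pd-r", step, j))
            m = bfv.combine_decrypt(c_gra[j], [agg, own])
            slots = batch_decode(RingElement.from_signed(m, self.params.t_chain))
            decoded[j] = slots[:self.N]
            self._log(step="training", round=step, sender="sp",
                      receiver="researcher", payload="partial-decryption",
                      nbytes=len(self.params.q.primes) * self.params.n * 8)
        return decoded, E_total

    def run(self, init_bank: np.ndarray | None = None) -> TrainingResult:
        cfg, t = self.cfg, self.params.t
        d = self.packed[0].d
        bank = (np.zeros((10, d + 1)) if init_bank is None
                else init_bank.astype(float).copy())
        snapshots, ratios = [], []
        violations = 0
        converged = diverged = False
        step = 0
        for it in range(cfg.epoch // 9):
            bank_old = bank.copy()
            for cv in range(1, 10):
                step += 1
                try:
                    B = slot_assign_params(bank, self.fold_vec, cv,
                                           self.scales, cfg.sf, t)
                except FloatingPointError:
                    diverged = True
                    break
                B_full = np.zeros((d + 1, self.params.n), dtype=object)
                B_full[:, :self.N] = B
                polys = [batch_encode(B_full[j], self.params.t_chain)
                         for j in range(d + 1)]
                c_B = bfv.encrypt_many(polys, self.pk, self.params,
                                       derive_rng(self.seed, "B", step))
                for cb in c_B:
                    self._log(step="training", round=step, sender="researcher",
                              receiver="sp", payload="parameter-ct",
                              nbytes=self._ct_bytes(cb))
                c_gra = None
                for pset in self.packed:
                    g = self._encrypted_gradient(c_B, pset)
                    c_gra = g if c_gra is None else [
                        bfv.he_add(a, b_) for a, b_ in zip(c_gra, g)]
                decoded, E_total = self._mask_and_decrypt(c_gra, cv, step)
                gra = accumulate_slots(decoded, self.fold_vec, cv, t)
                gra = unmask_aggregate(gra, E_total, t)
                bank = rescale_and_update(bank, gra, self.scales,
                                          self.g3.label_const, cfg.alpha, self.b)
                snapshots.append(bank.copy())
            if diverged:
                break
            r = convergence_ratio(bank, bank_old)
            ratios.append(r)
            if r < cfg.epsilon:
                converged = True
                break
        return TrainingResult(bank, snapshots, converged, ratios,
                              violations, diverged)
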