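"""Secure model evaluation: per-fold masked predictive values and
TP/FP/TN/FN counts over a 101-point threshold grid, computed under
encryption so the researcher learns only fold-level confusion counts.

Per fold FD the researcher encrypts the trained β(FD); the service provider
evaluates G₃(x^Tβ) on each provider's evaluation ciphertexts (samples at
random slots, with an encrypted occupancy vector marking genuine slots).
The owning provider masks predictions — empty slots with uniform noise over
[min G₃, max G₃], occupied slots with uniform noise over ±mask_bound — and
only the researcher sees the masked values σ.  The researcher thresholds σ,
and the slot-wise products of the plaintext indicator with the encrypted
label and occupancy yield the four counts, which providers mask again
(removable mod-t pads with disclosed sums) before the final decryption.

The per-threshold products are assembled as TP = X'·(y·occ),
FP = X'·(occ − y·occ), FN = (y·occ) − TP, TN = (occ − y·occ) − FP with
y·occ relinearized once per fold: the same plaintexts as the four literal
triple products, using only plaintext multiplications inside the V loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bfv
from .ring import RingElement, batch_decode, batch_encode, derive_rng
from .sigmoid import IntegerizedSigmoid, g3_eval_encrypted, g3_range, threshold_grid
from .training import sp_aggregate_partials


@dataclass
class EvaluationResult:
    counts: pd.DataFrame       # fold, threshold, TP, FP, TN, FN
    summary: pd.DataFrame      # per fold: auc, accuracy, f1
    grid: list


def _routed_decrypt(ct, provider_keys, researcher_key, seed, *labels):
    prov = [bfv.partial_decrypt(ct, k, derive_rng(seed, "ev-pd", *labels, k.party_id))
            for k in provider_keys]
    agg = sp_aggregate_partials(prov)
    own = bfv.partial_decrypt(ct, researcher_key,
                              derive_rng(seed, "ev-pd-r", *labels))
    return bfv.combine_decrypt(ct, [agg, own])


class SecureEvaluationSession:
    def __init__(self, eval_packs: list, provider_keys: list, researcher_key,
                 bank: np.ndarray, scales: np.ndarray,
                 g3: IntegerizedSigmoid, rlk, pk,
                 params: "bfv.EncryptionParams", master_seed: int,
                 sf: int = 1000, transcript=None,
                 mask_predictions: bool = True, mask_counts: bool = True):
        self.packs = eval_packs            # list (per provider) of {fold: EvalPacking}
        self.provider_keys = provider_keys
        self.researcher_key = researcher_key
        self.bank = bank
        self.scales = np.concatenate(([1.0], np.asarray(scales, dtype=float)))
        self.g3 = g3
        self.rlk = rlk
        self.pk = pk
        self.params = params
        self.seed = master_seed
        self.sf = sf
        self.transcript = transcript
        self.mask_predictions = mask_predictions
        self.mask_counts = mask_counts

    def _log(self, **kw):
        if self.transcript is not None:
            self.transcript.log(**kw)

    # -- Box 5: masked predictive values -----------------------------------

    def _beta_cts(self, fd: int, d: int) -> list:
        t = self.params.t
        beta = self.bank[fd - 1]
        polys = []
        for j in range(d + 1):
            v = beta[j] * self.sf / self.scales[j]
            b = int(np.sign(v) * np.floor(abs(v) + 0.5))
            b = (b + t // 2) % t - t // 2
            poly = np.zeros(self.params.n, dtype=object)
            poly[0] = b                    # constant polynomial: b in all slots
            polys.append(poly)
        return bfv.encrypt_many(polys, self.pk, self.params,
                                derive_rng(self.seed, "ev-beta", fd))

    def masked_predictions(self, fd: int, c_beta: list, pack) -> np.ndarray:
        xlin = c_beta[0]
        for j, cx in enumerate(pack.x_cts):
            xlin = bfv.he_add(xlin, bfv.relinearize(
                bfv.he_mul(c_beta[j + 1], cx), self.rlk))
        cG = g3_eval_encrypted(xlin, self.g3, self.rlk)
        lo, hi = g3_range(self.g3)
        rng = derive_rng(self.seed, "ev-mask", fd, pack.provider_id)
        if self.mask_predictions:
            noise = np.where(
                pack.occupancy == 1,
                rng.integers(-self.g3.mask_bound, self.g3.mask_bound + 1,
                             self.params.n),
                rng.integers(lo, hi + 1, self.params.n))
        else:
            noise = np.zeros(self.params.n, dtype=np.int64)
        ce = bfv.encrypt(batch_encode(noise, self.params.t_chain), self.pk,
                         self.params, rng)
        cG = bfv.he_add(cG, ce)
        self._log(step="evaluation", round=fd, sender=pack.provider_id,
                  receiver="sp", payload="prediction-mask-ct",
                  nbytes=2 * len(self.params.q.primes) * self.params.n * 8)
        m = _routed_decrypt(cG, self.provider_keys, self.researcher_key,
                            self.seed, "sigma", fd, pack.provider_id)
        return batch_decode(RingElement.from_signed(m, self.params.t_chain))

    # -- Boxes 4+6: confusion counts over the threshold grid ---------------

    def run(self, folds=None) -> EvaluationResult:
        g3, params = self.g3, self.params
        t = params.t
        d = len(next(iter(self.packs[0].values())).x_cts)
        grid = threshold_grid(g3)
        rows = []
        for fd in (folds or range(1, 11)):
            c_beta = self._beta_cts(fd, d)
            sigmas, yoccs, occ_m_yoccs, fold_sizes = [], [], [], []
            for pack_by_fold in self.packs:
                pack = pack_by_fold[fd]
                sigmas.append(self.masked_predictions(fd, c_beta, pack))
                yocc = bfv.relinearize(bfv.he_mul(pack.y_ct, pack.occ_ct),
                                       self.rlk)
                omy = bfv.he_sub(pack.occ_ct, yocc)
                # these two are multiplied 101 times: keep them NTT-resident
                yocc.parts = [p.to_ntt() for p in yocc.parts]
                omy.parts = [p.to_ntt() for p in omy.parts]
                yoccs.append(yocc)
                occ_m_yoccs.append(omy)
                fold_sizes.append(pack.fold_size)
            total = sum(fold_sizes)
            for vi, V in enumerate(grid):
                counts = self._counts_at_threshold(
                    fd, vi, V, sigmas, yoccs, occ_m_yoccs, total)
                rows.append({"fold": fd, "threshold": V, **counts})
        counts = pd.DataFrame(rows)
        return EvaluationResult(counts, summarize_counts(counts, g3), grid)

    def _counts_at_threshold(self, fd, vi, V, sigmas, yoccs, occ_m_yoccs,
                             total) -> dict:
        params, t = self.params, self.params.t
        csum = {k: None for k in ("TP", "FP", "TN", "FN")}
        for p, sigma in enumerate(sigmas):
            X = (np.asarray(sigma) >= V).astype(np.int64)
            xp = batch_encode(X, params.t_chain).centered()
            tp = bfv.he_mul_plain(yoccs[p], xp)
            fp = bfv.he_mul_plain(occ_m_yoccs[p], xp)
            parts = {"TP": tp, "FP": fp,
                     "FN": bfv.he_sub(yoccs[p], tp),
                     "TN": bfv.he_sub(occ_m_yoccs[p], fp)}
            for k in csum:
                csum[k] = parts[k] if csum[k] is None else bfv.he_add(csum[k], parts[k])
        # Box 6 masking: removable mod-t pads, sums disclosed to researcher
        keys = ("TP", "FP", "TN", "FN")
        noise_sums = {k: 0 for k in keys}
        if self.mask_counts:
            for pi in range(len(self.packs)):
                rng = derive_rng(self.seed, "cnt-mask", fd, vi, pi)
                noise = rng.integers(0, t, size=(4, params.n), dtype=np.int64)
                polys = [batch_encode(noise[j], params.t_chain) for j in range(4)]
                ncts = bfv.encrypt_many(polys, self.pk, params,
                                        derive_rng(self.seed, "cnt-enc", fd, vi, pi))
                for j, k in enumerate(keys):
                    csum[k] = bfv.he_add(csum[k], ncts[j])
                    noise_sums[k] = (noise_sums[k]
                                     + int(np.sum(noise[j].astype(object))) % t) % t
        out = {}
        cts = [csum[k] for k in keys]
        shares_by_party = [bfv.partial_decrypt_many(
            cts, k, derive_rng(self.seed, "cnt-pd", fd, vi, k.party_id))
            for k in self.provider_keys]
        own = bfv.partial_decrypt_many(
            cts, self.researcher_key, derive_rng(self.seed, "cnt-pd-r", fd, vi))
        for j, k in enumerate(keys):
            agg = sp_aggregate_partials([sh[j] for sh in shares_by_party])
            m = bfv.combine_decrypt(cts[j], [agg, own[j]])
            slots = batch_decode(RingElement.from_signed(m, params.t_chain))
            raw = (int(sum(int(v) for v in slots)) - noise_sums[k]) % t
            val = raw if raw <= t // 2 else raw - t
            if not (0 <= val <= total):
                raise bfv.DecryptionIntegrityError(
                    f"count {k}={val} outside [0, {total}] at fold {fd}")
            out[k] = int(val)
        return out


# ---------------------------------------------------------------------------
# plaintext oracle + reporting
# ---------------------------------------------------------------------------

def confusion_oracle(sigma_vals, y, occ, V) -> dict:
    """Brute-force slot-wise confusion counts for one threshold."""
    X = (np.asarray(sigma_vals) >= V).astype(int)
    y = np.asarray(y)
    occ = np.asarray(occ)
    return {"TP": int(np.sum(y * X * occ)),
            "FP": int(np.sum((1 - y) * X * occ)),
            "TN": int(np.sum((1 - y) * (1 - X) * occ)),
            "FN": int(np.sum(y * (1 - X) * occ))}


def roc_from_counts(df_fold: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    """FPR/TPR points and trapezoidal AUC from a fold's count table."""
    tp = df_fold["TP"].to_numpy(float)
    fp = df_fold["FP"].to_numpy(float)
    tn = df_fold["TN"].to_numpy(float)
    fn = df_fold["FN"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        fpr = np.where(fp + tn > 0, fp / (fp + tn), 0.0)
    order = np.lexsort((tpr, fpr))
    fx = np.concatenate(([0.0], fpr[order], [1.0]))
    fy = np.concatenate(([0.0], tpr[order], [1.0]))
    auc = float(np.trapezoid(fy, fx))
    return fpr, tpr, auc


def summarize_counts(counts: pd.DataFrame, g3: IntegerizedSigmoid) -> pd.DataFrame:
    """Per-fold AUC plus accuracy/F1 at the operating point nearest the
    0.5-probability threshold (V closest to A on the G₃ scale)."""
    rows = []
    for fd, df_fold in counts.groupby("fold"):
        df_fold = df_fold.sort_values("threshold")
        _, _, auc = roc_from_counts(df_fold)
        mid = df_fold.iloc[(df_fold["threshold"] - g3.A).abs().argmin()]
        tp, fp, tn, fn = (int(mid[k]) for k in ("TP", "FP", "TN", "FN"))
        tot = tp + fp + tn + fn
        acc = (tp + tn) / tot if tot else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        rows.append({"fold": int(fd), "auc": auc, "accuracy": acc, "f1": f1})
    return pd.DataFrame(rows)
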