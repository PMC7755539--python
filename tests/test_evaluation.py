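"""Secure evaluation: confusion counts vs the brute-force oracle, the
partition identity, threshold monotonicity, masking discordance bounds and
ROC/AUC reporting."""

import numpy as np
import pandas as pd
import pytest

from thelr import bfv
from thelr.cohort import CohortSpec, generate_cohort, prepare
from thelr.dataprep import pack_evaluation_folds, pack_training_set
from thelr.evaluation import (SecureEvaluationSession, confusion_oracle,
                              roc_from_counts, summarize_counts)
from thelr.ring import derive_rng
from thelr.sigmoid import g3_eval_int, threshold_grid
from thelr.training import IntegerOracleTrainer, TrainingConfig


class TestConfusionOracle:
    def test_all_ones(self):
        c = confusion_oracle([5, 5], [1, 1], [1, 1], V=3)
        assert c == {"TP": 2, "FP": 0, "TN": 0, "FN": 0}

    def test_partition_identity_random(self):
        rng = np.random.default_rng(0)
        sig = rng.integers(-100, 100, 50)
        y = rng.integers(0, 2, 50)
        occ = rng.integers(0, 2, 50)
        c = confusion_oracle(sig, y, occ, V=0)
        assert sum(c.values()) == occ.sum()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        sig = rng.integers(-100, 100, 80)
        y = rng.integers(0, 2, 80)
        occ = np.ones(80, dtype=int)
        tps, tns = [], []
        for V in range(-120, 121, 10):
            c = confusion_oracle(sig, y, occ, V)
            tps.append(c["TP"])
            tns.append(c["TN"])
        assert all(a >= b for a, b in zip(tps, tps[1:]))   # TP nonincreasing
        assert all(a <= b for a, b in zip(tns, tns[1:]))   # TN nondecreasing


class TestRoc:
    def test_perfectly_separable_auc_is_one(self):
        rows = []
        for V in range(0, 11):
            c = confusion_oracle([1] * 5 + [9] * 5, [0] * 5 + [1] * 5,
                                 [1] * 10, V)
            rows.append({"fold": 1, "threshold": V, **c})
        _, _, auc = roc_from_counts(pd.DataFrame(rows))
        assert auc == pytest.approx(1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(2)
        sig = rng.integers(0, 1000, 2000)
        y = rng.integers(0, 2, 2000)
        rows = [{"fold": 1, "threshold": V,
                 **confusion_oracle(sig, y, np.ones(2000, int), V)}
                for V in range(0, 1001, 10)]
        _, _, auc = roc_from_counts(pd.DataFrame(rows))
        assert abs(auc - 0.5) < 0.05


@pytest.fixture(scope="module")
def eval_setup(mini3, mini3_protocol_rlk, g3):
    cohorts, _ = generate_cohort(
        CohortSpec(z=2, n_per_provider=40, n_numeric=2, n_boolean=0, seed=9))
    datasets, fold_vec, scales = prepare(cohorts, fold_seed=9)
    packed = [pack_training_set(ds, mini3.pk1, mini3.p1,
                                derive_rng(9, "pack", ds.provider_id))
              for ds in datasets]
    cfg = TrainingConfig(epoch=9, alpha=0.5, epsilon=0.01)
    oracle = IntegerOracleTrainer(
        [(ds.features, ds.labels) for ds in datasets], fold_vec, scales,
        g3, cfg, mini3.p1.t).run(datasets[0].d)
    eval_packs = [pack_evaluation_folds(ds, fold_vec, mini3.pk1, mini3.p1,
                                        100 + i)
                  for i, ds in enumerate(datasets)]
    return datasets, fold_vec, scales, oracle.bank, eval_packs


def oracle_counts_for(datasets, fold_vec, scales, bank, eval_packs, g3, t, n,
                      fd, V):
    sc = np.concatenate(([1.0], scales))
    B = [int(np.sign(v) * np.floor(abs(v) + 0.5))
         for v in bank[fd - 1] * 1000 / sc]
    out = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for pi, ds in enumerate(datasets):
        pk_ = eval_packs[pi][fd]
        idx = np.flatnonzero(fold_vec == fd)
        xl = [B[0] + sum(B[j + 1] * int(ds.features[i, j])
                         for j in range(ds.d)) for i in idx]
        half = t // 2
        G = [((g3.A + g3.B * v + g3.C * v ** 3) % t + half) % t - half
             for v in xl]
        g0 = ((g3.A + g3.B * B[0] + g3.C * B[0] ** 3) % t + half) % t - half
        sig = np.full(n, g0, dtype=np.int64)
        sig[pk_.slots] = G
        yv = np.zeros(n, dtype=int)
        yv[pk_.slots] = ds.labels[idx]
        c = confusion_oracle(sig, yv, pk_.occupancy, V)
        for k in out:
            out[k] += c[k]
    return out


class TestSecureEvaluation:
    def test_unmasked_counts_equal_oracle(self, mini3, mini3_protocol_rlk,
                                          g3, eval_setup):
        datasets, fold_vec, scales, bank, eval_packs = eval_setup
        sess = SecureEvaluationSession(
            eval_packs, mini3.keys1[:-1], mini3.keys1[-1], bank, scales, g3,
            mini3_protocol_rlk, mini3.pk1, mini3.p1, 77,
            mask_predictions=False, mask_counts=False)
        res = sess.run(folds=[1, 4])
        t, n = mini3.p1.t, mini3.p1.n
        for _, row in res.counts.iterrows():
            exp = oracle_counts_for(datasets, fold_vec, scales, bank,
                                    eval_packs, g3, t, n,
                                    int(row["fold"]), int(row["threshold"]))
            for k in exp:
                assert int(row[k]) == exp[k]

    def test_partition_identity_all_thresholds(self, mini3,
                                               mini3_protocol_rlk, g3,
                                               eval_setup):
        datasets, fold_vec, scales, bank, eval_packs = eval_setup
        sess = SecureEvaluationSession(
            eval_packs, mini3.keys1[:-1], mini3.keys1[-1], bank, scales, g3,
            mini3_protocol_rlk, mini3.pk1, mini3.p1, 78,
            mask_predictions=False, mask_counts=True)
        res = sess.run(folds=[2])
        fold_total = sum(p[2].fold_size for p in eval_packs)
        assert len(res.counts) == 101
        sums = res.counts[["TP", "FP", "TN", "FN"]].sum(axis=1)
        assert np.all(sums == fold_total)

    def test_masked_discordance_confined_to_mask_band(self, mini3,
                                                      mini3_protocol_rlk, g3,
                                                      eval_setup):
        """With occupied-slot masking on, a count may differ from the
        unmasked run only for samples whose true G₃ value lies within
        mask_bound of the threshold."""
        datasets, fold_vec, scales, bank, eval_packs = eval_setup
        sess = SecureEvaluationSession(
            eval_packs, mini3.keys1[:-1], mini3.keys1[-1], bank, scales, g3,
            mini3_protocol_rlk, mini3.pk1, mini3.p1, 79,
            mask_predictions=True, mask_counts=True)
        res = sess.run(folds=[3])
        t, n = mini3.p1.t, mini3.p1.n
        for _, row in res.counts.iterrows():
            V = int(row["threshold"])
            exp = oracle_counts_for(datasets, fold_vec, scales, bank,
                                    eval_packs, g3, t, n, 3, V)
            # bound the number of discordant cells by the samples near V
            near = 0
            sc = np.concatenate(([1.0], scales))
            B = [int(np.sign(v) * np.floor(abs(v) + 0.5))
                 for v in bank[2] * 1000 / sc]
            for ds in datasets:
                idx = np.flatnonzero(fold_vec == 3)
                for i in idx:
                    xl = B[0] + sum(B[j + 1] * int(ds.features[i, j])
                                    for j in range(ds.d))
                    if abs(int(g3_eval_int(g3, xl)) - V) <= g3.mask_bound:
                        near += 1
            for k in ("TP", "FP", "TN", "FN"):
                assert abs(int(row[k]) - exp[k]) <= near

    def test_summary_metrics_columns(self, g3):
        rows = [{"fold": 1, "threshold": V,
                 **confusion_oracle([g3.A - 5, g3.A + 5], [0, 1], [1, 1], V)}
                for V in threshold_grid(g3)]
        s = summarize_counts(pd.DataFrame(rows), g3)
        assert list(s.columns) == ["fold", "auc", "accuracy", "f1"]
        assert s.iloc[0]["auc"] == pytest.approx(1.0)
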