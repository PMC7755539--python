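"""Synthetic multicenter logistic cohorts with known ground truth, plus the
two plaintext reference trainers used for equivalence and accuracy-loss
studies:

* ``float_lr_oracle`` — ordinary minibatch gradient descent with the exact
  sigmoid on the same fold schedule (the "nonsecure" baseline);
* ``integer_pipeline_oracle`` — the exact plaintext mirror of the secure
  pipeline (same G₃, same mod-t arithmetic, same rounding), bit-identical
  to the encrypted run.

The default benchmark shape is 3 providers × 1024 samples with 9 raw
features (numeric + boolean + one nominal), echoing the protocol's
experimental geometry at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataprep import (ColumnSpec, IntegerizedDataset, RawCohort,
                       assign_folds, integerize_table)
from .sigmoid import IntegerizedSigmoid, g3_eval_int, sigmoid, threshold_grid
from .training import (IntegerOracleTrainer, TrainingConfig, TrainingResult,
                       convergence_ratio, model_for_slot)
from .evaluation import confusion_oracle, roc_from_counts


@dataclass
class CohortSpec:
    z: int = 3
    n_per_provider: int = 1024
    n_numeric: int = 6
    n_boolean: int = 2
    nominal_levels: int = 0        # 0 disables the nominal column (≤ 4 levels)
    numeric_scale: float = 10.0
    beta_star: np.ndarray | None = None   # over expanded columns, incl intercept
    provider_shift: float = 0.0    # per-provider numeric covariate shift
    seed: int = 0

    @property
    def d_expanded(self) -> int:
        return self.n_numeric + self.n_boolean + self.nominal_levels


def default_beta(spec: CohortSpec) -> np.ndarray:
    """Moderate, reproducible effects keeping |x^Tβ| well inside (−8, 8)."""
    rng = np.random.default_rng([spec.seed, 77])
    beta = np.zeros(spec.d_expanded + 1)
    beta[1:1 + spec.n_numeric] = rng.uniform(0.3, 0.8, spec.n_numeric) \
        * rng.choice([-1, 1], spec.n_numeric)
    off = 1 + spec.n_numeric
    beta[off:off + spec.n_boolean] = rng.uniform(-0.8, 0.8, spec.n_boolean)
    off += spec.n_boolean
    beta[off:] = rng.uniform(-0.5, 0.5, spec.nominal_levels)
    return beta


def generate_cohort(spec: CohortSpec) -> tuple[list[RawCohort], dict]:
    """Per-provider tables with Bernoulli(σ(x^Tβ*)) labels."""
    beta = spec.beta_star if spec.beta_star is not None else default_beta(spec)
    cohorts = []
    for p in range(spec.z):
        rng = np.random.default_rng([spec.seed, p])
        cols = {}
        shift = spec.provider_shift * (p - (spec.z - 1) / 2)
        num = np.round(rng.normal(shift, 1.0,
                                  (spec.n_per_provider, spec.n_numeric)), 2)
        num = np.clip(num, -4.0, 4.0)
        for j in range(spec.n_numeric):
            cols[f"num{j}"] = num[:, j]
        boo = rng.integers(0, 2, (spec.n_per_provider, spec.n_boolean))
        for j in range(spec.n_boolean):
            cols[f"bin{j}"] = boo[:, j]
        expanded = [num, boo]
        if spec.nominal_levels:
            lev = rng.integers(0, spec.nominal_levels, spec.n_per_provider)
            cols["cat0"] = [f"L{v}" for v in lev]
            onehot = np.stack([(lev == v).astype(float)
                               for v in range(spec.nominal_levels)], axis=1)
            expanded.append(onehot)
        X = np.concatenate(expanded, axis=1)
        lin = beta[0] + X @ beta[1:]
        y = (rng.random(spec.n_per_provider) < sigmoid(lin)).astype(int)
        cols["outcome"] = y
        schema = ([ColumnSpec(f"num{j}", "numeric", spec.numeric_scale)
                   for j in range(spec.n_numeric)]
                  + [ColumnSpec(f"bin{j}", "boolean") for j in range(spec.n_boolean)]
                  + ([ColumnSpec("cat0", "nominal")] if spec.nominal_levels else [])
                  + [ColumnSpec("outcome", "label")])
        cohorts.append(RawCohort(f"provider-{p}", pd.DataFrame(cols), schema))
    truth = {"beta_star": list(np.asarray(beta, dtype=float)),
             "spec": {"z": spec.z, "N": spec.n_per_provider,
                      "d_expanded": spec.d_expanded, "seed": spec.seed}}
    return cohorts, truth


def prepare(cohorts: list[RawCohort], fold_seed: int = 0
            ) -> tuple[list[IntegerizedDataset], np.ndarray, np.ndarray]:
    """Integerize all providers and draw the shared fold vector (the study's
    single data-division vector, identical across providers)."""
    datasets = [integerize_table(c) for c in cohorts]
    fold_vec = assign_folds(datasets[0].labels, k=10, seed=fold_seed)
    return datasets, fold_vec, datasets[0].scales


# ---------------------------------------------------------------------------
# reference trainers
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    train: TrainingResult
    fold_scores: dict            # fold -> (scores on G3 scale, labels)
    summary: pd.DataFrame        # per fold auc/accuracy/f1
    counts: pd.DataFrame


def float_lr_oracle(datasets: list[IntegerizedDataset], fold_vec: np.ndarray,
                    cfg: TrainingConfig, g3: IntegerizedSigmoid) -> OracleResult:
    """Minibatch GD with the exact sigmoid, same rotation schedule.

    Linear predictors are clamped to ±8 (with a violation count) mirroring
    the approximation interval of the secure path.
    """
    X = np.concatenate([ds.features / ds.scales[None, :] for ds in datasets])
    y = np.concatenate([ds.labels for ds in datasets])
    fv = np.concatenate([fold_vec] * len(datasets))
    d = X.shape[1]
    b = cfg.b if cfg.b is not None else max(len(y) // 10, 1)
    bank = np.zeros((10, d + 1))
    snapshots, ratios = [], []
    violations = 0
    converged = False
    for it in range(cfg.epoch // 9):
        old = bank.copy()
        for cv in range(1, 10):
            m = model_for_slot(fv, cv)
            for model in range(1, 11):
                idx = np.flatnonzero(m == model)
                if not idx.size:
                    continue
                beta = bank[model - 1]
                lin = beta[0] + X[idx] @ beta[1:]
                violations += int(np.sum(np.abs(lin) >= 8.0))
                lin = np.clip(lin, -8.0, 8.0)
                resid = sigmoid(lin) - y[idx]
                g = np.concatenate(([resid.sum()], resid @ X[idx]))
                bank[model - 1] = beta - cfg.alpha * g / b
            snapshots.append(bank.copy())
        r = convergence_ratio(bank, old)
        ratios.append(r)
        if r < cfg.epsilon:
            converged = True
            break
    tr = TrainingResult(bank, snapshots, converged, ratios, violations)
    scores = _fold_scores_float(bank, X, y, fv, g3)
    counts, summary = score_counts(scores, g3)
    return OracleResult(tr, scores, summary, counts)


def integer_pipeline_oracle(datasets: list[IntegerizedDataset],
                            fold_vec: np.ndarray, cfg: TrainingConfig,
                            g3: IntegerizedSigmoid, t: int) -> OracleResult:
    """The plaintext mirror of the secure integer pipeline."""
    trainer = IntegerOracleTrainer(
        [(ds.features, ds.labels) for ds in datasets], fold_vec,
        datasets[0].scales, g3, cfg, t)
    tr = trainer.run(datasets[0].d)
    scores = _fold_scores_integer(tr.bank, datasets, fold_vec, g3, cfg.sf, t)
    counts, summary = score_counts(scores, g3)
    return OracleResult(tr, scores, summary, counts)


def _fold_scores_float(bank, X, y, fv, g3):
    out = {}
    for fd in range(1, 11):
        idx = np.flatnonzero(fv == fd)
        beta = bank[fd - 1]
        lin = np.clip(beta[0] + X[idx] @ beta[1:], -8.0, 8.0)
        # probabilities mapped onto the G3 output scale for a shared grid
        out[fd] = ((sigmoid(lin) * g3.S_out).astype(np.int64), y[idx])
    return out


def _fold_scores_integer(bank, datasets, fold_vec, g3, sf, t):
    out = {}
    scales = np.concatenate(([1.0], datasets[0].scales))
    for fd in range(1, 11):
        scores, labels = [], []
        beta = bank[fd - 1]
        B = np.array([int(np.sign(v) * np.floor(abs(v) + 0.5))
                      for v in beta * sf / scales], dtype=object)
        for ds in datasets:
            idx = np.flatnonzero(fold_vec == fd)
            xlin = B[0] + ds.features[idx].astype(object) @ B[1:]
            G = np.array([int(g3_eval_int(g3, int(v)) % t) for v in xlin],
                         dtype=object)
            half = t // 2
            G = np.where(G > half, G - t, G)
            scores.append(G.astype(np.int64))
            labels.append(ds.labels[idx])
        out[fd] = (np.concatenate(scores), np.concatenate(labels))
    return out


def score_counts(fold_scores: dict, g3: IntegerizedSigmoid
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion counts of plaintext scores over the standard 101-V grid."""
    from .evaluation import summarize_counts
    grid = threshold_grid(g3)
    rows = []
    for fd, (scores, labels) in fold_scores.items():
        occ = np.ones(len(labels), dtype=int)
        for V in grid:
            rows.append({"fold": fd, "threshold": V,
                         **confusion_oracle(scores, labels, occ, V)})
    counts = pd.DataFrame(rows)
    return counts, summarize_counts(counts, g3)


def accuracy_report(secure_summary: pd.DataFrame,
                    float_summary: pd.DataFrame) -> pd.DataFrame:
    """Per-metric comparison (mean, sd, paired difference, paired t-test)."""
    rows = []
    for metric in ("auc", "accuracy", "f1"):
        a = float_summary.sort_values("fold")[metric].to_numpy()
        b = secure_summary.sort_values("fold")[metric].to_numpy()
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
        rows.append({"metric": metric,
                     "nonsecure_mean": float(a.mean()),
                     "nonsecure_sd": float(a.std(ddof=1)),
                     "secure_mean": float(b.mean()),
                     "secure_sd": float(b.std(ddof=1)),
                     "mean_gap": float((a - b).mean()),
                     "p_value": p})
    return pd.DataFrame(rows)
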