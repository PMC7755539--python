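"""Provider-side data preparation.

Raw tabular cohorts (numeric / boolean / ordinal / nominal features plus a
binary label) are scaled and rounded to integers, split into 10 stratified
cross-validation folds, CRT-batched column-by-column (one polynomial per
feature, slots = samples) and encrypted under the combined public key.

Slot indices are 0-based internally; fold ids are 1-based (1..10), matching
the protocol's fold vector x^{d+1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bfv
from .ring import ConfigurationError, batch_encode

DEFAULT_FEATURE_BOUND = 800   # |scaled feature| cap: keeps label_const·|x|·(fold
                              # aggregate) below t/2 with masking headroom


@dataclass
class ColumnSpec:
    name: str
    kind: str                  # numeric | boolean | ordinal | nominal | label
    scale: float = 1.0         # numeric columns only


@dataclass
class RawCohort:
    provider_id: str
    table: pd.DataFrame
    schema: list[ColumnSpec]

    def __post_init__(self):
        lab = [c for c in self.schema if c.kind == "label"]
        if len(lab) != 1:
            raise ConfigurationError("schema needs exactly one label column")
        y = self.table[lab[0].name]
        if not set(np.unique(y)) <= {0, 1}:
            raise ConfigurationError("labels must be binary 0/1")


@dataclass
class IntegerizedDataset:
    provider_id: str
    features: np.ndarray       # (N, d) int64, integerized
    labels: np.ndarray         # (N,) int64 in {0,1}
    columns: list[str]         # expanded feature names (post one-hot)
    scales: np.ndarray         # (d,) effective scale per expanded column
    bound: int = DEFAULT_FEATURE_BOUND

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def d(self) -> int:
        return self.features.shape[1]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def integerize_table(cohort: RawCohort,
                     bound: int = DEFAULT_FEATURE_BOUND) -> IntegerizedDataset:
    """Scale/round numerics, map boolean/ordinal to small integers, one-hot
    expand nominals; enforce the overflow magnitude bound per column."""
    cols, scales, mats = [], [], []
    labels = None
    for spec in cohort.schema:
        col = cohort.table[spec.name]
        if spec.kind == "label":
            labels = col.to_numpy().astype(np.int64)
            continue
        if spec.kind == "numeric":
            vals = _round_half_away(col.to_numpy(dtype=float) * spec.scale)
            mats.append(vals[:, None])
            cols.append(spec.name)
            scales.append(float(spec.scale))
        elif spec.kind in ("boolean", "ordinal"):
            if spec.kind == "boolean" and col.dtype == object:
                mapping = {v: i for i, v in enumerate(sorted(set(col)))}
                vals = col.map(mapping).to_numpy()
            else:
                vals = col.to_numpy()
            mats.append(vals.astype(np.int64)[:, None])
            cols.append(spec.name)
            scales.append(1.0)
        elif spec.kind == "nominal":
            levels = sorted(set(col))
            onehot = np.stack([(col == lv).to_numpy().astype(np.int64)
                               for lv in levels], axis=1)
            mats.append(onehot)
            cols.extend(f"{spec.name}={lv}" for lv in levels)
            scales.extend([1.0] * len(levels))
        else:
            raise ConfigurationError(f"unknown column kind {spec.kind!r}")
    feats = np.concatenate(mats, axis=1) if mats else np.zeros((len(labels), 0),
                                                              dtype=np.int64)
    over = np.max(np.abs(feats), axis=0) > bound
    if np.any(over):
        bad = [cols[i] for i in np.flatnonzero(over)]
        raise ConfigurationError(
            f"integerized magnitude exceeds bound {bound} in column(s) {bad}")
    return IntegerizedDataset(cohort.provider_id, feats, labels, cols,
                              np.array(scales), bound)


# ---------------------------------------------------------------------------
# fold assignment (stratified) and the fold vector x^{d+1}
# ---------------------------------------------------------------------------

def assign_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Per-sample fold ids in 1..k via stratified round-robin after a seeded
    shuffle; fold sizes and per-fold class ratios differ by ≤ 1 sample."""
    labels = np.asarray(labels)
    if k > len(labels):
        raise ConfigurationError("more folds than samples")
    rng = np.random.default_rng(seed)
    fold = np.zeros(len(labels), dtype=np.int64)
    start = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold[i] = (start + pos) % k + 1
        start += len(idx)       # continue the round-robin across classes
    return fold


def encode_fold_vector(members: dict[int, list[int]], n_samples: int) -> np.ndarray:
    """Fold→member-list form to the per-sample vector x^{d+1}."""
    vec = np.zeros(n_samples, dtype=np.int64)
    seen = set()
    for fid, idxs in members.items():
        for i in idxs:
            if i in seen:
                raise ConfigurationError(f"sample {i} assigned to two folds")
            seen.add(i)
            vec[i] = fid
    if len(seen) != n_samples:
        raise ConfigurationError("fold assignment does not cover all samples")
    return vec


def fold_members(vec: np.ndarray) -> dict[int, list[int]]:
    return {int(f): list(np.flatnonzero(vec == f)) for f in np.unique(vec)}


# ---------------------------------------------------------------------------
# encryption packing
# ---------------------------------------------------------------------------

@dataclass
class PackedTrainingSet:
    provider_id: str
    x_cts: list                # d ciphertexts, slots 0..N-1 = column values
    y_ct: "bfv.Ciphertext"     # labels in {0,1}
    n_samples: int

    @property
    def d(self) -> int:
        return len(self.x_cts)


def pack_training_set(ds: IntegerizedDataset, pk: "bfv.CombinedPublicKey",
                      params: "bfv.EncryptionParams",
                      rng: np.random.Generator) -> PackedTrainingSet:
    """d+1 ciphertexts: one per feature column plus the label column."""
    if ds.n_samples > params.n:
        raise ConfigurationError(
            f"N={ds.n_samples} exceeds slot count n={params.n}; chunking "
            "across several ciphertexts is out of scope")
    polys = [batch_encode(ds.features[:, j], params.t_chain)
             for j in range(ds.d)]
    polys.append(batch_encode(ds.labels, params.t_chain))
    cts = bfv.encrypt_many(polys, pk, params, rng)
    return PackedTrainingSet(ds.provider_id, cts[:-1], cts[-1], ds.n_samples)


@dataclass
class EvalPacking:
    provider_id: str
    fold_id: int
    slots: np.ndarray          # random injective slot placement of the samples
    occupancy: np.ndarray      # (n,) 0/1, provider-private
    x_cts: list
    y_ct: "bfv.Ciphertext"
    occ_ct: "bfv.Ciphertext"
    fold_size: int


def pack_evaluation_folds(ds: IntegerizedDataset, fold_vec: np.ndarray,
                          pk: "bfv.CombinedPublicKey",
                          params: "bfv.EncryptionParams",
                          seed: int) -> dict[int, EvalPacking]:
    """Per fold: samples placed at seeded random slots, plus the encrypted
    occupancy vector recording which slots are genuine."""
    out = {}
    for fid, idxs in fold_members(fold_vec).items():
        if len(idxs) > params.n:
            raise ConfigurationError("fold larger than slot count")
        rng = np.random.default_rng([seed, fid])
        slots = rng.choice(params.n, size=len(idxs), replace=False)
        occ = np.zeros(params.n, dtype=np.int64)
        occ[slots] = 1
        polys = []
        for j in range(ds.d):
            col = np.zeros(params.n, dtype=np.int64)
            col[slots] = ds.features[idxs, j]
            polys.append(batch_encode(col, params.t_chain))
        yv = np.zeros(params.n, dtype=np.int64)
        yv[slots] = ds.labels[idxs]
        polys.append(batch_encode(yv, params.t_chain))
        polys.append(batch_encode(occ, params.t_chain))
        enc_rng = np.random.default_rng([seed, fid, 1])
        cts = bfv.encrypt_many(polys, pk, params, enc_rng)
        out[fid] = EvalPacking(ds.provider_id, fid, slots, occ,
                               cts[:-2], cts[-2], cts[-1], len(idxs))
    return out


# ---------------------------------------------------------------------------
# CSV + schema sidecar IO
# ---------------------------------------------------------------------------

def load_cohort_csv(csv_path, schema_yaml, provider_id: str) -> RawCohort:
    import yaml
    with open(schema_yaml) as fh:
        raw = yaml.safe_load(fh)
    schema = [ColumnSpec(name=c["name"], kind=c["kind"],
                         scale=float(c.get("scale", 1.0))) for c in raw["columns"]]
    return RawCohort(provider_id, pd.read_csv(csv_path), schema)


def save_cohort_csv(cohort: RawCohort, csv_path, schema_yaml) -> None:
    import yaml
    cohort.table.to_csv(csv_path, index=False)
    with open(schema_yaml, "w") as fh:
        yaml.safe_dump({"columns": [
            {"name": c.name, "kind": c.kind, "scale": c.scale}
            for c in cohort.schema]}, fh)
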