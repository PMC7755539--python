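"""Protocol runtime: parties, message transcript, study lifecycle and the
five-step workflow (initialization → application/authorization → key
generation + data preparation → relinearization keygen → training +
evaluation).

Transport is in-process message passing; every inter-party transfer is
recorded in a JSON-lines transcript (sender, receiver, payload type, byte
size) from which the scalability report is derived.  The interactive
research-authorization website of the deployed system is modelled as
in-process state.
"""

from __future__ import annotations

import json
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bfv
from .cohort import (CohortSpec, OracleResult, accuracy_report,
                     float_lr_oracle, generate_cohort, integer_pipeline_oracle,
                     prepare)
from .dataprep import (RawCohort, load_cohort_csv, pack_evaluation_folds,
                       pack_training_set)
from .evaluation import SecureEvaluationSession
from .ring import ConfigurationError, derive_rng
from .sigmoid import build_integerized
from .training import SecureTrainingSession, TrainingConfig


class AuthorizationRefused(RuntimeError):
    pass


@dataclass
class StudyRequest:
    study_id: str
    query: str = ""
    providers: list = field(default_factory=list)
    feature_columns: list = field(default_factory=list)
    label_column: str = "outcome"
    epoch: int = 45
    alpha: float = 0.1
    epsilon: float = 0.05


@dataclass
class AuthorizationState:
    decisions: dict = field(default_factory=dict)   # provider -> pending/approved/refused

    def all_approved(self, providers) -> bool:
        return all(self.decisions.get(p) == "approved" for p in providers)


class Transcript:
    """Ordered record of every inter-party transfer."""

    def __init__(self):
        self.entries: list[dict] = []

    def log(self, **kw):
        kw.setdefault("index", len(self.entries))
        self.entries.append(kw)

    def dump(self, path):
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def digest(self) -> str:
        h = hashlib.sha256()
        for e in self.entries:
            h.update(json.dumps(e, sort_keys=True).encode())
        return h.hexdigest()


def apply_query(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Row filter with a minimal expression grammar (comparisons, and/or)."""
    if not condition or not condition.strip():
        return table
    try:
        return table.query(condition)
    except Exception as exc:
        raise ConfigurationError(f"malformed query condition: {exc}") from exc


def transcript_report(source) -> pd.DataFrame:
    """Per-step transfer summary (message counts and byte totals)."""
    if isinstance(source, Transcript):
        df = source.to_frame()
    else:
        path = Path(source)
        if path.is_dir():
            path = path / "transcript.jsonl"
        df = pd.read_json(path, lines=True)
    if df.empty:
        return pd.DataFrame(columns=["step", "payload", "messages", "bytes"])
    rep = (df.groupby(["step", "payload"])
             .agg(messages=("nbytes", "size"), bytes=("nbytes", "sum"))
             .reset_index())
    return rep


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

def run_study(config: dict, outdir) -> Path:
    """Execute the full workflow from a study configuration.

    Config keys: ``profile`` (parameter profile), ``seed`` (master seed),
    ``study`` (query/epoch/alpha/epsilon/label settings), ``cohort``
    (synthetic CohortSpec fields) or ``providers`` (csv+schema paths),
    ``authorization`` (optional provider→decision map), ``evaluate`` (bool).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcript = Transcript()
    seed = int(config.get("seed", 0))
    profile = config.get("profile", "test")

    # step 1: initialization of encryption parameters
    p1, p2 = bfv.setup_params(profile)
    g3 = build_integerized()
    (outdir / "params.json").write_text(json.dumps(
        {"param1": p1.to_dict(), "param2": p2.to_dict()}, indent=1))
    (outdir / "constants.json").write_text(json.dumps(g3.to_dict(), indent=1))

    # step 2: research application + authorization
    study = config.get("study", {})
    if "cohort" in config:
        spec = CohortSpec(**{**config["cohort"], "seed": seed})
        cohorts, truth = generate_cohort(spec)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    else:
        cohorts = [load_cohort_csv(p["csv"], p["schema"], p["id"])
                   for p in config["providers"]]
    provider_ids = [c.provider_id for c in cohorts]
    req = StudyRequest(study_id=study.get("id", "study-1"),
                       query=study.get("query", ""),
                       providers=provider_ids,
                       epoch=int(study.get("epoch", 45)),
                       alpha=float(study.get("alpha", 0.1)),
                       epsilon=float(study.get("epsilon", 0.05)))
    auth = AuthorizationState(
        {p: config.get("authorization", {}).get(p, "approved")
         for p in provider_ids})
    for p, decision in auth.decisions.items():
        transcript.log(step="authorization", sender=p, receiver="sp",
                       payload=f"decision:{decision}", nbytes=1)
    if not auth.all_approved(provider_ids):
        transcript.dump(outdir / "transcript.jsonl")
        raise AuthorizationRefused(
            f"aborted before key generation: {auth.decisions}")

    # step 3: key generation + data preparation
    cohorts = [RawCohort(c.provider_id, apply_query(c.table, req.query),
                         c.schema) for c in cohorts]
    datasets, fold_vec, scales = prepare(cohorts, fold_seed=seed)
    np.savetxt(outdir / "fold_vector.txt", fold_vec, fmt="%d")
    party_ids = provider_ids + ["researcher"]
    crs1 = bfv.keygen_common(p1, seed)
    crs2 = bfv.keygen_common(p2, seed)
    keys1 = [bfv.keygen_party(p1, crs1, pid, derive_rng(seed, "kg1", pid))
             for pid in party_ids]
    keys2 = [bfv.keygen_party(p2, crs2, pid, derive_rng(seed, "kg2", pid))
             for pid in party_ids]
    pk1 = bfv.combine_public_keys(keys1, crs1)
    pk2 = bfv.combine_public_keys(keys2, crs2)
    for pid in party_ids:
        transcript.log(step="keygen", sender=pid, receiver="all",
                       payload="public-key-share",
                       nbytes=len(p1.q.primes) * p1.n * 8)
    packed = [pack_training_set(ds, pk1, p1, derive_rng(seed, "pack", ds.provider_id))
              for ds in datasets]
    for ds, ps in zip(datasets, packed):
        transcript.log(step="data-preparation", sender=ds.provider_id,
                       receiver="sp", payload="training-ciphertexts",
                       nbytes=(ps.d + 1) * 2 * len(p1.q.primes) * p1.n * 8)

    # step 4: combined relinearization key
    rlk = bfv.relin_keygen_protocol(keys1, keys2, p1, p2, pk2, seed)
    transcript.log(step="relin-keygen", sender="all", receiver="sp",
                   payload="relinearization-key",
                   nbytes=2 * len(rlk.levels) * len(p1.q.primes) * p1.n * 8)

    # step 5: model training + evaluation
    cfg = TrainingConfig(epoch=req.epoch, alpha=req.alpha, epsilon=req.epsilon)
    session = SecureTrainingSession(
        packed, keys1[:-1], keys1[-1], fold_vec, scales, g3, rlk, pk1, p1,
        cfg, seed, transcript=transcript)
    t0 = time.time()
    result = session.run()
    snaps = pd.DataFrame(
        [{"step": i, **{f"beta{m}_{j}": s[m, j] for m in range(10)
                        for j in range(s.shape[1])}}
         for i, s in enumerate(result.snapshots)])
    snaps.to_csv(outdir / "parameter_snapshots.csv", index=False)

    summary = {"converged": bool(result.converged),
               "diverged": bool(result.diverged),
               "ratios": [float(r) for r in result.ratios],
               "training_seconds": time.time() - t0}
    if config.get("evaluate", True) and not result.diverged:
        eval_packs = [pack_evaluation_folds(ds, fold_vec, pk1, p1,
                                            seed + 1000 + i)
                      for i, ds in enumerate(datasets)]
        esess = SecureEvaluationSession(
            eval_packs, keys1[:-1], keys1[-1], result.bank, scales, g3,
            rlk, pk1, p1, seed, transcript=transcript)
        ev = esess.run(folds=config.get("eval_folds"))
        ev.counts.to_csv(outdir / "confusion_counts.csv", index=False)
        ev.summary.to_csv(outdir / "fold_metrics.csv", index=False)
        summary["mean_auc"] = float(ev.summary["auc"].mean())
    transcript.dump(outdir / "transcript.jsonl")
    summary["transcript_digest"] = transcript.digest()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return outdir
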