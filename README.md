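# thelr — threshold-BFV privacy-preserving multicenter logistic regression

`thelr` implements a complete privacy-preserving protocol for training and
evaluating logistic regression models on patient-level data that is
horizontally distributed across several institutions ("data providers"),
coordinated by an untrusted service provider, on behalf of a researcher.
No party ever sees another party's plaintext data, the researcher's model
parameters stay hidden from the providers and the service provider, and the
only evaluation output revealed to the researcher is a table of per-fold
confusion counts.

It is aimed at biostatisticians and medical-informatics engineers who want
a fully inspectable, pure-Python reference for threshold homomorphic
encryption applied to multicenter clinical modelling.

## The cryptographic core

The scheme is a threshold variant of Brakerski/Fan-Vercauteren (BFV)
somewhat-homomorphic encryption over R_q = Z_q[x]/(xⁿ+1):

* each party *pᵢ* samples a ternary secret share *sᵢ* and publishes
  pkᵢ = −(a·sᵢ + eᵢ); the combined public key pk_co = (Σ pkᵢ, a)
  corresponds to the never-materialized secret s_co = Σ sᵢ;
* encryption, addition and multiplication are textbook BFV
  (c = (pk₀u + e₁ + Δm, pk₁u + e₂), Δ = ⌊q/t⌋), with CRT batching packing
  up to *n* values into one plaintext so every operation is SIMD;
* decryption is full-threshold: every party contributes
  μᵢ = c₁·sᵢ + e_smg with large "smudging" noise, and
  m = ⌊(t/q)·(c₀ + Σμᵢ)⌉ mod t;
* the **combined relinearization key** — the piece that makes deep circuits
  possible with many parties — is produced by a multi-round protocol run
  under a second parameter set whose per-ciphertext plaintext moduli are
  the primes of param1's coefficient modulus: parties encrypt their secret
  shares, the service provider assembles Enc(s_co) and Enc(s_co²)
  homomorphically, forms each key level B^l·s_co² − a_l·s_co − Σᵢe_il under
  encryption, and a threshold decryption reveals the key and nothing else.
  The key's noise is a sum of *z* per-party gaussians, so it grows only
  linearly with the number of parties.

## The statistical layer

Logistic regression P(y=1|x) = σ(xᵀβ) is trained by minibatch gradient
descent entirely on integers: σ is replaced by its degree-3 least-squares
fit on (−8, 8), scaled by SF = 1000 on the input and by the integer output
scale S_out = 627743311836 (probability 1), which makes the integerized
sigmoid exactly

    G₃(X) = A + B·X − X³,   A = ⌊S_out/2⌉,   X = ⌊SF·xᵀβ⌉.

Ten models are trained simultaneously — one per cross-validation fold —
inside one set of batched ciphertexts: at rotation step cv, slot *i*
(fold fᵢ) carries the parameters of model ((fᵢ + cv − 1) mod 10) + 1, so
over cv = 1..9 each model sees exactly the nine folds that are not its own.
Gradients (G₃(xᵀβ) − S_out·y)·xʲ are masked by the providers with uniform
mod-t one-time pads whose per-model sums are disclosed only to the
researcher, who unmasks fold aggregates without ever seeing per-sample
values. Evaluation thresholds the masked predictions on a 101-point grid
from min(G₃) to max(G₃) and reveals only TP/FP/TN/FN per fold per
threshold; occupied prediction slots are masked with uniform noise on
±1569358279 (±0.0025 on the S_out scale) and empty slots with noise
spanning the full G₃ range.

## Worked example

```sh
cat > study.yaml <<'YAML'
profile: mini
seed: 7
cohort: {z: 2, n_per_provider: 60, n_numeric: 2, n_boolean: 1}
study: {epoch: 9, alpha: 0.5, epsilon: 0.05}
eval_folds: [1, 2]
YAML
thelr run study.yaml --out demo-run
```

This generates a 2-provider synthetic cohort, runs the whole 5-step
workflow (parameter initialization, authorization, distributed keygen +
data preparation, the relinearization-key protocol, then encrypted
training and evaluation) and prints the run summary:

```
{"converged": false, "diverged": false, "ratios": [1.0],
 "training_seconds": 17.3, "mean_auc": 0.613,
 "transcript_digest": "e6224c69ff4c..."}
```

`demo-run/confusion_counts.csv` holds the researcher's only evaluation
view — counts per fold per threshold (thresholds live on the G₃ output
scale, e.g. −38005271848 is the grid minimum):

```
 fold    threshold  TP  FP  TN  FN
    1 -38005271848   6   6   0   0
    1 -30967733293   6   6   0   0
```

and `demo-run/fold_metrics.csv` the derived per-fold AUC/accuracy/F₁
(noisy here because each evaluation fold holds only 12 samples):

```
 fold      auc  accuracy       f1
    1 0.375000  0.416667 0.363636
    2 0.851852  0.666667 0.333333
```

`ratios` are the per-outer-loop convergence statistics
‖β_new − β_old‖/‖β_new‖; nine cv-steps are one outer loop, so a longer
`epoch` (e.g. the default 45) is needed before the 0.05 tolerance is met.
The transcript (`transcript.jsonl`) records every inter-party message with
byte sizes; `thelr report demo-run` summarizes it.

Library-level entry points mirror the workflow: `thelr.bfv` (scheme and
relinearization-key protocol), `thelr.sigmoid` (G₃), `thelr.dataprep`
(integerization, folds, packing), `thelr.training` / `thelr.evaluation`
(the secure sessions and their plaintext mirrors), `thelr.cohort`
(synthetic data and reference oracles), `thelr.runtime` (the study
lifecycle).

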