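# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `thelr`.

## Threshold BFV scheme

**Ring and representation.** All arithmetic lives in R_q = Z_q[x]/(xⁿ+1)
with n a power of two and q a product of distinct primes P ≡ 1 (mod 2n).
Elements are held in RNS form (one coefficient vector per prime) and
multiplied with the negacyclic NTT; the 2n-th root of unity per prime is
the smallest primitive one, fixed in the parameter fingerprint for
reproducibility. Chains whose primes fit below 2³¹ use int64 arithmetic
with a numba-compiled butterfly kernel; larger (reference-scale) primes
fall back to exact Python-int object arrays.

**Parameter profiles.**

| profile | n | q1 | t1 | q2 | use |
|---|---|---|---|---|---|
| reference | 16384 | 8 primes, 438 bits | 1125899904679937 | 5 primes, 300 bits | published deployment set (128/192-bit claims) |
| test | 4096 | 15 × 30-bit | 2 × 28-bit primes (≈2⁵⁶) | 7 × 30-bit | randomized correctness + end-to-end equivalence |
| mini | 1024 | 15 × 30-bit | 2 × 28-bit (≈2⁵⁶) | 7 × 30-bit | fast end-to-end runs, unit tests |
| tiny | 1024 | 6 × 28-bit | one 22-bit prime | 7 × 28-bit | cheap scheme-level tests, relin-noise study |

The desk-scale profiles keep every structural constraint of the reference
set (degree a power of two, all primes ≡ 1 mod 2n, shared degree across
param1/param2, param2 plaintext moduli = param1 coefficient primes) but
give no cryptographic security; they are flagged `production=False`. The
desk-scale plaintext modulus is a product of two NTT-friendly primes —
the congruence condition explicitly admits squarefree composites — chosen
≈2⁵⁶ so that gradient slot values, which scale with the label constant
6.28·10¹¹ times a feature bound, stay far from ±t/2. q1's size is set by
the deepest circuit (four chained ciphertext multiplications plus
smudging): each multiplication multiplies the integer noise by ≈ n·t, so
15 30-bit primes (450 bits) leave ≳15 bits of headroom after the
depth-4 gradient circuit and a 40-bit smudging margin.

**Multiplication.** The (t/q)-scaled tensor product is computed exactly:
operands are centered-lifted into an extended RNS basis large enough for
the integer tensor (2·|q| + log₂n + 4 bits), multiplied with NTTs,
CRT-composed to Python ints, scaled with exact rational round-half-up and
reduced back. A faster int64 path exists only for decryption's final
scale-round, where ⌊t·w/q⌉ mod t is assembled per-prime from precomputed
integer parts plus a float64 fractional correction; its rounding decision
is exact whenever the remaining noise budget exceeds ≈13 bits, which the
smudging sizing guarantees, and the multiprecision path remains available
(`exact=True`) and is asserted equal in the tests.

**Relinearization.** Keys follow the classic base-2^T decomposition:
level l holds (−(a_l·s + e_l) + B^l·s², a_l) with B = 2^T, T = 60 (one
digit per ≤60-bit prime; L = ⌊log₂q/T⌋). The multiparty generation
protocol works per param1 prime p_j: each party encrypts its share s1ᵢ
under pk2_co as a plain (non-batched) polynomial mod p_j — plaintext
multiplication is then exactly R_{p_j} multiplication, which is what makes
the per-prime emulation of R_q1 arithmetic sound; the service provider
sums to Enc(s_co), parties return Enc(s_co·s1ᵢ) plus an encryption of zero
carrying function-privacy noise 2⁴⁰ above the product's noise bound, and
each level is assembled under encryption and threshold-decrypted. The
resulting key error is Σᵢ e_il — a sum of z discrete gaussians — hence the
measured key noise grows like √z–z, not quadratically.

**Smudging.** Partial decryptions carry centered-uniform noise of
`noise_bound + 40` bits, keeping var_c/var_smg ≤ 2⁻⁸⁰ ≤ 2⁻⁴⁰ for every
tracked ciphertext; the per-ciphertext noise bound is maintained
analytically through every operation (log-sum for additions, n·t growth
for multiplications, ‖plain‖·n for plaintext products). The bound is
deliberately loose (a few bits above measured noise) — it only sizes
smudging and the function-privacy noise.

## Sigmoid integerization

σ(x) = 1/(1+e^{−x}) is fitted by discrete least squares on the uniform
grid of step 0.01 over [−8, 8] (the maximum fit error is ≈0.114 at the
interval ends). The input scale SF = 1000 and the output scale
S_out = 627743311836 give G₃(X) = A + B·X − X³ with A = ⌊S_out/2⌉ and
B = round(c₁·S_out/1000); S_out is pinned to the protocol's label
constant, the unique scale at which the cubic coefficient integerizes to
exactly −1. The occupied-slot masking bound 1569358279 equals
⌊0.0025·S_out⌋; the protocol describes it as ±0.005 "scaled down", which
holds on the scale S_out/2 — both printed integers are kept verbatim and
the derived fit coefficients are reported alongside in the constants file.
Note the cubic fit is *not* monotone on the full interval: G₃ peaks at
X* = √(B/3) ≈ 5600, so the threshold grid's extrema come from interior
critical points, computed exactly and checked exhaustively against a
16001-point scan.

## Training and evaluation protocol

Training follows the rotation schedule: epoch counts cv-steps (45 total =
5 outer loops of 9), the convergence ratio ‖β_new−β_old‖/‖β_new‖ is
checked once per outer loop against ε = 0.05, and β is initialized to
zeros for determinism. The minibatch divisor b defaults to the total fold
size across providers. Removable gradient masks are uniform over Z_t —
perfect one-time pads that cancel exactly under mod-t aggregation —
rather than "sufficiently large" bounded noise; this gives maximal hiding
and sidesteps an unspecified bound. Threshold-decryption shares are routed
so providers' shares aggregate at the service provider and only the
researcher completes decryption. Feature magnitudes after integerization
are capped at 800 so a fold-aggregated gradient slot cannot overflow ±t/2.

Per-threshold confusion ciphertexts are assembled as TP = X'·(y·occ),
FP = X'·(occ − y·occ), FN = y·occ − TP, TN = (occ − y·occ) − FP with
y·occ relinearized once per fold — plaintext-identical to the four literal
triple products, but with only plaintext multiplications inside the
101-point threshold loop. Only the provider owning an evaluation
ciphertext applies the occupancy-dependent prediction mask (non-owners
cannot know which slots are genuine); per-provider masked predictions are
concatenated, not summed. Accuracy and F₁ are reported at the grid point
nearest A (the 0.5-probability operating point).

Researcher-side arithmetic (parameter rounding to ⌊SF·β/scale⌉, mod-t
accumulation, unmasking, rescaling by 1/(S_out·scale)) is one shared code
path used verbatim by the secure session and by the plaintext
integer-oracle trainer, which is why the two produce bit-identical
parameter trajectories: the encrypted middle is exact mod-t arithmetic,
and everything outside it is literally the same code.

## Synthetic cohorts and what the tests show

The generator draws numeric features from clipped unit normals (rounded
to two decimals, integerization scale 10), boolean features from fair
coins and optional ≤4-level nominals, then labels from
Bernoulli(σ(xᵀβ*)) with reproducible moderate effects; an optional
per-provider mean shift models covariate heterogeneity. The default
benchmark is 3 providers × 1024 samples with 8 expanded features,
echoing the multicenter geometry of the motivating deployment at desk
scale. What it does **not** emulate: categorical codebooks and missing
data of real registries, label noise, provider-specific effect
heterogeneity, and record linkage across providers. Equivalence results
(secure = integer oracle, bit for bit) are data-independent statements
about the arithmetic; accuracy-loss results (float vs integer AUC gap
≤ 0.02, paired p > 0.05) are statements about this generator's
distribution and transfer qualitatively, not numerically, to real
registry data.

Problem sizes in the test suite are chosen to keep the full run desk
sized: randomized correctness uses 200 trials at n = 4096 spread over
z ∈ {1,2,3,5}; the end-to-end equivalence study uses 3 providers × 128
samples, d = 3, 9 cv-steps at n = 4096 with the full 10 × 101 unmasked
count comparison and a 2-fold masked-discordance check; the
relinearization-noise scaling study runs 4 z-values × 10 seeds on the
n = 1024 profile, where the measured quantity (key-noise growth in z) is
independent of the ring degree.

## Known limitations

* Full-threshold only: decryption needs every share; there is no
  t-out-of-z sharing or dropout tolerance.
* Semi-honest model; no IND-CCA hardening, no constant-time arithmetic.
* One polynomial per column: cohorts larger than n samples per provider
  would need chunking, which is out of scope.
* The desk-scale profiles trade security for speed and must never hold
  real data; only the reference profile matches published security
  levels.
* Accuracy/F₁ require a single operating point; the grid point nearest A
  is a convention, not part of the protocol.
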