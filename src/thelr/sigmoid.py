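"""Degree-3 least-squares approximation of the logistic sigmoid and its
integerized form G₃.

The BFV scheme evaluates only integer polynomials, so σ(x) = 1/(1+e^(−x)) is
replaced by a cubic least-squares fit over (−8, 8), the input is scaled by
SF = 1000 (valid interval (−8000, 8000)) and the output by an integer scale
S_out representing probability 1.  S_out is pinned to the protocol's label
constant 627743311836 — the unique reading under which the degree-3
coefficient integerizes to exactly −1 (c3·S_out/SF³ ≈ −1) — giving

    G₃(X) = A + B·X − X³,   A = ⌊S_out/2⌉,   X = ⌊SF·x⌉.

The occupied-slot masking bound 1569358279 equals ⌊0.0025·S_out⌋; note the
protocol describes it as "(−0.005, 0.005) in the scaled-down plaintext",
which holds on the scale S_out/2 — both printed integers are authoritative
and kept verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import bfv
from .ring import batch_encode

LABEL_CONST = 627743311836        # S_out: integer output scale (probability 1)
MASK_BOUND = 1569358279           # occupied-slot uniform masking bound
SF = 1000                         # input scaling factor
INTERVAL = (-8.0, 8.0)
INT_BOUND = 8000                  # |X| < 8000 for approximation validity


@dataclass
class SigmoidApprox:
    """p(x) = c0 + c1·x + c3·x³ fitted to σ on ``interval``."""
    c0: float
    c1: float
    c3: float
    interval: tuple[float, float] = INTERVAL
    max_err: float = float("nan")
    c2_residual: float = 0.0      # even-degree coefficient left by the fit


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def fit_sigmoid_ls3(interval: tuple[float, float] = INTERVAL,
                    grid_step: float = 0.01) -> SigmoidApprox:
    """Discrete least squares on a uniform grid (default step 0.01).

    The sigmoid's odd symmetry about (0, 1/2) forces c0 → 1/2 and the
    quadratic coefficient → 0; both are checked downstream rather than
    constrained here.
    """
    lo, hi = interval
    if hi <= lo or grid_step <= 0 or (hi - lo) < 2 * grid_step:
        raise ValueError("degenerate fitting grid")
    xs = np.arange(lo, hi + grid_step / 2, grid_step)
    V = np.vander(xs, 4, increasing=True)
    coef, *_ = np.linalg.lstsq(V, sigmoid(xs), rcond=None)
    c0, c1, c2, c3 = (float(c) for c in coef)
    fine = np.arange(lo, hi + grid_step / 20, grid_step / 10)
    err = float(np.max(np.abs(c0 + c1 * fine + c2 * fine ** 2
                              + c3 * fine ** 3 - sigmoid(fine))))
    return SigmoidApprox(c0, c1, c3, (lo, hi), err, c2)


@dataclass
class IntegerizedSigmoid:
    """G₃(X) = A + B·X + C·X³ on X = ⌊SF·x⌉, output on scale S_out."""
    sf: int
    A: int
    B: int
    C: int
    S_out: int
    label_const: int
    mask_bound: int
    int_bound: int = INT_BOUND
    approx: SigmoidApprox | None = None

    def to_dict(self) -> dict:
        return {"SF": self.sf, "A": self.A, "B": self.B, "C": self.C,
                "S_out": self.S_out, "label_const": self.label_const,
                "mask_bound": self.mask_bound, "int_bound": self.int_bound,
                "fit": None if self.approx is None else
                {"c0": self.approx.c0, "c1": self.approx.c1,
                 "c3": self.approx.c3, "max_err": self.approx.max_err}}


def build_integerized(approx: SigmoidApprox | None = None,
                      sf: int = SF) -> IntegerizedSigmoid:
    """Integerize the cubic fit; pins the two printed protocol constants.

    The degree-1/degree-3 coefficients shrink by 1/SF and 1/SF³; the output
    scale S_out is the label constant, making C = −1 exactly.
    """
    if approx is None:
        approx = fit_sigmoid_ls3()
    if sf != SF:
        raise ValueError(
            f"protocol constants are pinned to SF={SF}; got {sf}")
    S_out = LABEL_CONST
    A = round(approx.c0 * S_out)
    B = round(approx.c1 * S_out / sf)
    C = round(approx.c3 * S_out / sf ** 3)
    return IntegerizedSigmoid(sf, A, B, C, S_out, LABEL_CONST, MASK_BOUND,
                              int(abs(approx.interval[1]) * sf), approx)


def g3_eval_int(g3: IntegerizedSigmoid, X):
    """A + B·X + C·X³ over the integers (int64-safe for |X| ≤ 8000).

    Evaluable outside the valid interval; validity is the caller's concern
    (training transcripts flag violations).
    """
    X = np.asarray(X, dtype=np.int64) if not np.isscalar(X) else int(X)
    return g3.A + g3.B * X + g3.C * X * X * X


def g3_valid(g3: IntegerizedSigmoid, X) -> np.ndarray:
    return np.abs(np.asarray(X)) < g3.int_bound


def g3_range(g3: IntegerizedSigmoid) -> tuple[int, int]:
    """Exact min/max of G₃ over the closed interval [−8000, 8000].

    The cubic fit is not monotone on the full interval: with C < 0 the
    derivative B + 3C·X² vanishes at X* = ±√(B/3|C|) ≈ ±5600, inside the
    interval, so the extrema sit at the integer neighbours of the critical
    points (or at the endpoints for other coefficient signs).
    """
    cands = {-g3.int_bound, g3.int_bound}
    if g3.C < 0 and g3.B > 0:
        xstar = math.isqrt(g3.B // (3 * abs(g3.C)))
        for dx in (-1, 0, 1, 2):
            for s in (-1, 1):
                x = s * (xstar + dx)
                if abs(x) <= g3.int_bound:
                    cands.add(x)
    vals = [int(g3_eval_int(g3, x)) for x in cands]
    return min(vals), max(vals)


def threshold_grid(g3: IntegerizedSigmoid) -> list[int]:
    """101 integer thresholds V = min(G₃) : (max−min)/100 : max(G₃)."""
    lo, hi = g3_range(g3)
    return [lo + round(l * (hi - lo) / 100) for l in range(101)]


def g3_eval_encrypted(c_X: "bfv.Ciphertext", g3: IntegerizedSigmoid,
                      rlk: "bfv.RelinKey") -> "bfv.Ciphertext":
    """Homomorphic G₃: two ciphertext squarings/multiplications with
    relinearization after each, plus plaintext-constant operations; decrypts
    slot-wise equal to :func:`g3_eval_int`."""
    x2 = bfv.relinearize(bfv.he_mul(c_X, c_X), rlk)
    x3 = bfv.relinearize(bfv.he_mul(x2, c_X), rlk)
    acc = bfv.he_add(bfv.he_scalar_mul(c_X, g3.B), bfv.he_scalar_mul(x3, g3.C))
    const = np.zeros(c_X.params.n, dtype=object)
    const[0] = g3.A                    # constant polynomial ⇒ A in every slot
    return bfv.he_add_plain(acc, const)
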