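"""Penalized B-spline machinery shared by the LMS curve fitter.

Cubic B-spline bases with clamped knots at every integer week, a
difference penalty on the coefficients (P-spline style), and a bisection
search that converts an effective-degrees-of-freedom (edf) target into a
penalty weight: edf(lambda) = tr[(B'WB + lambda*P)^-1 B'WB].
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SingularBasisError",
    "SplineBasis",
    "difference_penalty",
    "edf_for_lambda",
    "lambda_for_edf",
]


class SingularBasisError(ValueError):
    """The data's week span cannot support the requested degrees of freedom."""


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """P = D'D with D the ``order``-th difference operator on k coefficients."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


class SplineBasis:
    """Clamped cubic B-spline basis on [lo, hi] with unit knot spacing.

    A constant basis (single column of ones) is used when ``edf == 1``; the
    penalty-order choice for 1 < edf < 2 is made by the caller.
    """

    def __init__(self, lo: float, hi: float, degree: int = 3, constant: bool = False):
        self.lo, self.hi = float(lo), float(hi)
        self.constant = constant
        self.degree = degree
        if constant:
            self.k = 1
            self.knots = None
            return
        if hi - lo < 2.0:
            raise SingularBasisError(
                f"week span {lo}..{hi} too narrow for a curved spline basis"
            )
        interior = np.arange(lo + 1.0, hi)
        self.knots = np.concatenate(
            [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
        )
        self.k = len(interior) + degree + 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.constant:
            return np.ones((x.size, 1))
        if np.any(x < self.lo) or np.any(x > self.hi):
            raise ValueError(f"design points outside [{self.lo}, {self.hi}]")
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False).toarray()

    def constant_coefs(self, value: float = 1.0) -> np.ndarray:
        """Coefficients representing the constant function ``value`` (partition of unity)."""
        return np.full(self.k, value, dtype=float)


def edf_for_lambda(btwb: np.ndarray, P: np.ndarray, lam: float) -> float:
    """tr[(B'WB + lam*P)^-1 B'WB], the smoother's effective dimension."""
    A = btwb + lam * P
    return float(np.trace(np.linalg.solve(A, btwb)))


def lambda_for_edf(
    btwb: np.ndarray,
    P: np.ndarray,
    target: float,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """Penalty weight whose edf matches ``target``, by bisection on log(lambda).

    Raises :class:`SingularBasisError` when the target exceeds the rank of
    the unpenalized problem or undershoots the penalty's null-space
    dimension (the edf floor as lambda -> infinity).
    """
    lo, hi = 1e-9, 1e12
    # expand the bracket if needed
    for _ in range(60):
        if edf_for_lambda(btwb, P, lo) >= target:
            break
        lo /= 100.0
    edf_lo = edf_for_lambda(btwb, P, lo)
    edf_hi = edf_for_lambda(btwb, P, hi)
    if target > edf_lo + tol:
        raise SingularBasisError(
            f"requested edf {target} exceeds the maximum attainable {edf_lo:.2f} "
            "for this week span"
        )
    if target < edf_hi - tol:
        raise SingularBasisError(
            f"requested edf {target} is below the penalty's floor {edf_hi:.2f}"
        )
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(max_iter):
        lmid = 0.5 * (llo + lhi)
        e = edf_for_lambda(btwb, P, np.exp(lmid))
        if abs(e - target) < tol:
            return float(np.exp(lmid))
        if e > target:  # need more penalty
            llo = lmid
        else:
            lhi = lmid
    return float(np.exp(0.5 * (llo + lhi)))
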