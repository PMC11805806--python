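"""Numerical Volterra-Lyapunov stability detection.

VL stability of ``A`` is equivalent to the existence of a diagonal
multiplier ``H`` with entries in (0, 1) such that the symmetric matrix
``H A + A^T H`` is negative definite (any positive multiplier can be
rescaled into the open unit box without changing the sign of the
spectrum).  The detector minimizes the objective

    O(h) = lambda_max(diag(h) A + A^T diag(h))

over the box (0, 1)^n from many random starts and stops at the first
iterate with a strictly negative value below a threshold.  A ``vl_stable``
verdict is therefore always correct (the certificate is checkable by a
single eigenvalue computation); failure to find a negative value is
reported as ``inconclusive``, never as "not VL stable".

The objective is the largest eigenvalue of a symmetric matrix: continuous,
piecewise smooth, but nondifferentiable at eigenvalue crossings.  Where the
top eigenvalue is simple its gradient is ``dO/dh_i = 2 v_i (A v)_i`` with
``v`` the top unit eigenvector; L-BFGS-B copes well with the residual
nonsmoothness in practice, and correctness never depends on the optimizer
since every verdict is certificate-checked.

A second, derivative-free semi-decision procedure walks a fixed countable
dense subset of the box (dyadic rationals ordered by denominator level):
it halts on every VL stable matrix given enough iterations, and cannot
halt on a non-VL-stable one, so a practical iteration cap turns "does not
halt" into ``inconclusive``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize

from lvig.matrices import as_interaction_matrix

__all__ = [
    "VLCertificate",
    "DetectionResult",
    "objective",
    "detect_vl",
    "detect_vl_dense",
    "verify_certificate",
    "dyadic_points",
]

#: box-constraint inset keeping multipliers strictly inside (0, 1)
_BOX_EPS = 1e-6


@dataclass(frozen=True)
class VLCertificate:
    """Diagonal multiplier ``h`` in (0,1)^n and the objective value there."""

    h: np.ndarray
    objective_value: float

    def __post_init__(self):
        h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if np.any(h <= 0) or np.any(h >= 1):
            raise ValueError("certificate multiplier must lie in the open box (0,1)^n")
        object.__setattr__(self, "h", h)


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of a VL-stability test.

    ``verdict`` is ``"vl_stable"`` (with a certificate whose objective is
    below ``threshold``) or ``"inconclusive"`` (no certificate; the matrix
    may or may not be VL stable).
    """

    verdict: str
    certificate: Optional[VLCertificate]
    n_starts_used: int
    threshold: float
    trace: tuple = field(default=())

    def __post_init__(self):
        if self.verdict not in ("vl_stable", "inconclusive"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "vl_stable" and (
            self.certificate is None
            or self.certificate.objective_value >= self.threshold
        ):
            raise ValueError("vl_stable verdict requires a certificate below threshold")
        if self.verdict == "inconclusive" and self.certificate is not None:
            raise ValueError("inconclusive verdict carries no certificate")


def objective(a, h) -> float:
    """Largest eigenvalue of ``diag(h) A + A^T diag(h)``.

    Positively homogeneous in ``h``: ``objective(A, c h) = c objective(A, h)``
    for ``c > 0``, which is why restricting multipliers to (0,1)^n loses
    nothing.
    """
    a = as_interaction_matrix(a)
    h = np.atleast_1d(np.asarray(h, dtype=float))
    if np.any(h <= 0):
        raise ValueError("multiplier h must be strictly positive")
    m = h[:, None] * a
    m = m + m.T
    return float(eigh(m, eigvals_only=True, subset_by_index=(a.shape[0] - 1,) * 2)[0])


def _objective_and_grad(a: np.ndarray, h: np.ndarray) -> tuple[float, np.ndarray]:
    m = h[:, None] * a
    m = m + m.T
    w, v = eigh(m, subset_by_index=(a.shape[0] - 1,) * 2)
    vec = v[:, 0]
    return float(w[0]), 2.0 * vec * (a @ vec)


class _CertificateFound(Exception):
    def __init__(self, h: np.ndarray, value: float):
        self.h = h
        self.value = value


def verify_certificate(a, cert: VLCertificate) -> bool:
    """Recompute the objective at the certificate; True iff strictly negative.

    Independent of how the certificate was obtained.
    """
    return objective(a, cert.h) < 0.0


def detect_vl(
    a,
    n_initial: int = 50,
    threshold: float = -1e-10,
    seed=None,
    *,
    method: str = "L-BFGS-B",
    maxiter: int = 200,
) -> DetectionResult:
    """Multi-start VL-stability test.

    Runs up to ``n_initial`` bounded local minimizations of the objective
    from uniform random starts in (0,1)^n, halting at the first evaluation
    strictly below ``threshold``.  ``trace`` records the best objective
    value seen per start.  The 1-species case is decided analytically
    (VL stable iff ``a_11 < 0``).
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    if n_initial < 1:
        raise ValueError("n_initial must be at least 1")
    if not threshold < 0:
        raise ValueError("threshold must be strictly negative")

    if n == 1:
        # analytic: VL stable iff a_11 < 0; the box infimum is at h -> 1
        h1 = 1.0 - _BOX_EPS
        val = 2.0 * h1 * float(a[0, 0])
        if val < threshold:
            cert = VLCertificate(h=np.array([h1]), objective_value=val)
            return DetectionResult("vl_stable", cert, 1, threshold, (val,))
        return DetectionResult("inconclusive", None, 1, threshold, (val,))

    rng = np.random.default_rng(seed)
    bounds = [(_BOX_EPS, 1.0 - _BOX_EPS)] * n
    trace = []

    def fun(h):
        val, grad = _objective_and_grad(a, h)
        best[0] = min(best[0], val)
        if val < threshold:
            raise _CertificateFound(np.array(h, dtype=float), val)
        return val, grad

    for start in range(n_initial):
        h0 = rng.uniform(_BOX_EPS, 1.0 - _BOX_EPS, size=n)
        best = [np.inf]
        try:
            minimize(
                fun,
                h0,
                jac=True,
                method=method,
                bounds=bounds,
                options={"maxiter": maxiter},
            )
        except _CertificateFound as hit:
            trace.append(hit.value)
            h = np.clip(hit.h, _BOX_EPS, 1.0 - _BOX_EPS)
            cert = VLCertificate(h=h, objective_value=hit.value)
            return DetectionResult(
                "vl_stable", cert, start + 1, threshold, tuple(trace)
            )
        trace.append(best[0])
    return DetectionResult("inconclusive", None, n_initial, threshold, tuple(trace))


def dyadic_points(n: int) -> Iterator[np.ndarray]:
    """Enumerate the dyadic rationals in (0,1)^n, dense and repetition-free.

    Level k yields points with coordinates ``i / 2^k`` (0 < i < 2^k) where at
    least one numerator is odd (points whose numerators are all even already
    appeared at an earlier level); within a level the order is lexicographic.
    """
    for level in itertools.count(1):
        denom = 2**level
        for nums in itertools.product(range(1, denom), repeat=n):
            if any(m % 2 == 1 for m in nums):
                yield np.array(nums, dtype=float) / denom


def detect_vl_dense(a, max_iterations: int = 10_000) -> DetectionResult:
    """Semi-decision test walking the dyadic dense sequence in (0,1)^n.

    Halts with a certificate at the first point with a strictly negative
    objective; a VL stable matrix is always detected for a large enough
    cap, while a non-VL-stable one exhausts the cap (``inconclusive``).
    """
    a = as_interaction_matrix(a)
    if max_iterations < 1:
        raise ValueError("max_iterations must be at least 1")
    n = a.shape[0]
    # the dense algorithm tests lambda < 0 exactly, so the threshold is 0
    for i, h in enumerate(itertools.islice(dyadic_points(n), max_iterations)):
        val = objective(a, h)
        if val < 0.0:
            cert = VLCertificate(h=h, objective_value=val)
            return DetectionResult("vl_stable", cert, i + 1, 0.0, (val,))
    return DetectionResult("inconclusive", None, max_iterations, 0.0, ())
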