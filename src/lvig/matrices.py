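"""Volterra-Lyapunov stable matrices: construction, generation, norms.

A real square matrix ``A`` is Volterra-Lyapunov (VL) stable if there is a
positive diagonal ``H`` such that ``H A + A^T H`` is negative definite.
Equivalently, ``A = H (S + J)`` for some positive diagonal ``H``, symmetric
stable ``S`` and antisymmetric ``J``; this constructive characterization is
what makes random generation of guaranteed-VL-stable matrices possible.

This module also ships the canonical small interaction matrices used
throughout: the May-Leonard competition matrix, the 3-species
rock-paper-scissors matrix, its 5-species rock-paper-scissors-lizard-Spock
extension, and a 4-species matrix whose invasion graph contains a cycle
mixing communities of different sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VLDecomposition",
    "SymmetrySplit",
    "as_interaction_matrix",
    "as_growth_rates",
    "compose",
    "random_vl_stable",
    "symmetry_split",
    "entrywise_norm",
    "asym_sym_ratio",
    "row_norm",
    "is_row_dd",
    "is_col_dd",
    "may_leonard",
    "rps3",
    "rpsls5",
    "cycle4",
]

#: absolute tolerance for symmetry / antisymmetry checks on ingest
_SYM_ATOL = 1e-12


def as_interaction_matrix(a) -> np.ndarray:
    """Validate and return an interaction matrix as a float ndarray.

    Raises ``ValueError`` for non-square, empty or non-finite input.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"interaction matrix must be square, got shape {a.shape}")
    if a.shape[0] < 1:
        raise ValueError("interaction matrix must have at least one species")
    if not np.all(np.isfinite(a)):
        raise ValueError("interaction matrix entries must be finite")
    return a


def as_growth_rates(b, n: int) -> np.ndarray:
    """Validate a growth-rate vector against the species count ``n``.

    A scalar is broadcast to all species; ``None`` defaults to all ones.
    """
    if b is None:
        return np.ones(n)
    b = np.asarray(b, dtype=float)
    if b.ndim == 0:
        return np.full(n, float(b))
    if b.shape != (n,):
        raise ValueError(f"growth rates have shape {b.shape}, expected ({n},)")
    if not np.all(np.isfinite(b)):
        raise ValueError("growth rates must be finite")
    return b


@dataclass(frozen=True)
class VLDecomposition:
    """Triple ``(h, s, jmat)`` with ``A = diag(h) (S + J)``.

    Doubles as a VL-stability certificate: ``h`` positive, ``S`` symmetric
    with strictly negative largest eigenvalue, ``J`` antisymmetric.  Stored
    matrices are exactly (anti)symmetrized on construction to avoid drift.
    """

    h: np.ndarray
    s: np.ndarray
    jmat: np.ndarray

    def __post_init__(self):
        h = np.atleast_1d(np.asarray(self.h, dtype=float))
        s = as_interaction_matrix(self.s)
        j = as_interaction_matrix(self.jmat)
        n = h.shape[0]
        if s.shape != (n, n) or j.shape != (n, n):
            raise ValueError("h, s and jmat must have consistent dimensions")
        if np.any(h <= 0):
            raise ValueError("diagonal multiplier h must be strictly positive")
        if not np.allclose(s, s.T, atol=_SYM_ATOL, rtol=0.0):
            raise ValueError("s must be symmetric")
        if not np.allclose(j, -j.T, atol=_SYM_ATOL, rtol=0.0):
            raise ValueError("jmat must be antisymmetric")
        s = (s + s.T) / 2.0
        j = (j - j.T) / 2.0
        if np.linalg.eigvalsh(s)[-1] >= 0:
            raise ValueError("s must be stable (largest eigenvalue strictly negative)")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "jmat", j)

    @property
    def n(self) -> int:
        return self.h.shape[0]


@dataclass(frozen=True)
class SymmetrySplit:
    """Split ``A = A_S + A_J`` into symmetric and antisymmetric parts."""

    a_s: np.ndarray
    a_j: np.ndarray


def compose(decomp: VLDecomposition) -> np.ndarray:
    """Return ``A = H (S + J)``, VL stable by construction.

    The inverse multiplier certifies stability:
    ``H^{-1} A + A^T H^{-1} = 2 S`` has strictly negative eigenvalues.
    """
    return decomp.h[:, None] * (decomp.s + decomp.jmat)


def random_vl_stable(
    n: int,
    seed=None,
    *,
    h_low: float = 0.1,
    h_high: float = 1.1,
    scale: float = 1.0,
    margin: float = 0.5,
) -> tuple[np.ndarray, VLDecomposition]:
    """Generate a random VL stable matrix with its generating decomposition.

    Steps: draw a positive diagonal ``H ~ U(h_low, h_high)``; an
    antisymmetric ``J = K - K^T`` from a standard-normal ``K`` scaled by
    ``scale``; a symmetric stable ``S = F + F^T - alpha I`` with ``F``
    standard normal scaled by ``scale`` and ``alpha`` the largest eigenvalue
    of ``F + F^T`` (clipped at 0) plus ``margin``, so the spectrum of ``S``
    is strictly below ``-margin`` (actually below 0 by at least ``margin``
    when the shift binds).  Fully reproducible from ``seed``.

    Returns
    -------
    (A, decomp) : the matrix ``A = H(S+J)`` and its certificate.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    h = rng.uniform(h_low, h_high, size=n)
    k = scale * rng.standard_normal((n, n))
    jmat = k - k.T
    f = scale * rng.standard_normal((n, n))
    sym = f + f.T
    alpha = max(0.0, float(np.linalg.eigvalsh(sym)[-1])) + margin
    s = sym - alpha * np.eye(n)
    decomp = VLDecomposition(h=h, s=s, jmat=jmat)
    return compose(decomp), decomp


def symmetry_split(a) -> SymmetrySplit:
    """Split a matrix into ``A_S = (A + A^T)/2`` and ``A_J = (A - A^T)/2``."""
    a = as_interaction_matrix(a)
    return SymmetrySplit(a_s=(a + a.T) / 2.0, a_j=(a - a.T) / 2.0)


def entrywise_norm(m) -> float:
    """Sum of absolute values of all entries."""
    return float(np.abs(np.asarray(m, dtype=float)).sum())


def asym_sym_ratio(a) -> float:
    """Ratio ``|A_J| / |A_S|`` of entrywise norms of the symmetry split.

    Raises ``ZeroDivisionError`` when the symmetric part vanishes.
    """
    split = symmetry_split(a)
    denom = entrywise_norm(split.a_s)
    if denom == 0.0:
        raise ZeroDivisionError("asymmetry ratio undefined: |A_S| = 0")
    return entrywise_norm(split.a_j) / denom


def row_norm(a) -> float:
    """Row norm ``max_i sum_j |a_ij|`` (the infinity operator norm)."""
    a = np.asarray(a, dtype=float)
    return float(np.abs(a).sum(axis=1).max())


def is_row_dd(a) -> bool:
    """Strong row diagonal dominance: ``|a_ii| > sum_{j != i} |a_ij|``."""
    a = np.abs(as_interaction_matrix(a))
    diag = np.diag(a)
    return bool(np.all(diag > a.sum(axis=1) - diag))


def is_col_dd(a) -> bool:
    """Strong column diagonal dominance: ``|a_jj| > sum_{i != j} |a_ij|``."""
    a = np.abs(as_interaction_matrix(a))
    diag = np.diag(a)
    return bool(np.all(diag > a.sum(axis=0) - diag))


# ---------------------------------------------------------------------------
# Canonical fixture systems (growth rates default to all ones)


def may_leonard(alpha: float, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """May-Leonard 3-species competition matrix with unit growth rates.

    The cyclic regime requires ``0 < alpha < 1 < beta``, ``alpha*beta < 1``
    and ``alpha + beta < 2``; parameters outside it are accepted with a
    warning, since the matrix itself is well defined for any values.
    """
    in_regime = 0 < alpha < 1 < beta and alpha * beta < 1 and alpha + beta < 2
    if not in_regime:
        warnings.warn(
            f"May-Leonard parameters alpha={alpha}, beta={beta} are outside "
            "the cyclic regime (0<alpha<1<beta, alpha*beta<1, alpha+beta<2)",
            stacklevel=2,
        )
    a = np.array(
        [
            [-1.0, -beta, -alpha],
            [-alpha, -1.0, -beta],
            [-beta, -alpha, -1.0],
        ]
    )
    return a, np.ones(3)


def _cyclic_rps(n: int, d: float) -> np.ndarray:
    """n-species matrix d*I + J with J the alternating-cyclic antisymmetric
    pattern: entry (i, j) is -1, +1, -1, ... moving right from the diagonal
    cyclically (n odd so the pattern is consistent)."""
    a = np.full((n, n), d) * np.eye(n)
    for i in range(n):
        for off in range(1, n):
            a[i, (i + off) % n] = -1.0 if off % 2 == 1 else 1.0
    return a


def rps3(d: float) -> tuple[np.ndarray, np.ndarray]:
    """3-species rock-paper-scissors matrix ``d*I + J`` (cycles for -1<d<0)."""
    return _cyclic_rps(3, d), np.ones(3)


def rpsls5(d: float) -> tuple[np.ndarray, np.ndarray]:
    """5-species rock-paper-scissors-lizard-Spock matrix ``d*I + J``."""
    return _cyclic_rps(5, d), np.ones(5)


def cycle4(d: float) -> tuple[np.ndarray, np.ndarray]:
    """4-species matrix whose invasion graph cycles through communities of
    mixed size: species 1 is replaced by {2,3} jointly, which are replaced
    by 4, which is replaced by 1."""
    a = np.array(
        [
            [d, -1.0, -1.0, 1.0],
            [1.0, d, 0.0, -1.0],
            [1.0, 0.0, d, -1.0],
            [-1.0, 1.0, 1.0, d],
        ]
    )
    return a, np.ones(4)
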