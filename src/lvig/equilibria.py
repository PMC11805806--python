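"""Communities, equilibria, invasion rates and the GASS.

A *community* is a subset ``I`` of the species {1..N} (1-based, sorted
tuples throughout).  It is *admissible* when the linear system
``-A(I) u = b(I)`` on the principal submatrix has a solution with all
coordinates strictly positive; embedding with zeros off ``I`` gives the
unique boundary equilibrium ``u^I`` of the Lotka-Volterra flow supported
exactly on ``I``.  The *invasion rate* of species ``i`` against community
``I`` is the per-capita growth rate of an infinitesimal invader,

    r_i(I) = b_i + sum_{j in I} a_ij u^I_j,

with the convention ``r_i(empty) = b_i``.  For a VL stable matrix the
unique *saturated* admissible equilibrium (all absent-species invasion
rates nonpositive) is the globally asymptotically stable stationary
solution (GASS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from lvig.matrices import as_growth_rates, as_interaction_matrix

__all__ = [
    "Equilibrium",
    "CatalogEntry",
    "RejectedCommunity",
    "CommunityCatalog",
    "principal_submatrix",
    "subvector",
    "solve_equilibrium",
    "invasion_rates",
    "enumerate_admissible",
    "find_gass",
    "is_hyperbolic",
]

#: coordinates below this are not "strictly positive" for admissibility
ADMISSIBILITY_TOL = 1e-9
#: condition-number cap beyond which a principal submatrix counts as singular
COND_CAP = 1e12
#: hard cap on species count for the 2^n community sweep
ENUMERATION_CAP = 20


def _check_community(members, n: int) -> tuple[int, ...]:
    mem = tuple(int(i) for i in members)
    if any(i < 1 or i > n for i in mem):
        raise IndexError(f"community {mem} out of range 1..{n}")
    if sorted(set(mem)) != list(mem):
        raise ValueError(f"community must be a sorted duplicate-free tuple, got {mem}")
    return mem


def principal_submatrix(a, members) -> np.ndarray:
    """Principal submatrix ``A(J)``: rows and columns at the (1-based,
    sorted) indices of ``J``, order preserved."""
    a = as_interaction_matrix(a)
    mem = _check_community(members, a.shape[0])
    if not mem:
        raise ValueError("principal submatrix of the empty community is undefined")
    idx = np.array(mem) - 1
    return a[np.ix_(idx, idx)]


def subvector(b, members, n: Optional[int] = None) -> np.ndarray:
    """Subvector ``b(J)`` at the 1-based indices of ``J``."""
    b = np.asarray(b, dtype=float)
    mem = _check_community(members, n if n is not None else b.shape[0])
    return b[np.array(mem, dtype=int) - 1] if mem else np.empty(0)


@dataclass(frozen=True)
class Equilibrium:
    """Candidate equilibrium for a community, embedded in R^n.

    ``admissible`` is True iff all in-community coordinates are strictly
    positive (and the submatrix solve was well conditioned); otherwise
    ``reason`` is ``"negative_coordinate"`` or ``"singular"``.
    """

    community: tuple
    u: np.ndarray
    admissible: bool
    reason: Optional[str] = None
    residual: float = 0.0
    condition: float = 1.0

    @property
    def dim(self) -> int:
        return len(self.community)


@dataclass(frozen=True)
class CatalogEntry:
    community: tuple
    equilibrium: Equilibrium
    rates: np.ndarray


@dataclass(frozen=True)
class RejectedCommunity:
    community: tuple
    reason: str


@dataclass
class CommunityCatalog:
    """All admissible communities of a system, with equilibria and rates."""

    n: int
    entries: list = field(default_factory=list)
    rejected: list = field(default_factory=list)

    def communities(self) -> list:
        return [e.community for e in self.entries]

    def get(self, community) -> CatalogEntry:
        mem = _check_community(community, self.n)
        for e in self.entries:
            if e.community == mem:
                return e
        raise KeyError(f"community {mem} is not admissible")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, community) -> bool:
        try:
            self.get(community)
            return True
        except KeyError:
            return False

    def to_records(self) -> list:
        """One dict per catalogued community (admissible and rejected),
        JSON-serializable."""
        rec = [
            {
                "community": list(e.community),
                "admissible": True,
                "u": [float(x) for x in e.equilibrium.u],
                "rates": [float(r) for r in e.rates],
            }
            for e in self.entries
        ]
        rec += [
            {"community": list(r.community), "admissible": False, "reason": r.reason}
            for r in self.rejected
        ]
        return rec


def solve_equilibrium(a, b, members, tol: float = ADMISSIBILITY_TOL) -> Equilibrium:
    """Solve ``-A(J) u = b(J)`` and embed into R^n with zeros off ``J``.

    The empty community yields the zero equilibrium (always admissible).
    Near-singular submatrices (condition number above ``COND_CAP``) are
    flagged ``reason="singular"``; nonpositive coordinates flag
    ``reason="negative_coordinate"``.
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    b = as_growth_rates(b, n)
    mem = _check_community(members, n)
    if not mem:
        return Equilibrium(community=(), u=np.zeros(n), admissible=True)
    sub = principal_submatrix(a, mem)
    rhs = subvector(b, mem, n)
    cond = float(np.linalg.cond(sub))
    if not np.isfinite(cond) or cond > COND_CAP:
        return Equilibrium(
            community=mem,
            u=np.full(n, np.nan),
            admissible=False,
            reason="singular",
            condition=cond,
        )
    u_sub = np.linalg.solve(-sub, rhs)
    residual = float(np.abs(sub @ u_sub + rhs).max())
    u = np.zeros(n)
    u[np.array(mem) - 1] = u_sub
    if np.any(u_sub <= tol):
        return Equilibrium(
            community=mem,
            u=u,
            admissible=False,
            reason="negative_coordinate",
            residual=residual,
            condition=cond,
        )
    return Equilibrium(
        community=mem, u=u, admissible=True, residual=residual, condition=cond
    )


def invasion_rates(a, b, eq: Equilibrium) -> np.ndarray:
    """Invasion rates ``r_i(I) = b_i + sum_{j in I} a_ij u^I_j`` for all i.

    For the empty community this reduces to ``r_i = b_i``.  At an exact
    equilibrium ``r_i = 0`` for every resident ``i in I``.
    """
    a = as_interaction_matrix(a)
    b = as_growth_rates(b, a.shape[0])
    return b + a @ eq.u


def enumerate_admissible(
    a, b=None, tol: float = ADMISSIBILITY_TOL, max_n: int = ENUMERATION_CAP
) -> CommunityCatalog:
    """Test all 2^n communities and catalog the admissible ones.

    Each admissible entry carries its equilibrium and full invasion-rate
    vector; non-admissible communities are recorded with the rejection
    reason.  The sweep is capped at ``max_n`` species.
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    if n > max_n:
        raise ValueError(f"n={n} exceeds the enumeration cap {max_n}")
    b = as_growth_rates(b, n)
    catalog = CommunityCatalog(n=n)
    for mask in range(2**n):
        mem = tuple(i + 1 for i in range(n) if mask >> i & 1)
        eq = solve_equilibrium(a, b, mem, tol=tol)
        if eq.admissible:
            catalog.entries.append(
                CatalogEntry(community=mem, equilibrium=eq, rates=invasion_rates(a, b, eq))
            )
        else:
            catalog.rejected.append(RejectedCommunity(community=mem, reason=eq.reason))
    return catalog


def find_gass(catalog: CommunityCatalog, tol: float = ADMISSIBILITY_TOL) -> Equilibrium:
    """Return the unique saturated equilibrium of the catalog.

    An admissible equilibrium is *saturated* when ``r_i(I) <= tol`` for
    every absent species ``i``.  Under VL stability exactly one such
    equilibrium exists and it is the GASS; zero or multiple candidates
    signal a non-VL-stable input (or tolerance failure) and raise.
    """
    candidates = []
    for e in catalog.entries:
        absent = [i for i in range(1, catalog.n + 1) if i not in e.community]
        if all(e.rates[i - 1] <= tol for i in absent):
            candidates.append(e.equilibrium)
    if len(candidates) != 1:
        raise ValueError(
            f"expected exactly one saturated equilibrium, found {len(candidates)}; "
            "is the interaction matrix VL stable?"
        )
    return candidates[0]


def is_hyperbolic(
    catalog: CommunityCatalog, tol: float = ADMISSIBILITY_TOL
) -> tuple[bool, list]:
    """Check ``|r_i(J)| > tol`` for every admissible ``J`` and absent ``i``.

    Returns the flag and the list of offending ``(community, species, rate)``
    triples.  Zero (or near-zero) absent-species rates correspond to
    non-hyperbolic equilibria, for which the invasion graph need not equal
    the connection graph.
    """
    violations = []
    for e in catalog.entries:
        for i in range(1, catalog.n + 1):
            if i in e.community:
                continue
            r = float(e.rates[i - 1])
            if abs(r) <= tol:
                violations.append((e.community, i, r))
    return (not violations), violations
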