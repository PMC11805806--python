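"""Invasion-graph construction, cycle detection and frondosity criteria.

The invasion graph (IG) has the admissible communities as nodes and an
edge ``I -> J`` exactly when ``I != J``, every species of ``J \\ I`` can
invade ``I`` (``r_j(I) > 0``) and every species of ``I \\ J`` dies out at
``J`` (``r_i(J) < 0``); vacuous conditions count as satisfied.  Under VL
stability the IG is a subgraph of the connection graph of actual
heteroclinic orbits, and when all equilibria are hyperbolic the two
coincide, so an acyclic IG certifies a gradient attractor whose structure
is fully recovered.

Cycles in the IG are the algebraic fingerprint of heteroclinic cycles.
Two sufficient conditions exclude them by forcing *maximal frondosity*
(every community admissible): full cooperativity with positive growth
rates, and a strong diagonal-dominance condition relative to the spread
of the growth rates.  A separate necessary product condition rules out
cycles among single-species equilibria whenever the matrix is row or
column diagonally dominant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from lvig.equilibria import (
    ADMISSIBILITY_TOL,
    CommunityCatalog,
    enumerate_admissible,
    is_hyperbolic,
    solve_equilibrium,
)
from lvig.matrices import (
    as_growth_rates,
    as_interaction_matrix,
    is_col_dd,
    is_row_dd,
)

__all__ = [
    "CycleReport",
    "StructureVerdict",
    "SingletonCycleReport",
    "build_ig",
    "find_cycles",
    "structure_verdict",
    "check_frondosity",
    "frondosity_sufficient_dd",
    "frondosity_sufficient_cooperative",
    "single_species_cycle_test",
    "to_dot",
    "write_graphml",
]

#: default cap on elementary-cycle enumeration
MAX_CYCLES = 100_000


def build_ig(catalog: CommunityCatalog, tol: float = ADMISSIBILITY_TOL) -> nx.DiGraph:
    """Construct the invasion graph of a community catalog.

    Nodes are admissible communities (1-based sorted tuples, including the
    empty community ``()``); each edge stores the licensing invasion rates
    in its ``"rates"`` attribute for auditability.  Inequalities in the
    edge rule are strict at tolerance ``tol``: a rate in ``[-tol, tol]``
    licenses nothing.
    """
    g = nx.DiGraph()
    g.add_nodes_from(e.community for e in catalog.entries)
    for src in catalog.entries:
        for dst in catalog.entries:
            if src.community == dst.community:
                continue
            gained = [j for j in dst.community if j not in src.community]
            lost = [i for i in src.community if i not in dst.community]
            if all(src.rates[j - 1] > tol for j in gained) and all(
                dst.rates[i - 1] < -tol for i in lost
            ):
                licensing = {f"r_{j}(I)": float(src.rates[j - 1]) for j in gained}
                licensing.update({f"r_{i}(J)": float(dst.rates[i - 1]) for i in lost})
                g.add_edge(src.community, dst.community, rates=licensing)
    return g


@dataclass(frozen=True)
class CycleReport:
    """Cycle structure of an invasion graph.

    ``has_cycle`` comes from the SCC decomposition (always exact, also
    detecting self-contained 1-node loops, which the IG construction
    forbids anyway); ``elementary_cycles`` is a capped enumeration in
    deterministic (lexicographic) order.
    """

    has_cycle: bool
    sccs: tuple
    elementary_cycles: tuple
    cap_hit: bool


def find_cycles(g: nx.DiGraph, max_cycles: int = MAX_CYCLES) -> CycleReport:
    """SCC decomposition plus elementary-cycle enumeration (capped)."""
    sccs = sorted(
        (tuple(sorted(c)) for c in nx.strongly_connected_components(g) if len(c) > 1),
    )
    cycles = []
    cap_hit = False
    if sccs:
        for cyc in nx.simple_cycles(g):
            if len(cycles) >= max_cycles:
                cap_hit = True
                break
            # rotate so the lexicographically smallest node leads
            k = min(range(len(cyc)), key=lambda i: cyc[i])
            cycles.append(tuple(cyc[k:] + cyc[:k]))
        cycles.sort()
    return CycleReport(
        has_cycle=bool(sccs),
        sccs=tuple(sccs),
        elementary_cycles=tuple(cycles),
        cap_hit=cap_hit,
    )


@dataclass(frozen=True)
class StructureVerdict:
    """Combined attractor-structure verdict for a system.

    ``gradient_certified`` means the flow is gradient with respect to its
    equilibria and the IG recovers the whole global attractor: it requires
    hyperbolicity of all equilibria *and* an acyclic IG.  When either
    fails, the IG is inconclusive about the attractor (there may be
    connections it does not show).
    """

    hyperbolic: bool
    acyclic: bool
    gradient_certified: bool
    frondosity: bool
    notes: str = ""


def structure_verdict(
    catalog: CommunityCatalog, g: nx.DiGraph, tol: float = ADMISSIBILITY_TOL
) -> StructureVerdict:
    """Combine hyperbolicity and acyclicity into an attractor verdict."""
    hyp, violations = is_hyperbolic(catalog, tol=tol)
    acyclic = not find_cycles(g).has_cycle
    frond = len(catalog) == 2**catalog.n
    notes = []
    if not hyp:
        notes.append(
            f"{len(violations)} near-zero absent-species invasion rate(s): "
            "equilibria are not all hyperbolic, the IG may miss connections"
        )
    if not acyclic:
        notes.append("IG has cycles: heteroclinic cycles are possible")
    return StructureVerdict(
        hyperbolic=hyp,
        acyclic=acyclic,
        gradient_certified=hyp and acyclic,
        frondosity=frond,
        notes="; ".join(notes),
    )


def check_frondosity(
    a, b=None, tol: float = ADMISSIBILITY_TOL
) -> tuple[bool, Optional[tuple], Optional[str]]:
    """Maximal frondosity: every nonempty community strictly admissible.

    Returns ``(flag, first_failing_community, reason)``.  Maximal
    frondosity excludes heteroclinic cycles outright.
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    b = as_growth_rates(b, n)
    for mask in range(1, 2**n):
        mem = tuple(i + 1 for i in range(n) if mask >> i & 1)
        eq = solve_equilibrium(a, b, mem, tol=tol)
        if not eq.admissible:
            return False, mem, eq.reason
    return True, None, None


def frondosity_sufficient_dd(a, b) -> tuple[bool, float]:
    """Strong diagonal-dominance sufficient condition for maximal frondosity.

    Requires ``min b_i > 0``; with ``M = max b_i / min b_i`` the condition is

        max_i sum_{j != i} |a_ij / a_jj| < 1 / (1 + M).

    Returns the flag and the slack (RHS - LHS, positive when satisfied).
    Sufficient only: systems violating it may still be maximally frondose.
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    b = as_growth_rates(b, n)
    if np.min(b) <= 0:
        raise ValueError("the diagonal-dominance criterion requires min b_i > 0")
    diag = np.diag(a)
    if np.any(diag == 0):
        raise ValueError("the criterion requires nonzero diagonal entries")
    p = np.abs(a / diag[None, :])
    np.fill_diagonal(p, 0.0)
    lhs = float(p.sum(axis=1).max())
    m = float(np.max(b) / np.min(b))
    rhs = 1.0 / (1.0 + m)
    return lhs < rhs, rhs - lhs


def frondosity_sufficient_cooperative(a, b) -> bool:
    """Full cooperativity criterion for maximal frondosity.

    True iff all off-diagonal interactions are strictly positive and
    ``min b_i > 0``.  VL stability of ``A`` is a prerequisite checked by
    the caller; this flag reports only the structural conditions.
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    b = as_growth_rates(b, n)
    off = a[~np.eye(n, dtype=bool)]
    return bool(np.all(off > 0) and np.min(b) > 0)


@dataclass(frozen=True)
class SingletonCycleReport:
    """Single-species-cycle scan combined with the necessary product test.

    For a cycle of single-species equilibria ``{s_1} -> ... -> {s_K} ->
    {s_1}`` a necessary condition is ``prod |a_{i,i+1}| >= prod |a_{ii}|``
    over the cyclic ordering; a row- or column-diagonally-dominant matrix
    violates it, so a singleton cycle found together with diagonal
    dominance indicates a bug and is flagged.
    """

    cycles: tuple  # tuples of singleton communities
    product_condition: tuple  # parallel tuple of bools
    row_dd: bool
    col_dd: bool
    contradiction: bool


def single_species_cycle_test(a, b, g: nx.DiGraph) -> SingletonCycleReport:
    """Scan the IG for cycles among singleton communities and evaluate the
    necessary product condition for each."""
    a = as_interaction_matrix(a)
    singles = [node for node in g.nodes if len(node) == 1]
    sub = g.subgraph(singles)
    cycles = []
    products = []
    for cyc in nx.simple_cycles(sub):
        k = min(range(len(cyc)), key=lambda i: cyc[i])
        cyc = tuple(cyc[k:] + cyc[:k])
        species = [c[0] for c in cyc]
        num = 1.0
        den = 1.0
        for i, s in enumerate(species):
            t = species[(i + 1) % len(species)]
            num *= abs(a[s - 1, t - 1])
            den *= abs(a[s - 1, s - 1])
        cycles.append(cyc)
        products.append(num >= den)
    order = np.argsort([str(c) for c in cycles]) if cycles else []
    cycles = tuple(cycles[i] for i in order)
    products = tuple(products[i] for i in order)
    row_dd = is_row_dd(a)
    col_dd = is_col_dd(a)
    return SingletonCycleReport(
        cycles=cycles,
        product_condition=products,
        row_dd=row_dd,
        col_dd=col_dd,
        contradiction=bool(cycles) and (row_dd or col_dd),
    )


# ---------------------------------------------------------------------------
# Export


def _label(community) -> str:
    return "(" + ",".join(str(i) for i in community) + ")"


def to_dot(
    g: nx.DiGraph,
    cycles=None,
    include_empty: bool = True,
) -> str:
    """Render the invasion graph in DOT format.

    Nodes are labelled ``(1,2,3)`` style; edges on any of the given cycles
    are drawn red.  ``include_empty=False`` drops the empty-community node.
    """
    cyc_edges = set()
    for cyc in cycles or ():
        for i, u in enumerate(cyc):
            cyc_edges.add((u, cyc[(i + 1) % len(cyc)]))
    lines = ["digraph IG {"]
    for node in sorted(g.nodes):
        if not include_empty and node == ():
            continue
        lines.append(f'  "{_label(node)}";')
    for u, v in sorted(g.edges):
        if not include_empty and ((u == ()) or (v == ())):
            continue
        attr = ' [color=red]' if (u, v) in cyc_edges else ""
        lines.append(f'  "{_label(u)}" -> "{_label(v)}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_graphml(g: nx.DiGraph, path) -> None:
    """Write the invasion graph as GraphML with string community labels."""
    h = nx.DiGraph()
    h.add_nodes_from(_label(n) for n in g.nodes)
    h.add_edges_from((_label(u), _label(v)) for u, v in g.edges)
    nx.write_graphml(h, path)
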