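"""Reproducible computational studies.

Four experiments, all bit-reproducible from an integer seed:

- ``detector_benchmark``: recall of the multi-start VL-stability detector
  on constructively generated VL stable matrices, per dimension.
- ``cycle_density``: fraction of sampled systems whose invasion graph
  contains a cycle, as a function of the antisymmetric-to-symmetric
  entrywise-norm ratio |A_J|/|A_S| and the dimension.
- ``dd_sweep``: search for cyclic invasion graphs among diagonally
  dominant systems with mixed-sign growth rates (none are expected).
- ``rpsls_d_sweep``: the 5-species rock-paper-scissors-lizard-Spock
  family as the self-regulation d varies, tracking admissible-community
  counts, cycles and hyperbolicity across the bifurcation at d = -1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from lvig.detector import detect_vl, verify_certificate
from lvig.equilibria import enumerate_admissible, is_hyperbolic
from lvig.graph import build_ig, find_cycles
from lvig.matrices import (
    entrywise_norm,
    is_col_dd,
    is_row_dd,
    random_vl_stable,
    rpsls5,
    symmetry_split,
)

__all__ = [
    "DetectorBenchmarkRow",
    "CycleDensityRow",
    "DDSweepReport",
    "RpslsSummary",
    "detector_benchmark",
    "cycle_density",
    "sample_with_ratio",
    "sample_dd_system",
    "dd_sweep",
    "rpsls_d_sweep",
    "rows_to_tsv",
]


@dataclass(frozen=True)
class DetectorBenchmarkRow:
    dim: int
    n_matrices: int
    n_initial: int
    recall: float
    inconclusive_rate: float
    seed: int


def detector_benchmark(
    dims: Sequence[int],
    n_matrices: int = 10,
    n_initial: int = 50,
    seed: int = 0,
    *,
    threshold: float = -1e-10,
    verify: bool = True,
) -> list[DetectorBenchmarkRow]:
    """Recall of ``detect_vl`` on generated VL stable matrices.

    Ground truth is free: every generated matrix is VL stable by
    construction, so recall is simply the fraction of ``vl_stable``
    verdicts.  With ``verify=True`` every returned certificate is
    independently re-checked (a failure would be a bug, not noise).
    """
    rows = []
    master = np.random.default_rng(seed)
    for dim in dims:
        hits = 0
        for _ in range(n_matrices):
            gen_seed = int(master.integers(2**31))
            det_seed = int(master.integers(2**31))
            a, _ = random_vl_stable(dim, seed=gen_seed)
            res = detect_vl(a, n_initial=n_initial, threshold=threshold, seed=det_seed)
            if res.verdict == "vl_stable":
                if verify and not verify_certificate(a, res.certificate):
                    raise AssertionError("certificate failed independent verification")
                hits += 1
        rows.append(
            DetectorBenchmarkRow(
                dim=int(dim),
                n_matrices=n_matrices,
                n_initial=n_initial,
                recall=hits / n_matrices if n_matrices else float("nan"),
                inconclusive_rate=1 - hits / n_matrices if n_matrices else float("nan"),
                seed=seed,
            )
        )
    return rows


@dataclass(frozen=True)
class CycleDensityRow:
    dim: int
    ratio: float
    n_samples: int
    cycle_density: float
    seed: int


def sample_with_ratio(n: int, ratio: float, rng, *, margin: float = 0.5) -> np.ndarray:
    """Draw a VL stable matrix whose split satisfies |A_J|/|A_S| = ratio.

    A standard-normal draw is split into symmetric and antisymmetric
    parts; the symmetric part's diagonal is shifted down so its spectrum
    is strictly negative (hence A = I(S+J) is VL stable by construction),
    and the antisymmetric part is rescaled to hit the target ratio.
    ``ratio=0`` yields a symmetric stable matrix.
    """
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    m = rng.standard_normal((n, n))
    split = symmetry_split(m)
    a_s = split.a_s - (max(0.0, float(np.linalg.eigvalsh(split.a_s)[-1])) + margin) * np.eye(n)
    norm_j = entrywise_norm(split.a_j)
    if ratio == 0.0 or norm_j == 0.0:
        return a_s
    a_j = split.a_j * (ratio * entrywise_norm(a_s) / norm_j)
    return a_s + a_j


def cycle_density(
    dims: Sequence[int],
    ratios: Sequence[float],
    n_samples: int = 100,
    seed: int = 0,
) -> list[CycleDensityRow]:
    """Fraction of sampled systems (unit growth rates) whose IG has a cycle,
    per (dimension, |A_J|/|A_S| ratio) cell."""
    rows = []
    master = np.random.default_rng(seed)
    for dim in dims:
        for ratio in ratios:
            rng = np.random.default_rng(int(master.integers(2**31)))
            n_cyclic = 0
            for _ in range(n_samples):
                a = sample_with_ratio(dim, float(ratio), rng)
                catalog = enumerate_admissible(a, None)
                if find_cycles(build_ig(catalog)).has_cycle:
                    n_cyclic += 1
            rows.append(
                CycleDensityRow(
                    dim=int(dim),
                    ratio=float(ratio),
                    n_samples=n_samples,
                    cycle_density=n_cyclic / n_samples if n_samples else float("nan"),
                    seed=seed,
                )
            )
    return rows


@dataclass(frozen=True)
class DDSweepReport:
    n_samples: int
    dims: tuple
    n_cyclic: int
    n_singleton_cyclic: int
    cyclic_examples: tuple
    seed: int


def sample_dd_system(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw a strongly diagonally dominant system with mixed-sign b.

    Off-diagonal interactions are standard normal (positive and negative);
    the diagonal is negative (self-regulation) with magnitude exceeding
    the off-diagonal row or column sum by a positive slack, making the
    matrix strongly row- or column-diagonally-dominant (coin flip) and
    hence VL stable.  Growth rates are standard normal (mixed signs).
    """
    a = rng.standard_normal((n, n))
    np.fill_diagonal(a, 0.0)
    slack = rng.uniform(0.05, 1.0, size=n)
    if rng.random() < 0.5:
        dom = np.abs(a).sum(axis=1)
    else:
        dom = np.abs(a).sum(axis=0)
    np.fill_diagonal(a, -(dom + slack))
    b = rng.standard_normal(n)
    return a, b


def dd_sweep(
    n_samples: int = 1000,
    dims: Sequence[int] = (3, 4, 5, 6),
    seed: int = 0,
    *,
    max_examples: int = 10,
) -> DDSweepReport:
    """Search diagonally dominant systems for cyclic invasion graphs.

    Reports the count of cyclic IGs (expected 0) and, separately, of
    cycles among singleton communities (provably impossible under
    diagonal dominance, so a nonzero count indicates a bug)."""
    rng = np.random.default_rng(seed)
    n_cyclic = 0
    n_singleton = 0
    examples = []
    for k in range(n_samples):
        n = int(dims[k % len(dims)])
        a, b = sample_dd_system(n, rng)
        assert is_row_dd(a) or is_col_dd(a)
        catalog = enumerate_admissible(a, b)
        g = build_ig(catalog)
        rep = find_cycles(g, max_cycles=10)
        if rep.has_cycle:
            n_cyclic += 1
            if len(examples) < max_examples:
                examples.append((a.tolist(), b.tolist()))
            singles = [node for node in g.nodes if len(node) == 1]
            if any(True for _ in nx.simple_cycles(g.subgraph(singles))):
                n_singleton += 1
    return DDSweepReport(
        n_samples=n_samples,
        dims=tuple(int(d) for d in dims),
        n_cyclic=n_cyclic,
        n_singleton_cyclic=n_singleton,
        cyclic_examples=tuple(examples),
        seed=seed,
    )


@dataclass(frozen=True)
class RpslsSummary:
    d: float
    n_admissible: int
    has_cycle: bool
    n_cycles: int
    hyperbolic: bool
    matches_symmetric_part: Optional[bool]  # only evaluated for d < -1


def rpsls_d_sweep(d_values: Sequence[float]) -> list[RpslsSummary]:
    """Summarize the RPSLS family across self-regulation strengths d < 0.

    For d < -1 the invasion graph is additionally compared with the IG of
    the decoupled symmetric system diag(d) (node and edge sets must agree
    once the cyclic part is dominated)."""
    out = []
    for d in d_values:
        d = float(d)
        if d >= 0:
            raise ValueError("the RPSLS family requires d < 0")
        a, b = rpsls5(d)
        catalog = enumerate_admissible(a, b)
        g = build_ig(catalog)
        rep = find_cycles(g)
        hyp, _ = is_hyperbolic(catalog)
        matches = None
        if d < -1:
            diag_cat = enumerate_admissible(d * np.eye(5), b)
            diag_g = build_ig(diag_cat)
            matches = set(g.nodes) == set(diag_g.nodes) and set(g.edges) == set(
                diag_g.edges
            )
        out.append(
            RpslsSummary(
                d=d,
                n_admissible=len(catalog),
                has_cycle=rep.has_cycle,
                n_cycles=len(rep.elementary_cycles),
                hyperbolic=hyp,
                matches_symmetric_part=matches,
            )
        )
    return out


def rows_to_tsv(rows) -> str:
    """Serialize a list of experiment dataclass rows as a TSV table."""
    if not rows:
        return ""
    dicts = [asdict(r) for r in rows]
    cols = list(dicts[0])
    lines = ["\t".join(cols)]
    for d in dicts:
        lines.append("\t".join(str(d[c]) for c in cols))
    return "\n".join(lines) + "\n"
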