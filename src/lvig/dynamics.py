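"""Numerical integration of the Lotka-Volterra ODE.

Used to validate catalog predictions empirically: interior trajectories of
a VL stable system converge to the GASS, faces (walls) of the positive
cone are invariant, and transitions between boundary equilibria follow the
invasion-graph edges.  Coordinates that start at exactly zero are removed
from the integrated subsystem instead of being carried as tiny values, so
wall dynamics are exact restrictions of the flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from lvig.equilibria import CommunityCatalog
from lvig.matrices import as_growth_rates, as_interaction_matrix

__all__ = ["Trajectory", "simulate", "omega_limit_check"]

#: state-norm cap treated as numerical blow-up (impossible for VL stable A)
BLOWUP_NORM = 1e8


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution: ``states[k]`` approximates u(times[k])."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    metadata: dict = field(default_factory=dict)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def simulate(
    a,
    b,
    u0,
    t_final: Optional[float] = None,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_points: int = 400,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``du_i/dt = u_i (b_i + (A u)_i)`` from ``u0`` on [0, t_final].

    ``u0`` must be nonnegative; its zero coordinates stay exactly zero
    (face invariance is enforced structurally by integrating the reduced
    subsystem on the support of ``u0``).  When ``t_final`` is omitted it
    defaults to ``200 / |min diag(A)|``, long enough for the strongly
    self-regulated fixtures to settle.  Raises ``RuntimeError`` on
    numerical blow-up, which cannot occur for VL stable ``A``.
    """
    a = as_interaction_matrix(a)
    n = a.shape[0]
    b = as_growth_rates(b, n)
    u0 = np.asarray(u0, dtype=float)
    if u0.shape != (n,):
        raise ValueError(f"u0 has shape {u0.shape}, expected ({n},)")
    if np.any(u0 < 0):
        raise ValueError("initial state must be nonnegative")
    if t_final is None:
        dmin = float(np.abs(np.diag(a)).min())
        if dmin == 0:
            raise ValueError("cannot infer t_final for a matrix with zero diagonal")
        t_final = 200.0 / dmin
    if t_final <= 0:
        raise ValueError("t_final must be positive")

    support = np.flatnonzero(u0 > 0)
    times = np.linspace(0.0, t_final, n_points)
    states = np.zeros((n_points, n))
    if support.size == 0:
        return Trajectory(times=times, states=states, metadata={"rtol": rtol})

    a_red = a[np.ix_(support, support)]
    b_red = b[support]

    def rhs(_t, u):
        return u * (b_red + a_red @ u)

    def blowup(_t, u):
        return float(np.linalg.norm(u)) - BLOWUP_NORM

    blowup.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, t_final),
        u0[support],
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        events=blowup,
    )
    if sol.status == 1:  # terminated by the blow-up event
        raise RuntimeError("trajectory norm exceeded the blow-up cap")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states[:, support] = np.clip(sol.y.T, 0.0, None)
    return Trajectory(
        times=times,
        states=states,
        metadata={"rtol": rtol, "atol": atol, "method": method, "t_final": t_final},
    )


def omega_limit_check(
    traj: Trajectory,
    catalog: CommunityCatalog,
    *,
    window: float = 0.1,
    diameter_tol: float = 1e-6,
) -> tuple[Optional[np.ndarray], float, bool]:
    """Identify the catalog equilibrium the trajectory settles on.

    Looks at the terminal ``window`` fraction of samples; if its diameter
    is below ``diameter_tol`` the run counts as converged and the closest
    admissible equilibrium (Euclidean distance to the final state) is
    returned as ``(equilibrium_u, distance, True)``.  Non-converged runs
    return ``(None, nan, False)``.
    """
    k = max(2, int(len(traj.times) * window))
    tail = traj.states[-k:]
    diameter = float(np.linalg.norm(tail.max(axis=0) - tail.min(axis=0)))
    if diameter > diameter_tol:
        return None, float("nan"), False
    final = traj.final
    best_u, best_d = None, np.inf
    for e in catalog.entries:
        d = float(np.linalg.norm(final - e.equilibrium.u))
        if d < best_d:
            best_u, best_d = e.equilibrium.u, d
    return best_u, best_d, True
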