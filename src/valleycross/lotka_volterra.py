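"""Deterministic ecology: Lotka-Volterra dynamics on a trait subset.

On the O(1) time scale the rescaled population process is governed by the
competitive Lotka-Volterra system restricted to the macroscopic support
``v``::

    dn_v/dt = (b(v) - d(v) - sum_w c(v, w) n_w) n_v .

A *coexistence equilibrium* of a support is a strictly positive solution of
the linear system ``b(v) - d(v) = sum_w c(v, w) nbar_w``, assumed by the
theory to be the unique globally asymptotically stable attractor.  Global
stability is undecidable in general, so equilibria carry a layered verdict:
local stability is certified via the Jacobian spectrum, global stability is
only ever *heuristic* (multi-start convergence), and callers decide how much
certification they require.

The *invasion fitness* ``f(w, v) = b(w) - d(w) - sum_v c(w, v) nbar_v`` is
the initial per-capita growth rate of a rare trait-``w`` population in the
environment set by the residents; the whole metastability calculus branches
on its sign, so an (excluded-by-assumption) zero fitness raises instead of
being silently signed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateLVError, ZeroInvasionFitnessError
from .trait_model import TraitGraphModel

__all__ = [
    "Stability",
    "LVEquilibrium",
    "integrate_lvs",
    "coexistence_equilibrium",
    "assess_stability",
    "invasion_fitness",
]

POSITIVITY_TOL = 1e-10
EIGENVALUE_TOL = 1e-9
ODE_TOL = 1e-6
FITNESS_TOL = 1e-9


class Stability(str, Enum):
    VERIFIED_LOCALLY_STABLE = "verified-locally-stable"
    VERIFIED_UNSTABLE = "verified-unstable"
    HEURISTIC_GLOBALLY_STABLE = "heuristic-globally-stable"
    UNKNOWN = "unknown"

    @property
    def at_least_heuristically_stable(self) -> bool:
        return self is Stability.HEURISTIC_GLOBALLY_STABLE

    @property
    def locally_stable(self) -> bool:
        return self in (Stability.VERIFIED_LOCALLY_STABLE,
                        Stability.HEURISTIC_GLOBALLY_STABLE)


@dataclass
class LVEquilibrium:
    """An equilibrium of the Lotka-Volterra system on a support set."""

    support: tuple[str, ...]
    abundances: dict[str, float]
    positive: bool
    stable: Stability

    def abundance(self, v: str) -> float:
        return self.abundances.get(v, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.abundances[v] for v in self.support])


def _interaction(model: TraitGraphModel, support: tuple[str, ...]):
    """Interaction matrix C and net growth vector r restricted to a support."""
    C = np.array([[model.c[(v, w)] for w in support] for v in support])
    r = np.array([model.r(v) for v in support])
    return C, r


def _rhs(C: np.ndarray, r: np.ndarray):
    def fun(_t, n):
        return n * (r - C @ n)
    return fun


def integrate_lvs(model: TraitGraphModel,
                  support: Iterable[str],
                  init: Mapping[str, float],
                  horizon: float,
                  rtol: float = 1e-9,
                  atol: float = 1e-12):
    """Integrate the Lotka-Volterra system on ``support`` from ``init``.

    Returns ``(times, trajectory)`` with the trajectory clamped at zero
    (components can numerically undershoot by O(atol)).
    """
    support = tuple(support)
    model._check(*support)
    C, r = _interaction(model, support)
    n0 = np.array([float(init.get(v, 0.0)) for v in support])
    if np.any(n0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    sol = solve_ivp(_rhs(C, r), (0.0, horizon), n0, method="LSODA",
                    rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:  # pragma: no cover - solver diagnostics passthrough
        raise RuntimeError(f"LV integration failed: {sol.message}")
    traj = np.clip(sol.y.T, 0.0, None)
    return sol.t, traj


def _equilibrium_solution(model: TraitGraphModel, support: tuple[str, ...]):
    """Solve the linear equilibrium system; None when no solution exists."""
    C, r = _interaction(model, support)
    k = len(support)
    if np.linalg.matrix_rank(C) < k:
        # Singular interaction matrix: either the system is inconsistent
        # (no equilibrium with full support at all) or it has a continuum
        # of equilibria, which violates the standing uniqueness assumption.
        sol, residual, *_ = np.linalg.lstsq(C, r, rcond=None)
        if np.allclose(C @ sol, r, atol=1e-9):
            raise DegenerateLVError(
                f"interaction matrix on {support!r} is singular with a "
                "continuum of equilibria")
        return None
    return np.linalg.solve(C, r)


def coexistence_equilibrium(model: TraitGraphModel,
                            support: Iterable[str],
                            assess: bool = True) -> LVEquilibrium | None:
    """The candidate coexistence equilibrium of a support, or ``None``.

    Solves the linear system on the full support and returns it only when
    strictly positive, together with a stability verdict.  ``None`` means no
    equilibrium in which *all* traits of the support persist exists.
    """
    support = tuple(support)
    if not support:
        raise ValueError("support must be nonempty")
    model._check(*support)
    nbar = _equilibrium_solution(model, support)
    if nbar is None:
        return None
    positive = bool(np.min(nbar) > POSITIVITY_TOL)
    eq = LVEquilibrium(support=support,
                       abundances={v: float(n) for v, n in zip(support, nbar)},
                       positive=positive,
                       stable=Stability.UNKNOWN)
    if not positive:
        return None
    if assess:
        eq.stable = assess_stability(model, eq)
    return eq


def _jacobian(model: TraitGraphModel, eq: LVEquilibrium) -> np.ndarray:
    C, r = _interaction(model, eq.support)
    n = eq.as_array()
    growth = r - C @ n  # zero at an interior equilibrium
    return np.diag(growth) - n[:, None] * C


def assess_stability(model: TraitGraphModel,
                     eq: LVEquilibrium,
                     n_starts: int | None = None,
                     horizon: float = 200.0) -> Stability:
    """Layered stability verdict for a positive equilibrium.

    Local stability is decided by the Jacobian spectrum (margin 1e-9).  On
    top of a locally stable verdict, convergence of the flow from a grid of
    at least ``2**|support|`` perturbed starting points upgrades it to
    *heuristic-globally-stable*; global stability is never certified.
    """
    if not eq.positive:
        raise ValueError("stability assessment requires a positive equilibrium")
    J = _jacobian(model, eq)
    re = np.real(np.linalg.eigvals(J))
    if np.max(re) > EIGENVALUE_TOL:
        return Stability.VERIFIED_UNSTABLE
    if np.max(re) > -EIGENVALUE_TOL:
        return Stability.UNKNOWN
    k = len(eq.support)
    nbar = eq.as_array()
    # deterministic perturbation grid: every corner of a +/-40% box, plus a
    # near-extinct and a high-density start
    factors = [0.6, 1.4]
    starts = [np.array(f) * nbar
              for f in itertools.product(factors, repeat=k)]
    starts.append(nbar * 0.01 + 1e-3)
    starts.append(nbar * 3.0)
    if n_starts is not None and len(starts) > n_starts:
        starts = starts[:n_starts]
    for n0 in starts:
        init = dict(zip(eq.support, n0))
        _, traj = integrate_lvs(model, eq.support, init, horizon)
        if np.max(np.abs(traj[-1] - nbar)) > ODE_TOL:
            return Stability.VERIFIED_LOCALLY_STABLE
    return Stability.HEURISTIC_GLOBALLY_STABLE


def invasion_fitness(model: TraitGraphModel,
                     w: str,
                     eq: LVEquilibrium) -> float:
    """Invasion fitness ``f(w, v)`` of trait ``w`` against residents at
    equilibrium ``eq``.

    Residents themselves have fitness exactly zero (forced by the
    equilibrium equations).  For a non-resident, a fitness of zero within
    1e-9 is excluded by assumption and raises
    :class:`ZeroInvasionFitnessError` rather than being signed arbitrarily.
    """
    model._check(w)
    if w in eq.support:
        return 0.0
    f = model.r(w) - sum(model.c[(w, v)] * eq.abundances[v] for v in eq.support)
    if abs(f) < FITNESS_TOL:
        raise ZeroInvasionFitnessError(
            f"invasion fitness of {w!r} against {eq.support!r} is zero "
            "within tolerance")
    return f


def equilibria_to_csv(equilibria: Iterable[LVEquilibrium], path) -> None:
    """Export equilibria as CSV (support, abundances, verdict)."""
    import pandas as pd

    rows = [
        {
            "support": "+".join(eq.support),
            "abundances": ";".join(f"{eq.abundances[v]:.12g}" for v in eq.support),
            "verdict": eq.stable.value,
        }
        for eq in equilibria
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
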