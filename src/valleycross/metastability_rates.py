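"""The metastability calculus: ESC detection and valley-crossing rates.

An *evolutionary stable condition* (ESC) is a resident set ``v`` at a stable
coexistence equilibrium whose mutation-spreading neighbourhood ``V_alpha``
contains no fit trait, together with the mutation-fed exponent profile
``beta_w = (1 - d(v, w)/alpha)_+``.  Its *stability degree* ``L(v)`` is the
directed graph distance to the nearest fit trait — the width of the
surrounding fitness valley — and sets the escape time scale
``1/(K mu_K^L)``.

Crossing the valley happens along shortest paths to the *mutant candidates*
(fit traits at distance exactly ``L``).  The per-path rate combines

* the equilibrium sizes of the mutation-fed traits inside ``V_alpha``
  (prefactors ``a_v``),
* for each unfit trait strictly outside ``V_alpha`` on the path, the
  expected number of birth events ``lambda(rho) = rho/(1 - 2 rho)`` during a
  subcritical excursion (each birth being a chance to mutate onward), and
* the fixation probability ``f/b`` of the terminal fit mutant.

Summed over paths and candidates these yield the exit rate ``R(v)`` and the
branch probabilities ``R(v, w)/R(v)`` of the limiting exponential exit law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .errors import (
    CriticalExcursionError,
    NotAnESCError,
    StabilityUnknownError,
    UnreachableTraitError,
)
from .lotka_volterra import (
    LVEquilibrium,
    Stability,
    coexistence_equilibrium,
    invasion_fitness,
)
from .trait_model import Path, TraitGraphModel, alpha_neighborhood, \
    graph_distance, shortest_paths

__all__ = [
    "ESCState",
    "CrossingRates",
    "stability_degree",
    "mutant_candidates",
    "esc_state",
    "equilibrium_prefactors",
    "excursion_factor",
    "excursion_factor_series",
    "birth_fraction",
    "path_crossing_rate",
    "path_arrival_rate",
    "crossing_rates",
    "esc_transition_probabilities",
]

RHO_TOL = 1e-9


@dataclass
class ESCState:
    """A validated evolutionary stable condition."""

    residents: frozenset[str]
    equilibrium: LVEquilibrium
    beta: dict[str, float]
    L: float  # stability degree (int >= 1 or math.inf)
    mutant_candidates: frozenset[str]
    v_alpha: frozenset[str] = field(default_factory=frozenset)
    boundary: frozenset[str] = field(default_factory=frozenset)

    @property
    def model_support(self) -> tuple[str, ...]:
        return self.equilibrium.support

    def fitness(self, model: TraitGraphModel, w: str) -> float:
        return invasion_fitness(model, w, self.equilibrium)


@dataclass
class CrossingRates:
    """Valley-crossing rates out of an ESC on the ``1/(K mu_K^L)`` scale."""

    per_path: dict[Path, float]
    per_trait: dict[str, float]
    total: float
    branch_probs: dict[str, float]
    timescale_exponent: float

    def __post_init__(self):
        if self.total > 0:
            s = sum(self.per_trait.values())
            assert abs(s - self.total) <= 1e-12 * max(1.0, abs(self.total))


# --------------------------------------------------------------------------
# stability degree and candidates


def _coexists(model: TraitGraphModel, residents: Iterable[str],
              trust_stability: bool = False) -> LVEquilibrium | None:
    """The stable coexistence equilibrium of a resident set, or None.

    "Can coexist" requires a strictly positive equilibrium that is at least
    locally stable; with ``trust_stability`` a merely positive equilibrium
    of unknown global behaviour is accepted on the caller's assertion.
    """
    eq = coexistence_equilibrium(model, sorted(residents, key=model.index))
    if eq is None:
        return None
    if eq.stable is Stability.VERIFIED_UNSTABLE:
        return None
    if eq.stable is Stability.UNKNOWN and not trust_stability:
        return None
    return eq


def stability_degree(model: TraitGraphModel,
                     residents: Iterable[str],
                     trust_stability: bool = False) -> float:
    """Stability degree ``L(v)``: 0 when the set cannot coexist, otherwise
    the minimal graph distance to a fit trait (``inf`` when none is
    reachable, in which case the equilibrium is a final state)."""
    residents = frozenset(residents)
    eq = _coexists(model, residents, trust_stability)
    if eq is None:
        return 0
    best = math.inf
    for w in model.traits:
        if w in residents:
            continue
        if invasion_fitness(model, w, eq) > 0:
            best = min(best, graph_distance(model, residents, [w]))
    return best


def mutant_candidates(model: TraitGraphModel,
                      residents: Iterable[str],
                      trust_stability: bool = False) -> frozenset[str]:
    """Fit traits at distance exactly ``L(v)``: the only traits that can
    trigger an exit from the ESC.  Empty when ``L = inf``."""
    residents = frozenset(residents)
    eq = _coexists(model, residents, trust_stability)
    if eq is None:
        raise NotAnESCError(f"{sorted(residents)!r} cannot coexist")
    L = stability_degree(model, residents, trust_stability)
    if math.isinf(L):
        return frozenset()
    return frozenset(
        w for w in model.traits
        if w not in residents
        and invasion_fitness(model, w, eq) > 0
        and graph_distance(model, residents, [w]) == L)


def esc_state(model: TraitGraphModel,
              residents: Iterable[str],
              trust_stability: bool = False) -> ESCState:
    """Validate a resident set as an ESC and assemble its state.

    Raises :class:`NotAnESCError` naming the violated condition when the set
    does not coexist, a trait inside ``V_alpha`` is fit, or the stability
    degree does not exceed ``alpha``; raises
    :class:`StabilityUnknownError` when stability could not be certified and
    ``trust_stability`` is not set.
    """
    residents = frozenset(residents)
    eq = coexistence_equilibrium(model, sorted(residents, key=model.index))
    if eq is None:
        raise NotAnESCError(
            f"{sorted(residents)!r} has no positive coexistence equilibrium")
    if eq.stable is Stability.VERIFIED_UNSTABLE:
        raise NotAnESCError(
            f"equilibrium of {sorted(residents)!r} is unstable")
    if eq.stable is Stability.UNKNOWN and not trust_stability:
        raise StabilityUnknownError(
            f"stability of {sorted(residents)!r} could not be certified; "
            "pass trust_stability=True to override")
    v_alpha, boundary = alpha_neighborhood(model, residents)
    for w in sorted(v_alpha - residents, key=model.index):
        if invasion_fitness(model, w, eq) > 0:
            raise NotAnESCError(
                f"fit trait {w!r} inside the mutation-spreading "
                f"neighbourhood of {sorted(residents)!r}")
    L = stability_degree(model, residents, trust_stability=True)
    if L <= model.alpha:
        raise NotAnESCError(
            f"stability degree {L} of {sorted(residents)!r} does not exceed "
            f"alpha={model.alpha}")
    beta = {
        w: max(1.0 - graph_distance(model, residents, [w]) / model.alpha, 0.0)
        for w in model.traits
    }
    cands = frozenset() if math.isinf(L) else frozenset(
        w for w in model.traits
        if w not in residents
        and invasion_fitness(model, w, eq) > 0
        and graph_distance(model, residents, [w]) == L)
    assert not (cands & v_alpha)
    return ESCState(residents=residents, equilibrium=eq, beta=beta, L=L,
                    mutant_candidates=cands, v_alpha=frozenset(v_alpha),
                    boundary=frozenset(boundary))


# --------------------------------------------------------------------------
# equilibrium prefactors


def equilibrium_prefactors(model: TraitGraphModel,
                           esc: ESCState) -> dict[str, float]:
    """Prefactors ``a_v`` of the mutation-fed equilibrium sizes inside the
    mutation-spreading neighbourhood: ``N_v ~ a_v K mu_K^d(v, v)``.

    Each shortest path from the residents contributes the product of
    (birth rate x mutant-law weight) / |invasion fitness| along its edges,
    seeded by the resident equilibrium abundance of its first vertex; a
    resident's own prefactor is its equilibrium abundance (a length-zero
    path with an empty product).
    """
    out: dict[str, float] = {}
    for v in sorted(esc.v_alpha, key=model.index):
        if v in esc.residents:
            out[v] = esc.equilibrium.abundances[v]
            continue
        if math.isinf(graph_distance(model, esc.residents, [v])):
            raise UnreachableTraitError(
                f"trait {v!r} lies in V_alpha but is unreachable from "
                f"{sorted(esc.residents)!r}")
        total = 0.0
        for gamma in shortest_paths(model, esc.residents, v):
            term = esc.equilibrium.abundances[gamma[0]]
            for i in range(1, len(gamma)):
                u, w = gamma[i - 1], gamma[i]
                term *= model.b[u] * model.m[(u, w)] / abs(
                    invasion_fitness(model, w, esc.equilibrium))
            total += term
        out[v] = total
    return out


# --------------------------------------------------------------------------
# subcritical excursions


def excursion_factor(rho: float) -> float:
    """Expected number of birth events before extinction in a birth-death
    excursion with per-event birth probability ``rho``.

    Closed form ``rho / (1 - 2 rho)`` for subcritical excursions
    (``rho < 1/2``); values for ``rho > 1/2`` are supplied through the
    symmetry relation ``lambda(rho) rho = lambda(1-rho) (1-rho)`` as a
    convenience (the calculus itself only ever needs the subcritical side).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if abs(rho - 0.5) < RHO_TOL:
        raise CriticalExcursionError("rho = 1/2: critical excursion")
    if rho < 0.5:
        return rho / (1.0 - 2.0 * rho)
    return excursion_factor(1.0 - rho) * (1.0 - rho) / rho


def excursion_factor_series(rho: float, terms: int = 200) -> float:
    """Truncated series for the excursion birth count,
    ``sum_l (2l)!/((l-1)!(l+1)!) rho^l (1-rho)^(l+1)``; an independent check
    of the closed form."""
    # term_(l+1)/term_l = (2l+1)(2l+2)/(l(l+2)) * rho(1-rho); iterating the
    # ratio avoids overflowing the combinatorial coefficient
    term = rho * (1.0 - rho) ** 2  # l = 1: coefficient 2!/0!2! = 1
    total = term
    for ell in range(1, terms):
        term *= (2 * ell + 1) * (2 * ell + 2) / (ell * (ell + 2)) \
            * rho * (1.0 - rho)
        total += term
    return total


def birth_fraction(model: TraitGraphModel, w: str,
                   eq: LVEquilibrium) -> float:
    """Per-event birth probability ``rho(w, v)`` of a rare trait-``w``
    individual in the resident environment:
    ``b / (b + d + sum_v c(w, v) nbar_v)``."""
    model._check(w)
    denom = model.b[w] + model.d[w] + sum(
        model.c[(w, v)] * eq.abundances[v] for v in eq.support)
    return model.b[w] / denom


# --------------------------------------------------------------------------
# crossing rates


def _check_path(model: TraitGraphModel, esc: ESCState, gamma: Path) -> None:
    if gamma[0] not in esc.residents:
        raise ValueError(f"path must start in the residents, got {gamma[0]!r}")
    if gamma.length != esc.L:
        raise ValueError(
            f"path length {gamma.length} != stability degree {esc.L}")
    if gamma[-1] not in esc.mutant_candidates:
        raise ValueError(f"path must end in a mutant candidate, got {gamma[-1]!r}")
    for v in gamma.vertices[1:-1]:
        if invasion_fitness(model, v, esc.equilibrium) > 0:
            raise ValueError(
                f"interior trait {v!r} of {gamma.vertices!r} is fit; the "
                "valley assumption is violated")


def path_arrival_rate(model: TraitGraphModel, esc: ESCState,
                      gamma: Path) -> float:
    """Rate (on the ``1/(K mu_K^L)`` scale) at which single mutants of the
    terminal trait of ``gamma`` are *born* along the path — the crossing
    rate without the final fixation factor."""
    _check_path(model, esc, gamma)
    fa = math.floor(model.alpha)
    eq = esc.equilibrium
    rate = eq.abundances[gamma[0]]
    # mutation-fed equilibrium chain inside V_alpha
    for i in range(1, fa + 1):
        u, w = gamma[i - 1], gamma[i]
        rate *= model.b[u] * model.m[(u, w)] / abs(
            invasion_fitness(model, w, eq))
    # the first mutant launched beyond V_alpha
    u, w = gamma[fa], gamma[fa + 1]
    rate *= model.b[u] * model.m[(u, w)]
    # subcritical excursions bridging the remaining valley traits
    for j in range(fa + 1, int(esc.L)):
        rho = birth_fraction(model, gamma[j], eq)
        rate *= excursion_factor(rho) * model.m[(gamma[j], gamma[j + 1])]
    return rate


def path_crossing_rate(model: TraitGraphModel, esc: ESCState,
                       gamma: Path) -> float:
    """Rate ``R(v, gamma)`` at which a mutant arises along ``gamma`` *and*
    fixates: the arrival rate times the fixation probability ``f/b`` of the
    terminal trait."""
    w = gamma[-1]
    f = invasion_fitness(model, w, esc.equilibrium)
    return path_arrival_rate(model, esc, gamma) * f / model.b[w]


def crossing_rates(model: TraitGraphModel, esc: ESCState) -> CrossingRates:
    """Aggregate ``R(v, gamma)`` over all shortest paths into per-candidate
    rates ``R(v, w)``, the total exit rate ``R(v)`` and branch
    probabilities."""
    if math.isinf(esc.L):
        raise ValueError("no exit: the ESC has infinite stability degree")
    per_path: dict[Path, float] = {}
    per_trait: dict[str, float] = {}
    for w in sorted(esc.mutant_candidates, key=model.index):
        total_w = 0.0
        for gamma in shortest_paths(model, esc.residents, w):
            r = path_crossing_rate(model, esc, gamma)
            per_path[gamma] = r
            total_w += r
        per_trait[w] = total_w
    total = sum(per_trait.values())
    branch = {w: (r / total if total > 0 else 0.0)
              for w, r in per_trait.items()}
    return CrossingRates(per_path=per_path, per_trait=per_trait, total=total,
                         branch_probs=branch, timescale_exponent=esc.L)


def esc_transition_probabilities(model: TraitGraphModel,
                                 esc: ESCState,
                                 trust_stability: bool = False,
                                 ) -> dict[frozenset[str], float]:
    """Transition probabilities ``p(v, w-set)`` to successor ESCs.

    Each mutant candidate is followed through the deterministic ln K
    invasion dynamics to its terminal ESC; candidates mapping to the same
    resident set pool their branch probabilities.  A candidate whose
    dynamics terminate early raises :class:`InvasionTerminatedError`.
    """
    from .lnk_dynamics import run_invasion  # deferred: avoids import cycle

    rates = crossing_rates(model, esc)
    out: dict[frozenset[str], float] = {}
    for w in sorted(esc.mutant_candidates, key=model.index):
        outcome = run_invasion(model, esc, w, trust_stability=trust_stability)
        outcome.raise_if_terminated(mutant=w)
        target = outcome.esc.residents
        out[target] = out.get(target, 0.0) + rates.branch_probs[w]
    return out
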