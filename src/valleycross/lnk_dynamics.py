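"""Deterministic invasion dynamics on the ln K time scale.

Between metastable jumps, the orders of magnitude of all subpopulations
evolve deterministically: writing ``N_w = K^{beta_w}``, each exponent is a
maximum of affine functions of (ln K-scaled) time,

    beta_w(t) = max_u [ beta_u(0) + (t - t_u) f(u, v) - d(u, w)/alpha ]_+ ,

where ``v`` is the current resident set, ``f(u, v)`` the invasion fitness,
``d(u, w)`` the directed graph distance and ``t_u`` the time at which trait
``u`` is first seeded by a mutant (the first time one of its in-neighbours
reaches exponent ``1/alpha``).  The dynamics are therefore piecewise linear
and are propagated here *event to event* with closed-form event times — no
time stepping.  Events are:

* a non-resident trait reaching exponent 1 (it becomes macroscopic and the
  resident set is updated through a short Lotka-Volterra phase),
* a trait crossing ``1/alpha`` for the first time (seeding its fit
  out-neighbours),
* a living trait's exponent hitting 0 (extinction), and
* global stabilisation at the mutation-fed profile
  ``beta_w = (1 - d(v, w)/alpha)_+`` — an evolutionary stable condition.

The invasion run alternates exponent propagation and resident updates from
the post-fixation initial condition (invading mutant at ``1/alpha``, all
other traits at the ESC profile) until a new ESC is reached or a
termination criterion fires (ambiguous Lotka-Volterra attractor,
simultaneous macroscopic arrivals, zero invasion fitness, a recurring
non-ESC state, or the step limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvasionTerminatedError,
    NoUniqueEquilibriumError,
    NotAnESCError,
    StabilityUnknownError,
    ZeroInvasionFitnessError,
)
from .lotka_volterra import (
    LVEquilibrium,
    coexistence_equilibrium,
    integrate_lvs,
    invasion_fitness,
)
from .metastability_rates import ESCState, esc_state
from .trait_model import TraitGraphModel

__all__ = [
    "ExponentProfile",
    "PhaseEvent",
    "InvasionOutcome",
    "propagate_exponents",
    "lv_phase_update",
    "run_invasion",
]

EVENT_TOL = 1e-9      # two macroscopic arrivals closer than this are ambiguous
BETA_TOL = 1e-12
CYCLE_QUANTUM = 1e-7  # beta quantisation grid for recurrence detection
MACRO_TOL = 1e-9


@dataclass
class ExponentProfile:
    """Exponents ``beta`` of all traits plus the current resident set."""

    beta: dict[str, float]
    residents: frozenset[str]
    time: float = 0.0

    def living(self) -> frozenset[str]:
        return frozenset(v for v, b in self.beta.items() if b > BETA_TOL)

    def quantized(self) -> tuple:
        return tuple(round(b / CYCLE_QUANTUM) for b in
                     (self.beta[v] for v in sorted(self.beta)))


@dataclass
class PhaseEvent:
    kind: str          # "macroscopic" | "seeded" | "extinct" | "stabilized" | "terminated"
    time: float
    trait: str | None = None
    detail: str = ""


@dataclass
class InvasionOutcome:
    kind: str                                  # "esc-reached" | "terminated"
    esc: ESCState | None
    resident_sequence: list[frozenset[str]]
    termination_reason: str | None = None
    events: list[PhaseEvent] = field(default_factory=list)
    final_profile: ExponentProfile | None = None

    def raise_if_terminated(self, mutant=None) -> None:
        if self.kind == "terminated":
            raise InvasionTerminatedError(self.termination_reason, mutant)


# --------------------------------------------------------------------------
# single-phase propagation


class _Phase:
    """Exponent dynamics for one fixed resident set.

    Every exponent is the clamped maximum of affine *source terms*: trait
    ``u`` alive at the phase start (or seeded during it at time ``t_u``)
    contributes ``beta_u(start) + (t - t_u) f(u, v) - d(u, w)/alpha`` to
    every trait ``w`` it can reach.
    """

    def __init__(self, model: TraitGraphModel, residents: frozenset[str],
                 eq: LVEquilibrium, beta: dict[str, float], t0: float):
        self.model = model
        self.alpha = model.alpha
        self.residents = residents
        self.eq = eq
        self.t = t0
        self.f = {u: invasion_fitness(model, u, eq) for u in model.traits}
        # trait -> (beta at birth, birth time)
        self.sources: dict[str, tuple[float, float]] = {
            u: (beta[u], t0) for u in model.traits if beta[u] > BETA_TOL}
        self.extinct_reported: set[str] = set()
        self.seed_fit_traits(t0)

    # -- term algebra -------------------------------------------------------

    def _dist(self, u: str, w: str) -> float:
        return self.model._dist.get(u, {}).get(w, math.inf)

    def _terms(self, w: str, t: float):
        for u, (b0, tb) in self.sources.items():
            d = self._dist(u, w)
            if math.isinf(d):
                continue
            yield u, b0 + (t - tb) * self.f[u] - d / self.alpha

    def beta_at(self, t: float) -> dict[str, float]:
        out = {}
        for w in self.model.traits:
            val = max((x for _, x in self._terms(w, t)), default=0.0)
            out[w] = min(max(val, 0.0), 1.0)
        return out

    # -- events -------------------------------------------------------------

    def seed_fit_traits(self, t: float) -> list[str]:
        """Give every fit, so-far sourceless trait with an in-neighbour at or
        above 1/alpha its own growth term starting from exponent 0."""
        beta = self.beta_at(t)
        thresh = 1.0 / self.alpha - 1e-12
        seeded = []
        for x in self.model.traits:
            if x in self.sources or x in self.residents or self.f[x] <= 0:
                continue
            if any(beta[u] >= thresh for u in self.model.in_neighbors(x)):
                self.sources[x] = (0.0, t)
                seeded.append(x)
        return seeded

    def _macroscopic_candidates(self):
        for u, (b0, tb) in self.sources.items():
            if u in self.residents or self.f[u] <= 0:
                continue
            yield tb + (1.0 - b0) / self.f[u], u

    def _seed_candidates(self):
        """Future times at which some trait first reaches 1/alpha and thereby
        seeds a fit out-neighbour."""
        thresh = 1.0 / self.alpha
        beta = self.beta_at(self.t)
        for x in self.model.traits:
            if x in self.sources or x in self.residents or self.f[x] <= 0:
                continue
            for u in self.model.in_neighbors(x):
                if beta[u] >= thresh - 1e-12:
                    yield self.t, u  # should have been handled; defensive
                    continue
                for s, (b0, tb) in self.sources.items():
                    if self.f[s] <= 0:
                        continue
                    d = self._dist(s, u)
                    if math.isinf(d):
                        continue
                    tc = tb + (thresh + d / self.alpha - b0) / self.f[s]
                    if tc >= self.t - EVENT_TOL:
                        yield tc, u

    def extinction_time(self, w: str) -> float | None:
        """Time at which ``beta_w`` hits 0 (None if it never does)."""
        lo, hi = -math.inf, math.inf
        any_term = False
        for u, (b0, tb) in self.sources.items():
            d = self._dist(u, w)
            if math.isinf(d):
                continue
            any_term = True
            slope = self.f[u]
            val_now = b0 + (self.t - tb) * slope - d / self.alpha
            if slope == 0.0:
                if val_now > 0:
                    return None  # constant positive term (resident feed)
                continue
            zero = tb + (d / self.alpha - b0) / slope
            if slope < 0:
                lo = max(lo, zero)   # all decaying terms must have died
            else:
                hi = min(hi, zero)   # before any rising term comes alive
        if not any_term:
            return None
        # the exponent vanishes on [lo, hi]; a *future* extinction of a
        # currently living trait needs that interval to start at or after now
        if lo == -math.inf or lo > hi + EVENT_TOL:
            return None
        if lo < self.t - EVENT_TOL:
            return None
        return lo

    def _extinction_candidates(self):
        beta = self.beta_at(self.t)
        for w in self.model.traits:
            if w in self.residents or w in self.extinct_reported:
                continue
            if beta[w] <= BETA_TOL:
                continue
            te = self.extinction_time(w)
            if te is not None and te >= self.t - EVENT_TOL:
                yield te, w

    def next_event(self) -> PhaseEvent:
        """The earliest upcoming event (ties: seeds and extinctions are
        processed before macroscopic arrivals; two distinct macroscopic
        arrivals within tolerance are ambiguous)."""
        macro = sorted((t, u) for t, u in self._macroscopic_candidates()
                       if t >= self.t - EVENT_TOL)
        seeds = sorted(set((t, u) for t, u in self._seed_candidates()))
        exts = sorted(self._extinction_candidates())
        candidates = []
        if seeds:
            candidates.append((seeds[0][0], 0, "seeded", seeds[0][1]))
        if exts:
            candidates.append((exts[0][0], 1, "extinct", exts[0][1]))
        if macro:
            candidates.append((macro[0][0], 2, "macroscopic", macro[0][1]))
        if not candidates:
            return PhaseEvent("stabilized", self.t)
        candidates.sort(key=lambda c: (c[0], c[1]))
        t_ev, _, kind, trait = candidates[0]
        if kind == "macroscopic":
            clashing = {u for t, u in macro if abs(t - t_ev) < EVENT_TOL}
            if len(clashing) > 1:
                return PhaseEvent("terminated", t_ev, None,
                                  "simultaneous-events")
        return PhaseEvent(kind, t_ev, trait)

    def apply(self, event: PhaseEvent) -> None:
        """Advance the phase clock to the event and update bookkeeping."""
        self.t = event.time
        if event.kind == "seeded":
            # the crossing trait is event.trait; seeding happens via the scan
            self.seed_fit_traits(self.t)
        elif event.kind == "extinct":
            self.extinct_reported.add(event.trait)
            self.seed_fit_traits(self.t)

    def settle(self) -> tuple[float, dict[str, float]]:
        """After stabilisation (no fit sources left) every transient term
        decays linearly onto the resident-fed profile
        ``(1 - d(v, w)/alpha)_+``; return the (finite) time at which the
        last trait reaches it, together with that profile."""
        limit = {}
        for w in self.model.traits:
            d = min((self._dist(v, w) for v in self.residents),
                    default=math.inf)
            limit[w] = max(1.0 - d / self.alpha, 0.0) if math.isfinite(d) else 0.0
        t_end = self.t
        for w in self.model.traits:
            for u, (b0, tb) in self.sources.items():
                slope = self.f[u]
                if slope >= 0:
                    continue
                d = self._dist(u, w)
                if math.isinf(d):
                    continue
                if b0 + (self.t - tb) * slope - d / self.alpha > limit[w]:
                    t_end = max(t_end,
                                tb + (limit[w] + d / self.alpha - b0) / slope)
        return t_end, dict(limit)


def _resident_equilibrium(model: TraitGraphModel,
                          residents: frozenset[str]) -> LVEquilibrium:
    eq = coexistence_equilibrium(model, sorted(residents, key=model.index))
    if eq is None or not eq.stable.locally_stable:
        raise NoUniqueEquilibriumError(
            f"residents {sorted(residents)!r} lack a stable positive "
            "equilibrium")
    return eq


def propagate_exponents(model: TraitGraphModel,
                        profile: ExponentProfile,
                        ) -> tuple[ExponentProfile, PhaseEvent]:
    """Advance the exponent system by a single event.

    The residents must admit a stable coexistence equilibrium; all event
    times are computed in closed form from the affine pieces.
    """
    eq = _resident_equilibrium(model, profile.residents)
    phase = _Phase(model, profile.residents, eq, dict(profile.beta),
                   profile.time)
    event = phase.next_event()
    if event.kind == "stabilized":
        t_end, beta = phase.settle()
        return ExponentProfile(beta, profile.residents, t_end), event
    phase.apply(event)
    beta = phase.beta_at(phase.t)
    for v in profile.residents:
        beta[v] = 1.0
    return ExponentProfile(beta, profile.residents, phase.t), event


# --------------------------------------------------------------------------
# Lotka-Volterra resident updates


def lv_phase_update(model: TraitGraphModel,
                    residents: frozenset[str],
                    newcomer: str,
                    newcomer_init: float = 1e-3,
                    horizon_chunk: float = 100.0,
                    max_chunks: int = 60,
                    support_tol: float = 1e-6) -> frozenset[str]:
    """Resident set after a newly macroscopic trait joins the residents.

    Integrates the Lotka-Volterra system on ``residents + newcomer`` from
    the resident equilibrium with a small newcomer density until it settles,
    and returns the support of the attained equilibrium.  A handful of
    perturbed restarts must agree on that support, otherwise
    :class:`NoUniqueEquilibriumError` is raised.
    """
    model._check(newcomer, *residents)
    eq = _resident_equilibrium(model, residents)
    support = tuple(sorted(residents | {newcomer}, key=model.index))

    def _settle(init: dict[str, float]) -> frozenset[str] | None:
        state = dict(init)
        for _ in range(max_chunks):
            _, traj = integrate_lvs(model, support, state, horizon_chunk)
            prev = np.array([state[v] for v in support])
            state = dict(zip(support, traj[-1]))
            cur = np.array(traj[-1])
            drift = np.abs(cur - prev).max()
            if drift < 1e-10:
                return frozenset(v for v in support
                                 if state[v] > support_tol)
        return None

    base = {v: eq.abundances[v] for v in residents}
    base[newcomer] = newcomer_init
    inits = [dict(base)]
    for factor in (0.1, 10.0):
        alt = dict(base)
        alt[newcomer] = newcomer_init * factor
        inits.append(alt)
    for scale in (0.9, 1.1):
        alt = {v: n * scale for v, n in base.items()}
        alt[newcomer] = newcomer_init
        inits.append(alt)

    outcomes = {_settle(init) for init in inits}
    if len(outcomes) != 1 or None in outcomes:
        raise NoUniqueEquilibriumError(
            f"LV phase {support!r} has no unique attractor "
            f"(multi-start outcomes: {sorted(map(str, outcomes))})")
    final = outcomes.pop()
    if not final:
        raise NoUniqueEquilibriumError(
            f"LV phase {support!r} collapsed to full extinction")
    # the attained support must itself carry a stable positive equilibrium
    check = coexistence_equilibrium(model, sorted(final, key=model.index))
    if check is None or not check.stable.locally_stable:
        raise NoUniqueEquilibriumError(
            f"support {sorted(final)!r} attained by the LV phase has no "
            "stable positive equilibrium")
    return final


# --------------------------------------------------------------------------
# full invasion run


def run_invasion(model: TraitGraphModel,
                 esc: ESCState,
                 mutant: str | None = None,
                 trust_stability: bool = False,
                 step_limit: int | None = None) -> InvasionOutcome:
    """Follow the ln K dynamics from an ESC perturbed by one fixating mutant
    until a new ESC is reached or the algorithm terminates.

    The initial condition places the mutant at exponent ``1/alpha`` and every
    other trait at the ESC profile.  With ``mutant=None`` the profile is
    already stable and is returned unchanged in zero steps.
    """
    residents = esc.residents
    seq = [residents]
    events: list[PhaseEvent] = []
    if mutant is None:
        return InvasionOutcome("esc-reached", esc, seq,
                               final_profile=ExponentProfile(
                                   dict(esc.beta), residents, 0.0))
    if mutant not in esc.mutant_candidates:
        raise ValueError(f"{mutant!r} is not a mutant candidate of "
                         f"{sorted(residents)!r}")

    beta = dict(esc.beta)
    beta[mutant] = min(1.0 / model.alpha, 1.0)
    t = 0.0
    limit = step_limit if step_limit is not None else 10 * len(model.traits) ** 2
    history = {(residents, _quantize(beta))}

    def _terminated(reason: str) -> InvasionOutcome:
        return InvasionOutcome("terminated", None, seq, reason, events,
                               ExponentProfile(dict(beta), residents, t))

    # with alpha < 1 the mutant enters macroscopically (trait substitution
    # regime): the first resident update happens without exponent dynamics
    pending = mutant if beta[mutant] >= 1.0 - MACRO_TOL else None
    for _ in range(limit):
        if pending is not None:
            w_star, pending = pending, None
        else:
            # propagate exponents until fixation or stabilisation
            try:
                eq = _resident_equilibrium(model, residents)
                phase = _Phase(model, residents, eq, beta, t)
            except NoUniqueEquilibriumError:
                return _terminated("no-unique-lv-equilibrium")
            except ZeroInvasionFitnessError:
                return _terminated("zero-fitness")
            w_star = None
            while True:
                event = phase.next_event()
                events.append(event)
                if event.kind == "terminated":
                    return _terminated(event.detail)
                if event.kind == "stabilized":
                    t, beta = phase.settle()
                    for v in residents:
                        beta[v] = 1.0
                    return _finish(model, esc, residents, beta, t, seq,
                                   events, trust_stability)
                if event.kind == "macroscopic":
                    t = event.time
                    beta = phase.beta_at(t)
                    for v in residents:
                        beta[v] = 1.0
                    beta[event.trait] = 1.0
                    w_star = event.trait
                    break
                phase.apply(event)
        try:
            new_residents = lv_phase_update(model, residents, w_star)
        except NoUniqueEquilibriumError:
            return _terminated("no-unique-lv-equilibrium")
        except ZeroInvasionFitnessError:
            return _terminated("zero-fitness")
        for v in new_residents:
            beta[v] = 1.0
        residents = frozenset(new_residents)
        seq.append(residents)
        key = (residents, _quantize(beta))
        if key in history:
            return _terminated("non-convergent-cycle")
        history.add(key)
    return _terminated("step-limit")


def _quantize(beta: dict[str, float]) -> tuple:
    return tuple(round(beta[v] / CYCLE_QUANTUM) for v in sorted(beta))


def _finish(model, start_esc, residents, beta, t, seq, events,
            trust_stability) -> InvasionOutcome:
    """Stabilisation reached: certify the resident set as an ESC."""
    try:
        new_esc = esc_state(model, residents, trust_stability=trust_stability)
    except (NotAnESCError, StabilityUnknownError) as exc:
        return InvasionOutcome(
            "terminated", None, seq, f"stabilized-but-not-esc: {exc}", events,
            ExponentProfile(dict(beta), residents, t))
    profile = ExponentProfile({w: new_esc.beta[w] for w in model.traits},
                              residents, t)
    return InvasionOutcome("esc-reached", new_esc, seq, None, events, profile)
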