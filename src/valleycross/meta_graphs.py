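"""Metastability graphs, stability strata and limiting jump processes.

The *metastability graph* has one node per resident set that supports an
ESC (stability degree ``L > alpha``) and one edge per realisable transition
``v -> v_ESC(v, w)`` over the mutant candidates ``w``.  Nodes carry the exit
rate ``R(v)`` (valid on the time scale ``1/(K mu_K^{L(v)})``) and edges the
transition probabilities ``p(v, .)``.

Fixing a time scale ``1/(K mu_K^L)`` collapses this multi-scale object to
the *L-scale graph*: only nodes with ``L(v) >= L`` remain visible, faster
transitions happen instantaneously (paths through less stable ESCs collapse
onto single edges, probabilities obtained by absorption analysis), and more
stable nodes are absorbing.  The limiting population process is then a
Markov jump process on this graph whose state carries the Lotka-Volterra
equilibrium abundances of the current node.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateLVError,
    FinitePassageError,
    NotAnESCError,
    StabilityUnknownError,
    ZeroInvasionFitnessError,
)
from .lnk_dynamics import run_invasion
from .metastability_rates import ESCState, crossing_rates, esc_state
from .trait_model import TraitGraphModel

__all__ = [
    "MetaNode",
    "MetaEdge",
    "MetaGraph",
    "JumpTrajectory",
    "build_metastability_graph",
    "stability_strata",
    "verify_finite_passage",
    "build_scale_graph",
    "sample_limit_process",
]

TraitSet = frozenset


def _label(node: frozenset[str]) -> str:
    return "{" + ",".join(sorted(node)) + "}"


@dataclass
class MetaNode:
    residents: frozenset[str]
    L: float
    exit_rate: float
    abundances: dict[str, float]
    esc: ESCState | None = None
    frontier_invalid: dict[str, str] = field(default_factory=dict)

    @property
    def absorbing(self) -> bool:
        return math.isinf(self.L)


@dataclass
class MetaEdge:
    source: frozenset[str]
    target: frozenset[str]
    probability: float
    rate: float
    timescale_exponent: float
    via: tuple[str, ...] = ()   # mutant candidates (or collapsed paths) behind the edge


@dataclass
class MetaGraph:
    level: str | int            # "ESC" or the integer L of an L-scale graph
    nodes: dict[frozenset[str], MetaNode]
    edges: dict[tuple[frozenset[str], frozenset[str]], MetaEdge]
    max_support: int = 3

    def successors(self, v: frozenset[str]) -> list[MetaEdge]:
        return [e for (s, _), e in self.edges.items() if s == v]

    def node(self, traits) -> MetaNode:
        return self.nodes[frozenset(traits)]

    # -- exports ------------------------------------------------------------

    def to_dot(self) -> str:
        lines = ["digraph meta {"]
        for v, n in sorted(self.nodes.items(), key=lambda kv: _label(kv[0])):
            lstr = "inf" if math.isinf(n.L) else f"{int(n.L)}"
            lines.append(
                f'  "{_label(v)}" [label="{_label(v)}\\nL={lstr}'
                f'\\nR={n.exit_rate:.3g}"];')
        for (s, t), e in sorted(self.edges.items(),
                                key=lambda kv: (_label(kv[0][0]), _label(kv[0][1]))):
            lines.append(
                f'  "{_label(s)}" -> "{_label(t)}" '
                f'[label="p={e.probability:.3g}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.MultiDiGraph() if any(s == t for s, t in self.edges) else nx.DiGraph()
        for v, n in self.nodes.items():
            g.add_node(_label(v), L=("inf" if math.isinf(n.L) else int(n.L)),
                       exit_rate=n.exit_rate,
                       abundances=";".join(
                           f"{k}={val:.10g}" for k, val in sorted(n.abundances.items())))
        for (s, t), e in self.edges.items():
            g.add_edge(_label(s), _label(t), probability=e.probability,
                       rate=e.rate, timescale_exponent=float(e.timescale_exponent))
        nx.write_graphml(g, path)


@dataclass
class JumpTrajectory:
    """A sampled realisation of the limiting jump process on an L-scale
    graph: visited nodes, exponential holding times (on the ``1/(K mu_K^L)``
    scale; ``inf`` in an absorbing final node) and per-node equilibrium
    abundances."""

    states: list[frozenset[str]]
    holding_times: list[float]
    abundances: list[dict[str, float]]

    def to_jsonl(self) -> str:
        lines = []
        for s, h, a in zip(self.states, self.holding_times, self.abundances):
            lines.append(json.dumps({
                "state": sorted(s),
                "holding_time": ("inf" if math.isinf(h) else h),
                "abundances": a,
            }))
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# construction


def build_metastability_graph(model: TraitGraphModel,
                              max_support: int = 3,
                              trust_stability: bool = False) -> MetaGraph:
    """Enumerate all ESC resident sets (supports up to ``max_support``) and
    the transitions between them.

    A node whose ln K dynamics terminate for some needed mutant candidate is
    kept but marked *frontier-invalid* for that candidate; its outgoing
    probabilities then cover only the certifiable transitions.
    """
    nodes: dict[frozenset[str], MetaNode] = {}
    for size in range(1, max_support + 1):
        for combo in itertools.combinations(model.traits, size):
            residents = frozenset(combo)
            try:
                esc = esc_state(model, residents,
                                trust_stability=trust_stability)
            except (NotAnESCError, DegenerateLVError,
                    StabilityUnknownError, ZeroInvasionFitnessError):
                continue
            if math.isinf(esc.L):
                rate = 0.0
            else:
                rate = crossing_rates(model, esc).total
            nodes[residents] = MetaNode(
                residents=residents, L=esc.L, exit_rate=rate,
                abundances=dict(esc.equilibrium.abundances), esc=esc)

    edges: dict[tuple[frozenset[str], frozenset[str]], MetaEdge] = {}
    for residents, node in sorted(nodes.items(), key=lambda kv: _label(kv[0])):
        if node.absorbing:
            continue
        rates = crossing_rates(model, node.esc)
        for w in sorted(node.esc.mutant_candidates, key=model.index):
            outcome = run_invasion(model, node.esc, w,
                                   trust_stability=trust_stability)
            if outcome.kind == "terminated":
                node.frontier_invalid[w] = outcome.termination_reason
                continue
            target = outcome.esc.residents
            if target not in nodes:
                # an ESC with support above the enumeration cap, discovered
                # dynamically: add it so that the edge has a target
                tesc = outcome.esc
                trate = (0.0 if math.isinf(tesc.L)
                         else crossing_rates(model, tesc).total)
                nodes[target] = MetaNode(
                    residents=target, L=tesc.L, exit_rate=trate,
                    abundances=dict(tesc.equilibrium.abundances), esc=tesc)
            key = (residents, target)
            prob = rates.branch_probs[w]
            if key in edges:
                e = edges[key]
                edges[key] = MetaEdge(residents, target,
                                      e.probability + prob,
                                      node.exit_rate * (e.probability + prob),
                                      node.L, e.via + (w,))
            else:
                edges[key] = MetaEdge(residents, target, prob,
                                      node.exit_rate * prob, node.L, (w,))
    return MetaGraph(level="ESC", nodes=nodes, edges=edges,
                     max_support=max_support)


def stability_strata(meta: MetaGraph) -> dict[float, set[frozenset[str]]]:
    """Partition the nodes by exact stability degree."""
    strata: dict[float, set[frozenset[str]]] = {}
    for v, n in meta.nodes.items():
        strata.setdefault(n.L, set()).add(v)
    return strata


def _reachable_subchain(meta: MetaGraph, starts, L: float):
    """States with L(.) < L reachable from ``starts`` without passing
    through a state of degree >= L."""
    seen: set[frozenset[str]] = set()
    stack = [s for s in starts if meta.nodes[s].L < L]
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        for e in meta.successors(x):
            t = e.target
            if meta.nodes[t].L < L and t not in seen:
                stack.append(t)
    return seen


def verify_finite_passage(meta: MetaGraph, L: int,
                          ) -> dict[frozenset[str], tuple[bool, set]]:
    """For each node of stability degree exactly ``L``: does the jump chain
    started there reach a node of degree >= L with probability one?

    In a finite chain this holds iff no reachable sub-chain state (degree
    < L) lies in a set from which the >=L states cannot be reached; the
    verdict comes with that witness set when it fails.  A frontier-invalid
    intermediate state also invalidates the passage (its transitions are
    not certified).
    """
    if not L > 0:
        raise ValueError("L must be positive")
    high = {v for v, n in meta.nodes.items() if n.L >= L}
    low = {v for v, n in meta.nodes.items() if n.L < L}
    # states in `low` from which `high` is reachable
    can_reach = set()
    changed = True
    while changed:
        changed = False
        for v in low:
            if v in can_reach:
                continue
            for e in meta.successors(v):
                if e.target in high or e.target in can_reach:
                    can_reach.add(v)
                    changed = True
                    break
    bad = (low - can_reach) | {v for v in low if meta.nodes[v].frontier_invalid}

    out: dict[frozenset[str], tuple[bool, set]] = {}
    for v, n in meta.nodes.items():
        if n.L != L:
            continue
        if n.frontier_invalid:
            out[v] = (False, {v})
            continue
        starts = [e.target for e in meta.successors(v)]
        reach = _reachable_subchain(meta, starts, L)
        witness = reach & bad
        out[v] = (not witness, witness)
    return out


def build_scale_graph(meta: MetaGraph, L: int) -> MetaGraph:
    """Collapse the metastability graph onto the ``1/(K mu_K^L)`` time
    scale.

    Nodes are the ESCs with degree >= L; an edge (v, w) exists iff
    ``L(v) = L`` and ``w`` is reached through intermediate ESCs that are all
    strictly less stable.  The (possibly infinite) sum over such paths is
    evaluated exactly by solving the linear absorption system on the
    intermediate states; parallel collapsed edges merge by adding
    probabilities and rates.
    """
    passage = verify_finite_passage(meta, L)
    for v, (ok, witness) in passage.items():
        if not ok:
            raise FinitePassageError(L, {_label(x) for x in witness} or {_label(v)})

    nodes = {v: MetaNode(residents=n.residents, L=n.L, exit_rate=n.exit_rate,
                         abundances=dict(n.abundances), esc=n.esc,
                         frontier_invalid=dict(n.frontier_invalid))
             for v, n in meta.nodes.items() if n.L >= L}
    edges: dict[tuple[frozenset[str], frozenset[str]], MetaEdge] = {}
    for v, n in nodes.items():
        if n.L != L:
            continue
        probs = _absorption_probabilities(meta, v, L)
        for target, p in sorted(probs.items(), key=lambda kv: _label(kv[0])):
            if p <= 0.0:
                continue
            edges[(v, target)] = MetaEdge(v, target, p,
                                          meta.nodes[v].exit_rate * p, L)
    return MetaGraph(level=L, nodes=nodes, edges=edges,
                     max_support=meta.max_support)


def _absorption_probabilities(meta: MetaGraph, v: frozenset[str], L: float,
                              ) -> dict[frozenset[str], float]:
    """Probabilities of first reaching each state with degree >= L from
    ``v``, travelling through states of degree < L (linear absorption
    solve; exact for the geometric cycle cases)."""
    first = {e.target: e.probability for e in meta.successors(v)}
    trans = sorted(_reachable_subchain(meta, list(first), L),
                   key=_label)
    idx = {x: i for i, x in enumerate(trans)}
    targets = sorted({t for t in first if meta.nodes[t].L >= L}
                     | {e.target for x in trans for e in meta.successors(x)
                        if meta.nodes[e.target].L >= L}, key=_label)
    tidx = {a: j for j, a in enumerate(targets)}
    k = len(trans)
    Q = np.zeros((k, k))
    Rm = np.zeros((k, len(targets)))
    for x in trans:
        for e in meta.successors(x):
            if e.target in idx:
                Q[idx[x], idx[e.target]] += e.probability
            else:
                Rm[idx[x], tidx[e.target]] += e.probability
    if k:
        H = np.linalg.solve(np.eye(k) - Q, Rm)
    out: dict[frozenset[str], float] = {}
    for t, p in first.items():
        if meta.nodes[t].L >= L:
            out[t] = out.get(t, 0.0) + p
        else:
            for a, j in tidx.items():
                out[a] = out.get(a, 0.0) + p * H[idx[t], j]
    return out


def hitting_probability(meta: MetaGraph,
                        start: frozenset[str],
                        target: frozenset[str]) -> float:
    """Probability that the jump chain started in ``start`` ever visits
    ``target`` (linear absorption solve on the whole graph)."""
    start, target = frozenset(start), frozenset(target)
    others = sorted((v for v in meta.nodes if v != target), key=_label)
    idx = {x: i for i, x in enumerate(others)}
    k = len(others)
    Q = np.zeros((k, k))
    r = np.zeros(k)
    for x in others:
        for e in meta.successors(x):
            if e.target == target:
                r[idx[x]] += e.probability
            else:
                Q[idx[x], idx[e.target]] += e.probability
    try:
        h = np.linalg.solve(np.eye(k) - Q, r)
    except np.linalg.LinAlgError:
        # a closed class avoiding the target makes I - Q singular; the
        # hitting probability is the minimal solution of h = Qh + r,
        # reached by value iteration from zero
        h = np.zeros(k)
        for _ in range(100_000):
            nxt = Q @ h + r
            if np.abs(nxt - h).max() < 1e-15:
                h = nxt
                break
            h = nxt
    if start == target:
        return 1.0
    return float(min(max(h[idx[start]], 0.0), 1.0))


# --------------------------------------------------------------------------
# sampling


def sample_limit_process(scale_graph: MetaGraph,
                         start,
                         horizon: float,
                         seed: int) -> JumpTrajectory:
    """Sample the limiting Markov jump process on an L-scale graph.

    From a node with degree equal to the graph level, the holding time is
    exponential with the total outgoing rate and the successor drawn
    proportionally to the edge rates; more stable nodes are absorbing.
    """
    if scale_graph.level == "ESC":
        raise ValueError("sampling is defined on L-scale graphs")
    L = scale_graph.level
    rng = np.random.default_rng(seed)
    state = frozenset(start)
    if state not in scale_graph.nodes:
        raise KeyError(f"start node {_label(state)} not in the graph")
    states, holds, abunds = [], [], []
    t = 0.0
    while True:
        node = scale_graph.nodes[state]
        out = scale_graph.successors(state)
        total = sum(e.rate for e in out)
        if node.L != L or total <= 0.0:
            states.append(state)
            holds.append(math.inf)
            abunds.append(dict(node.abundances))
            break
        hold = rng.exponential(1.0 / total)
        states.append(state)
        abunds.append(dict(node.abundances))
        if t + hold > horizon:
            holds.append(horizon - t)
            break
        holds.append(hold)
        t += hold
        probs = np.array([e.rate for e in out]) / total
        state = out[rng.choice(len(out), p=probs)].target
    return JumpTrajectory(states=states, holding_times=holds,
                          abundances=abunds)
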