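"""Trait-graph models: definition, validation, IO and graph utilities.

A model is a finite directed graph ``G = (V, E)`` whose vertices are traits.
Each trait ``v`` carries a per-capita birth rate ``b(v)`` and natural death
rate ``d(v)``; each ordered pair a competition coefficient ``c(v, w)`` (the
pressure imposed *on* ``v`` *by* ``w``; the stochastic simulator rescales it
by the carrying capacity ``K``).  Mutation happens at a birth event with
probability ``mu_K = K**(-1/alpha)`` and sends the offspring of a trait-``v``
parent to ``w`` with probability ``m(v, w)``; edges are exactly the pairs
with ``m(v, w) > 0``.

The exponent ``alpha`` controls how deep into the graph recurrent mutation
can maintain microscopic subpopulations: traits at graph distance ``d`` from
the residents equilibrate at size of order ``K * mu_K**d``, which is
non-negligible iff ``d < alpha``.  ``alpha`` must not be an integer so that
no subpopulation sits at the critical order ``K^0``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    IntegerAlphaError,
    MutantLawError,
    NegativeRateError,
    PathOverflowError,
    SchemaError,
    SelfCompetitionError,
    UnknownTraitError,
)

__all__ = [
    "TraitGraphModel",
    "Path",
    "load_model",
    "loads_model",
    "save_model",
    "graph_distance",
    "shortest_paths",
    "alpha_neighborhood",
    "to_dot",
    "to_graphml",
]

_M_ROW_TOL = 1e-9


@dataclass(frozen=True)
class Path:
    """A finite directed path ``(gamma_0, ..., gamma_l)`` on the trait graph.

    A single vertex counts as a path of length zero; the length is the number
    of edges.
    """

    vertices: tuple[str, ...]

    def __post_init__(self):
        if not self.vertices:
            raise ValueError("a path needs at least one vertex")

    @property
    def length(self) -> int:
        return len(self.vertices) - 1

    def __iter__(self):
        return iter(self.vertices)

    def __getitem__(self, i):
        return self.vertices[i]

    def __len__(self):
        return len(self.vertices)


@dataclass
class TraitGraphModel:
    """A fully parameterised trait-graph model.

    Parameters
    ----------
    traits
        Ordered trait identifiers; the declaration order fixes all
        deterministic iteration orders downstream.
    edges
        Directed mutation edges ``(v, w)``.
    b, d
        Per-trait birth and natural death rates (time^-1).
    c
        Competition coefficients ``c[(v, w)]``: pressure on ``v`` by ``w``
        (unscaled; the simulator divides by ``K``).
    m
        Mutant-law weights per edge; for every trait with outgoing edges the
        weights form a probability measure.
    alpha
        Positive non-integer mutation exponent, ``mu_K = K**(-1/alpha)``.
    K
        Carrying capacity (used by the stochastic simulator only).
    """

    traits: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    b: dict[str, float]
    d: dict[str, float]
    c: dict[tuple[str, str], float]
    m: dict[tuple[str, str], float]
    alpha: float
    K: int = 1000
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False, default=None)
    _dist: dict[str, dict[str, float]] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        self.validate()
        g = nx.DiGraph()
        g.add_nodes_from(self.traits)
        g.add_edges_from(self.edges)
        object.__setattr__(self, "_graph", g)
        object.__setattr__(self, "_dist", dict(nx.all_pairs_shortest_path_length(g)))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.traits)) != len(self.traits):
            raise SchemaError("duplicate trait identifiers")
        tset = set(self.traits)
        for v, w in self.edges:
            if v not in tset or w not in tset:
                raise SchemaError(f"edge ({v!r}, {w!r}) uses unknown traits")
            if v == w:
                raise SchemaError(f"self-loop edge on {v!r} not allowed (m(v,v)=0)")
        if not (isinstance(self.alpha, (int, float)) and self.alpha > 0):
            raise SchemaError("alpha must be a positive real")
        if float(self.alpha).is_integer():
            raise IntegerAlphaError(
                f"alpha must be non-integer, got {self.alpha}")
        if not (isinstance(self.K, int) and self.K >= 1):
            raise SchemaError("K must be a positive integer")
        for v in self.traits:
            if v not in self.b or v not in self.d:
                raise SchemaError(f"missing birth/death rate for trait {v!r}")
            if self.b[v] <= 0:
                raise NegativeRateError(f"birth rate b({v!r}) must be > 0")
            if self.d[v] < 0:
                raise NegativeRateError(f"death rate d({v!r}) must be >= 0")
        for v, w in itertools.product(self.traits, repeat=2):
            cvw = self.c.get((v, w))
            if cvw is None:
                raise SchemaError(f"missing competition entry c({v!r},{w!r})")
            if cvw < 0:
                raise NegativeRateError(f"c({v!r},{w!r}) must be >= 0")
        for v in self.traits:
            if self.c[(v, v)] <= 0:
                raise SelfCompetitionError(f"c({v!r},{v!r}) must be > 0")
        for (v, w), weight in self.m.items():
            if (v, w) not in self.edges:
                raise MutantLawError(
                    f"m({v!r},{w!r}) given but ({v!r},{w!r}) is not an edge")
            if not (0 < weight <= 1):
                raise MutantLawError(f"m({v!r},{w!r}) must lie in (0, 1]")
        for v in self.traits:
            out = [w for (u, w) in self.edges if u == v]
            if not out:
                continue
            missing = [w for w in out if (v, w) not in self.m]
            if missing:
                raise MutantLawError(
                    f"edges out of {v!r} lack mutant-law weights: {missing}")
            total = sum(self.m[(v, w)] for w in out)
            if abs(total - 1.0) > _M_ROW_TOL:
                raise MutantLawError(
                    f"m({v!r}, .) sums to {total!r}, not 1")

    # -- convenience --------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def mu(self) -> float:
        """Mutation probability ``mu_K = K**(-1/alpha)``."""
        return float(self.K) ** (-1.0 / self.alpha)

    def r(self, v: str) -> float:
        """Individual fitness ``r(v) = b(v) - d(v)`` (net growth rate)."""
        self._check(v)
        return self.b[v] - self.d[v]

    def out_neighbors(self, v: str) -> list[str]:
        self._check(v)
        return [w for w in self.traits if (v, w) in self.edges]

    def in_neighbors(self, v: str) -> list[str]:
        self._check(v)
        return [w for w in self.traits if (w, v) in self.edges]

    def index(self, v: str) -> int:
        self._check(v)
        return self.traits.index(v)

    def _check(self, *vs: str) -> None:
        for v in vs:
            if v not in self.b:
                raise UnknownTraitError(f"unknown trait {v!r}")

    def replace(self, **kwargs) -> "TraitGraphModel":
        """Return a copy with some fields replaced (re-validated)."""
        data = dict(traits=self.traits, edges=self.edges, b=dict(self.b),
                    d=dict(self.d), c=dict(self.c), m=dict(self.m),
                    alpha=self.alpha, K=self.K)
        data.update(kwargs)
        return TraitGraphModel(**data)


# --------------------------------------------------------------------------
# IO


def _coerce_document(doc: Mapping) -> TraitGraphModel:
    try:
        traits = tuple(str(t) for t in doc["traits"])
        alpha = float(doc["alpha"])
        K = int(doc.get("K", 1000))
        b = {str(k): float(v) for k, v in doc["b"].items()}
        d = {str(k): float(v) for k, v in doc["d"].items()}
        raw_c = doc["c"]
        raw_edges = doc["edges"]
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed model document: {exc}") from exc

    if isinstance(raw_c, (int, float)):
        c = {(v, w): float(raw_c) for v in traits for w in traits}
    else:
        try:
            c = {(str(v), str(w)): float(raw_c[v][w])
                 for v in raw_c for w in raw_c[v]}
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed competition matrix: {exc}") from exc

    edges, m = set(), {}
    for e in raw_edges:
        try:
            v, w, weight = str(e["from"]), str(e["to"]), float(e["m"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed edge entry {e!r}: {exc}") from exc
        edges.add((v, w))
        m[(v, w)] = weight

    return TraitGraphModel(traits=traits, edges=frozenset(edges), b=b, d=d,
                           c=c, m=m, alpha=alpha, K=K)


def load_model(source) -> TraitGraphModel:
    """Load and validate a model from a JSON/YAML file path, file object or
    already-parsed mapping."""
    if isinstance(source, Mapping):
        return _coerce_document(source)
    if hasattr(source, "read"):
        return loads_model(source.read())
    with open(source, "r", encoding="utf8") as fh:
        return loads_model(fh.read())


def loads_model(text: str) -> TraitGraphModel:
    """Parse a model from a JSON or YAML string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SchemaError(f"document is neither JSON nor YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise SchemaError("model document must be a mapping")
    return _coerce_document(doc)


def model_to_document(model: TraitGraphModel) -> dict:
    """Serialise a model to the published JSON-compatible schema."""
    cvals = set(model.c.values())
    if len(cvals) == 1:
        c = next(iter(cvals))
    else:
        c = {v: {w: model.c[(v, w)] for w in model.traits} for v in model.traits}
    return {
        "traits": list(model.traits),
        "alpha": model.alpha,
        "K": model.K,
        "b": {v: model.b[v] for v in model.traits},
        "d": {v: model.d[v] for v in model.traits},
        "c": c,
        "edges": [
            {"from": v, "to": w, "m": model.m[(v, w)]}
            for v in model.traits
            for w in model.traits
            if (v, w) in model.edges
        ],
    }


def save_model(model: TraitGraphModel, path) -> None:
    with open(path, "w", encoding="utf8") as fh:
        json.dump(model_to_document(model), fh, indent=2)
        fh.write("\n")


# --------------------------------------------------------------------------
# graph utilities


def graph_distance(model: TraitGraphModel,
                   src: Iterable[str],
                   dst: Iterable[str]) -> float:
    """Directed graph distance ``d(src, dst)``: the length of the shortest
    path from any trait in ``src`` to any trait in ``dst``.

    Returns ``math.inf`` when no such path exists.  Not symmetric in general.
    """
    src, dst = list(src), list(dst)
    if not src or not dst:
        raise UnknownTraitError("source and destination sets must be nonempty")
    model._check(*src, *dst)
    dstset = set(dst)
    best = math.inf
    for s in src:
        row = model._dist.get(s, {})
        for t in dstset:
            dist = row.get(t)
            if dist is not None and dist < best:
                best = dist
    return best


def shortest_paths(model: TraitGraphModel,
                   src: Iterable[str],
                   dst: str,
                   cap: int = 100_000) -> list[Path]:
    """All shortest directed paths from the set ``src`` to the trait ``dst``.

    The result is deduplicated and sorted lexicographically on the (index-
    mapped) vertex sequence.  Raises :class:`PathOverflowError` instead of
    silently truncating when more than ``cap`` paths exist.
    """
    src = list(src)
    model._check(*src, dst)
    dist = graph_distance(model, src, [dst])
    if math.isinf(dist):
        raise UnknownTraitError(
            f"{dst!r} is not reachable from {sorted(src)!r}")
    target_len = int(dist)
    paths: list[Path] = []
    seen: set[tuple[str, ...]] = set()
    for s in sorted(src, key=model.index):
        if model._dist.get(s, {}).get(dst, math.inf) != target_len:
            continue
        for raw in nx.all_shortest_paths(model.graph, s, dst):
            tup = tuple(raw)
            if tup not in seen:
                seen.add(tup)
                paths.append(Path(tup))
                if len(paths) > cap:
                    raise PathOverflowError(
                        f"more than {cap} shortest paths from "
                        f"{sorted(src)!r} to {dst!r}")
    paths.sort(key=lambda p: tuple(model.index(v) for v in p.vertices))
    return paths


def alpha_neighborhood(model: TraitGraphModel,
                       residents: Iterable[str]) -> tuple[set[str], set[str]]:
    """The mutation-spreading neighbourhood of a resident set.

    Returns ``(V_alpha, boundary)`` where ``V_alpha`` holds every trait at
    directed distance strictly less than ``alpha`` from the residents (these
    are the traits kept alive purely by recurrent mutation) and ``boundary``
    those at distance exactly ``floor(alpha)``.
    """
    residents = list(residents)
    if not residents:
        raise UnknownTraitError("resident set must be nonempty")
    model._check(*residents)
    v_alpha, boundary = set(), set()
    floor_a = math.floor(model.alpha)
    for w in model.traits:
        dist = graph_distance(model, residents, [w])
        if dist < model.alpha:
            v_alpha.add(w)
        if dist == floor_a:
            boundary.add(w)
    return v_alpha, boundary


# --------------------------------------------------------------------------
# exports


def to_dot(model: TraitGraphModel, fitness: Mapping[str, float] | None = None) -> str:
    """Render the trait graph in DOT format, optionally annotating each trait
    with a fitness value (e.g. individual fitness r, or invasion fitness with
    respect to a chosen resident set)."""
    lines = ["digraph traits {"]
    for v in model.traits:
        label = v if fitness is None else f"{v}\\nf={fitness[v]:.3g}"
        lines.append(f'  "{v}" [label="{label}"];')
    for v in model.traits:
        for w in model.out_neighbors(v):
            lines.append(f'  "{v}" -> "{w}" [label="{model.m[(v, w)]:g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(model: TraitGraphModel, path,
               fitness: Mapping[str, float] | None = None) -> None:
    g = nx.DiGraph()
    for v in model.traits:
        attrs = {"b": model.b[v], "d": model.d[v], "r": model.r(v)}
        if fitness is not None:
            attrs["fitness"] = float(fitness[v])
        g.add_node(v, **attrs)
    for v, w in sorted(model.edges):
        g.add_edge(v, w, m=model.m[(v, w)])
    nx.write_graphml(g, path)
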