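"""Programmatic model generators: worked examples and parametric valleys.

The seven example landscapes are specified in the literature-standard way:
a trait graph together with sign/order constraints on individual fitnesses
``r(v) = b(v) - d(v)`` (equal competition) or on pairwise invasion
fitnesses (non-equal competition).  The generators here pick one concrete
parameterisation satisfying every stated constraint — the constraints, not
the specific numbers, determine all qualitative conclusions (ESC sets,
stability degrees, strata, meta-graph edges).  The chosen numbers are
recorded in each fixture's manifest so every downstream computation is
reproducible bit for bit.

Conventions used throughout: ``d(v) = 1`` and ``b(v) = 1 + r(v)`` under
equal competition (``c = 1``), so monomorphic equilibria sit at
``nbar(v) = r(v)``; all individual fitnesses are chosen pairwise distinct
wherever the competition kernel is symmetric, so that no invasion fitness
can vanish (non-degeneracy assumption).
"""

from __future__ import annotations

import numpy as np

from .trait_model import TraitGraphModel

__all__ = [
    "make_linear_valley",
    "valley2_toy",
    "valley_y_toy",
    "make_example",
    "make_random_model",
    "fixture",
    "fixture_manifest",
    "FIXTURE_NAMES",
]


def _equal_competition_model(traits, edges_m, r, alpha, K,
                             c_overrides=None, b=None, d=None):
    """Assemble a model with c = 1 (plus optional overrides), d = 1 and
    b = 1 + r unless explicit rates are given."""
    traits = tuple(traits)
    if d is None:
        d = {v: 1.0 for v in traits}
    if b is None:
        b = {v: d[v] + r[v] for v in traits}
    c = {(v, w): 1.0 for v in traits for w in traits}
    for key, val in (c_overrides or {}).items():
        c[key] = val
    edges = frozenset(edges_m)
    return TraitGraphModel(traits=traits, edges=edges, b=b, d=d, c=c,
                           m=dict(edges_m), alpha=alpha, K=K)


# --------------------------------------------------------------------------
# parametric valleys


def make_linear_valley(width: int, alpha: float,
                       fit_excess: float = 1.0,
                       unfit_deficit: float = 1.0,
                       r0: float = 1.0,
                       b=None, d=None,
                       K: int = 1000) -> TraitGraphModel:
    """A chain ``0 -> 1 -> ... -> width`` under equal competition: baseline
    fitness ``r0`` at the resident end, deleterious intermediates at
    ``r0 - unfit_deficit``, and a beneficial terminal trait at
    ``r0 + fit_excess``.  For ``width > alpha`` the resident ``{0}`` has
    stability degree ``width``."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if fit_excess <= 0 or unfit_deficit <= 0:
        raise ValueError("fit_excess and unfit_deficit must be positive")
    traits = tuple(str(i) for i in range(width + 1))
    r = {t: r0 for t in traits}
    for i in range(1, width):
        r[str(i)] = r0 - unfit_deficit
    r[str(width)] = r0 + fit_excess
    edges_m = {(str(i), str(i + 1)): 1.0 for i in range(width)}
    bb = dict(zip(traits, b)) if b is not None else None
    dd = dict(zip(traits, d)) if d is not None else None
    return _equal_competition_model(traits, edges_m, r, alpha, K,
                                    b=bb, d=dd)


def valley2_toy(K: int = 1000) -> TraitGraphModel:
    """The width-2 valley workhorse: ``b = (2, 0.5, 3)``,
    ``d = (1, 0.5, 1)``, equal competition, ``alpha = 1.5``.

    Hand-computable reference values: ``nbar(0) = 1``,
    ``f(1, {0}) = -1``, ``f(2, {0}) = 1``, ``a_1 = 2``,
    ``rho(1, {0}) = 1/4`` and exit rate ``R({0}) = 1/3``.
    """
    return make_linear_valley(2, alpha=1.5, b=(2.0, 0.5, 3.0),
                              d=(1.0, 0.5, 1.0), K=K)


def valley_y_toy(K: int = 1000) -> TraitGraphModel:
    """A branching valley: ``0 -> 1``, then ``1 -> 2`` and ``1 -> 3`` with
    equal mutant-law weights; the two fit targets differ in fitness and
    birth rate (``f(2,{0}) = 1, b(2) = 3``; ``f(3,{0}) = 3, b(3) = 5``), so
    the branch probabilities are 5/14 and 9/14."""
    traits = ("0", "1", "2", "3")
    edges_m = {("0", "1"): 1.0, ("1", "2"): 0.5, ("1", "3"): 0.5}
    b = {"0": 2.0, "1": 0.5, "2": 3.0, "3": 5.0}
    d = {"0": 1.0, "1": 0.5, "2": 1.0, "3": 1.0}
    c = {(v, w): 1.0 for v in traits for w in traits}
    return TraitGraphModel(traits=traits, edges=frozenset(edges_m), b=b, d=d,
                           c=c, m=dict(edges_m), alpha=1.5, K=K)


# --------------------------------------------------------------------------
# the seven worked examples


def _example1(K: int) -> TraitGraphModel:
    # Two unfit first-layer traits; three fit second-layer targets, one of
    # which (2a) is terminal while 2b and 2c continue to the still fitter
    # trait 4 along paths of different lengths (2b directly, 2c via the
    # unfit-relative-to-nothing intermediate 3 which is itself fitter than
    # 2c, so the ln K walk 2c -> 3 -> 4 proceeds uphill).
    traits = ("0", "1a", "1b", "2a", "2b", "2c", "3", "4")
    r = {"0": 1.0, "1a": 0.45, "1b": 0.5, "2a": 1.5, "2b": 1.6,
         "2c": 1.4, "3": 1.7, "4": 2.0}
    edges_m = {("0", "1a"): 0.5, ("0", "1b"): 0.5, ("1a", "2a"): 1.0,
               ("1b", "2b"): 0.5, ("1b", "2c"): 0.5, ("2b", "4"): 1.0,
               ("2c", "3"): 1.0, ("3", "4"): 1.0}
    return _equal_competition_model(traits, edges_m, r, alpha=1.5, K=K)


def _example2(K: int) -> TraitGraphModel:
    # A polymorphic coexistence ESC {0,3}: traits 0 and 3 have equal net
    # growth and reduced cross-competition (0.5), giving the stable pair
    # equilibrium (2/3, 2/3); traits 4 and 5 are strongly fit but mutually
    # exclusive (cross-competition 3).
    traits = ("0", "1", "2", "3", "4", "5")
    r = {"0": 1.0, "1": 0.4, "2": 0.45, "3": 1.0, "4": 2.0, "5": 2.0}
    edges_m = {("0", "1"): 1.0, ("1", "4"): 1.0, ("3", "2"): 1.0,
               ("2", "5"): 1.0}
    c_over = {("0", "3"): 0.5, ("3", "0"): 0.5,
              ("4", "5"): 3.0, ("5", "4"): 3.0}
    return _equal_competition_model(traits, edges_m, r, alpha=1.5, K=K,
                                    c_overrides=c_over)


def _example3(K: int) -> TraitGraphModel:
    # Cyclic dominance 2 << 4 << 5 << 2 on the loop 2 -> 3 -> 4 -> 5 -> 2,
    # encoded with asymmetric competition among {2, 4, 5}.  The magnitudes
    # enforce that trait 4 dies out under resident {5} (f(4,{5}) = -2)
    # before trait 2 regrows to macroscopic size (f(2,{5}) = 0.3), so the
    # invasion of a 4-mutant into resident {2} returns to the ESC {2}.
    traits = ("0", "1", "2", "3", "4", "5")
    r = {"0": 1.0, "1": 0.45, "2": 2.0, "3": 0.55, "4": 2.0, "5": 2.0}
    edges_m = {("0", "1"): 1.0, ("1", "2"): 1.0, ("2", "3"): 1.0,
               ("3", "4"): 1.0, ("4", "5"): 1.0, ("5", "2"): 1.0}
    c_over = {("2", "4"): 1.5, ("4", "2"): 0.5,   # 2 << 4
              ("4", "5"): 2.0, ("5", "4"): 0.5,   # 4 << 5, f(4,{5}) = -2
              ("2", "5"): 0.85, ("5", "2"): 1.5}  # 5 << 2, f(2,{5}) = 0.3
    return _equal_competition_model(traits, edges_m, r, alpha=1.5, K=K,
                                    c_overrides=c_over)


def _example4(K: int) -> TraitGraphModel:
    # Trait-substitution regime (alpha < 1) with a cycle {2},{3},{7} in the
    # metastability graph that is escaped towards {4} -> {6} with a
    # geometric number of loops; cyclic dominance 2 << 3 << 7 << 2 via
    # asymmetric competition between 7 and 2.
    traits = ("0", "1", "2", "3", "4", "5", "6", "7")
    r = {"0": 1.0, "1": 0.4, "2": 2.0, "3": 2.0, "4": 2.3, "5": 0.6,
         "6": 3.0, "7": 2.0}
    edges_m = {("0", "1"): 1.0, ("1", "2"): 1.0, ("2", "3"): 1.0,
               ("3", "4"): 0.5, ("3", "7"): 0.5, ("7", "2"): 1.0,
               ("4", "5"): 1.0, ("5", "6"): 1.0}
    # May-Leonard triple on {2, 3, 7}: each trait is beaten by the next
    # (2 << 3 << 7 << 2), and cross-competitions 1.6 + 0.5 > 2 make the
    # interior equilibrium of the triple unstable, so no polymorphic
    # coexistence arises.
    c_over = _rps_competition("2", "3", "7")
    return _equal_competition_model(traits, edges_m, r, alpha=0.5, K=K,
                                    c_overrides=c_over)


def _rps_competition(a: str, b: str, c: str,
                     win: float = 0.5, lose: float = 1.6) -> dict:
    """Cyclic dominance a << b << c << a among equal-r traits."""
    return {(b, a): win, (a, b): lose,
            (c, b): win, (b, c): lose,
            (a, c): win, (c, a): lose}


def _example5(K: int) -> TraitGraphModel:
    # Example 4 with an unfit intermediate 8 inserted between 3 and 4 (and
    # the tail 5, 6 removed): the valley 3 -> 8 -> 4 has width 2, so {4}
    # becomes unreachable on the 1-scale and the finite-passage assumption
    # fails at L = 2.
    traits = ("0", "1", "2", "3", "4", "7", "8")
    r = {"0": 1.0, "1": 0.4, "2": 2.0, "3": 2.0, "4": 2.5, "7": 2.0,
         "8": 0.7}
    edges_m = {("0", "1"): 1.0, ("1", "2"): 1.0, ("2", "3"): 1.0,
               ("3", "8"): 0.5, ("3", "7"): 0.5, ("8", "4"): 1.0,
               ("7", "2"): 1.0}
    c_over = _rps_competition("2", "3", "7")
    return _equal_competition_model(traits, edges_m, r, alpha=0.5, K=K,
                                    c_overrides=c_over)


def _example6(K: int) -> TraitGraphModel:
    # Linear chain with successive valleys of widths 3, 2, 3: the jump
    # chain is the deterministic sequence {0}, {3}, {5}, {8}; {6} is a
    # stranded ESC of degree 2.
    traits = tuple(str(i) for i in range(9))
    rvals = (1.0, 0.2, 0.4, 1.5, 0.9, 2.0, 1.2, 0.7, 2.5)
    r = dict(zip(traits, rvals))
    edges_m = {(str(i), str(i + 1)): 1.0 for i in range(8)}
    return _equal_competition_model(traits, edges_m, r, alpha=1.5, K=K)


def _example7(K: int) -> TraitGraphModel:
    # Two length-3 paths out of {0} towards the fit traits 3 and 5; the
    # 3-branch passes the ESC {3} (degree 2) before reaching {5}, so on the
    # 3-scale both branches collapse onto the single edge ({0}, {5}).
    traits = ("0", "1", "2", "3", "4", "5", "6")
    r = {"0": 1.0, "1": 0.3, "2": 0.5, "3": 1.5, "4": 0.7, "5": 2.0,
         "6": 0.4}
    edges_m = {("0", "1"): 1.0, ("1", "2"): 0.5, ("1", "6"): 0.5,
               ("2", "3"): 1.0, ("3", "4"): 1.0, ("4", "5"): 1.0,
               ("6", "5"): 1.0}
    return _equal_competition_model(traits, edges_m, r, alpha=1.5, K=K)


_EXAMPLES = {
    "example1": _example1,
    "example2": _example2,
    "example3": _example3,
    "example4": _example4,
    "example5": _example5,
    "example6": _example6,
    "example7": _example7,
}

FIXTURE_NAMES = tuple(_EXAMPLES) + ("valley2", "valley-y")


def make_example(name: str, K: int = 1000) -> TraitGraphModel:
    """Build one of the seven worked-example landscapes by name."""
    try:
        return _EXAMPLES[name](K)
    except KeyError:
        raise ValueError(
            f"unknown example {name!r}; choose from {sorted(_EXAMPLES)}")


def fixture(name: str, K: int = 1000) -> TraitGraphModel:
    """Build any named fixture (examples or valley toys)."""
    if name in _EXAMPLES:
        return make_example(name, K)
    if name == "valley2":
        return valley2_toy(K)
    if name in ("valley-y", "valley_y"):
        return valley_y_toy(K)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def fixture_manifest(name: str) -> dict:
    """The constraints a fixture encodes and the concrete numbers chosen."""
    model = fixture(name)
    manifest = {
        "name": name,
        "alpha": model.alpha,
        "traits": list(model.traits),
        "r": {v: model.r(v) for v in model.traits},
        "b": dict(model.b),
        "d": dict(model.d),
        "c_overrides": {f"{v}->{w}": model.c[(v, w)]
                        for v in model.traits for w in model.traits
                        if model.c[(v, w)] != 1.0},
        "edges": {f"{v}->{w}": model.m[(v, w)] for v, w in sorted(model.edges)},
    }
    constraints = {
        "example1": ["r(1a), r(1b) < r(0) < r(2c) < r(2a) < r(2b) < r(3) < r(4)",
                     "alpha in (1, 2)"],
        "example2": ["f(0,3), f(3,0) > 0 (reduced cross-competition 0.5)",
                     "f(1,{0,3}), f(2,{0,3}) < 0; f(4,{0,3}), f(5,{0,3}) > 0",
                     "0,1,2,3 << 4,5; 1,2 << 0,3; f(4,5), f(5,4) < 0",
                     "alpha in (1, 2)"],
        "example3": ["0 << 2 << 4 << 5 << 2; 1 << 2; 3 << 4",
                     "f(1,0), f(3,2), f(3,5) < 0",
                     "1/|f(4,5)| < (1 - 1/alpha)/f(2,5): trait 4 goes "
                     "extinct under resident {5} before trait 2 re-fixates",
                     "alpha in (1, 2)"],
        "example4": ["0 << 2 << 3 << 4 << 6; 1 << 2; 5 << 6; 3 << 7 << 2",
                     "f(1,0), f(5,4) < 0", "alpha in (0, 1)"],
        "example5": ["0 << 2 << 3 << 4; 3 << 7 << 2; 1 << 2; 8 << 4",
                     "f(1,0), f(8,3) < 0", "alpha in (0, 1)"],
        "example6": ["r(1) < r(2) < r(0) < r(3); r(4) < r(3) < r(5)",
                     "r(7) < r(6) < r(5) < r(8)", "alpha in (1, 2)"],
        "example7": ["r(1), r(2), r(4), r(6) < r(0) < r(3) < r(5)",
                     "alpha in (1, 2)"],
        "valley2": ["r(1) < r(0) < r(2); width-2 valley; alpha in (1, 2)"],
        "valley-y": ["r(1) < r(0) < r(2) < r(3); branching valley; "
                     "alpha in (1, 2)"],
    }
    manifest["constraints"] = constraints.get(name, [])
    return manifest


# --------------------------------------------------------------------------
# random landscapes (property-test material)


def make_random_model(n_traits: int, alpha: float, seed: int,
                      extra_edges: int = 2, K: int = 1000,
                      ) -> TraitGraphModel:
    """A random connected DAG-on-a-chain landscape with pairwise distinct
    individual fitnesses under equal competition."""
    rng = np.random.default_rng(seed)
    traits = tuple(str(i) for i in range(n_traits))
    # a backbone chain plus a few random forward shortcuts
    edges = {(str(i), str(i + 1)) for i in range(n_traits - 1)}
    for _ in range(extra_edges):
        i = int(rng.integers(0, n_traits - 2))
        j = int(rng.integers(i + 2, n_traits))
        edges.add((str(i), str(j)))
    out_counts: dict[str, list[str]] = {}
    for v, w in edges:
        out_counts.setdefault(v, []).append(w)
    m = {}
    for v, outs in out_counts.items():
        share = 1.0 / len(outs)
        for w in outs:
            m[(v, w)] = share
    # distinct r values, strictly positive births
    r_vals = rng.permutation(np.linspace(0.2, 2.0, n_traits))
    r = {v: float(x) for v, x in zip(traits, r_vals)}
    return _equal_competition_model(traits, m, r, alpha=alpha, K=K)
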