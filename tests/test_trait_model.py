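import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import valleycross as vc
from valleycross.trait_model import model_to_document, to_dot


def chain_doc(alpha=1.5, m01=1.0):
    return {
        "traits": ["0", "1", "2"],
        "alpha": alpha,
        "K": 1000,
        "b": {"0": 2.0, "1": 0.5, "2": 3.0},
        "d": {"0": 1.0, "1": 0.5, "2": 1.0},
        "c": 1.0,
        "edges": [{"from": "0", "to": "1", "m": m01},
                  {"from": "1", "to": "2", "m": 1.0}],
    }


class TestLoadValidate:
    def test_round_trip_identity(self, tmp_path):
        model = vc.load_model(chain_doc())
        assert len(model.traits) == 3 and len(model.edges) == 2
        path = tmp_path / "m.json"
        vc.save_model(model, path)
        again = vc.load_model(path)
        assert again == model

    def test_yaml_accepted(self):
        import yaml

        model = vc.loads_model(yaml.safe_dump(chain_doc()))
        assert model.alpha == 1.5

    @pytest.mark.parametrize("mutate, error", [
        (lambda d: d.update(alpha=2.0), vc.IntegerAlphaError),
        (lambda d: d.update(alpha=-1.0), vc.SchemaError),
        (lambda d: d["b"].update({"1": -0.5}), vc.NegativeRateError),
        (lambda d: d["edges"][0].update(m=0.4), vc.MutantLawError),
        (lambda d: d.pop("traits"), vc.SchemaError),
        (lambda d: d["edges"].append({"from": "2", "to": "x", "m": 1.0}),
         vc.SchemaError),
    ])
    def test_distinct_validation_errors(self, mutate, error):
        doc = chain_doc()
        mutate(doc)
        with pytest.raises(error):
            vc.load_model(doc)

    def test_nonpositive_self_competition_rejected(self):
        doc = chain_doc()
        doc["c"] = {v: {w: (0.0 if v == w == "1" else 1.0)
                        for w in "012"} for v in "012"}
        with pytest.raises(vc.SelfCompetitionError):
            vc.load_model(doc)


class TestGraphOps:
    def test_distances_directed(self):
        m = vc.load_model(chain_doc())
        assert vc.graph_distance(m, {"0"}, {"2"}) == 2
        assert vc.graph_distance(m, {"0"}, {"0"}) == 0
        assert math.isinf(vc.graph_distance(m, {"2"}, {"0"}))

    def test_shortest_paths_chain_and_diamond(self):
        m = vc.load_model(chain_doc())
        assert [p.vertices for p in vc.shortest_paths(m, {"0"}, "2")] \
            == [("0", "1", "2")]
        diamond = vc.load_model({
            "traits": ["0", "a", "b", "2"], "alpha": 1.5, "K": 100,
            "b": {t: 2.0 for t in "0ab2"}, "d": {t: 1.0 for t in "0ab2"},
            "c": 1.0,
            "edges": [{"from": "0", "to": "a", "m": 0.5},
                      {"from": "0", "to": "b", "m": 0.5},
                      {"from": "a", "to": "2", "m": 1.0},
                      {"from": "b", "to": "2", "m": 1.0}]})
        paths = vc.shortest_paths(diamond, {"0"}, "2")
        assert [p.vertices for p in paths] == [("0", "a", "2"), ("0", "b", "2")]
        assert all(p.length == 2 for p in paths)

    def test_path_cap_fails_loudly(self):
        diamond_chain = {"traits": [], "alpha": 1.5, "K": 10, "b": {},
                         "d": {}, "c": 1.0, "edges": []}
        # 6 stacked diamonds -> 2^6 shortest paths
        prev = "s0"
        diamond_chain["traits"].append(prev)
        for k in range(6):
            a, b_, nxt = f"a{k}", f"b{k}", f"s{k + 1}"
            diamond_chain["traits"] += [a, b_, nxt]
            diamond_chain["edges"] += [
                {"from": prev, "to": a, "m": 0.5},
                {"from": prev, "to": b_, "m": 0.5},
                {"from": a, "to": nxt, "m": 1.0},
                {"from": b_, "to": nxt, "m": 1.0}]
            prev = nxt
        for t in diamond_chain["traits"]:
            diamond_chain["b"][t] = 2.0
            diamond_chain["d"][t] = 1.0
        m = vc.load_model(diamond_chain)
        assert len(vc.shortest_paths(m, {"s0"}, "s6")) == 64
        with pytest.raises(vc.PathOverflowError):
            vc.shortest_paths(m, {"s0"}, "s6", cap=10)

    def test_example1_path_to_2c(self, examples):
        m = examples["example1"]
        assert [p.vertices for p in vc.shortest_paths(m, {"0"}, "2c")] \
            == [("0", "1b", "2c")]

    def test_unknown_trait_raises(self):
        m = vc.load_model(chain_doc())
        with pytest.raises(vc.UnknownTraitError):
            vc.graph_distance(m, {"0"}, {"zz"})


class TestAlphaNeighborhood:
    @pytest.mark.parametrize("alpha, expected_va, expected_bd", [
        (1.5, {"0", "1"}, {"1"}),
        (0.5, {"0"}, {"0"}),
        (2.5, {"0", "1", "2"}, {"2"}),
    ])
    def test_valley_chain(self, alpha, expected_va, expected_bd):
        m = vc.load_model(chain_doc(alpha=alpha))
        va, bd = vc.alpha_neighborhood(m, {"0"})
        assert va == expected_va and bd == expected_bd

    def test_example2_joint_neighborhood(self, examples):
        va, _ = vc.alpha_neighborhood(examples["example2"], {"0", "3"})
        assert va == {"0", "1", "2", "3"}

    @given(alpha=st.floats(0.1, 4.9).filter(lambda a: abs(a - round(a)) > 1e-3))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_in_alpha(self, alpha):
        m = vc.make_random_model(6, alpha=alpha, seed=5)
        bigger = m.replace(alpha=alpha + 1.0 if not float(alpha + 1.0).is_integer()
                           else alpha + 1.001)
        va1, bd1 = vc.alpha_neighborhood(m, {"0"})
        va2, _ = vc.alpha_neighborhood(bigger, {"0"})
        assert bd1 <= va1 <= va2
        assert "0" in va1


class TestDistanceProperties:
    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_shortest_paths_match_distance_and_triangle(self, seed):
        m = vc.make_random_model(7, alpha=1.5, seed=seed)
        src, mid, dst = m.traits[0], m.traits[3], m.traits[-1]
        d_direct = vc.graph_distance(m, {src}, {dst})
        via = vc.graph_distance(m, {src}, {mid}) \
            + vc.graph_distance(m, {mid}, {dst})
        assert d_direct <= via
        if math.isfinite(d_direct):
            for p in vc.shortest_paths(m, {src}, dst):
                assert p.length == d_direct
                assert all((p[i], p[i + 1]) in m.edges
                           for i in range(p.length))


class TestExports:
    def test_dot_and_graphml(self, tmp_path, valley2):
        dot = to_dot(valley2, fitness={v: valley2.r(v) for v in valley2.traits})
        assert '"0" -> "1"' in dot
        out = tmp_path / "g.graphml"
        from valleycross.trait_model import to_graphml

        to_graphml(valley2, out)
        assert out.stat().st_size > 0

    def test_document_scalar_competition_preserved(self, valley2):
        doc = model_to_document(valley2)
        assert doc["c"] == 1.0
        assert json.dumps(doc)  # serialisable
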