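import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import valleycross as vc


class TestStabilityDegreeAndCandidates:
    @pytest.mark.parametrize("name, residents, expected_L", [
        ("example1", {"0"}, 2),
        ("example2", {"0", "3"}, 2),
        ("example6", {"0"}, 3),
        ("example7", {"0"}, 3),
        ("example7", {"3"}, 2),
    ])
    def test_worked_example_degrees(self, examples, name, residents, expected_L):
        assert vc.stability_degree(examples[name], residents) == expected_L

    def test_noncoexisting_set_has_degree_zero(self, examples):
        # equal competition, distinct r: a pair has no joint equilibrium
        assert vc.stability_degree(examples["example6"], {"0", "1"}) == 0

    def test_no_fit_trait_is_final(self, examples):
        assert math.isinf(vc.stability_degree(examples["example6"], {"8"}))
        assert vc.mutant_candidates(examples["example6"], {"8"}) == frozenset()

    @pytest.mark.parametrize("name, residents, expected", [
        ("example2", {"0", "3"}, {"4", "5"}),
        ("example4", {"3"}, {"4", "7"}),
        ("example5", {"3"}, {"7"}),
        ("example1", {"0"}, {"2a", "2b", "2c"}),
    ])
    def test_mutant_candidate_sets(self, examples, name, residents, expected):
        assert vc.mutant_candidates(examples[name], residents) == expected


class TestESCState:
    def test_valley2_profile(self, valley2, valley2_esc):
        esc = valley2_esc
        assert esc.L == 2
        assert esc.beta == pytest.approx({"0": 1.0, "1": 1 / 3, "2": 0.0})
        assert esc.v_alpha == {"0", "1"}
        assert not esc.mutant_candidates & esc.v_alpha

    def test_fit_neighbor_disqualifies(self, examples):
        with pytest.raises(vc.NotAnESCError):
            vc.esc_state(examples["example1"], {"2b"})

    def test_degree_below_alpha_disqualifies(self, examples):
        # L({2}) = 1 < alpha = 1.5 in example 4's predecessor trait
        with pytest.raises(vc.NotAnESCError):
            vc.esc_state(examples["example6"], {"2"})

    def test_profile_formula_on_all_esc_nodes(self, examples, meta_graphs):
        for name, meta in meta_graphs.items():
            model = examples[name]
            for residents, node in meta.nodes.items():
                esc = node.esc
                assert esc.L > model.alpha
                for w in model.traits:
                    d = vc.graph_distance(model, residents, [w])
                    expected = max(1 - d / model.alpha, 0.0) \
                        if math.isfinite(d) else 0.0
                    assert esc.beta[w] == pytest.approx(expected)


class TestPrefactors:
    def test_residents_get_their_abundance(self, valley2, valley2_esc):
        prefs = vc.equilibrium_prefactors(valley2, valley2_esc)
        assert prefs["0"] == pytest.approx(1.0)

    def test_valley2_hand_value(self, valley2, valley2_esc):
        # a_1 = nbar_0 * b(0) m(0,1) / |f(1,{0})| = 1 * 2 / 1 = 2
        prefs = vc.equilibrium_prefactors(valley2, valley2_esc)
        assert prefs["1"] == pytest.approx(2.0)

    def test_parallel_paths_sum(self):
        # two length-1 feeds into the same trait: contributions add
        doc = {
            "traits": ["a", "b", "x", "far"], "alpha": 1.5, "K": 1000,
            "b": {"a": 2.5, "b": 3.0, "x": 0.5, "far": 6.0},
            "d": {"a": 1.0, "b": 1.0, "x": 0.5, "far": 1.0},
            "c": {"a": {"a": 1.0, "b": 0.5, "x": 1.0, "far": 1.0},
                  "b": {"a": 0.5, "b": 1.0, "x": 1.0, "far": 1.0},
                  "x": {"a": 1.0, "b": 1.0, "x": 1.0, "far": 1.0},
                  "far": {"a": 1.0, "b": 1.0, "x": 1.0, "far": 1.0}},
            "edges": [{"from": "a", "to": "x", "m": 1.0},
                      {"from": "b", "to": "x", "m": 1.0},
                      {"from": "x", "to": "far", "m": 1.0}],
        }
        m = vc.load_model(doc)
        esc = vc.esc_state(m, {"a", "b"})
        eq = esc.equilibrium
        f_x = vc.invasion_fitness(m, "x", eq)
        expected = (eq.abundances["a"] * 2.5 + eq.abundances["b"] * 3.0) \
            / abs(f_x)
        prefs = vc.equilibrium_prefactors(m, esc)
        assert prefs["x"] == pytest.approx(expected)


class TestExcursionFactor:
    def test_endpoints_and_hand_value(self):
        assert vc.excursion_factor(0.0) == 0.0
        assert vc.excursion_factor(0.25) == pytest.approx(0.5)

    @pytest.mark.parametrize("rho, terms, tol", [
        (0.1, 200, 1e-8),
        (0.25, 200, 1e-8),
        # terms decay like (4 rho (1-rho))^l = 0.96^l at rho = 0.4, so 200
        # terms only reach ~1.5e-4; ~600 reach 1e-8
        (0.4, 200, 3e-4),
        (0.4, 600, 1e-8),
    ])
    def test_series_matches_closed_form(self, rho, terms, tol):
        assert vc.excursion_factor_series(rho, terms=terms) \
            == pytest.approx(vc.excursion_factor(rho), abs=tol)

    @given(rho=st.floats(0.01, 0.99).filter(lambda r: abs(r - 0.5) > 1e-3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry_relation(self, rho):
        lam = vc.excursion_factor
        assert lam(rho) * rho == pytest.approx(lam(1 - rho) * (1 - rho),
                                               rel=1e-12)

    def test_critical_refused(self):
        with pytest.raises(vc.CriticalExcursionError):
            vc.excursion_factor(0.5)

    def test_monte_carlo_birth_count(self):
        # independent oracle: simulate subcritical excursions from a single
        # individual with per-event birth probability rho and count births
        rho, n = 0.25, 100_000
        rng = np.random.default_rng(20240)
        sizes = np.ones(n, dtype=np.int64)
        births = np.zeros(n, dtype=np.int64)
        active = sizes > 0
        while active.any():
            idx = np.nonzero(active)[0]
            up = rng.random(idx.size) < rho
            sizes[idx] += np.where(up, 1, -1)
            births[idx] += up
            active[idx] = sizes[idx] > 0
        mean = births.mean()
        se = births.std(ddof=1) / math.sqrt(n)
        assert abs(mean - vc.excursion_factor(rho)) < 3 * se

    def test_birth_fraction_valley2(self, valley2, valley2_esc):
        rho = vc.birth_fraction(valley2, "1", valley2_esc.equilibrium)
        assert rho == pytest.approx(0.25)

    def test_sign_identity_rho_vs_fitness(self, examples):
        # rho < 1/2 exactly when f < 0 (same denominator algebra)
        for name in ("example1", "example6", "example7"):
            m = examples[name]
            for res in [{"0"}]:
                eq = vc.coexistence_equilibrium(m, tuple(res))
                for w in m.traits:
                    if w in res:
                        continue
                    f = vc.invasion_fitness(m, w, eq)
                    rho = vc.birth_fraction(m, w, eq)
                    assert (rho < 0.5) == (f < 0)


class TestCrossingRates:
    def test_valley2_rate_third(self, valley2, valley2_esc):
        rates = vc.crossing_rates(valley2, valley2_esc)
        assert rates.total == pytest.approx(1 / 3)
        assert rates.timescale_exponent == 2
        assert rates.branch_probs == {"2": 1.0}

    def test_valley_y_hand_values(self, valley_y, valley_y_esc):
        rates = vc.crossing_rates(valley_y, valley_y_esc)
        assert rates.per_trait["2"] == pytest.approx(1 / 6)
        assert rates.per_trait["3"] == pytest.approx(3 / 10)
        assert rates.total == pytest.approx(7 / 15)
        assert rates.branch_probs["3"] == pytest.approx(9 / 14)

    def test_no_lambda_factor_when_valley_width_floor_plus_one(
            self, valley2, valley2_esc):
        # alpha = 1.5, L = 2: the excursion product is empty, so the rate
        # factorises as nbar * (b m / |f|) * b m * f/b exactly
        gamma = vc.shortest_paths(valley2, {"0"}, "2")[0]
        rate = vc.path_crossing_rate(valley2, valley2_esc, gamma)
        assert rate == pytest.approx(1.0 * (2.0 / 1.0) * 0.5 * (1.0 / 3.0))

    def test_excursion_factor_enters_for_wider_valley(self):
        m = vc.make_linear_valley(3, alpha=1.5)
        esc = vc.esc_state(m, {"0"})
        gamma = vc.shortest_paths(m, {"0"}, "3")[0]
        arrival = vc.path_arrival_rate(m, esc, gamma)
        eq = esc.equilibrium
        rho2 = vc.birth_fraction(m, "2", eq)
        expected = (eq.abundances["0"] * m.b["0"] / abs(
            vc.invasion_fitness(m, "1", eq)) * m.b["1"]
            * vc.excursion_factor(rho2))
        assert arrival == pytest.approx(expected)

    def test_fixation_factor_increases_with_terminal_birth_rate(
            self, valley2, valley2_esc):
        # raising b of the fit terminal (same death rate) raises both its
        # fitness and the final factor f/b, hence the crossing rate
        base = vc.crossing_rates(valley2, valley2_esc).total
        boosted = valley2.replace(b={**valley2.b, "2": 4.0})
        esc2 = vc.esc_state(boosted, {"0"})
        assert vc.crossing_rates(boosted, esc2).total > base

    def test_rate_additivity_example1(self, examples):
        m = examples["example1"]
        esc = vc.esc_state(m, {"0"})
        rates = vc.crossing_rates(m, esc)
        assert set(rates.per_trait) == {"2a", "2b", "2c"}
        assert rates.total == pytest.approx(sum(rates.per_trait.values()))
        assert sum(rates.branch_probs.values()) == pytest.approx(1.0)

    def test_fit_interior_trait_rejected(self, examples):
        m = examples["example1"]
        esc = vc.esc_state(m, {"0"})
        bad = vc.Path(("0", "1b", "2c", "3", "4"))
        with pytest.raises(ValueError):
            vc.path_crossing_rate(m, esc, bad)


class TestTransitionProbabilities:
    def test_example1_candidates_pool_into_target(self, examples):
        m = examples["example1"]
        esc = vc.esc_state(m, {"0"})
        rates = vc.crossing_rates(m, esc)
        p = vc.esc_transition_probabilities(m, esc)
        assert set(p) == {frozenset({"2a"}), frozenset({"4"})}
        assert p[frozenset({"4"})] == pytest.approx(
            rates.branch_probs["2b"] + rates.branch_probs["2c"])
        assert sum(p.values()) == pytest.approx(1.0)

    def test_single_candidate_degenerate(self, valley2, valley2_esc):
        p = vc.esc_transition_probabilities(valley2, valley2_esc)
        assert p == {frozenset({"2"}): pytest.approx(1.0)}

    def test_valley_y_terminal_targets(self, valley_y, valley_y_esc):
        p = vc.esc_transition_probabilities(valley_y, valley_y_esc)
        assert p[frozenset({"2"})] == pytest.approx(5 / 14)
        assert p[frozenset({"3"})] == pytest.approx(9 / 14)
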