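"""Worked examples, brute-force oracle equivalence and structural
properties of the network metrics."""

import numpy as np
import pytest

from groupnet.metrics import (
    centralization,
    cohesion_compactness,
    components,
    degree_table,
    density,
    dyad_census,
    isolates,
    metrics_panel,
    panel_row,
    reciprocity,
    round3,
    transitivity_percent,
)

from conftest import complete_arcs, net_from_arcs, random_digraph
import oracles


class TestWorkedExamples:
    def test_sparse_eleven_node_census(self):
        # 3 mutual + 3 asymmetric dyads on 11 nodes: 9 arcs, 49 null dyads
        arcs = {(0, 1), (1, 0), (2, 3), (3, 2), (4, 5), (5, 4),
                (0, 2), (1, 4), (6, 0)}
        net = net_from_arcs(11, arcs)
        c = dyad_census(net)
        assert (c.mutual, c.asymmetric, c.null) == (3, 3, 49)
        assert round3(density(net)) == 0.082
        assert round3(reciprocity(net)[1]) == 0.5

    def test_denser_week12_shaped_census(self):
        # 7 mutual + 6 asymmetric dyads on 11 nodes: 20 arcs
        arcs = {(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1), (3, 4),
                (4, 3), (5, 6), (6, 5), (7, 8), (8, 7), (9, 10), (10, 9),
                (0, 3), (1, 5), (2, 7), (4, 9), (6, 10), (8, 0)}
        net = net_from_arcs(11, arcs)
        c = dyad_census(net)
        assert (c.mutual, c.asymmetric) == (7, 6)
        assert net.arc_count == 20
        assert round3(density(net)) == 0.182
        assert round3(reciprocity(net)[1]) == 0.538

    def test_empty_and_complete_censuses(self):
        empty = net_from_arcs(11, set())
        c = dyad_census(empty)
        assert (c.mutual, c.asymmetric, c.null) == (0, 0, 55)
        assert density(empty) == 0.0
        full3 = net_from_arcs(3, complete_arcs(3))
        assert dyad_census(full3).mutual == 3
        assert dyad_census(full3).null == 0
        assert density(full3) == 1.0

    def test_isolates_in_roster_order(self):
        arcs = {(0, 2), (2, 0), (6, 7), (8, 9), (10, 0)}
        net = net_from_arcs(11, arcs)
        assert isolates(net) == ["2", "4", "5", "6"]
        assert isolates(net_from_arcs(3, complete_arcs(3))) == []
        assert isolates(net_from_arcs(4, set())) == ["1", "2", "3", "4"]

    def test_degree_table_examples(self):
        net = net_from_arcs(3, {(0, 1)})
        assert degree_table(net) == [("1", 0, 1, 1), ("2", 1, 0, 1), ("3", 0, 0, 0)]
        full = net_from_arcs(4, complete_arcs(4))
        assert all(row[1:] == (3, 3, 6) for row in degree_table(full))
        mixed = net_from_arcs(3, {(0, 1), (1, 0), (0, 2)})
        assert mixed and degree_table(mixed)[0] == ("1", 1, 2, 3)

    def test_degree_totals_sum_to_twice_arcs(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            arcs = random_digraph(n, rng)
            net = net_from_arcs(n, arcs)
            assert sum(r[3] for r in degree_table(net)) == 2 * net.arc_count

    def test_reciprocity_examples(self):
        all_mutual = net_from_arcs(4, {(0, 1), (1, 0), (2, 3), (3, 2)})
        assert reciprocity(all_mutual) == (1.0, 1.0)
        empty = net_from_arcs(4, set())
        assert reciprocity(empty) == (None, None)
        one_way = net_from_arcs(6, {(0, 1), (1, 2), (3, 4), (4, 3), (2, 5)})
        arc_based, dyad_based = reciprocity(one_way)
        assert arc_based == pytest.approx(2 / 5)
        assert dyad_based == pytest.approx(1 / 4)

    def test_components_examples(self):
        two_pairs = net_from_arcs(5, {(0, 1), (1, 0), (2, 3), (3, 2)})
        excess, membership = components(two_pairs)
        assert excess == 1
        assert membership == [("1", "2"), ("3", "4")]
        chain = net_from_arcs(5, {(0, 1), (1, 2), (2, 3), (3, 4)})
        assert components(chain)[0] == 0
        assert components(net_from_arcs(4, set())) == (0, [])

    def test_centralization_star_and_cycle(self):
        star = net_from_arcs(4, {(0, 1), (1, 0), (0, 2), (2, 0), (0, 3), (3, 0)})
        assert centralization(star, "degree") == pytest.approx(1.0)
        cycle = net_from_arcs(5, {(i, (i + 1) % 5) for i in range(5)})
        for kind in ("degree", "indegree", "outdegree", "closeness", "betweenness"):
            assert centralization(cycle, kind) == pytest.approx(0.0)
        out_star = net_from_arcs(4, {(0, 1), (0, 2), (0, 3)})
        assert centralization(out_star, "indegree") == pytest.approx(1 / 9)

    def test_unknown_centralization_kind(self):
        with pytest.raises(ValueError, match="unknown"):
            centralization(net_from_arcs(4, set()), "eigenvector")

    def test_transitivity_examples(self):
        closed = net_from_arcs(3, {(0, 1), (1, 2), (0, 2)})
        assert transitivity_percent(closed) == 1.0
        open_path = net_from_arcs(3, {(0, 1), (1, 2)})
        assert transitivity_percent(open_path) == 0.0
        assert transitivity_percent(net_from_arcs(3, set())) is None
        # a pure 2-cycle has no eligible triple (closure through i=k excluded)
        assert transitivity_percent(net_from_arcs(3, {(0, 1), (1, 0)})) is None

    def test_compactness_examples(self):
        assert cohesion_compactness(net_from_arcs(4, complete_arcs(4))) == 1.0
        assert cohesion_compactness(net_from_arcs(4, set())) == 0.0
        path = net_from_arcs(3, {(0, 1), (1, 2)})
        assert cohesion_compactness(path) == pytest.approx(2.5 / 6)

    def test_panel_aggregates_and_rounding(self):
        empty = metrics_panel(net_from_arcs(11, set()))
        assert empty.density == 0.0
        assert empty.isolate_count == 11
        assert empty.reciprocity_nonnull is None
        full = metrics_panel(net_from_arcs(5, complete_arcs(5)))
        assert full.density == 1.0
        assert full.transitivity_pct == 1.0
        assert full.cohesion_compactness == 1.0
        assert full.centralization_degree == 0.0
        row = panel_row(full)
        assert row["size"] == 5 and row["density"] == 1.0

    def test_round3_is_half_up(self):
        assert round3(0.0825) == 0.083
        assert round3(0.5345) == 0.535
        assert round3(9 / 110) == 0.082
        assert round3(None) is None


class TestOracleEquivalence:
    """Every metric must agree with direct dyad/triple/geodesic enumeration
    on a large sample of random digraphs (n <= 7)."""

    N_GRAPHS = 1000

    def test_all_metrics_match_brute_force(self):
        rng = np.random.default_rng(42)
        for g in range(self.N_GRAPHS):
            n = int(rng.integers(2, 8))
            arcs = random_digraph(n, rng)
            net = net_from_arcs(n, arcs)
            c = dyad_census(net)
            assert (c.mutual, c.asymmetric, c.null) == oracles.bf_dyad_census(n, arcs)
            assert density(net) == pytest.approx(oracles.bf_density(n, arcs))
            ids = net.roster.ids
            assert [ids.index(m) for m in isolates(net)] == oracles.bf_isolates(n, arcs)
            assert [r[1:] for r in degree_table(net)] == oracles.bf_degrees(n, arcs)
            rec, bf_rec = reciprocity(net), oracles.bf_reciprocity(n, arcs)
            for got, want in zip(rec, bf_rec):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want)
            excess, membership = components(net)
            bf_excess, bf_membership = oracles.bf_components(n, arcs)
            assert excess == bf_excess
            assert [
                tuple(sorted(ids.index(m) for m in comp)) for comp in membership
            ] == bf_membership
            got_t = transitivity_percent(net)
            want_t = oracles.bf_transitivity(n, arcs)
            if want_t is None:
                assert got_t is None
            else:
                assert got_t == pytest.approx(want_t)
            assert cohesion_compactness(net) == pytest.approx(
                oracles.bf_compactness(n, arcs)
            )
            if n >= 3:
                for kind in ("degree", "indegree", "outdegree", "closeness",
                             "betweenness"):
                    assert centralization(net, kind) == pytest.approx(
                        oracles.bf_centralization(n, arcs, kind), abs=1e-10
                    ), (g, n, kind, sorted(arcs))


class TestProperties:
    def test_adding_an_arc_increases_density_and_compactness(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 8))
            arcs = random_digraph(n, rng, p=0.3)
            missing = sorted(complete_arcs(n) - arcs)
            if not missing:
                continue
            new_arc = missing[int(rng.integers(len(missing)))]
            before = net_from_arcs(n, arcs)
            after = net_from_arcs(n, arcs | {new_arc})
            assert density(after) > density(before)
            assert cohesion_compactness(after) >= cohesion_compactness(before)

    def test_metrics_invariant_under_node_relabeling(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            arcs = random_digraph(n, rng)
            perm = rng.permutation(n)
            relabeled = {(int(perm[e]), int(perm[a])) for e, a in arcs}
            p1 = metrics_panel(net_from_arcs(n, arcs))
            p2 = metrics_panel(net_from_arcs(n, relabeled))
            assert p1.density == pytest.approx(p2.density)
            assert p1.reciprocity_nonnull == p2.reciprocity_nonnull
            assert p1.excess_components == p2.excess_components
            assert p1.centralization_degree == pytest.approx(p2.centralization_degree)
            assert p1.centralization_betweenness == pytest.approx(
                p2.centralization_betweenness
            )
            assert p1.cohesion_compactness == pytest.approx(p2.cohesion_compactness)
            assert p1.transitivity_pct == (
                pytest.approx(p2.transitivity_pct)
                if p2.transitivity_pct is not None
                else None
            )

    def test_symmetric_network_has_unit_reciprocity(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            half = random_digraph(n, rng, p=0.4)
            sym = half | {(a, e) for e, a in half}
            if not sym:
                continue
            assert reciprocity(net_from_arcs(n, sym)) == (1.0, 1.0)

    def test_centralizations_stay_in_unit_interval(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 9))
            net = net_from_arcs(n, random_digraph(n, rng))
            for kind in ("degree", "indegree", "outdegree", "closeness",
                         "betweenness"):
                assert 0.0 <= centralization(net, kind) <= 1.0

    def test_single_member_roster_rejected_upstream(self):
        # density's n >= 2 precondition is enforced by the roster invariant
        from groupnet.survey_io import Roster, SurveyValidationError

        with pytest.raises(SurveyValidationError):
            Roster(group_id="x", members=(("1", "a"),))
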