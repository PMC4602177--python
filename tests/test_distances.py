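import itertools

import pytest

from conftest import make_state, simple_maps
from pdlrs.distances import (
    ConfigurationPair,
    edge_distance,
    gstar_clades,
    posterior_summaries,
    roofs_and_shades,
    temporal_distance,
    topological_distance,
)

PSEUDO5 = ("p1", "p2", "p3", "p4", "p5")


def five_pseudo_maps():
    names = list(PSEUDO5) + ["g1"]
    species = {n: "S" for n in names}
    classes = {n: ("pseudogene" if n.startswith("p") else "gene") for n in names}
    return species, classes


@pytest.fixture
def worked_pair():
    """Early-vs-late configurations whose shade multisets are {1,1} and
    {1,2,2}."""
    species, classes = five_pseudo_maps()
    early = make_state(
        "((((p1:1,p2:1):0.5)PSG:0.5,(((p3:1,p4:1):1,p5:1):0.5)PSG:0.5):1,g1:2):1;",
        species,
        classes,
    )
    late = make_state(
        "((((p1:0.5)PSG:0.5,(p2:0.5)PSG:0.5):1,(((p3:0.5)PSG:0.5,(p4:0.5)PSG:0.5):1,"
        "(p5:0.5)PSG:0.5):1):1,g1:2):1;",
        species,
        classes,
    )
    return early, late


class TestEdgeDistance:
    def test_same_edge_zero_adjacent_one(self):
        species, classes = simple_maps(["a1", "a2", "b1"])
        st = make_state("((a1:1,a2:1):1,b1:2):1;", species, classes)
        edges = gstar_clades(st)
        e_a1 = frozenset({"a1"})
        e_a2 = frozenset({"a2"})
        e_cherry = frozenset({"a1", "a2"})
        assert edge_distance(e_a1, e_a1, edges) == 0
        assert edge_distance(e_a1, e_cherry, edges) == 1  # share a vertex
        assert edge_distance(e_a1, e_a2, edges) == 1  # siblings

    def test_caterpillar_against_bfs_oracle(self):
        import networkx as nx

        names = [f"x{i}" for i in range(6)]
        species = {n: "S" for n in names}
        classes = {n: "gene" for n in names}
        nwk = "(((((x0:1,x1:1):1,x2:2):1,x3:3):1,x4:4):1,x5:5):1;"
        st = make_state(nwk, species, classes)
        edges = gstar_clades(st)
        # build the G* graph explicitly, nodes = clades + leaf/root markers
        G = nx.Graph()
        from pdlrs.gene_tree import suppress

        sup = suppress(st)
        node_id = {}
        for n in sup.root.postorder():
            node_id[n] = len(node_id)
            G.add_node(node_id[n])
        for n in sup.root.postorder():
            if n.parent is not None:
                G.add_edge(node_id[n], node_id[n.parent])
        clade_of = {n: sup.clade(n) if n.children else frozenset([n.name]) for n in node_id}
        by_clade = {clade_of[n]: n for n in node_id if n.parent is not None}
        for ca, cb in itertools.combinations(edges, 2):
            na, nb = by_clade[ca], by_clade[cb]
            # minimal path containing both edges: between the far endpoints
            candidates = []
            for ea in (na, na.parent):
                for eb in (nb, nb.parent):
                    path = nx.shortest_path(G, node_id[ea], node_id[eb])
                    # the path must contain both edges fully
                    pset = set(path)
                    if {node_id[na], node_id[na.parent]} <= pset and {
                        node_id[nb],
                        node_id[nb.parent],
                    } <= pset:
                        candidates.append(len(path) - 2)
            assert edge_distance(ca, cb, edges) == min(candidates)


class TestRoofsAndShades:
    def test_identical_configurations_self_shade(self, worked_pair):
        early, _ = worked_pair
        pair = ConfigurationPair.from_states(early, early)
        rels = roofs_and_shades(pair)
        assert len(rels) == 2
        for roof, shade, _side in rels:
            assert shade == [roof]

    def test_early_roof_covers_late_shade(self, worked_pair):
        early, late = worked_pair
        pair = ConfigurationPair.from_states(early, late)
        rels = roofs_and_shades(pair)
        shades = sorted(len(s) for _, s, _ in rels)
        assert shades == [2, 3]
        for roof, shade, side in rels:
            assert side == "a"  # all roofs from the early configuration
            for e in shade:
                assert e < roof

    def test_partition_property(self, worked_pair):
        early, late = worked_pair
        pair = ConfigurationPair.from_states(early, late)
        rels = roofs_and_shades(pair)
        seen_a, seen_b = [], []
        for roof, shade, side in rels:
            if side == "a":
                seen_a.append(roof)
                seen_b.extend(shade)
            else:
                seen_b.append(roof)
                seen_a.extend(shade)
        assert sorted(map(sorted, seen_a)) == sorted(map(sorted, pair.config_a))
        assert sorted(map(sorted, seen_b)) == sorted(map(sorted, pair.config_b))


class TestTopologicalDistance:
    def test_identical_is_zero(self, worked_pair):
        early, _ = worked_pair
        pair = ConfigurationPair.from_states(early, early)
        assert topological_distance(pair) == (0.0, 0.0)

    def test_worked_example_arithmetic(self, worked_pair):
        early, late = worked_pair
        pair = ConfigurationPair.from_states(early, late)
        da, dm = topological_distance(pair)
        assert da == pytest.approx(((1 + 1) / 2 + (1 + 2 + 2) / 3) / 2)
        assert dm == max(max(1, 1), max(1, 2, 2))

    def test_symmetry_and_da_le_dm(self, worked_pair):
        early, late = worked_pair
        p1 = ConfigurationPair.from_states(early, late)
        p2 = ConfigurationPair.from_states(late, early)
        assert topological_distance(p1) == topological_distance(p2)
        da, dm = topological_distance(p1)
        assert da <= dm


class TestTemporalDistance:
    def test_absolute_difference_and_scaling(self, worked_pair):
        early, late = worked_pair
        ta = {c: 0.5 for c in [frozenset({"p1", "p2"}), frozenset({"p3", "p4", "p5"})]}
        tb = {
            frozenset({n}): 0.3 for n in PSEUDO5
        }
        pair = ConfigurationPair.from_states(early, late, ta, tb)
        Ta, Tm = temporal_distance(pair)
        assert Ta == pytest.approx(0.2)
        assert Tm == pytest.approx(0.2)
        pair3 = ConfigurationPair.from_states(
            early, late, {k: 3 * v for k, v in ta.items()}, {k: 3 * v for k, v in tb.items()}
        )
        Ta3, Tm3 = temporal_distance(pair3)
        assert (Ta3, Tm3) == pytest.approx((3 * Ta, 3 * Tm))

    def test_missing_time_rejected(self, worked_pair):
        early, late = worked_pair
        pair = ConfigurationPair.from_states(early, late)
        with pytest.raises(ValueError, match="time"):
            temporal_distance(pair)


class TestPosteriorSummaries:
    def test_concentrated_on_truth_is_zero(self, worked_pair):
        early, _ = worked_pair
        times = {c: 0.4 for c in [frozenset({"p1", "p2"}), frozenset({"p3", "p4", "p5"})]}
        summ = posterior_summaries(
            early, [(early, times, 1.0)], truth_times=times
        )
        assert (summ.E_Da, summ.M_Da, summ.E_Dm, summ.M_Dm) == (0, 0, 0, 0)
        assert summ.E_Ta == 0 and summ.M_Tm == 0

    def test_weighted_mean_and_max(self, worked_pair):
        early, late = worked_pair
        summ = posterior_summaries(
            early, [(early, None, 0.5), (late, None, 0.5)], temporal=False
        )
        da_late, dm_late = topological_distance(
            ConfigurationPair.from_states(early, late)
        )
        assert summ.E_Da == pytest.approx(da_late / 2)
        assert summ.M_Da == pytest.approx(da_late)
        assert summ.E_Dm == pytest.approx(dm_late / 2)
        assert summ.M_Dm == pytest.approx(dm_late)
        assert summ.E_Da <= summ.M_Da and summ.E_Dm <= summ.M_Dm

    def test_differing_topologies_excluded(self, worked_pair):
        early, _ = worked_pair
        species, classes = five_pseudo_maps()
        other = make_state(
            "((((p1:1,p3:1):0.5)PSG:0.5,(((p2:1,p4:1):1,p5:1):0.5)PSG:0.5):1,g1:2):1;",
            species,
            classes,
        )
        summ = posterior_summaries(
            early, [(early, None, 0.5), (other, None, 0.5)], temporal=False
        )
        assert summ.n_used == 1
        assert summ.n_excluded == 1
        with pytest.raises(ValueError):
            posterior_summaries(early, [(other, None, 1.0)], temporal=False)
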