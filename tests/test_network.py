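import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from thermobgc import network as net

from conftest import edges_frame


class TestBuildNetwork:
    def test_cutoff_is_inclusive(self):
        nw = net.build_network(edges_frame([("A", "B", 0.50)]), cutoff=0.5)
        assert nw.n_edges == 1

    def test_edge_just_above_cutoff_discarded(self):
        nw = net.build_network(edges_frame([("A", "B", 0.51)]), nodes=["A", "B"], cutoff=0.5)
        assert nw.n_edges == 0
        assert len(net.connected_components(nw)) == 2

    def test_isolated_nodes_become_singletons(self):
        nw = net.build_network(edges_frame([]), nodes=["A", "B", "C"])
        fams = net.connected_components(nw)
        assert [f.family_id for f in fams] == ["A", "B", "C"]

    def test_unknown_node_in_edge_errors(self):
        with pytest.raises(ValueError, match="unknown node"):
            net.build_network(edges_frame([("A", "Z", 0.2)]), nodes=["A", "B"])


class TestConnectedComponents:
    def test_chain_plus_singleton(self):
        nw = net.build_network(edges_frame([("A", "B", 0.1), ("B", "C", 0.2)]), nodes="ABCD")
        fams = {f.family_id: set(f.members) for f in net.connected_components(nw)}
        assert fams == {"A": {"A", "B", "C"}, "D": {"D"}}

    def test_complete_graph_single_family(self):
        rows = [(a, b, 0.1) for a, b in itertools.combinations("ABCD", 2)]
        fams = net.connected_components(net.build_network(edges_frame(rows)))
        assert len(fams) == 1 and len(fams[0]) == 4

    def test_random_graph_matches_transitive_closure_oracle(self, rng):
        """Components agree with brute-force transitive closure on n=50."""
        nodes = [f"n{i:02d}" for i in range(50)]
        rows = [
            (a, b, float(rng.uniform(0, 0.5)))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.03
        ]
        nw = net.build_network(edges_frame(rows), nodes=nodes)
        fams = net.connected_components(nw)
        # oracle: iterate reachability to a fixed point
        parent = {n: {n} for n in nodes}
        for a, b, _ in rows:
            merged = parent[a] | parent[b]
            for m in merged:
                parent[m] = merged
        changed = True
        while changed:
            changed = False
            for n in nodes:
                for m in list(parent[n]):
                    if parent[m] is not parent[n] and parent[m] != parent[n]:
                        u = parent[m] | parent[n]
                        for x in u:
                            parent[x] = u
                        changed = True
        oracle = {frozenset(v) for v in parent.values()}
        assert {f.members for f in fams} == oracle

    def test_partition_invariant_to_input_order(self, rng):
        rows = [("A", "B", 0.1), ("B", "C", 0.3), ("D", "E", 0.2)]
        base = net.connected_components(net.build_network(edges_frame(rows), nodes="ABCDE"))
        for _ in range(5):
            shuffled = [rows[i] for i in rng.permutation(len(rows))]
            alt = net.connected_components(
                net.build_network(edges_frame(shuffled), nodes="EDCBA")
            )
            assert [(f.family_id, f.members) for f in alt] == [
                (f.family_id, f.members) for f in base
            ]


class TestNoveltyClassification:
    def test_family_with_reference_is_known(self):
        nw = net.build_network(edges_frame([("A", "B", 0.1), ("B", "BGC0000001", 0.2)]))
        fams = net.classify_novelty(net.connected_components(nw), {"BGC0000001"})
        assert fams[0].is_known

    def test_reference_free_family_is_novel(self):
        nw = net.build_network(edges_frame([]), nodes=["D"])
        fams = net.classify_novelty(net.connected_components(nw), {"BGC0000001"})
        assert fams[0].is_known is False

    def test_all_reference_all_known(self):
        refs = ["BGC0000001", "BGC0000002"]
        nw = net.build_network(edges_frame([]), nodes=refs)
        fams = net.classify_novelty(net.connected_components(nw), set(refs))
        assert net.novel_fraction(fams) == 0.0

    def test_adding_reference_never_flips_known_to_novel(self):
        nw = net.build_network(edges_frame([("A", "B", 0.1)]))
        fams = net.classify_novelty(net.connected_components(nw), {"A"})
        fams_more = net.classify_novelty(fams, {"A", "B"})
        assert fams[0].is_known and fams_more[0].is_known


class TestMinReferenceDistance:
    def test_minimum_over_direct_reference_edges(self):
        nw = net.build_network(
            edges_frame([("A", "BGC0000001", 0.30), ("A", "BGC0000002", 0.45)])
        )
        scores = net.min_reference_distance(nw, {"BGC0000001", "BGC0000002"})
        assert scores.set_index("bgc_id").loc["A", "distance_to_reference"] == pytest.approx(0.30)

    def test_sentinel_when_no_reference_edge(self):
        nw = net.build_network(edges_frame([("A", "B", 0.2)]), nodes=["A", "B", "BGC0000001"])
        scores = net.min_reference_distance(nw, {"BGC0000001"}).set_index("bgc_id")
        assert scores.loc["A", "distance_to_reference"] == pytest.approx(0.51)

    def test_indirect_path_to_reference_scores_sentinel(self):
        # A - B - ref: A is in a known family but has no direct reference edge
        nw = net.build_network(edges_frame([("A", "B", 0.2), ("B", "BGC0000001", 0.3)]))
        scores = net.min_reference_distance(nw, {"BGC0000001"}).set_index("bgc_id")
        assert scores.loc["A", "distance_to_reference"] == pytest.approx(0.51)
        assert scores.loc["B", "distance_to_reference"] == pytest.approx(0.3)

    def test_references_excluded_and_sentinel_validated(self):
        nw = net.build_network(edges_frame([("A", "BGC0000001", 0.2)]))
        scores = net.min_reference_distance(nw, {"BGC0000001"})
        assert "BGC0000001" not in set(scores["bgc_id"])
        with pytest.raises(ValueError, match="sentinel"):
            net.min_reference_distance(nw, {"BGC0000001"}, sentinel=0.4)

    def test_every_score_at_most_sentinel(self, default_study):
        _, inventory, = default_study[1], default_study[2]
        cls = "terpene"
        edges = default_study[3][cls]
        nodes = set(inventory.loc[inventory["bgc_class"] == cls, "bgc_id"])
        nodes |= set(edges["bgc_a"]) | set(edges["bgc_b"])
        nw = net.build_network(edges, nodes=nodes)
        refs = {n for n in nodes if n.startswith("BGC")}
        scores = net.min_reference_distance(nw, refs)
        assert (scores["distance_to_reference"] <= 0.51 + 1e-12).all()


class TestSampleMinNovelty:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["bgc_id", "distance_to_reference"])

    def _inv(self, rows):
        df = pd.DataFrame(rows, columns=["bgc_id", "sample_id", "bgc_class"])
        df["is_reference"] = False
        return df

    def test_minimum_within_sample(self):
        scores = self._scores([("x1", 0.51), ("x2", 0.22), ("x3", 0.40)])
        inv = self._inv([("x1", "S1", "NRPS"), ("x2", "S1", "NRPS"), ("x3", "S1", "NRPS")])
        out = net.sample_min_novelty(scores, inv, "NRPS")
        assert out["S1"] == pytest.approx(0.22)

    def test_all_sentinel_sample_scores_sentinel(self):
        scores = self._scores([("x1", 0.51), ("x2", 0.51)])
        inv = self._inv([("x1", "S1", "PKS"), ("x2", "S1", "PKS")])
        assert net.sample_min_novelty(scores, inv, "PKS")["S1"] == pytest.approx(0.51)

    def test_sample_without_class_is_absent(self):
        scores = self._scores([("x1", 0.3)])
        inv = self._inv([("x1", "S1", "NRPS"), ("x2", "S2", "PKS")])
        out = net.sample_min_novelty(scores, inv, "terpene")
        assert len(out) == 0


class TestModularityCommunities:
    def test_two_disjoint_cliques(self):
        rows = [(a, b, 0.1) for a, b in itertools.combinations(["A1", "A2", "A3"], 2)]
        rows += [(a, b, 0.1) for a, b in itertools.combinations(["B1", "B2", "B3"], 2)]
        comms, q = net.modularity_communities(net.build_network(edges_frame(rows)))
        assert len(comms) == 2 and q > 0

    def test_edgeless_graph_singletons_q_zero(self):
        comms, q = net.modularity_communities(net.build_network(edges_frame([]), nodes="ABC"))
        assert len(comms) == 3 and q == 0.0

    def test_bridged_cliques_match_exhaustive_modularity_search(self):
        """Greedy modularity equals the exhaustive optimum on two bridged triangles."""
        rows = [(a, b, 0.1) for a, b in itertools.combinations(["A1", "A2", "A3"], 2)]
        rows += [(a, b, 0.1) for a, b in itertools.combinations(["B1", "B2", "B3"], 2)]
        rows.append(("A1", "B1", 0.1))
        nw = net.build_network(edges_frame(rows))
        comms, q = net.modularity_communities(nw)

        def partitions(collection):
            if len(collection) == 1:
                yield [collection]
                return
            first, rest = collection[0], collection[1:]
            for smaller in partitions(rest):
                for i, subset in enumerate(smaller):
                    yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
                yield [[first]] + smaller

        g = nw.graph
        best = max(
            (nx.community.modularity(g, [set(p) for p in part]), part)
            for part in partitions(sorted(g.nodes))
        )
        assert q == pytest.approx(best[0], abs=1e-9)
        assert {frozenset(c) for c in comms} == {frozenset(p) for p in best[1]}


def test_family_table_and_membership(default_families):
    tab = net.family_table(default_families)
    assert set(tab.columns) == {"family_id", "n_members", "bgc_class", "is_known"}
    members = net.family_membership(default_families)
    assert sum(len(f) for f in default_families) == len(members)
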