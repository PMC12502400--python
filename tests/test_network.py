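import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from guideomics.network import (
    betweenness,
    build_network,
    project_compound,
    project_ko,
    subnetwork_report,
    attach_activity,
    write_graphml,
)
from guideomics.synthetic import make_universe
from guideomics.tables import OmicsTable, ReactionUniverse, ValidationError, sum_normalize


# --------------------------------------------------------------------------
# independent oracle: explicit BFS shortest-path enumeration


def brute_force_betweenness(g):
    nodes = sorted(g.nodes)
    adj = {n: sorted(g.neighbors(n)) for n in nodes}
    bc = {n: 0.0 for n in nodes}

    def all_shortest_paths(s, t):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            return []
        paths = []

        def back(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1:
                    back(path + [v])

        back([s])
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in paths) / len(paths)
    return bc


def make_funmg(features, nonzero_fraction, n_samples=100):
    """feature x sample table where each feature is nonzero in the given
    fraction of samples."""
    vals = np.zeros((len(features), n_samples))
    for i, f in enumerate(features):
        k = int(round(nonzero_fraction[f] * n_samples))
        vals[i, :k] = 1.0 + i
    return OmicsTable("funMG", pd.DataFrame(
        vals, index=features, columns=[f"s{j}" for j in range(n_samples)]
    ))


class TestBuildNetwork:
    def test_prevalence_boundary_inclusive(self, tiny_universe):
        funmg = make_funmg(["KO1", "KO2", "KO3"],
                           {"KO1": 0.50, "KO2": 0.49, "KO3": 0.80})
        net = build_network(tiny_universe, funmg, prevalence=0.5)
        assert "KO1" in net.ko_nodes and "KO3" in net.ko_nodes
        assert "KO2" not in net.ko_nodes

    def test_prevalence_out_of_range(self, tiny_universe):
        funmg = make_funmg(["KO1"], {"KO1": 1.0})
        with pytest.raises(ValidationError):
            build_network(tiny_universe, funmg, prevalence=0.0)
        with pytest.raises(ValidationError):
            build_network(tiny_universe, funmg, prevalence=1.5)

    def test_unknown_feature_warned_and_dropped(self, tiny_universe):
        funmg = make_funmg(["KO1", "KO_ghost"], {"KO1": 1.0, "KO_ghost": 1.0})
        with pytest.warns(UserWarning, match="absent from reaction universe"):
            net = build_network(tiny_universe, funmg, prevalence=0.5)
        assert "KO_ghost" not in net.graph

    def test_cofactor_removal_commutes_with_construction(self):
        u, _ = make_universe(n_ko=40, n_compound=45, n_cofactor=6, seed=31)
        features = sorted(u.ko_reactions)
        funmg = make_funmg(features, {f: 1.0 for f in features})
        direct = build_network(u, funmg, prevalence=0.5, cofactors=u.cofactors)
        bare = build_network(u, funmg, prevalence=0.5, cofactors=frozenset())
        # post hoc: remove cofactor nodes and then isolated compounds
        g = bare.graph.copy()
        g.remove_nodes_from([c for c in u.cofactors if c in g])
        g.remove_nodes_from([n for n, d in g.nodes(data=True)
                             if d["kind"] == "compound" and g.degree(n) == 0])
        assert set(g.nodes) == set(direct.graph.nodes)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in direct.graph.edges}

    def test_raising_prevalence_only_removes_kos(self, rng):
        u, _ = make_universe(n_ko=30, n_compound=45, n_cofactor=5, seed=37)
        features = sorted(u.ko_reactions)
        frac = {f: float(rng.uniform(0.2, 1.0)) for f in features}
        funmg = make_funmg(features, frac)
        lo = build_network(u, funmg, prevalence=0.3)
        hi = build_network(u, funmg, prevalence=0.7)
        assert set(hi.ko_nodes) <= set(lo.ko_nodes)


class TestProjections:
    def test_shared_compound_rule(self, tiny_universe):
        funmg = make_funmg(["KO1", "KO2", "KO3"], {k: 1.0 for k in ("KO1", "KO2", "KO3")})
        net = build_network(tiny_universe, funmg, prevalence=0.5)
        g = project_ko(net)
        assert set(g.edges) == {("KO1", "KO2")}
        assert g["KO1"]["KO2"]["shared"] == "B"

    def test_compound_projection_single_ko(self, tiny_universe):
        funmg = make_funmg(["KO1"], {"KO1": 1.0})
        net = build_network(tiny_universe, funmg, prevalence=0.5)
        g = project_compound(net)
        assert set(g.edges) == {("A", "B")}
        assert g["A"]["B"]["shared"] == "KO1"

    def test_ko_projection_matches_pairwise_intersection(self):
        u, _ = make_universe(n_ko=25, n_compound=40, n_cofactor=5, seed=41)
        features = sorted(u.ko_reactions)
        funmg = make_funmg(features, {f: 1.0 for f in features})
        net = build_network(u, funmg, prevalence=0.5)
        g = project_ko(net)
        compounds = {
            ko: {c for c in net.graph.neighbors(ko)} for ko in net.ko_nodes
        }
        for a, b in itertools.combinations(net.ko_nodes, 2):
            assert g.has_edge(a, b) == bool(compounds[a] & compounds[b])
            if g.has_edge(a, b):
                assert set(g[a][b]["shared"].split("|")) == compounds[a] & compounds[b]

    def test_inversion_duality(self):
        """Compound projection of a universe equals the KO projection of the
        role-swapped universe (compounds become the gene-like side)."""
        u, _ = make_universe(n_ko=20, n_compound=40, n_cofactor=5, seed=43)
        features = sorted(u.ko_reactions)
        funmg = make_funmg(features, {f: 1.0 for f in features})
        net = build_network(u, funmg, prevalence=0.5)
        cpd = project_compound(net)

        # swapped universe: one pseudo-reaction per original KO, whose
        # "compounds" are the original KO's non-cofactor compounds; nodes
        # are the original compounds
        swapped_kos = {}
        for cid in cpd.nodes:
            rxns = set()
            for ko in net.ko_nodes:
                if net.graph.has_edge(ko, cid):
                    rxns.add(f"R_{ko}")
            swapped_kos[cid] = rxns
        dual = nx.Graph()
        dual.add_nodes_from(cpd.nodes)
        for r in sorted({r for rs in swapped_kos.values() for r in rs}):
            members = sorted(c for c, rs in swapped_kos.items() if r in rs)
            for a, b in itertools.combinations(members, 2):
                dual.add_edge(a, b)
        assert set(cpd.nodes) == set(dual.nodes)
        assert {frozenset(e) for e in cpd.edges} == {frozenset(e) for e in dual.edges}

    def test_cofactors_never_nodes(self):
        u, _ = make_universe(n_ko=20, n_compound=40, n_cofactor=5, seed=47)
        features = sorted(u.ko_reactions)
        funmg = make_funmg(features, {f: 1.0 for f in features})
        net = build_network(u, funmg, prevalence=0.5)
        assert not (set(project_compound(net).nodes) & set(u.cofactors))

    def test_shrinking_cofactor_set_only_adds_edges(self):
        u, _ = make_universe(n_ko=25, n_compound=40, n_cofactor=6, seed=53)
        features = sorted(u.ko_reactions)
        funmg = make_funmg(features, {f: 1.0 for f in features})
        full = build_network(u, funmg, prevalence=0.5, cofactors=u.cofactors)
        fewer = build_network(u, funmg, prevalence=0.5,
                              cofactors=frozenset(sorted(u.cofactors)[:-2]))
        e_full = {frozenset(e) for e in project_ko(full).edges}
        e_fewer = {frozenset(e) for e in project_ko(fewer).edges}
        assert e_full <= e_fewer


class TestBetweenness:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        rep = betweenness(g)
        assert rep.table.loc["B", "bc_raw"] == 1.0
        assert rep.table.loc["B", "bc_norm"] == 1.0
        assert rep.table.loc["A", "bc_raw"] == 0.0

    def test_star_graph(self):
        g = nx.star_graph(5)  # center 0, 5 leaves
        rep = betweenness(g)
        assert rep.table.loc[0, "bc_norm"] == pytest.approx(1.0)
        assert (rep.table.drop(index=0)["bc_norm"] == 0).all()

    def test_under_three_nodes_zero(self):
        g = nx.Graph([("a", "b")])
        rep = betweenness(g)
        assert (rep.table["bc_raw"] == 0).all()

    def test_random_graphs_match_brute_force(self, rng):
        for i in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)),
                                    seed=int(rng.integers(0, 2**31)))
            rep = betweenness(g)
            oracle = brute_force_betweenness(g)
            for node in g.nodes:
                assert rep.table.loc[node, "bc_raw"] == pytest.approx(
                    oracle[node], abs=1e-9
                )

    def test_conservation_of_traversals(self, rng):
        g = nx.gnp_random_graph(10, 0.4, seed=7)
        rep = betweenness(g)
        oracle = brute_force_betweenness(g)
        assert rep.table["bc_raw"].sum() == pytest.approx(sum(oracle.values()), abs=1e-9)


class TestSubnetworkReport:
    def test_full_subset_equals_community_mean(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        rep = betweenness(g)
        s = subnetwork_report(g, rep, list(g.nodes), "all")
        assert s.mean_bc_norm == pytest.approx(s.community_mean_bc_norm)

    def test_empty_subset_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        rep = betweenness(g)
        with pytest.raises(ValidationError):
            subnetwork_report(g, rep, [], "none")

    def test_missing_nodes_flagged(self):
        g = nx.path_graph(["a", "b", "c"])
        rep = betweenness(g)
        with pytest.warns(UserWarning, match="absent"):
            s = subnetwork_report(g, rep, ["b", "zzz"], "sub")
        assert s.n_missing == 1 and s.n_nodes == 1


class TestActivityAndOutput:
    def test_activity_ratio_direct_arithmetic(self, tiny_universe, small_meta):
        vals = np.ones((3, 12))
        vals[1] = 2.0
        funmg = OmicsTable("funMG", pd.DataFrame(
            vals, index=["KO1", "KO2", "KO3"], columns=small_meta.samples))
        mt_vals = vals.copy()
        mt_vals[0] = 3.0
        funmt = OmicsTable("funMT", pd.DataFrame(
            mt_vals, index=["KO1", "KO2", "KO3"], columns=small_meta.samples))
        prev = make_funmg(["KO1", "KO2", "KO3"], {k: 1.0 for k in ("KO1", "KO2", "KO3")})
        net = build_network(tiny_universe, prev, prevalence=0.5)
        nmg, nmt = sum_normalize(funmg), sum_normalize(funmt)
        attach_activity(net, nmt, nmg)
        eps = net.provenance["activity_eps"]
        for ko in net.ko_nodes:
            expected = (nmt.data.loc[ko].mean() + eps) / (nmg.data.loc[ko].mean() + eps)
            assert net.graph.nodes[ko]["activity"] == pytest.approx(expected, rel=1e-12)

    def test_graphml_bytes_deterministic(self, tmp_path, tiny_universe):
        funmg = make_funmg(["KO1", "KO2", "KO3"], {k: 1.0 for k in ("KO1", "KO2", "KO3")})
        net = build_network(tiny_universe, funmg, prevalence=0.5)
        g = project_ko(net)
        write_graphml(g, tmp_path / "a.graphml")
        write_graphml(g, tmp_path / "b.graphml")
        assert (tmp_path / "a.graphml").read_bytes() == (tmp_path / "b.graphml").read_bytes()
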