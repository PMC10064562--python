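"""Co-occurrence network construction and graph features vs brute force."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pahpheno.cases import CaseDatabase, CaseRecord, canonical_genotype
from pahpheno.graph import (GRAPH_DIMS_PER_MUTATION, HubSet,
                            MutationNetwork, NodeNotInNetworkError,
                            build_network, connectivity_report,
                            encode_genotype_graph, find_hub_nodes,
                            hub_distances, node_attributes)
from pahpheno.hgvs import parse_hgvs_cdna
from pahpheno.phenotype import Phenotype, classify_phenotype
from pahpheno.simulate import SimulationConfig, generate_cohort
from ._oracles import (betweenness_by_enumeration, bfs_distances,
                       closeness_per_component, eccentricity_per_component,
                       pagerank_power_iteration)


def _case(pid, a, b, phe):
    return CaseRecord(patient_id=pid,
                      genotype=canonical_genotype(parse_hgvs_cdna(a),
                                                  parse_hgvs_cdna(b)),
                      phe_pretreatment=phe,
                      phenotype=classify_phenotype(phe))


def _db(rows):
    return CaseDatabase(records=[_case(*r) for r in rows])


X, Y, Z = "c.100A>G", "c.200C>T", "c.300G>A"


def test_build_counts_patients_per_genotype():
    db = _db([("P1", X, Y, 1500), ("P2", X, Y, 1500), ("P3", Y, Z, 300)])
    net = build_network(db)
    x, y, z = (parse_hgvs_cdna(s) for s in (X, Y, Z))
    assert set(net.graph.nodes) == {x, y, z}
    assert net.graph[x][y]["weight"] == 2
    assert net.graph[y][z]["weight"] == 1
    assert net.graph[x][y]["counts"][Phenotype.CPKU] == 2


def test_homozygote_self_loop_leaves_centralities_untouched():
    db = _db([("P1", X, Y, 1500), ("P2", X, X, 1500)])
    net = build_network(db)
    x = parse_hgvs_cdna(X)
    assert net.graph.degree(x) == 1          # self-loop not a neighbour
    assert net.self_loops[x]["weight"] == 1
    assert net.total_edge_weight() == 2


def test_total_edge_weight_equals_patient_count(small_cohort):
    db, _ = small_cohort
    assert build_network(db).total_edge_weight() == len(db)


def test_network_build_permutation_invariant(worked_db):
    rng = np.random.default_rng(3)
    shuffled = CaseDatabase(records=[worked_db.records[i]
                                     for i in rng.permutation(len(worked_db))])
    a, b = build_network(worked_db), build_network(shuffled)
    assert set(a.graph.edges) == set(b.graph.edges)
    for u, v in a.graph.edges:
        assert a.graph[u][v]["weight"] == b.graph[u][v]["weight"]
    assert find_hub_nodes(a) == find_hub_nodes(b)


# -- centralities vs brute force --------------------------------------------

def _net_from_nx(g: nx.Graph) -> MutationNetwork:
    g = g.copy()
    for u, v in g.edges:
        g[u][v].setdefault("weight", 1)
    return MutationNetwork(graph=g)


def _adj(g: nx.Graph) -> dict:
    return {v: sorted(g.neighbors(v)) for v in g.nodes}


def _assert_metrics_match(g: nx.Graph):
    net = _net_from_nx(g)
    adj = _adj(g)
    bet = betweenness_by_enumeration(adj)
    clo = closeness_per_component(adj)
    ecc = eccentricity_per_component(adj)
    weights = {(u, v): g[u][v].get("weight", 1) for u, v in g.edges}
    pr = pagerank_power_iteration(adj, weights)
    for v in g.nodes:
        got = node_attributes(net, v)
        assert got[0] == len(adj[v])
        assert got[1] == pytest.approx(bet[v], abs=1e-9)
        assert got[2] == pytest.approx(pr[v], abs=1e-9)
        assert got[3] == pytest.approx(clo[v], abs=1e-9)
        assert got[4] == ecc[v]


def test_centralities_match_oracles_on_all_four_node_graphs():
    nodes = list(range(4))
    pairs = list(itertools.combinations(nodes, 2))
    for bits in range(2 ** len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for k, (u, v) in enumerate(pairs):
            if bits >> k & 1:
                g.add_edge(u, v)
        _assert_metrics_match(g)


def test_centralities_match_oracles_on_random_graphs():
    rng = np.random.default_rng(17)
    for trial in range(30):
        n = int(rng.integers(5, 13))
        p = float(rng.uniform(0.15, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2 ** 31)))
        for u, v in g.edges:
            g[u][v]["weight"] = int(rng.integers(1, 6))
        _assert_metrics_match(g)


def test_path_middle_node_betweenness_is_one():
    net = _net_from_nx(nx.path_graph(3))
    assert node_attributes(net, 1)[1] == pytest.approx(1.0)


def test_triangle_symmetry():
    net = _net_from_nx(nx.cycle_graph(3))
    for v in range(3):
        attrs = node_attributes(net, v)
        assert attrs[0] == 2 and attrs[4] == 1.0


def test_pagerank_sums_to_one(worked_net):
    total = sum(node_attributes(worked_net, m)[2] for m in worked_net.nodes)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_incident_edge_betweenness_mode():
    from pahpheno.graph import incident_edge_betweenness
    net = _net_from_nx(nx.path_graph(4))
    scores = incident_edge_betweenness(net)
    # interior nodes of a path mediate more shortest paths than endpoints
    assert scores[1] == scores[2] > scores[0] == scores[3]
    # every edge's betweenness is counted once per endpoint
    total = sum(nx.edge_betweenness_centrality(net.graph).values())
    assert sum(scores.values()) == pytest.approx(2 * total)


def test_unknown_node_lookup_fails(worked_net):
    with pytest.raises(NodeNotInNetworkError):
        node_attributes(worked_net, parse_hgvs_cdna("c.999A>T"))


# -- hub identification and distances ----------------------------------------

def test_worked_fixture_recovers_reference_hub_trio(worked_hubs):
    assert worked_hubs.hub_cpku.label == "c.728G>A"
    assert worked_hubs.hub_mpku.label == "c.721C>T"
    assert worked_hubs.hub_mhp.label == "c.158G>A"


def test_single_class_toy_hub_is_max_weighted_degree():
    db = _db([("P1", X, Y, 1500), ("P2", X, Y, 1500), ("P3", X, Z, 1500)])
    with pytest.raises(ValueError, match="zero|cannot place"):
        find_hub_nodes(build_network(db))  # only cPKU populated


def test_hub_override_checked_for_membership(worked_net):
    ghost = parse_hgvs_cdna("c.999A>T")
    with pytest.raises(NodeNotInNetworkError):
        find_hub_nodes(worked_net, override=HubSet(ghost, ghost, ghost))


def test_hub_distance_examples():
    db = _db([("P1", X, Y, 1500), ("P2", Y, Z, 700), ("P3", X, Z, 300)])
    net = build_network(db)
    x = parse_hgvs_cdna(X)
    hubs = HubSet(hub_cpku=x, hub_mpku=x, hub_mhp=x)
    assert hub_distances(net, x, hubs)[0] == 0.0


def test_hub_distance_on_path():
    db = _db([("P1", X, Y, 1500), ("P2", Y, Z, 700), ("P3", X, Y, 300)])
    net = build_network(db)
    x, z = parse_hgvs_cdna(X), parse_hgvs_cdna(Z)
    hubs = HubSet(hub_cpku=x, hub_mpku=x, hub_mhp=x)
    assert hub_distances(net, z, hubs)[0] == 2.0


def test_distances_match_bfs_oracle_and_triangle_inequality(small_cohort):
    db, _ = small_cohort
    net = build_network(db)
    hubs = find_hub_nodes(net)
    adj = {v: list(net.graph.neighbors(v)) for v in net.graph.nodes}
    hub_list = [hubs.hub_cpku, hubs.hub_mpku, hubs.hub_mhp]
    oracle = {h: bfs_distances(adj, h) for h in hub_list}
    sentinel = net.disconnection_sentinel()
    for m in net.nodes:
        got = hub_distances(net, m, hubs)
        for k, h in enumerate(hub_list):
            expected = oracle[h].get(m, sentinel)
            assert got[k] == expected
    # triangle inequality between reachable hub pairs through any node
    d01 = oracle[hub_list[0]].get(hub_list[1])
    if d01 is not None:
        for m in net.nodes:
            a = oracle[hub_list[0]].get(m)
            b = oracle[hub_list[1]].get(m)
            if a is not None and b is not None:
                assert d01 <= a + b


def test_disconnected_hub_gets_finite_sentinel():
    db = _db([("P1", X, Y, 1500), ("P2", Z, "c.400T>A", 300), ("P3", X, Y, 700)])
    net = build_network(db)
    x, z = parse_hgvs_cdna(X), parse_hgvs_cdna(Z)
    hubs = HubSet(hub_cpku=x, hub_mpku=x, hub_mhp=z)
    d = hub_distances(net, x, hubs)
    assert d[2] == net.disconnection_sentinel()
    assert np.all(np.isfinite(d))


# -- genotype encoding and component report ----------------------------------

def test_genotype_graph_vector_sixteen_and_swap_invariant(worked_net, worked_hubs):
    a, b = parse_hgvs_cdna("c.728G>A"), parse_hgvs_cdna("c.158G>A")
    v1 = encode_genotype_graph(canonical_genotype(a, b), worked_net, worked_hubs)
    v2 = encode_genotype_graph(canonical_genotype(b, a), worked_net, worked_hubs)
    assert v1.shape == (2 * GRAPH_DIMS_PER_MUTATION,)
    np.testing.assert_array_equal(v1, v2)


def test_homozygote_graph_vector_halves(worked_net, worked_hubs):
    m = parse_hgvs_cdna("c.728G>A")
    v = encode_genotype_graph(canonical_genotype(m, m), worked_net, worked_hubs)
    np.testing.assert_array_equal(v[:8], v[8:])


def test_unseen_mutation_strict_vs_lenient(worked_net, worked_hubs):
    g = canonical_genotype(parse_hgvs_cdna("c.999A>T"), parse_hgvs_cdna("c.728G>A"))
    with pytest.raises(NodeNotInNetworkError):
        encode_genotype_graph(g, worked_net, worked_hubs, strict=True)
    v = encode_genotype_graph(g, worked_net, worked_hubs, strict=False)
    assert np.all(np.isfinite(v))
    # canonical order puts the unseen c.999A>T second: its hub distances
    # carry the disconnection sentinel and its centralities are zero
    assert np.all(v[8:11] == worked_net.disconnection_sentinel())
    assert np.all(v[11:] == 0.0)


def test_connectivity_report_partitions_nodes(worked_net):
    rep = connectivity_report(worked_net)
    assert sum(rep.sizes) == len(worked_net.nodes)
    assert rep.sizes == [17]  # the worked fixture is one component


def test_connectivity_report_two_components():
    db = _db([("P1", X, Y, 1500), ("P2", Z, "c.400T>A", 300)])
    rep = connectivity_report(build_network(db))
    assert rep.sizes == [2, 2]
    assert rep.isolated == []
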