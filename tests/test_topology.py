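"""Topology metrics against hand-computed examples and brute-force oracles."""
import itertools

import networkx as nx
import numpy as np
import pytest

from follisim.network import FDC, ReticularNetwork, StromalNode
from follisim.topology import (
    DegenerateComparisonError,
    erdos_renyi_null,
    ring_lattice_clustering,
    small_world_indices,
    subtype_comparison,
    topology_report,
    watts_strogatz_reference,
)
from conftest import make_network


# -- brute-force oracles -----------------------------------------------------

def transitivity_oracle(g: nx.Graph) -> float:
    """3 x triangles / connected triples by triple enumeration."""
    nodes = list(g.nodes())
    triangles = triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        e = g.has_edge(a, b) + g.has_edge(b, c) + g.has_edge(a, c)
        if e == 3:
            triangles += 1
        # connected triples centred at each node
    for v in nodes:
        d = g.degree(v)
        triples += d * (d - 1) // 2
    return 3 * triangles / triples if triples else 0.0


def floyd_warshall_mean_path(g: nx.Graph) -> float:
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    nodes = list(sub.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for u, v in sub.edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    mask = ~np.eye(n, dtype=bool)
    return float(dist[mask].mean())


# -- examples ---------------------------------------------------------------

def test_triangle_is_fully_clustered(triangle_net):
    rep = topology_report(triangle_net)
    assert rep.C_local == 1.0
    assert rep.C_global == 1.0
    assert rep.L == 1.0
    assert rep.n_edges == 3


def test_star_has_no_triangles(star_net):
    rep = topology_report(star_net)
    assert rep.C_local == 0.0
    assert rep.C_global == 0.0


def test_path_mean_shortest_path(path_net):
    rep = topology_report(path_net)
    assert rep.L == pytest.approx(4 / 3)


def test_edge_lengths_are_euclidean(path_net):
    rep = topology_report(path_net)
    assert sorted(rep.edge_length_per_edge) == pytest.approx([10.0, 10.0])


def test_empty_and_single_node_graphs_rejected():
    with pytest.raises(ValueError):
        topology_report(ReticularNetwork(nodes=[], edges=set()))
    one = ReticularNetwork(
        nodes=[StromalNode(id=0, position=np.zeros(3))], edges=set()
    )
    with pytest.raises(ValueError):
        topology_report(one)


@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_bruteforce_oracles_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 30))
    m = int(rng.integers(n, min(3 * n, n * (n - 1) // 2)))
    net = erdos_renyi_null(n, m, seed=seed)
    g = net.to_networkx()
    rep = topology_report(net)
    assert rep.C_global == pytest.approx(transitivity_oracle(g))
    assert rep.L == pytest.approx(floyd_warshall_mean_path(g))
    # C_local oracle: mean of 2*tri/(d(d-1)) with 0 for degree < 2
    vals = []
    for v in g.nodes():
        nbrs = list(g.neighbors(v))
        d = len(nbrs)
        if d < 2:
            vals.append(0.0)
            continue
        tri = sum(
            g.has_edge(a, b) for a, b in itertools.combinations(nbrs, 2)
        )
        vals.append(2 * tri / (d * (d - 1)))
    assert rep.C_local == pytest.approx(float(np.mean(vals)))


# -- ER null -----------------------------------------------------------------

def test_er_null_exact_edge_count_and_simple():
    for seed in range(50):
        net = erdos_renyi_null(20, 30, seed=seed)
        assert net.n_edges == 30
        assert all(i != j for i, j in net.edges)


def test_er_null_forced_triangle():
    net = erdos_renyi_null(3, 3, seed=0)
    assert net.edges == {(0, 1), (0, 2), (1, 2)}


def test_er_null_rejects_out_of_range_m():
    with pytest.raises(ValueError):
        erdos_renyi_null(4, 7, seed=0)


def test_er_null_reproducible():
    assert erdos_renyi_null(30, 60, seed=5).edges == \
        erdos_renyi_null(30, 60, seed=5).edges


# -- Watts–Strogatz reference ------------------------------------------------

def test_ring_lattice_clustering_closed_form():
    # k=4: each node's 4 neighbours share 3 edges out of 6 possible pairs
    assert ring_lattice_clustering(4) == pytest.approx(0.5)
    net = watts_strogatz_reference(20, 4, p=0.0, seed=0)
    rep = topology_report(net)
    assert rep.C_local == pytest.approx(0.5)


def test_cycle_graph_mean_path():
    # C10 distances from any node: 1,1,2,2,3,3,4,4,5 -> mean 25/9
    net = watts_strogatz_reference(10, 2, p=0.0, seed=0)
    rep = topology_report(net)
    assert rep.L == pytest.approx(25 / 9)


def test_full_rewiring_approaches_er_clustering():
    cs = [
        topology_report(watts_strogatz_reference(60, 6, p=1.0, seed=s)).C_local
        for s in range(100)
    ]
    # ER level is ~ k/n = 0.1; the lattice value would be 0.6
    assert np.mean(cs) < 0.2


def test_ws_parameter_validation():
    with pytest.raises(ValueError):
        watts_strogatz_reference(10, 3, 0.1, seed=0)  # odd k
    with pytest.raises(ValueError):
        watts_strogatz_reference(10, 10, 0.1, seed=0)  # k >= n
    with pytest.raises(ValueError):
        watts_strogatz_reference(10, 4, 1.5, seed=0)


# -- small-world indices -----------------------------------------------------

def test_er_input_gives_sigma_near_one():
    net = erdos_renyi_null(100, 500, seed=3)
    sigma, omega = small_world_indices(net, n_null=30, seed=0)
    assert 0.7 < sigma < 1.3
    # omega ~ 1 - C_ER/C_latt, close to its analytic value
    rep = topology_report(net)
    k = 10
    expected_omega_tail = rep.C_local / ring_lattice_clustering(k)
    assert omega == pytest.approx(1.0 - expected_omega_tail, abs=0.25)


def test_lattice_dominated_graph_has_higher_sigma_than_er():
    lattice = watts_strogatz_reference(100, 6, p=0.05, seed=1)
    er = erdos_renyi_null(100, 300, seed=1)
    s_latt, o_latt = small_world_indices(lattice, n_null=20, seed=0)
    s_er, _ = small_world_indices(er, n_null=20, seed=0)
    assert s_latt > s_er
    assert o_latt < 0  # lattice-like


def test_synthesized_follicle_is_small_world(small_follicle):
    sigma, omega = small_world_indices(small_follicle, n_null=10, seed=0)
    assert sigma > 2.0
    assert -1.0 <= omega <= 1.0


# -- subtype comparison -------------------------------------------------------

def test_subtype_comparison_requires_both_subtypes(triangle_net):
    with pytest.raises(DegenerateComparisonError):
        subtype_comparison(triangle_net)


def test_fdc_hub_has_higher_mean_degree(mixed_subtype_net):
    df = subtype_comparison(mixed_subtype_net)
    deg = df[df.metric == "degree"].set_index("subtype")["mean"]
    assert deg[FDC] > deg["CD21neg_RC"]


def test_subtype_pvalue_uniform_under_null():
    rng = np.random.default_rng(0)
    ps = []
    for s in range(40):
        net = erdos_renyi_null(40, 120, seed=s)
        subs = ["FDC"] * 20 + ["CD21neg_RC"] * 20
        pos = rng.random((40, 3)) * 100
        relabeled = make_network(pos, net.edges, subtypes=subs)
        df = subtype_comparison(relabeled)
        ps.append(df[df.metric == "degree"]["p_value"].iloc[0])
    # under the null p-values should not pile up near 0
    assert np.mean(np.array(ps) < 0.05) < 0.25
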