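"""Set-conditioned degrees, hub selection, differential hubs, expansion."""

import networkx as nx
import numpy as np
import pytest

from omicshub import (
    conditioned_degrees,
    differential_hubs,
    expand_first_neighbors,
    generate_interaction_network,
    read_edge_list,
    select_hubs,
)
from omicshub.hubs import (
    HubRecord,
    MalformedEdgeLineError,
    annotation_tier,
    records_to_frame,
    write_edge_list,
)


def test_read_edge_list_dedup_and_self_loops(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text("a\tb\na\tb\nb\ta\na\ta\n", )
    g = read_edge_list(p, header=False)
    assert sorted(g.edges()) == [("a", "b")]


def test_read_edge_list_empty_and_malformed(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("interactor_a\tinteractor_b\n")
    assert read_edge_list(p).number_of_edges() == 0
    bad = tmp_path / "bad.tsv"
    bad.write_text("a\tb\nonlyone\n", )
    with pytest.raises(MalformedEdgeLineError, match="line 2"):
        read_edge_list(bad, header=False)


def test_edge_list_round_trip(tmp_path):
    g, _ = generate_interaction_network(60, 2, 12, 2.0, seed=4)
    path = tmp_path / "net.tsv"
    write_edge_list(g, path)
    back = read_edge_list(path)
    assert {frozenset(e) for e in g.edges()} == {frozenset(e) for e in back.edges()}


def test_star_graph_conditioned_degrees():
    g = nx.star_graph(["c", "x1", "x2", "x3", "x4", "x5"])
    recs = {r.node_id: r for r in conditioned_degrees(g, {"s": {"x1", "x2"}})}
    assert recs["c"].degree_total == 5
    assert recs["c"].degree_in_set["s"] == 2
    assert recs["x1"].degree_in_set["s"] == 0  # its only neighbor is c


def test_saturation_identity_and_handshake():
    g, _ = generate_interaction_network(80, 3, 15, 2.5, seed=7)
    recs = conditioned_degrees(g, {"all": set(g.nodes())})
    assert all(r.degree_in_set["all"] == r.degree_total for r in recs)
    assert sum(r.degree_total for r in recs) == 2 * g.number_of_edges()


def test_conditioned_degrees_match_edge_double_loop():
    rng = np.random.default_rng(12)
    g = nx.gnm_random_graph(40, 120, seed=12)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
    query = set(rng.choice(sorted(g.nodes()), size=15, replace=False))
    recs = {r.node_id: r for r in conditioned_degrees(g, {"q": query})}
    total = {n: 0 for n in g.nodes()}
    in_set = {n: 0 for n in g.nodes()}
    for u, v in g.edges():
        total[u] += 1
        total[v] += 1
        if v in query:
            in_set[u] += 1
        if u in query:
            in_set[v] += 1
    for n in g.nodes():
        assert recs[n].degree_total == total[n]
        assert recs[n].degree_in_set["q"] == in_set[n]


def test_hub_record_invariant_enforced():
    with pytest.raises(ValueError):
        HubRecord(node_id="x", degree_total=3, degree_in_set={"s": 4})


def _records(degrees: dict[str, int], label: str = "s"):
    return [
        HubRecord(node_id=n, degree_total=max(d, 60), degree_in_set={label: d})
        for n, d in degrees.items()
    ]


def test_select_hubs_threshold_and_ranking():
    recs = _records({"A": 59, "B": 24, "C": 9})
    assert select_hubs(recs, "s", min_degree=10) == ["A", "B"]
    assert select_hubs(_records({"A": 10}), "s", 10) == ["A"]  # inclusive
    assert annotation_tier(recs, "s", 3) == ["A", "B", "C"]
    # ties broken by node id ascending
    assert select_hubs(_records({"B": 12, "A": 12}), "s", 10) == ["A", "B"]
    with pytest.raises(KeyError):
        select_hubs(recs, "nope", 10)


@pytest.mark.parametrize(
    "d1,d2,flagged",
    [
        (20, 10, True),    # abs 10 >= 9, rel 0.50 >= 0.20
        (50, 42, False),   # abs 8 < 9
        (100, 85, False),  # rel 0.15 < 0.20
    ],
)
def test_differential_hub_rule(d1, d2, flagged):
    calls = differential_hubs(_records({"n": d1}), _records({"n": d2}), "s")
    assert calls[0].flagged is flagged
    assert calls[0].abs_diff == abs(d1 - d2)
    if flagged:
        assert calls[0].direction == "higher-in-1"


def test_differential_hubs_antisymmetric():
    rng = np.random.default_rng(3)
    deg1 = {f"n{i}": int(rng.integers(0, 40)) for i in range(30)}
    deg2 = {f"n{i}": int(rng.integers(0, 40)) for i in range(30)}
    fwd = differential_hubs(_records(deg1), _records(deg2), "s")
    rev = differential_hubs(_records(deg2), _records(deg1), "s")
    flip = {"higher-in-1": "higher-in-2", "higher-in-2": "higher-in-1",
            "equal": "equal"}
    for a, b in zip(fwd, rev):
        assert a.node_id == b.node_id
        assert a.flagged == b.flagged
        assert b.direction == flip[a.direction]
    # both-zero nodes have rel_diff 0 and are never flagged
    z = differential_hubs(_records({"z": 0}), _records({"z": 0}), "s")
    assert z[0].rel_diff == 0.0 and not z[0].flagged


def test_expand_first_neighbors():
    g = nx.path_graph(["a", "b", "c"])
    assert expand_first_neighbors(g, {"a"}) == {"a", "b"}
    assert expand_first_neighbors(g, set()) == set()
    assert expand_first_neighbors(g, {"ghost"}) == {"ghost"}
    rng = np.random.default_rng(5)
    h = nx.gnm_random_graph(30, 60, seed=5)
    seeds = set(rng.choice(30, size=5, replace=False).tolist())
    expected = set(seeds)
    for s in seeds:
        expected |= set(h.adj[s])
    assert expand_first_neighbors(h, seeds) == expected


def test_planted_hub_recovery():
    """Planted hubs (degree >= 20) are all selected at min_degree 10 when the
    query set is the hubs' first neighborhood."""
    g, truth = generate_interaction_network(300, 4, 20, 3.0, seed=21)
    neighborhood = expand_first_neighbors(g, truth.hub_ids) - truth.hub_ids
    recs = conditioned_degrees(g, {"nbh": neighborhood})
    selected = select_hubs(recs, "nbh", min_degree=10)
    assert truth.hub_ids <= set(selected)


def test_records_to_frame_columns():
    recs = _records({"A": 5})
    df = records_to_frame(recs)
    assert list(df.columns) == ["node_id", "degree_total", "degree.s"]


def test_degree_scatter_plot_smoke():
    import matplotlib
    matplotlib.use("Agg")
    from omicshub.hubs import plot_degree_scatter

    recs = _records({"A": 12, "B": 5, "C": 1})
    ax = plot_degree_scatter(recs, "s")
    assert ax.get_xlabel() == "degree.total"
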