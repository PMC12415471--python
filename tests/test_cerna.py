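"""Hypergeometric shared-miRNA test, ceRNA screening and network export."""

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernakit import (
    InteractionSet,
    assemble_triplets,
    export_network,
    network_graph,
    screen_pairs,
    shared_mirna_test,
)
from cernakit.cerna import CeRNAPair


def enumeration_p(M, K, n, k):
    """P(X >= k) by counting all C(M, n) draws sharing >= k with a K-set."""
    total = comb(M, n)
    hits = sum(
        comb(K, j) * comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


def test_hypergeom_trivial_cases():
    universe = {f"m{i}" for i in range(10)}
    t_a = set(list(universe)[:4])
    k, p = shared_mirna_test(t_a, set(), universe)
    assert (k, p) == (0, 1.0)
    k, p = shared_mirna_test(universe, universe, universe)
    assert k == 10 and p == pytest.approx(1.0)


def test_hypergeom_worked_example():
    universe = {f"m{i}" for i in range(10)}
    t_a = {f"m{i}" for i in range(5)}
    t_b = {"m0", "m1", "m2", "m9"}
    k, p = shared_mirna_test(t_a, t_b, universe)
    assert k == 3
    assert p == pytest.approx(55 / 210, abs=1e-12)


def test_hypergeom_rejects_sets_outside_universe():
    with pytest.raises(ValueError):
        shared_mirna_test({"x"}, set(), {"m1"})


def test_hypergeom_matches_enumeration_full_sweep_small():
    """Exhaustive-draw oracle over a reduced sweep (full sweep in acceptance)."""
    for M in range(1, 9):
        universe = {f"m{i}" for i in range(M)}
        ulist = sorted(universe)
        for K in range(M + 1):
            t_a = set(ulist[:K])
            for n in range(M + 1):
                t_b = set(ulist[M - n :])
                k, p = shared_mirna_test(t_a, t_b, universe)
                assert p == pytest.approx(enumeration_p(M, K, n, k), abs=1e-12)


def test_hypergeom_p_monotone_in_k():
    # verify monotonicity of the sf tail directly on the enumeration oracle scale
    from scipy import stats

    M, K, n = 12, 6, 5
    ps = [float(stats.hypergeom.sf(k - 1, M, K, n)) for k in range(0, 6)]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------- screening
def make_screen_inputs():
    """One strong planted pair among decoys, with controllable statistics."""
    rng = np.random.default_rng(5)
    mirnas = [f"m{i}" for i in range(30)]
    pairs = []
    for m in mirnas[:5]:
        pairs += [(m, "L1"), (m, "G1")]
    # decoy sponge with disjoint miRNAs
    for m in mirnas[5:8]:
        pairs += [(m, "L2")]
    for m in mirnas[8:11]:
        pairs += [(m, "G2")]
    iset = InteractionSet(pairs)
    base = rng.normal(10, 0.1, 6)
    shared = np.array([0.0, 0.5, 1.0, 2.0, 2.5, 3.0])
    expr = pd.DataFrame(
        {
            "L1": base + shared,
            "G1": base + shared + rng.normal(0, 0.05, 6),
            "L2": rng.normal(10, 1, 6),
            "G2": rng.normal(10, 1, 6),
        }
    ).T
    sponges = {"L1": "lncRNA", "L2": "lncRNA"}
    return sponges, ["G1", "G2"], iset, expr


def test_screen_retains_planted_pair_and_rejects_disjoint():
    sponges, mrnas, iset, expr = make_screen_inputs()
    retained, tested = screen_pairs(sponges, mrnas, iset, expr)
    assert [(p.sponge_id, p.mrna_id) for p in retained] == [("L1", "G1")]
    assert len(tested) == 4
    pair = retained[0]
    assert pair.shared_k == 5 and pair.pcc > 0.8 and pair.fdr < 0.05


def test_screen_thresholds_are_strict():
    sponges, mrnas, iset, expr = make_screen_inputs()
    # k = 5 rejected when min_shared demands 6
    none, _ = screen_pairs(sponges, mrnas, iset, expr, min_shared=6)
    assert none == []
    # pcc threshold equal to realized pcc -> strict > rejects
    retained, tested = screen_pairs(sponges, mrnas, iset, expr)
    realized_pcc = retained[0].pcc
    none2, _ = screen_pairs(sponges, mrnas, iset, expr, pcc_threshold=realized_pcc)
    assert none2 == []


def test_screen_relaxing_thresholds_is_monotone():
    sponges, mrnas, iset, expr = make_screen_inputs()
    base, _ = screen_pairs(sponges, mrnas, iset, expr)
    key = lambda pairs: {(p.sponge_id, p.mrna_id) for p in pairs}
    for kwargs in (
        {"min_shared": 1},
        {"p_threshold": 0.5},
        {"fdr_threshold": 0.5},
        {"pcc_threshold": 0.0},
    ):
        relaxed, _ = screen_pairs(sponges, mrnas, iset, expr, **kwargs)
        assert key(base) <= key(relaxed)


# ----------------------------------------------------------------- triplets
def make_pair(shared=("m1", "m2")):
    return CeRNAPair(
        sponge_id="L1",
        sponge_class="lncRNA",
        mrna_id="G1",
        shared_k=len(shared),
        shared_mirnas=tuple(shared),
        p_hyper=1e-4,
        fdr=1e-3,
        pcc=0.95,
    )


def test_assemble_keeps_only_scc_surviving_mirnas():
    pair = make_pair()
    filtered = InteractionSet([("m1", "G1")])  # m2 failed the SCC filter
    scc = pd.DataFrame(
        {"mirna_id": ["m1", "m2"], "target_id": ["G1", "G1"], "scc": [-0.9, -0.2]}
    )
    triplets = assemble_triplets([pair], filtered, scc)
    assert [(t.sponge_id, t.mirna_id, t.mrna_id) for t in triplets] == [
        ("L1", "m1", "G1")
    ]
    assert triplets[0].scc_mirna_mrna == pytest.approx(-0.9)


def test_assemble_pair_with_no_surviving_mirna_contributes_nothing():
    pair = make_pair()
    triplets = assemble_triplets([pair], InteractionSet([]), pd.DataFrame(
        columns=["mirna_id", "target_id", "scc"]))
    assert triplets == []


def test_assemble_optional_sponge_scc_filter():
    pair = make_pair(shared=("m1",))
    filtered = InteractionSet([("m1", "G1")])
    scc = pd.DataFrame({"mirna_id": ["m1"], "target_id": ["G1"], "scc": [-0.9]})
    sponge_scc = {("m1", "L1"): -0.3}
    assert assemble_triplets([pair], filtered, scc, sponge_scc) != []
    assert (
        assemble_triplets([pair], filtered, scc, sponge_scc, filter_sponge_scc=True)
        == []
    )


# ------------------------------------------------------------------- export
def test_sif_one_triplet_two_edges(tmp_path):
    pair = make_pair(shared=("m1",))
    filtered = InteractionSet([("m1", "G1")])
    scc = pd.DataFrame({"mirna_id": ["m1"], "target_id": ["G1"], "scc": [-0.9]})
    triplets = assemble_triplets([pair], filtered, scc)
    out = tmp_path / "net.sif"
    export_network(triplets, out, "sif")
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 2
    g = network_graph(triplets)
    assert g.number_of_nodes() == 3


def test_shared_mirna_node_deduplicated():
    pairs = [make_pair(shared=("m1",)),
             CeRNAPair("C1", "circRNA", "G2", 1, ("m1",), 1e-4, 1e-3, 0.9)]
    filtered = InteractionSet([("m1", "G1"), ("m1", "G2")])
    scc = pd.DataFrame(
        {"mirna_id": ["m1", "m1"], "target_id": ["G1", "G2"], "scc": [-0.9, -0.8]}
    )
    triplets = assemble_triplets(pairs, filtered, scc)
    g = network_graph(triplets)
    assert sum(1 for n in g if n == "m1") == 1
    assert g.nodes["C1"]["node_type"] == "circRNA"


def test_graphml_round_trip(tmp_path):
    pairs = [make_pair()]
    filtered = InteractionSet([("m1", "G1"), ("m2", "G1")])
    scc = pd.DataFrame(
        {"mirna_id": ["m1", "m2"], "target_id": ["G1", "G1"], "scc": [-0.9, -0.85]}
    )
    triplets = assemble_triplets(pairs, filtered, scc)
    out = tmp_path / "net.graphml"
    export_network(triplets, out, "graphml")
    back = nx.read_graphml(out)
    g = network_graph(triplets)
    assert set(back.nodes) == set(g.nodes)
    assert {(u, v) for u, v in back.edges} == set(g.edges)


def test_export_unknown_format_lists_supported(tmp_path):
    with pytest.raises(ValueError, match="sif"):
        export_network([], tmp_path / "x", "xgmml")


def test_writers_produce_isomorphic_graphs(tmp_path):
    pairs = [make_pair()]
    filtered = InteractionSet([("m1", "G1"), ("m2", "G1")])
    scc = pd.DataFrame(
        {"mirna_id": ["m1", "m2"], "target_id": ["G1", "G1"], "scc": [-0.9, -0.85]}
    )
    triplets = assemble_triplets(pairs, filtered, scc)
    export_network(triplets, tmp_path / "n.sif", "sif")
    export_network(triplets, tmp_path / "n.tsv", "tsv")
    sif_edges = {
        (a, c) for a, _, c in
        (line.split("\t") for line in (tmp_path / "n.sif").read_text().strip().splitlines())
    }
    tsv_lines = (tmp_path / "n.tsv").read_text().strip().splitlines()[1:]
    tsv_edges = {(a, c) for a, _, c in (line.split("\t") for line in tsv_lines)}
    assert sif_edges == tsv_edges == set(network_graph(triplets).edges)
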