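"""ceRNA pair screening and sponge-miRNA-mRNA triplet assembly.

A candidate ceRNA pair is a (sponge, mRNA) combination of differentially
expressed RNAs where the sponge is a lncRNA or circRNA.  A pair is retained
when the two members share more than ``min_shared - 1`` miRNAs, the shared
count is over-represented by a one-sided hypergeometric test (raw p and BH
FDR both below 0.05), and the two members are positively co-expressed
(Pearson correlation strictly above 0.8 on log-normalized expression).
The FDR is adjusted separately within each sponge class, mirroring the two
separate co-expression networks (lncRNA-miRNA-mRNA and circRNA-miRNA-mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .targets import InteractionSet, pearson


@dataclass
class CeRNAPair:
    sponge_id: str
    sponge_class: str
    mrna_id: str
    shared_k: int
    shared_mirnas: tuple[str, ...]
    p_hyper: float
    fdr: float
    pcc: float


@dataclass
class CeRNATriplet:
    sponge_id: str
    sponge_class: str
    mirna_id: str
    mrna_id: str
    scc_mirna_mrna: float
    scc_mirna_sponge: float
    pair: CeRNAPair


def shared_mirna_test(
    t_a: set[str], t_b: set[str], universe: set[str]
) -> tuple[int, float]:
    """Shared-miRNA count and one-sided hypergeometric over-representation p.

    With population M = |universe|, K = |t_a| successes and n = |t_b| draws,
    p = P(X >= k) where k = |t_a & t_b|.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not t_a <= universe or not t_b <= universe:
        raise ValueError("miRNA sets must be contained in the universe")
    k = len(t_a & t_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(t_a), len(t_b)))
    return k, min(p, 1.0)


def screen_pairs(
    sponges: dict[str, str],
    mrnas,
    interactions: InteractionSet,
    expression: pd.DataFrame,
    universe: set[str] | None = None,
    min_shared: int = 4,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    pcc_threshold: float = 0.8,
) -> tuple[list[CeRNAPair], pd.DataFrame]:
    """Screen all candidate (sponge, mRNA) pairs with the ceRNA criteria.

    ``sponges`` maps sponge id -> class ("lncRNA"/"circRNA"); candidates are
    every combination with an mRNA where both members hold a nonempty miRNA
    set.  Thresholds are strict comparisons: shared_k >= min_shared
    (the default 4 reads "more than 3 shared miRNAs" literally),
    p < p_threshold, FDR < fdr_threshold, PCC > pcc_threshold.  Returns the
    retained pairs and the full table of tested pairs.
    """
    if universe is None:
        universe = interactions.mirna_universe
    tested: list[CeRNAPair] = []
    for sponge_id in sorted(sponges):
        t_sponge = interactions.mirnas_of.get(sponge_id, set())
        if not t_sponge:
            continue
        for mrna_id in sorted(mrnas):
            t_mrna = interactions.mirnas_of.get(mrna_id, set())
            if not t_mrna:
                continue
            shared = tuple(sorted(t_sponge & t_mrna))
            k, p = shared_mirna_test(t_sponge, t_mrna, universe)
            pcc = pearson(
                expression.loc[sponge_id].to_numpy(),
                expression.loc[mrna_id].to_numpy(),
            )
            tested.append(
                CeRNAPair(
                    sponge_id=sponge_id,
                    sponge_class=sponges[sponge_id],
                    mrna_id=mrna_id,
                    shared_k=k,
                    shared_mirnas=shared,
                    p_hyper=p,
                    fdr=float("nan"),
                    pcc=pcc,
                )
            )
    # BH within each sponge class (two separate networks)
    for cls in sorted({p.sponge_class for p in tested}):
        members = [p for p in tested if p.sponge_class == cls]
        adj = bh_adjust([p.p_hyper for p in members])
        for pair, fdr in zip(members, adj):
            pair.fdr = float(fdr)
    retained = [
        p
        for p in tested
        if p.shared_k >= min_shared
        and p.p_hyper < p_threshold
        and p.fdr < fdr_threshold
        and p.pcc > pcc_threshold
    ]
    table = pd.DataFrame(
        [
            (
                p.sponge_id,
                p.sponge_class,
                p.mrna_id,
                p.shared_k,
                p.p_hyper,
                p.fdr,
                p.pcc,
            )
            for p in tested
        ],
        columns=["sponge_id", "sponge_class", "mrna_id", "shared_k", "p_hyper", "fdr", "pcc"],
    )
    return retained, table


def assemble_triplets(
    pairs: list[CeRNAPair],
    filtered_interactions: InteractionSet,
    scc_table: pd.DataFrame,
    mirna_sponge_scc: dict[tuple[str, str], float] | None = None,
    filter_sponge_scc: bool = False,
    scc_threshold: float = -0.7,
) -> list[CeRNATriplet]:
    """Expand screened pairs into sponge-miRNA-mRNA triplets.

    One triplet is emitted per (pair, shared miRNA) whose miRNA-mRNA link
    survived the negative-co-expression filter (``filtered_interactions``).
    The miRNA-sponge Spearman correlation is recorded when available; by
    default it is not used as a filter (``filter_sponge_scc`` enables the
    optional anticorrelation requirement on the sponge side).
    """
    scc_lookup = {
        (m, t): s
        for m, t, s in zip(
            scc_table["mirna_id"], scc_table["target_id"], scc_table["scc"]
        )
    }
    mirna_sponge_scc = mirna_sponge_scc or {}
    triplets: list[CeRNATriplet] = []
    for pair in pairs:
        for mirna in pair.shared_mirnas:
            if (mirna, pair.mrna_id) not in filtered_interactions:
                continue
            sponge_scc = mirna_sponge_scc.get((mirna, pair.sponge_id), float("nan"))
            if filter_sponge_scc and not (sponge_scc < scc_threshold):
                continue
            triplets.append(
                CeRNATriplet(
                    sponge_id=pair.sponge_id,
                    sponge_class=pair.sponge_class,
                    mirna_id=mirna,
                    mrna_id=pair.mrna_id,
                    scc_mirna_mrna=scc_lookup.get(
                        (mirna, pair.mrna_id), float("nan")
                    ),
                    scc_mirna_sponge=sponge_scc,
                    pair=pair,
                )
            )
    return triplets


def triplets_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                t.sponge_id,
                t.sponge_class,
                t.mirna_id,
                t.mrna_id,
                t.pair.shared_k,
                t.pair.p_hyper,
                t.pair.fdr,
                t.pair.pcc,
                t.scc_mirna_mrna,
                t.scc_mirna_sponge,
            )
            for t in triplets
        ],
        columns=[
            "sponge_id",
            "sponge_class",
            "mirna_id",
            "mrna_id",
            "shared_k",
            "p_hyper",
            "fdr",
            "pcc",
            "scc_mirna_mrna",
            "scc_mirna_sponge",
        ],
    )


def network_graph(triplets: list[CeRNATriplet]) -> nx.DiGraph:
    """Typed sponge->miRNA->mRNA graph with de-duplicated nodes and edges."""
    g = nx.DiGraph()
    for t in sorted(triplets, key=lambda t: (t.sponge_id, t.mirna_id, t.mrna_id)):
        g.add_node(t.sponge_id, node_type=t.sponge_class)
        g.add_node(t.mirna_id, node_type="miRNA")
        g.add_node(t.mrna_id, node_type="mRNA")
        g.add_edge(t.sponge_id, t.mirna_id, interaction="sponges")
        g.add_edge(t.mirna_id, t.mrna_id, interaction="targets")
    return g


SUPPORTED_FORMATS = ("sif", "graphml", "tsv")


def export_network(triplets: list[CeRNATriplet], path: str | Path, fmt: str) -> None:
    """Write the triplet network in a Cytoscape-readable format.

    Supported: "sif" (node relation node lines), "graphml", and an
    edge-list "tsv".  All three writers produce isomorphic graphs.
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown format {fmt!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}"
        )
    g = network_graph(triplets)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return
    edges = sorted(g.edges(data=True))
    if fmt == "sif":
        lines = [f"{u}\t{d['interaction']}\t{v}" for u, v, d in edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        lines = ["source\tinteraction\ttarget"]
        lines += [f"{u}\t{d['interaction']}\t{v}" for u, v, d in edges]
        path.write_text("\n".join(lines) + "\n")
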