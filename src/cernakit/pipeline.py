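"""End-to-end orchestration: simulate -> DE -> targets -> ceRNA -> back-splice.

``run_pipeline`` drives every stage on one simulated study, writes all
declared artifacts under an output directory, and returns a summary with
truth-based recovery metrics (DE recall, ceRNA triplet recall/precision,
back-splice junction recall).  Identical configs (including the seed)
produce byte-identical output trees.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import backsplice as bs
from . import simulate as sim
from .assays import ddct, melanin_fit, two_group_test
from .cerna import assemble_triplets, export_network, screen_pairs, triplets_frame
from .expression import de_test, filter_lncrna_candidates, fpkm, size_factors
from .targets import (
    intersect_predictions,
    log_normalized,
    negative_coexpression_filter,
    spearman,
)


def run_pipeline(
    config: sim.SimConfig,
    outdir: str | Path,
    alpha: float = 0.05,
    scc_threshold: float = -0.7,
    min_shared: int = 4,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    pcc_threshold: float = 0.8,
    min_reads: int = 2,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- simulation ------------------------------------------------------
    matrices, truth = sim.simulate_counts(config)
    annotation = sim.feature_annotation(config)
    table_a, table_b = sim.simulate_target_tables(config, truth)
    toy, _, records, bsj_truth = sim.simulate_backsplice_reads(config)
    truth.bsj_truth = bsj_truth
    ct_table, standards = sim.simulate_assay_tables(config)

    combined_counts = pd.concat(
        [
            m.counts.assign(rna_class=m.classes).reset_index()[
                ["feature_id", "rna_class"] + config.sample_ids
            ]
            for m in matrices.values()
        ],
        ignore_index=True,
    )
    combined_counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    table_a.to_csv(outdir / "targets_a.tsv", sep="\t", index=False)
    table_b.to_csv(outdir / "targets_b.tsv", sep="\t", index=False)
    sim.write_fasta(toy, outdir / "genome.fa")
    sim.write_gtf(toy, outdir / "annotation.gtf")
    sim.write_sam(records, outdir / "reads.sam")
    ct_table.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    standards.to_csv(outdir / "melanin_standards.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())

    # ---- lncRNA candidate filter ----------------------------------------
    lnc_ann = annotation[annotation["biotype"] == "lncRNA"]
    lnc_keep = set(filter_lncrna_candidates(lnc_ann))
    matrices["lncRNA"] = matrices["lncRNA"].subset(
        [f for f in matrices["lncRNA"].counts.index if f in lnc_keep]
    )

    # ---- differential expression per RNA class --------------------------
    de_results: dict[str, pd.DataFrame] = {}
    for cls, cm in matrices.items():
        res = de_test(cm, alpha=alpha)
        res.rename_axis("feature_id").reset_index().to_csv(
            outdir / f"de_{cls}.tsv", sep="\t", index=False
        )
        de_results[cls] = res
    de_sets = {
        cls: set(res.index[res["significant"]]) for cls, res in de_results.items()
    }

    # ---- expression matrices for co-expression filters ------------------
    lengths = annotation.set_index("feature_id")["length"]
    target_frames = []
    for cls in ("mRNA", "lncRNA", "circRNA"):
        target_frames.append(fpkm(matrices[cls].counts, lengths))
    target_expr = log_normalized(pd.concat(target_frames))
    mirna_norm = matrices["miRNA"].counts / size_factors(matrices["miRNA"].counts)
    mirna_expr = log_normalized(mirna_norm)
    combined_expr = pd.concat([target_expr, mirna_expr])

    # ---- high-confidence interactions and negative co-expression --------
    interactions = intersect_predictions(table_a, table_b)
    filtered, scc_table = negative_coexpression_filter(
        interactions,
        mirna_expr,
        target_expr,
        threshold=scc_threshold,
        de_mirnas=de_sets["miRNA"],
        de_targets=de_sets["mRNA"],
    )
    interactions.to_frame().to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    scc_table.to_csv(outdir / "interactions_scc.tsv", sep="\t", index=False)

    # ---- ceRNA screen ----------------------------------------------------
    sponges = {f: "lncRNA" for f in sorted(de_sets["lncRNA"])}
    sponges.update({f: "circRNA" for f in sorted(de_sets["circRNA"])})
    pairs, tested = screen_pairs(
        sponges,
        sorted(de_sets["mRNA"]),
        interactions,
        combined_expr,
        min_shared=min_shared,
        p_threshold=p_threshold,
        fdr_threshold=fdr_threshold,
        pcc_threshold=pcc_threshold,
    )
    tested.to_csv(outdir / "pairs_tested.tsv", sep="\t", index=False)

    mirna_sponge_scc = {}
    for sponge_id in sponges:
        for mirna in interactions.mirnas_of.get(sponge_id, set()):
            if mirna in mirna_expr.index and sponge_id in target_expr.index:
                mirna_sponge_scc[(mirna, sponge_id)] = spearman(
                    mirna_expr.loc[mirna].to_numpy(),
                    target_expr.loc[sponge_id].to_numpy(),
                )
    triplets = assemble_triplets(pairs, filtered, scc_table, mirna_sponge_scc)
    triplets_frame(triplets).to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    export_network(triplets, outdir / "network.sif", "sif")
    export_network(triplets, outdir / "network.graphml", "graphml")
    export_network(triplets, outdir / "network_edges.tsv", "tsv")

    # ---- back-splice calls ----------------------------------------------
    genome = bs.load_genome(outdir / "genome.fa")
    diagnostics: dict = {}
    calls = bs.run_caller(
        outdir / "reads.sam",
        genome,
        outdir / "annotation.gtf",
        min_reads=min_reads,
        diagnostics=diagnostics,
    )
    bs.write_calls_tsv(calls, outdir / "circ_calls.tsv")
    bs.write_calls_bed(calls, outdir / "circ_calls.bed")

    # ---- assays ----------------------------------------------------------
    rel = ddct(ct_table, calibrator_group="A")
    rel.to_csv(outdir / "qpcr_relative_expression.tsv", sep="\t", index=False)
    comparison = two_group_test(
        rel.loc[rel["group"] == "A", "rel_expr"],
        rel.loc[rel["group"] == "B", "rel_expr"],
    )
    curve = melanin_fit(standards["conc_mg_per_ml"], standards["absorbance"])

    # ---- truth-based summary --------------------------------------------
    summary = _summarize(
        config, truth, de_results, de_sets, pairs, triplets, calls, diagnostics,
        comparison, curve,
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _summarize(
    config, truth, de_results, de_sets, pairs, triplets, calls, diagnostics,
    comparison, curve,
) -> dict:
    all_sig = set().union(*de_sets.values()) if de_sets else set()
    planted = set(truth.de_features)
    recovered = planted & all_sig
    sign_errors = 0
    for fid in recovered:
        cls = truth.de_features[fid]["class"]
        want = truth.de_features[fid]["direction"]
        got = de_results[cls].loc[fid, "direction"] if fid in de_results[cls].index else None
        if got is not None and got != want:
            sign_errors += 1

    out_triplets = {(t.sponge_id, t.mirna_id, t.mrna_id) for t in triplets}
    true_triplets = set(truth.triplets)
    recall = (
        len(out_triplets & true_triplets) / len(true_triplets) if true_triplets else float("nan")
    )
    precision = (
        len(out_triplets & true_triplets) / len(out_triplets) if out_triplets else float("nan")
    )

    true_bsj = {(b["chrom"], b["start"], b["end"]) for b in truth.bsj_truth}
    called = {(c.chrom, c.start, c.end) for c in calls}
    bsj_recall = len(called & true_bsj) / len(true_bsj) if true_bsj else float("nan")
    false_calls = len(called - true_bsj)

    return {
        "n_de": {cls: int(len(s)) for cls, s in de_sets.items()},
        "de_planted": len(planted),
        "de_recovered": len(recovered),
        "de_recovery_rate": len(recovered) / len(planted) if planted else float("nan"),
        "de_sign_errors": sign_errors,
        "n_cerna_pairs": len(pairs),
        "n_triplets": len(out_triplets),
        "triplet_recall": recall,
        "triplet_precision": precision,
        "n_circ_calls": len(calls),
        "bsj_recall": bsj_recall,
        "bsj_false_calls": false_calls,
        "ambiguous_rematches": diagnostics.get("ambiguous", 0),
        "qpcr_mean_fold_b": comparison.mean_b,
        "qpcr_p": comparison.p,
        "melanin_slope": curve.slope,
        "melanin_intercept": curve.intercept,
        "melanin_r2": curve.r2,
    }
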