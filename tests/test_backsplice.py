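"""CIGAR classification and the chiastic back-splice junction caller."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernakit import (
    SimConfig,
    annotation_filter,
    call_circles,
    classify_cigar,
    detect_junction_candidates,
    mate_constraint,
    simulate_backsplice_reads,
    splice_signal_check,
)
from cernakit.backsplice import (
    ExonIndex,
    JunctionCandidate,
    parse_gtf_exons,
    run_caller,
)
from cernakit.simulate import write_gtf, write_sam
from intervaltree import IntervalTree


# ------------------------------------------------------------------- CIGAR
@pytest.mark.parametrize(
    "cigar,category,xyz",
    [
        ("100M", "none", None),
        ("30S70M", "left_clip", (30, 70, 0)),
        ("30H70M", "left_clip", (30, 70, 0)),
        ("70M30S", "right_clip", (70, 30, 0)),
        ("70M30H", "right_clip", (70, 30, 0)),
        ("20S60M20S", "double_clip", (20, 60, 20)),
        ("20H60M20H", "double_clip", (20, 60, 20)),
        ("10M5I85M", "none", None),
        ("5S10M5I80M", "none", None),
    ],
)
def test_classify_cigar_patterns(cigar, category, xyz):
    sig = classify_cigar(cigar)
    assert sig.category == category
    if xyz:
        assert (sig.x, sig.y, sig.z) == xyz


def test_classify_cigar_malformed_reports_offset():
    with pytest.raises(ValueError, match="offset"):
        classify_cigar("10M7")
    with pytest.raises(ValueError):
        classify_cigar("")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(1, 200), st.sampled_from("MS")), min_size=1, max_size=4
))
def test_classify_cigar_round_trips_on_printed_cigars(ops):
    # merge adjacent equal ops so the printed string is canonical
    merged = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1][0] += n
        else:
            merged.append([n, op])
    cigar = "".join(f"{n}{op}" for n, op in merged)
    sig = classify_cigar(cigar)
    kinds = "".join(op for _, op in merged)
    expected = {"SM": "left_clip", "MS": "right_clip", "SMS": "double_clip"}.get(
        kinds, "none"
    )
    assert sig.category == expected


# ------------------------------------------------------- handcrafted genome
def mini_genome():
    """60 bp chromosome with a planted circle at [21, 40] (1-based)."""
    rng = np.random.default_rng(0)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)]))
    seq[18:20] = "AG"  # acceptor flank, bases 19-20
    seq[40:42] = "GT"  # donor flank, bases 41-42
    return {"chrT": "".join(seq)}


def make_record(chrom, pos1, cigar, seq, name="r1", paired=False, mate_pos1=None):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": 60}]}
    )
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = pos1 - 1
    rec.cigarstring = cigar
    rec.query_sequence = seq
    rec.flag = (1 | 64) if paired else 0
    if mate_pos1 is not None:
        rec.next_reference_id = 0
        rec.next_reference_start = mate_pos1 - 1
    return rec


def junction_read(genome, s, e, a, total, left=True):
    g = genome["chrT"]
    tail = g[e - a : e]
    head = g[s - 1 : s - 1 + (total - a)]
    seq = tail + head
    if left:
        return make_record("chrT", s, f"{a}S{total - a}M", seq)
    return make_record("chrT", e - a + 1, f"{a}M{total - a}S", seq)


def test_left_and_right_clip_reads_yield_exact_planted_junction():
    genome = mini_genome()
    s, e = 21, 40
    for left in (True, False):
        rec = junction_read(genome, s, e, a=10, total=20, left=left)
        cands = detect_junction_candidates([rec], genome, min_clip=8)
        assert [(c.start, c.end) for c in cands] == [(s, e)]


def test_linear_and_colinear_reads_yield_no_candidate():
    genome = mini_genome()
    g = genome["chrT"]
    linear = make_record("chrT", 5, "20M", g[4:24])
    assert detect_junction_candidates([linear], genome) == []
    # colinear clip: suffix continues downstream of the anchor (splice-like)
    seq = g[9:19] + g[29:39]  # anchor at 10..19, clip matches at 30..39
    colinear = make_record("chrT", 10, "10M10S", seq)
    assert detect_junction_candidates([colinear], genome, min_clip=8) == []


def test_double_clip_resolves_single_exon_circle():
    genome = mini_genome()
    s, e = 21, 40  # 20 bp circle, read of 30 bp wraps it
    g = genome["chrT"]
    circle = g[s - 1 : e]
    seq = circle[-8:] + circle + circle[:8]  # 8S 20M 8S
    rec = make_record("chrT", s, "8S20M8S", seq)
    cands = detect_junction_candidates([rec], genome, min_clip=8)
    assert [(c.start, c.end) for c in cands] == [(s, e)]


def test_ambiguous_rematch_is_discarded_and_counted():
    # genome with the clip sequence occurring twice downstream
    word = "ACGTACGTTG"
    g = "TTTTTTTTTTCCCCCCCCCC" + word + "AAAA" + word + "GGGGGGGGGG"
    genome = {"chrT": g}
    seq = word + g[10:20]  # clip = word, anchor matches at pos 11..20
    rec = make_record("chrT", 11, "10S10M", seq)
    diag = {}
    cands = detect_junction_candidates([rec], genome, min_clip=8, diagnostics=diag)
    assert cands == [] and diag["ambiguous"] == 1


def test_mate_constraint_containment_and_bypass():
    inside = JunctionCandidate("chrT", 21, 40, "q1", True, "chrT", 25)
    outside = JunctionCandidate("chrT", 21, 40, "q2", True, "chrT", 50)
    other_chrom = JunctionCandidate("chrT", 21, 40, "q3", True, "chrX", 25)
    unpaired = JunctionCandidate("chrT", 21, 40, "q4", False, None, None)
    kept = mate_constraint([inside, outside, other_chrom, unpaired])
    assert [c.query_name for c in kept] == ["q1", "q4"]


def test_splice_signal_plus_minus_and_none():
    genome = mini_genome()
    assert splice_signal_check(genome, "chrT", 21, 40, "+") == "GT-AG"
    # minus strand: genomic flanks AC...CT read GT-AG after reverse complement
    g = list(mini_genome()["chrT"])
    g[18:20] = "AC"
    g[40:42] = "CT"
    genome_minus = {"chrT": "".join(g)}
    assert splice_signal_check(genome_minus, "chrT", 21, 40, "-") == "GT-AG"
    assert splice_signal_check(genome_minus, "chrT", 21, 40, "+") != "GT-AG"
    g[18:20] = "AA"
    g[40:42] = "TT"
    assert splice_signal_check({"chrT": "".join(g)}, "chrT", 21, 40, "+") == "none"
    # too close to the chromosome edge: no signal readable
    assert splice_signal_check(genome, "chrT", 2, 40, "+") == "none"
    assert splice_signal_check(genome, "chrT", 21, 59, "+") == "none"


def test_annotation_filter_tolerance_and_source_gene():
    index = ExonIndex(
        exon_starts={"chrT": {21}},
        exon_ends={"chrT": {40}},
        genes={"chrT": IntervalTree.from_tuples([(10, 51, "G")])},
    )
    exact = JunctionCandidate("chrT", 21, 40, "q", False, None, None)
    off_by_one = JunctionCandidate("chrT", 22, 40, "q", False, None, None)
    inside_exon = JunctionCandidate("chrT", 30, 40, "q", False, None, None)
    assert annotation_filter([exact], index)[0].source_gene == "G"
    assert annotation_filter([off_by_one], index, tolerance=0) == []
    assert annotation_filter([off_by_one], index, tolerance=2) != []
    assert annotation_filter([inside_exon], index, tolerance=0) == []
    assert annotation_filter([inside_exon], index, keep_intergenic=True) != []


def test_call_circles_grouping_thresholds_and_name_dedup():
    def cand(name):
        return JunctionCandidate("chrT", 21, 40, name, False, None, None,
                                 strand="+", signal="GT-AG")

    # same read name twice (both mates clipped) counts once
    calls = call_circles([cand("a"), cand("a"), cand("b")], min_reads=2)
    assert len(calls) == 1 and calls[0].junction_reads == 2
    assert call_circles([cand("a"), cand("a")], min_reads=2) == []


def test_caller_output_invariant_to_record_order(tmp_path):
    cfg = SimConfig(seed=13, circle_count=4, n_background_reads=200,
                    chrom_length=40_000)
    toy, _, records, bsj = simulate_backsplice_reads(cfg)
    rng = np.random.default_rng(1)
    shuffled = [records[i] for i in rng.permutation(len(records))]
    write_sam(records, tmp_path / "a.sam")
    write_sam(shuffled, tmp_path / "b.sam")
    write_gtf(toy, tmp_path / "ann.gtf")
    calls_a = run_caller(tmp_path / "a.sam", toy.sequences, tmp_path / "ann.gtf")
    calls_b = run_caller(tmp_path / "b.sam", toy.sequences, tmp_path / "ann.gtf")
    assert calls_a == calls_b
    assert all(c.start < c.end and c.junction_reads >= 2 for c in calls_a)


def test_caller_recovers_planted_junctions_with_source_genes(tmp_path):
    cfg = SimConfig(seed=8, circle_count=6, n_background_reads=400,
                    chrom_length=50_000)
    toy, _, records, bsj = simulate_backsplice_reads(cfg)
    write_sam(records, tmp_path / "reads.sam")
    write_gtf(toy, tmp_path / "ann.gtf")
    calls = run_caller(tmp_path / "reads.sam", toy.sequences, tmp_path / "ann.gtf")
    called = {(c.chrom, c.start, c.end): c for c in calls}
    truth = {(b["chrom"], b["start"], b["end"]): b for b in bsj}
    assert set(called) == set(truth)
    for key, c in called.items():
        assert c.signal == "GT-AG"
        assert c.strand == truth[key]["strand"]
        assert c.source_gene == truth[key]["gene_id"]
        assert c.junction_reads == cfg.reads_per_junction


def test_unknown_chromosome_rejected():
    rec = make_record("chrT", 1, "10S10M", "A" * 20)
    with pytest.raises(ValueError, match="absent"):
        detect_junction_candidates([rec], {"chrX": "A" * 60})


def test_parse_gtf_exons_reads_boundaries(tmp_path):
    cfg = SimConfig(seed=8, circle_count=2, n_background_reads=10,
                    chrom_length=30_000)
    toy, _, _, _ = simulate_backsplice_reads(cfg)
    write_gtf(toy, tmp_path / "ann.gtf")
    index = parse_gtf_exons(tmp_path / "ann.gtf")
    for g in toy.genes:
        for es, ee in g["exons"]:
            assert es in index.exon_starts[g["chrom"]]
            assert ee in index.exon_ends[g["chrom"]]
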