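"""Back-splice circRNA junction calling from SAM alignments.

A read spanning a back-splice junction (BSJ) aligns in two pieces whose
genomic order is reversed relative to the read (chiastic): the aligner
anchors one piece and soft/hard-clips the other, leaving a CIGAR of the
form xS yM (left clip) or xM yS (right clip); a circle shorter than the
read yields xS yM zS (double clip).  The caller scans clipped records,
re-matches the clipped segment against the reference near the anchor,
keeps only chiastic configurations, applies the paired-end mate
containment constraint, reads the splice-signal dinucleotides (GT-AG
canonical, AT-AC weak) strand-aware at the junction flanks, optionally
restricts junctions to annotated exon boundaries, and reports junctions
supported by at least ``min_reads`` distinct read names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from intervaltree import IntervalTree

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClipSignature:
    """Clip-pattern category of a CIGAR with the segment lengths in bases.

    For left_clip ("xS yM") x is the clip and y the match; for right_clip
    ("xM yS") x is the match and y the clip; for double_clip ("xS yM zS")
    x and z are the terminal clips around the match y.
    """

    category: str  # left_clip | right_clip | double_clip | none
    x: int = 0
    y: int = 0
    z: int = 0


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r} at offset {pos}")
        ops.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ValueError(f"malformed CIGAR {cigar!r} at offset {pos}")
    return ops


def classify_cigar(cigar: str) -> ClipSignature:
    """Classify a CIGAR string into its back-splice clip signature.

    Exactly "clip,match" -> left_clip; "match,clip" -> right_clip;
    "clip,match,clip" -> double_clip (clips may be S or H); anything else
    (pure match, internal indels, more blocks) -> none.
    """
    ops = parse_cigar(cigar)
    kinds = "".join("C" if op in "SH" else ("M" if op == "M" else "?") for _, op in ops)
    if kinds == "CM":
        return ClipSignature("left_clip", x=ops[0][0], y=ops[1][0])
    if kinds == "MC":
        return ClipSignature("right_clip", x=ops[0][0], y=ops[1][0])
    if kinds == "CMC":
        return ClipSignature("double_clip", x=ops[0][0], y=ops[1][0], z=ops[2][0])
    return ClipSignature("none")


@dataclass
class JunctionCandidate:
    """One read-level chiastic clip match supporting a putative BSJ."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    query_name: str
    paired: bool
    mate_chrom: str | None
    mate_pos: int | None  # 1-based leftmost mate base
    strand: str = "."
    signal: str = "none"
    source_gene: str | None = None


def _find_matches(haystack: str, needle: str, lo: int, hi: int) -> list[int]:
    """0-based start offsets of exact needle occurrences in haystack[lo:hi]."""
    out = []
    lo = max(lo, 0)
    hi = min(hi, len(haystack))
    pos = haystack.find(needle, lo, hi)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1, hi)
    return out


def detect_junction_candidates(
    records,
    genome: dict[str, str],
    window: int = 100_000,
    min_clip: int = 10,
    diagnostics: dict | None = None,
) -> list[JunctionCandidate]:
    """Scan clipped SAM records for chiastic (back-splice) configurations.

    For each record with a terminal clip of at least ``min_clip`` bases the
    clipped query segment is re-matched exactly against the reference
    within ``window`` bases of the anchor.  A candidate is emitted only in
    the chiastic order: a right-clip's clipped suffix must match strictly
    upstream of the anchor (circle start), a left-clip's clipped prefix
    strictly downstream (circle end).  Colinear matches (ordinary splices)
    yield no candidate; ambiguous re-matches (several chiastic hits) are
    discarded and tallied in ``diagnostics``.
    """
    if diagnostics is None:
        diagnostics = {}
    diagnostics.setdefault("ambiguous", 0)
    diagnostics.setdefault("hard_clip_skipped", 0)
    candidates: list[JunctionCandidate] = []
    for rec in records:
        if rec.is_unmapped:
            continue
        sig = classify_cigar(rec.cigarstring)
        if sig.category == "none":
            continue
        chrom = rec.reference_name
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        gseq = genome[chrom]
        seq = rec.query_sequence  # soft-clipped bases included
        has_hard = "H" in rec.cigarstring
        if has_hard:
            # hard-clipped bases are not stored in SEQ; cannot re-match
            diagnostics["hard_clip_skipped"] += 1
            continue
        pos1 = rec.reference_start + 1
        paired = rec.is_paired
        mate_chrom = rec.next_reference_name if paired and rec.next_reference_id >= 0 else None
        mate_pos = rec.next_reference_start + 1 if paired and rec.next_reference_id >= 0 else None

        def emit(start: int, end: int) -> None:
            candidates.append(
                JunctionCandidate(
                    chrom=chrom,
                    start=start,
                    end=end,
                    query_name=rec.query_name,
                    paired=paired,
                    mate_chrom=mate_chrom,
                    mate_pos=mate_pos,
                )
            )

        if sig.category == "left_clip":
            if sig.x < min_clip:
                continue
            anchor_start, anchor_end = pos1, pos1 + sig.y - 1
            clip = seq[: sig.x]
            # chiastic: clip (circle tail) must match ending downstream of anchor
            hits = _find_matches(gseq, clip, anchor_start - 1, anchor_end + window)
            hits = [h for h in hits if h + sig.x > anchor_end]  # match end beyond anchor
            if len(hits) > 1:
                diagnostics["ambiguous"] += 1
                continue
            if hits:
                emit(anchor_start, hits[0] + sig.x)
        elif sig.category == "right_clip":
            if sig.y < min_clip:
                continue
            anchor_start, anchor_end = pos1, pos1 + sig.x - 1
            clip = seq[sig.x :]
            # chiastic: clip (circle head) must match starting upstream of anchor
            hits = _find_matches(gseq, clip, anchor_start - 1 - window, anchor_end)
            hits = [h for h in hits if h + 1 < anchor_start]
            if len(hits) > 1:
                diagnostics["ambiguous"] += 1
                continue
            if hits:
                emit(hits[0] + 1, anchor_end)
        else:  # double_clip: single-exon / long-short-long circle
            if sig.x < min_clip or sig.z < min_clip:
                continue
            anchor_start, anchor_end = pos1, pos1 + sig.y - 1
            left_clip_seq = seq[: sig.x]
            right_clip_seq = seq[sig.x + sig.y :]
            tail_ok = gseq[anchor_end - sig.x : anchor_end] == left_clip_seq
            head_ok = gseq[anchor_start - 1 : anchor_start - 1 + sig.z] == right_clip_seq
            if tail_ok and head_ok:
                emit(anchor_start, anchor_end)
    return candidates


def mate_constraint(candidates: list[JunctionCandidate]) -> list[JunctionCandidate]:
    """Paired-end containment filter: the mate must map inside the circle.

    For paired supporting reads the mate's leftmost position must fall
    within [start, end] on the same chromosome; single-end records bypass
    the filter.
    """
    kept = []
    for c in candidates:
        if not c.paired:
            kept.append(c)
            continue
        if c.mate_chrom != c.chrom or c.mate_pos is None:
            continue
        if c.start <= c.mate_pos <= c.end:
            kept.append(c)
    return kept


def splice_signal_check(
    genome: dict[str, str], chrom: str, start: int, end: int, strand: str
) -> str:
    """Classify the BSJ flank dinucleotides as GT-AG, AT-AC, or none.

    The donor dinucleotide sits immediately 3' of the donor end of the
    circle and the acceptor dinucleotide immediately 5' of the acceptor
    end, read on the given strand (reverse-complemented for '-').  Within
    2 bases of a chromosome edge no signal is readable.
    """
    gseq = genome[chrom]
    if start - 3 < 0 or end + 2 > len(gseq):
        return "none"
    donor_plus = gseq[end : end + 2]  # bases end+1..end+2
    acceptor_plus = gseq[start - 3 : start - 1]  # bases start-2..start-1
    if strand == "-":
        donor, acceptor = revcomp(acceptor_plus), revcomp(donor_plus)
    else:
        donor, acceptor = donor_plus, acceptor_plus
    if (donor, acceptor) == ("GT", "AG"):
        return "GT-AG"
    if (donor, acceptor) == ("AT", "AC"):
        return "AT-AC"
    return "none"


def assign_signals(
    candidates: list[JunctionCandidate], genome: dict[str, str]
) -> list[JunctionCandidate]:
    """Assign strand and splice-signal class to each candidate.

    The plus strand is tried first; if neither strand shows a signal the
    candidate keeps strand '.' and signal 'none'.
    """
    for c in candidates:
        plus = splice_signal_check(genome, c.chrom, c.start, c.end, "+")
        minus = splice_signal_check(genome, c.chrom, c.start, c.end, "-")
        if plus != "none":
            c.strand, c.signal = "+", plus
        elif minus != "none":
            c.strand, c.signal = "-", minus
        else:
            c.strand, c.signal = ".", "none"
    return candidates


@dataclass
class ExonIndex:
    """Exon boundary sets and gene intervals extracted from a GTF."""

    exon_starts: dict[str, set[int]] = field(default_factory=dict)
    exon_ends: dict[str, set[int]] = field(default_factory=dict)
    genes: dict[str, IntervalTree] = field(default_factory=dict)


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def parse_gtf_exons(path: str | Path) -> ExonIndex:
    """Read exon boundaries (1-based inclusive) and gene spans from a GTF."""
    index = ExonIndex()
    gene_spans: dict[tuple[str, str], list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _, ftype, start, end, _, _, _, attrs = fields[:9]
            start, end = int(start), int(end)
            m = _GTF_GENE_ID.search(attrs)
            gid = m.group(1) if m else None
            if ftype == "exon":
                index.exon_starts.setdefault(chrom, set()).add(start)
                index.exon_ends.setdefault(chrom, set()).add(end)
                if gid:
                    span = gene_spans.setdefault((chrom, gid), [start, end])
                    span[0] = min(span[0], start)
                    span[1] = max(span[1], end)
            elif ftype == "gene" and gid:
                span = gene_spans.setdefault((chrom, gid), [start, end])
                span[0] = min(span[0], start)
                span[1] = max(span[1], end)
    for (chrom, gid), (s, e) in gene_spans.items():
        index.genes.setdefault(chrom, IntervalTree()).addi(s, e + 1, gid)
    return index


def annotation_filter(
    candidates: list[JunctionCandidate],
    index: ExonIndex,
    tolerance: int = 0,
    keep_intergenic: bool = False,
) -> list[JunctionCandidate]:
    """Keep candidates whose BSJ ends sit on annotated exon boundaries.

    The junction start must lie within ``tolerance`` bases of an annotated
    exon start and the end within ``tolerance`` of an exon end.  The source
    gene is assigned from the smallest gene interval containing the circle;
    unannotated candidates are kept only with ``keep_intergenic``.
    """
    kept = []
    for c in candidates:
        starts = index.exon_starts.get(c.chrom, set())
        ends = index.exon_ends.get(c.chrom, set())
        on_start = any(abs(c.start - b) <= tolerance for b in starts)
        on_end = any(abs(c.end - b) <= tolerance for b in ends)
        if on_start and on_end:
            tree = index.genes.get(c.chrom)
            if tree is not None:
                hits = [iv for iv in tree.overlap(c.start, c.end + 1)
                        if iv.begin <= c.start and iv.end >= c.end + 1]
                if hits:
                    c.source_gene = min(hits, key=lambda iv: iv.end - iv.begin).data
            kept.append(c)
        elif keep_intergenic:
            kept.append(c)
    return kept


@dataclass
class CircCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    signal: str
    junction_reads: int
    source_gene: str | None = None


def call_circles(
    candidates: list[JunctionCandidate],
    min_reads: int = 2,
    require_gt_ag: bool = False,
) -> list[CircCall]:
    """Group candidates by junction and emit calls with enough read support.

    Junction read support counts distinct query names, so a read pair whose
    two mates both clip at the junction contributes once.  Calls are sorted
    by chromosome then start.
    """
    grouped: dict[tuple[str, int, int, str], dict] = {}
    for c in candidates:
        if require_gt_ag and c.signal != "GT-AG":
            continue
        key = (c.chrom, c.start, c.end, c.strand)
        g = grouped.setdefault(key, {"names": set(), "signal": c.signal, "gene": c.source_gene})
        g["names"].add(c.query_name)
        if g["gene"] is None:
            g["gene"] = c.source_gene
    calls = []
    for (chrom, start, end, strand), g in grouped.items():
        if start >= end:
            continue
        if len(g["names"]) >= min_reads:
            calls.append(
                CircCall(chrom, start, end, strand, g["signal"], len(g["names"]), g["gene"])
            )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return calls


def run_caller(
    sam_path: str | Path,
    genome: dict[str, str],
    gtf_path: str | Path | None = None,
    min_reads: int = 2,
    window: int = 100_000,
    min_clip: int = 10,
    tolerance: int = 0,
    keep_intergenic: bool = False,
    require_gt_ag: bool = False,
    diagnostics: dict | None = None,
) -> list[CircCall]:
    """Full back-splice pipeline: scan, mate filter, signals, annotation, call."""
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        records = list(fh)
    candidates = detect_junction_candidates(
        records, genome, window=window, min_clip=min_clip, diagnostics=diagnostics
    )
    candidates = mate_constraint(candidates)
    candidates = assign_signals(candidates, genome)
    if gtf_path is not None:
        index = parse_gtf_exons(gtf_path)
        candidates = annotation_filter(
            candidates, index, tolerance=tolerance, keep_intergenic=keep_intergenic
        )
    return call_circles(candidates, min_reads=min_reads, require_gt_ag=require_gt_ag)


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def write_calls_tsv(calls: list[CircCall], path: str | Path) -> None:
    lines = ["chrom\tstart\tend\tstrand\tsignal\tjunction_reads\tsource_gene"]
    for c in calls:
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.signal}\t{c.junction_reads}\t{c.source_gene or '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_calls_bed(calls: list[CircCall], path: str | Path) -> None:
    """BED6 (0-based half-open), score = junction read count."""
    lines = []
    for i, c in enumerate(calls):
        lines.append(
            f"{c.chrom}\t{c.start - 1}\t{c.end}\tcirc_{i + 1}\t{c.junction_reads}\t{c.strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
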