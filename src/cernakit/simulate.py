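"""Synthetic whole-transcriptome study generator with known planted truth.

Emulates a two-breed skin transcriptome design: two groups ("A" and "B",
standing for the two breeds) with a small number of pooled libraries per
group, four RNA classes (mRNA, lncRNA, circRNA, miRNA) counted per library,
two independent miRNA-target predictor tables, a toy genome/annotation with
aligned reads carrying back-splice junction signatures, and bench-assay
tables (qPCR CT values, melanin standard absorbances).

Every generator is a pure function of :class:`SimConfig`; the planted truth
(differential features, sponge–miRNA–mRNA triplets, back-splice junctions)
is returned alongside the data so downstream stages can be scored against
it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .expression import CountMatrix

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")

# seed-stream tags so each generator draws from its own independent stream
_STREAM_COUNTS = 1
_STREAM_TARGETS = 2
_STREAM_GENOME = 3
_STREAM_ASSAYS = 4


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated two-group whole-transcriptome study.

    Defaults describe the "easy regime": 3 libraries per group, NB counts
    with moderate dispersion, a planted differential fraction at |log2FC| = 2,
    and 10 planted sponge–mRNA pairs each sharing 5 miRNAs whose expression
    is tied through a per-sample latent factor (sponge and mRNA up together,
    miRNA down); the latent amplitude is calibrated so the latent-only
    population Pearson(sponge, mRNA) is ~0.9 at the default dispersion,
    putting realized pair statistics comfortably past the screening
    thresholds.
    """

    seed: int = 0
    n_mrna: int = 500
    n_lncrna: int = 120
    n_circrna: int = 90
    n_mirna: int = 150
    samples_per_group: int = 3
    nb_mean_log_range: tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.02
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    n_triplets: int = 10
    mirnas_per_triplet: int = 5
    triplet_latent_sd: float = 0.5
    triplet_base_mean: float = 300.0
    decoy_target_fraction: float = 0.5
    circle_count: int = 20
    reads_per_junction: int = 10
    read_length: int = 100
    n_background_reads: int = 2000
    chrom_length: int = 100_000
    n_chroms: int = 2
    qpcr_fold_change: float = 4.0
    qpcr_ct_sd: float = 0.05
    melanin_slope: float = 1.6
    melanin_intercept: float = 0.05
    melanin_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_circrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        lo, hi = self.nb_mean_log_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("nb_mean_log_range must be a finite (lo, hi) pair")
        if not (np.isfinite(self.nb_dispersion) and self.nb_dispersion > 0):
            raise ValueError("nb_dispersion must be a positive real")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (np.isfinite(self.de_log2fc) and self.de_log2fc >= 0):
            raise ValueError("de_log2fc must be a nonnegative real")
        if not 0.0 <= self.decoy_target_fraction < 1.0:
            raise ValueError("decoy_target_fraction must lie in [0, 1)")
        if self.n_triplets < 0 or self.mirnas_per_triplet < 1:
            raise ValueError("n_triplets >= 0 and mirnas_per_triplet >= 1 required")
        if self.circle_count < 0 or self.reads_per_junction < 1:
            raise ValueError("circle_count >= 0 and reads_per_junction >= 1 required")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")

    @property
    def sample_ids(self) -> list[str]:
        k = self.samples_per_group
        return [f"A{i + 1}" for i in range(k)] + [f"B{i + 1}" for i in range(k)]

    @property
    def groups(self) -> pd.Series:
        k = self.samples_per_group
        return pd.Series(["A"] * k + ["B"] * k, index=self.sample_ids, name="group")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class SimTruth:
    """Planted ground truth of one simulated study."""

    de_features: dict[str, dict] = field(default_factory=dict)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    pair_mirnas: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    bsj_truth: list[dict] = field(default_factory=list)

    @property
    def true_interactions(self) -> set[tuple[str, str]]:
        """All planted (miRNA, target) links implied by the triplets."""
        pairs: set[tuple[str, str]] = set()
        for sponge, mirna, mrna in self.triplets:
            pairs.add((mirna, sponge))
            pairs.add((mirna, mrna))
        return pairs

    def to_json(self) -> str:
        payload = {
            "de_features": self.de_features,
            "triplets": [list(t) for t in self.triplets],
            "pair_mirnas": {f"{s}\t{g}": m for (s, g), m in self.pair_mirnas.items()},
            "bsj_truth": self.bsj_truth,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _feature_ids(cls: str, n: int) -> list[str]:
    return [f"{cls}_{i + 1:05d}" for i in range(n)]


def simulate_counts(config: SimConfig) -> tuple[dict[str, CountMatrix], SimTruth]:
    """Draw NB count matrices for the four RNA classes and record planted truth.

    Counts are NB(mean, dispersion) with per-feature means log-uniform over
    ``10**nb_mean_log_range``.  A ``de_fraction`` of features per class has
    its group-B mean multiplied by ``2**(+/- de_log2fc)``.  Planted
    sponge--miRNA--mRNA structures tie member means to a shared per-sample
    latent factor so the sponge and mRNA co-vary positively and the miRNA
    anti-varies, on top of coherent group shifts (sponge/mRNA up in B, miRNA
    down) when the members are seated in the DE set.
    """
    rng = config.rng(_STREAM_COUNTS)
    truth = SimTruth()
    samples = config.sample_ids
    n_samples = len(samples)
    group_b = np.array([g == "B" for g in config.groups])

    ids = {
        "mRNA": _feature_ids("mRNA", config.n_mrna),
        "lncRNA": _feature_ids("lncRNA", config.n_lncrna),
        "circRNA": _feature_ids("circRNA", config.n_circrna),
        "miRNA": _feature_ids("miRNA", config.n_mirna),
    }

    # seat planted pair members: sponges alternate lncRNA/circRNA
    n_pairs = config.n_triplets
    k_mir = config.mirnas_per_triplet
    if n_pairs * k_mir > config.n_mirna:
        raise ValueError("not enough miRNAs to seat the planted triplets")
    sponge_lnc = [ids["lncRNA"][i] for i in range((n_pairs + 1) // 2)]
    sponge_circ = [ids["circRNA"][i] for i in range(n_pairs // 2)]
    sponges: list[str] = []
    for i in range(n_pairs):
        sponges.append(sponge_lnc[i // 2] if i % 2 == 0 else sponge_circ[i // 2])
    pair_mrnas = [ids["mRNA"][i] for i in range(n_pairs)]
    pair_mirnas = [
        [ids["miRNA"][i * k_mir + j] for j in range(k_mir)] for i in range(n_pairs)
    ]
    planted_members: dict[str, list[tuple[str, str]]] = {c: [] for c in RNA_CLASSES}
    for i in range(n_pairs):
        sponge = sponges[i]
        cls = "lncRNA" if sponge.startswith("lncRNA") else "circRNA"
        planted_members[cls].append((sponge, "up"))
        planted_members["mRNA"].append((pair_mrnas[i], "up"))
        for m in pair_mirnas[i]:
            planted_members["miRNA"].append((m, "down"))
        truth.pair_mirnas[(sponge, pair_mrnas[i])] = list(pair_mirnas[i])
        for m in pair_mirnas[i]:
            truth.triplets.append((sponge, m, pair_mrnas[i]))

    # per-pair latent factors, one value per sample; centered within each
    # group so the co-expression structure is orthogonal to the group
    # contrast (the planted fold change stays exactly de_log2fc)
    latent = rng.standard_normal((n_pairs, n_samples))
    if n_pairs:
        latent[:, ~group_b] -= latent[:, ~group_b].mean(axis=1, keepdims=True)
        latent[:, group_b] -= latent[:, group_b].mean(axis=1, keepdims=True)
    pair_of: dict[str, list[int]] = {}
    sign_of: dict[str, float] = {}
    for i in range(n_pairs):
        for fid, sgn in ((sponges[i], 1.0), (pair_mrnas[i], 1.0)):
            pair_of.setdefault(fid, []).append(i)
            sign_of[fid] = sgn
        for m in pair_mirnas[i]:
            pair_of.setdefault(m, []).append(i)
            sign_of[m] = -1.0

    matrices: dict[str, CountMatrix] = {}
    for cls in RNA_CLASSES:
        n = len(ids[cls])
        lo, hi = config.nb_mean_log_range
        base = 10.0 ** rng.uniform(lo, hi, size=n)
        id_list = ids[cls]
        index = {fid: i for i, fid in enumerate(id_list)}
        for fid, _ in planted_members[cls]:
            base[index[fid]] = config.triplet_base_mean

        # choose the DE set: planted members first, then random fill
        n_de = int(round(config.de_fraction * n))
        de_ids: list[str] = []
        directions: dict[str, str] = {}
        if config.de_fraction > 0:
            for fid, direction in planted_members[cls]:
                de_ids.append(fid)
                directions[fid] = direction
            n_de = max(n_de, len(de_ids))
            pool = [f for f in id_list if f not in directions]
            extra = rng.choice(len(pool), size=n_de - len(de_ids), replace=False)
            for j in sorted(extra):
                fid = pool[j]
                de_ids.append(fid)
                directions[fid] = "up" if rng.random() < 0.5 else "down"

        mu = np.tile(base[:, None], (1, n_samples))
        for fid in de_ids:
            i = index[fid]
            fold = 2.0**config.de_log2fc
            if directions[fid] == "down":
                fold = 1.0 / fold
            mu[i, group_b] *= fold
            truth.de_features[fid] = {
                "class": cls,
                "direction": directions[fid],
                "log2fc": config.de_log2fc if directions[fid] == "up" else -config.de_log2fc,
            }
        for fid, _ in planted_members[cls]:
            i = index[fid]
            for p in pair_of[fid]:
                mu[i, :] *= np.exp(
                    sign_of[fid] * config.triplet_latent_sd * latent[p, :]
                )

        n_param = 1.0 / config.nb_dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
        df = pd.DataFrame(counts, index=pd.Index(id_list, name="feature_id"), columns=samples)
        matrices[cls] = CountMatrix(
            counts=df,
            classes=pd.Series(cls, index=df.index, name="rna_class"),
            groups=config.groups,
        )
    return matrices, truth


def simulate_target_tables(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit two predictor tables whose intersection is exactly the planted links.

    Both tables contain every planted miRNA-target interaction; on top, a
    ``decoy_target_fraction`` of each table's rows are decoys unique to that
    table (disjoint between tables), so set intersection removes them.
    """
    rng = config.rng(_STREAM_TARGETS)
    true_pairs = sorted(truth.true_interactions)
    d = config.decoy_target_fraction
    n_true = len(true_pairs)
    n_decoy = int(round(n_true * d / (1.0 - d))) if d > 0 else 0

    mirna_ids = _feature_ids("miRNA", config.n_mirna)
    target_ids = (
        _feature_ids("mRNA", config.n_mrna)
        + _feature_ids("lncRNA", config.n_lncrna)
        + _feature_ids("circRNA", config.n_circrna)
    )
    forbidden = set(true_pairs)
    decoys: list[tuple[str, str]] = []
    while len(decoys) < 2 * n_decoy:
        pair = (
            mirna_ids[rng.integers(len(mirna_ids))],
            target_ids[rng.integers(len(target_ids))],
        )
        if pair not in forbidden:
            decoys.append(pair)
            forbidden.add(pair)

    def table(tool: str, own_decoys: list[tuple[str, str]]) -> pd.DataFrame:
        rows = [(m, t, float(np.round(rng.uniform(0.5, 1.0), 4)), tool) for m, t in true_pairs]
        rows += [(m, t, float(np.round(rng.uniform(0.5, 1.0), 4)), tool) for m, t in own_decoys]
        return pd.DataFrame(rows, columns=["mirna_id", "target_id", "score", "tool"])

    table_a = table("predictorA", decoys[:n_decoy])
    table_b = table("predictorB", decoys[n_decoy:])
    return table_a, table_b


# --------------------------------------------------------------------------
# toy genome / annotation / back-splice reads


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    genes: list[dict]  # chrom, gene_id, strand, exons [(start, end) 1-based]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.array(list("ACGT"))


def _build_toy_genome(config: SimConfig, rng: np.random.Generator) -> ToyGenome:
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs: dict[str, np.ndarray] = {
        c: _random_sequence(rng, config.chrom_length) for c in chroms
    }
    genes: list[dict] = []
    gene_i = 0
    for chrom in chroms:
        pos = 500  # 0-based cursor
        while pos < config.chrom_length - 4000:
            n_exons = int(rng.integers(3, 7))
            exons: list[tuple[int, int]] = []
            cursor = pos
            for _ in range(n_exons):
                elen = int(rng.integers(150, 401))
                exons.append((cursor + 1, cursor + elen))  # 1-based inclusive
                cursor += elen + int(rng.integers(100, 301))
            if exons[-1][1] >= config.chrom_length - 500:
                break
            gene_i += 1
            strand = "+" if rng.random() < 0.7 else "-"
            genes.append(
                {
                    "chrom": chrom,
                    "gene_id": f"gene_{gene_i:04d}",
                    "strand": strand,
                    "exons": exons,
                }
            )
            pos = exons[-1][1] + int(rng.integers(400, 1200))
    return ToyGenome({c: s for c, s in seqs.items()}, genes)


def simulate_backsplice_reads(
    config: SimConfig,
) -> tuple[ToyGenome, list[dict], list[pysam.AlignedSegment], list[dict]]:
    """Build a toy genome + annotation and aligned reads with planted BSJs.

    For each planted circle (an exon-bounded interval of one gene) the genome
    is edited to carry canonical splice dinucleotides at the circle flanks
    (GT..AG read on the gene strand), and ``reads_per_junction`` paired reads
    are synthesized across the back-splice point: read = circle tail + circle
    head, emitted as a soft-clipped alignment (``xS yM`` anchored at the
    circle start or ``xM yS`` anchored at the circle end) whose mate maps
    inside the circle.  Linear background reads carry full-match CIGARs.

    Returns (genome, gtf_records, sam_records, bsj_truth).
    """
    rng = config.rng(_STREAM_GENOME)
    toy = _build_toy_genome(config, rng)
    seqs: dict[str, np.ndarray] = {
        c: np.array(list(s)) if isinstance(s, str) else s for c, s in toy.sequences.items()
    }
    base_arrays = {c: _BASES[s] if s.dtype == np.int8 else s for c, s in seqs.items()}

    # pick circle host genes and exon-bounded intervals
    L = config.read_length
    candidates = []
    for g in toy.genes:
        exons = g["exons"]
        for i in range(len(exons)):
            for j in range(i, len(exons)):
                s, e = exons[i][0], exons[j][1]
                if L + 50 <= e - s + 1 <= 1500:
                    candidates.append((g, s, e))
                    break
            else:
                continue
            break
    if config.circle_count > len(candidates):
        raise ValueError(
            f"cannot place {config.circle_count} circles; only {len(candidates)} host genes"
        )
    chosen_idx = rng.choice(len(candidates), size=config.circle_count, replace=False)
    bsj_truth: list[dict] = []
    for ci in sorted(chosen_idx):
        g, s, e = candidates[ci]
        chrom = g["chrom"]
        arr = base_arrays[chrom]
        if s - 3 < 0 or e + 2 > len(arr):
            raise ValueError("circle coordinates outside genome")
        if g["strand"] == "+":
            arr[s - 3 : s - 1] = list("AG")  # acceptor, 5' of start
            arr[e : e + 2] = list("GT")  # donor, 3' of end
        else:
            arr[s - 3 : s - 1] = list("AC")
            arr[e : e + 2] = list("CT")
        bsj_truth.append(
            {"chrom": chrom, "start": int(s), "end": int(e), "strand": g["strand"], "gene_id": g["gene_id"]}
        )

    genome = {c: "".join(a) for c, a in base_arrays.items()}
    toy.sequences = genome

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in sorted(genome)],
        }
    )
    tid = {c: i for i, c in enumerate(sorted(genome))}
    records: list[pysam.AlignedSegment] = []

    def make_record(
        name: str, chrom: str, pos1: int, cigar: str, seq: str, flag: int,
        mate_pos1: int | None = None,
    ) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.reference_id = tid[chrom]
        rec.reference_start = pos1 - 1
        rec.cigarstring = cigar
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        rec.mapping_quality = 60
        rec.flag = flag
        if mate_pos1 is not None:
            rec.next_reference_id = tid[chrom]
            rec.next_reference_start = mate_pos1 - 1
        else:
            rec.next_reference_id = -1
            rec.next_reference_start = -1
        return rec

    for k, bsj in enumerate(bsj_truth):
        chrom, s, e = bsj["chrom"], bsj["start"], bsj["end"]
        gseq = genome[chrom]
        for r in range(config.reads_per_junction):
            a = int(rng.integers(15, L - 14))  # clip/match split, both parts >= 15
            tail = gseq[e - a : e]  # last a bases of the circle
            head = gseq[s - 1 : s - 1 + (L - a)]
            seq = tail + head
            name = f"junc_{k + 1:03d}_{r + 1:02d}"
            mate_pos = int(rng.integers(s, e - L + 2))
            mate_seq = gseq[mate_pos - 1 : mate_pos - 1 + L]
            if r % 2 == 0:
                # anchor on circle head: clipped prefix is the tail segment
                rec = make_record(name, chrom, s, f"{a}S{L - a}M", seq, 1 | 2 | 64, mate_pos)
            else:
                # anchor on circle tail: clipped suffix is the head segment
                rec = make_record(
                    name, chrom, e - a + 1, f"{a}M{L - a}S", seq, 1 | 2 | 64, mate_pos
                )
            mate = make_record(name, chrom, mate_pos, f"{L}M", mate_seq, 1 | 2 | 128, rec.reference_start + 1)
            records.append(rec)
            records.append(mate)

    chrom_list = sorted(genome)
    for b in range(config.n_background_reads):
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        pos = int(rng.integers(1, len(genome[chrom]) - L))
        seq = genome[chrom][pos - 1 : pos - 1 + L]
        records.append(make_record(f"bg_{b + 1:05d}", chrom, pos, f"{L}M", seq, 0))

    gtf_records = _gtf_records(toy)
    return toy, gtf_records, records, bsj_truth


def _gtf_records(toy: ToyGenome) -> list[dict]:
    records = []
    for g in toy.genes:
        records.append(g)
    return records


def write_gtf(toy: ToyGenome, path: str | Path) -> None:
    """Write the toy annotation as Ensembl-dialect GTF (1-based inclusive)."""
    lines = []
    for g in toy.genes:
        gid, tid_ = g["gene_id"], g["gene_id"] + ".t1"
        start = g["exons"][0][0]
        end = g["exons"][-1][1]
        attrs_g = f'gene_id "{gid}";'
        attrs_t = f'gene_id "{gid}"; transcript_id "{tid_}";'
        lines.append(
            f"{g['chrom']}\tcernakit\tgene\t{start}\t{end}\t.\t{g['strand']}\t.\t{attrs_g}"
        )
        lines.append(
            f"{g['chrom']}\tcernakit\ttranscript\t{start}\t{end}\t.\t{g['strand']}\t.\t{attrs_t}"
        )
        for es, ee in g["exons"]:
            lines.append(
                f"{g['chrom']}\tcernakit\texon\t{es}\t{ee}\t.\t{g['strand']}\t.\t{attrs_t}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(toy: ToyGenome, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(toy.sequences[c]), id=c, description="") for c in sorted(toy.sequences)]
    SeqIO.write(recs, str(path), "fasta")


def write_sam(records: list[pysam.AlignedSegment], path: str | Path) -> None:
    if not records:
        raise ValueError("no records to write")
    with pysam.AlignmentFile(str(path), "w", header=records[0].header) as fh:
        for rec in records:
            fh.write(rec)


# --------------------------------------------------------------------------
# assay tables


def simulate_assay_tables(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a qPCR CT table and a melanin standard-curve absorbance table.

    The CT table carries one target gene and one reference gene per sample
    with a planted group-B fold change of ``qpcr_fold_change`` (reference
    gene flat across groups).  The absorbance table follows a known linear
    working curve over the standard melanin concentration grid
    0–0.6 mg/mL with Gaussian noise.
    """
    rng = config.rng(_STREAM_ASSAYS)
    rows = []
    for sample in config.sample_ids:
        group = "A" if sample.startswith("A") else "B"
        ref_ct = 16.0 + rng.normal(0.0, config.qpcr_ct_sd)
        target_ct = 24.0 + rng.normal(0.0, config.qpcr_ct_sd)
        if group == "B":
            target_ct -= np.log2(config.qpcr_fold_change)
        rows.append((sample, group, "TARGET1", "target", round(float(target_ct), 4)))
        rows.append((sample, group, "ACTB", "reference", round(float(ref_ct), 4)))
    ct = pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "role", "ct"])

    concs = [0, 0.02, 0.04, 0.06, 0.08, 0.1, 0.12, 0.14, 0.16, 0.2, 0.3, 0.4, 0.5, 0.6]
    absorb = [
        round(float(config.melanin_slope * c + config.melanin_intercept
                    + rng.normal(0.0, config.melanin_noise_sd)), 5)
        for c in concs
    ]
    standards = pd.DataFrame({"conc_mg_per_ml": concs, "absorbance": absorb})
    return ct, standards


# --------------------------------------------------------------------------
# bundle writer


def write_bundle(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Run all four generators and write every artifact under ``outdir``.

    Files: counts.tsv, annotation.tsv, design.tsv, targets_a.tsv,
    targets_b.tsv, genome.fa, annotation.gtf, reads.sam, ct.tsv,
    melanin_standards.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, truth = simulate_counts(config)
    combined = pd.concat(
        [
            m.counts.assign(rna_class=m.classes).reset_index()[
                ["feature_id", "rna_class"] + config.sample_ids
            ]
            for m in matrices.values()
        ],
        ignore_index=True,
    )
    combined.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    config.groups.rename_axis("sample_id").reset_index().to_csv(
        outdir / "design.tsv", sep="\t", index=False
    )
    feature_annotation(config).to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    table_a, table_b = simulate_target_tables(config, truth)
    table_a.to_csv(outdir / "targets_a.tsv", sep="\t", index=False)
    table_b.to_csv(outdir / "targets_b.tsv", sep="\t", index=False)

    toy, _, records, bsj = simulate_backsplice_reads(config)
    truth.bsj_truth = bsj
    write_fasta(toy, outdir / "genome.fa")
    write_gtf(toy, outdir / "annotation.gtf")
    write_sam(records, outdir / "reads.sam")

    ct, standards = simulate_assay_tables(config)
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    standards.to_csv(outdir / "melanin_standards.tsv", sep="\t", index=False)

    (outdir / "truth.json").write_text(truth.to_json())
    return truth


def feature_annotation(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-feature annotation (length, exon count, biotype).

    Planted sponge lncRNAs are guaranteed to pass the lncRNA candidate
    filter (length > 200 and >= 2 exons); a tail of decoy lncRNAs is given
    short lengths or single exons so the filter has work to do.
    """
    rng = config.rng(5)
    rows = []
    n_planted_lnc = (config.n_triplets + 1) // 2
    for i, fid in enumerate(_feature_ids("mRNA", config.n_mrna)):
        rows.append((fid, int(rng.integers(500, 5001)), int(rng.integers(2, 16)), "mRNA"))
    for i, fid in enumerate(_feature_ids("lncRNA", config.n_lncrna)):
        if i < n_planted_lnc:
            length, exons = int(rng.integers(500, 3001)), int(rng.integers(2, 6))
        elif rng.random() < 0.1:
            length, exons = int(rng.integers(100, 201)), int(rng.integers(1, 3))
        elif rng.random() < 0.1:
            length, exons = int(rng.integers(300, 3001)), 1
        else:
            length, exons = int(rng.integers(201, 3001)) + 1, int(rng.integers(2, 6))
        rows.append((fid, length, exons, "lncRNA"))
    for fid in _feature_ids("circRNA", config.n_circrna):
        rows.append((fid, int(rng.integers(200, 1501)), int(rng.integers(1, 6)), "circRNA"))
    for fid in _feature_ids("miRNA", config.n_mirna):
        rows.append((fid, int(rng.integers(18, 31)), 1, "miRNA"))
    return pd.DataFrame(rows, columns=["feature_id", "length", "exon_count", "biotype"])


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "nb_mean_log_range" in data:
        data["nb_mean_log_range"] = tuple(data["nb_mean_log_range"])
    return SimConfig(**data)


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["nb_mean_log_range"] = list(d["nb_mean_log_range"])
    return d
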