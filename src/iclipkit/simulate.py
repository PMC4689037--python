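"""Synthetic-data generator for the whole pipeline.

Produces a toy genome with non-overlapping multi-exon gene models, barcoded
crosslink-truncation reads with PCR duplication, regulated/control/population
cassette-exon sets with planted trimer pairs, and ground-truth records for
parameter-recovery tests. All outputs are deterministic functions of the
configuration (including its seed).

Gene layout: the first exon is 5'UTR, the last exon is 3'UTR, and every
internal exon is ORF, separated by introns; region classes therefore tile
each gene exactly. A configurable fraction of genes are single-block ncRNAs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotate import Annotation, Gene, Region
from .exonsets import ExonRecord
from .io import revcomp
from .reads import BARCODE_BLOCK

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


class SimSizingError(ValueError):
    """Requested gene content cannot be packed into the genome budget."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 10
    exons_per_gene: int = 3
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (200, 600)
    utr_len_range: tuple[int, int] = (80, 160)
    intergenic_gap_range: tuple[int, int] = (300, 800)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ncrna_gene_fraction: float = 0.15
    max_genome_len: int | None = None

    crosslink_motif: str = "GAAGA"
    crosslink_offset: int = 1     # crosslink nt within the motif (first A)
    motif_site_fraction: float = 0.0
    n_crosslink_events: int = 1000
    pcr_duplication_mean: float = 0.0
    read_len: int = 50
    barcode_index: str = "AACC"
    sequencing_error_rate: float = 0.0
    restrict_to_full_inserts: bool = True

    n_regulated_exons: int = 100
    n_control_exons: int = 100
    n_population_exons: int = 2000
    pair_plant_rate: float = 0.0
    intron_flank_len: int = 150

    def __post_init__(self):
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for name in ("motif_site_fraction", "pair_plant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("exon_len_range", "intron_len_range", "utr_len_range",
                     "intergenic_gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) pair")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exons_per_gene < 3:
            raise ValueError("exons_per_gene must be >= 3")
        if self.read_len <= BARCODE_BLOCK:
            raise ValueError("read_len must exceed the 9-nt barcode block")
        if len(self.barcode_index) != 4:
            raise ValueError("barcode_index must be 4 nt")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass
class CdnaRecord:
    chrom: str
    strand: str
    position: int        # crosslink nucleotide
    barcode: str
    n_copies: int        # total reads emitted for this cDNA
    truncated: bool
    from_motif: bool


@dataclass
class SimTruth:
    planted_crosslinks: list[tuple[str, str, int]] = field(default_factory=list)
    unique_cdna_count: int = 0
    cdna_records: list[CdnaRecord] = field(default_factory=list)
    planted_pair_exons: list[tuple[str, int, int, str]] = field(default_factory=list)
    qualifying_control_exons: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, length: int,
              composition: tuple[float, ...]) -> str:
    return "".join(rng.choice(BASES, size=length, p=composition))


def make_genome(cfg: SimConfig) -> tuple[dict[str, str], Annotation]:
    """Build a single-chromosome toy genome and its tiling gene models."""
    rng = np.random.default_rng(cfg.seed)
    cursor = int(rng.integers(*cfg.intergenic_gap_range))
    genes: list[Gene] = []
    for gi in range(cfg.n_genes):
        gid = f"gene{gi:04d}"
        strand = str(rng.choice(["+", "-"]))
        is_ncrna = rng.random() < cfg.ncrna_gene_fraction
        regions: list[Region] = []
        pos = cursor
        if is_ncrna:
            length = int(sum(rng.integers(*cfg.exon_len_range, size=3)))
            regions.append(Region(pos, pos + length, "ncRNA"))
            pos += length
        else:
            utr5 = int(rng.integers(*cfg.utr_len_range))
            utr3 = int(rng.integers(*cfg.utr_len_range))
            orf_lens = [int(rng.integers(*cfg.exon_len_range))
                        for _ in range(cfg.exons_per_gene - 2)]
            intron_lens = [int(rng.integers(*cfg.intron_len_range))
                           for _ in range(cfg.exons_per_gene - 1)]
            # genomic order depends on strand: UTR5 at 5' end of transcript
            blocks = [("UTR5", utr5)]
            for orf_len, intron_len in zip(orf_lens, intron_lens):
                blocks.append(("intron", intron_len))
                blocks.append(("ORF", orf_len))
            blocks.append(("intron", intron_lens[-1]))
            blocks.append(("UTR3", utr3))
            if strand == "-":
                blocks = blocks[::-1]
            for cls, length in blocks:
                regions.append(Region(pos, pos + length, cls))
                pos += length
        genes.append(Gene(gid, "chr1", cursor, pos, strand, regions))
        cursor = pos + int(rng.integers(*cfg.intergenic_gap_range))
    total_len = cursor
    if cfg.max_genome_len is not None and total_len > cfg.max_genome_len:
        raise SimSizingError(
            f"gene content needs {total_len} nt but max_genome_len is "
            f"{cfg.max_genome_len}")
    genome = {"chr1": _rand_seq(rng, total_len, cfg.base_composition)}
    return genome, Annotation(genes)


def uniform_sites(genome: dict[str, str], n_sites: int,
                  rng: np.random.Generator):
    """Sites uniform over (position, strand) of the genome — a flat null."""
    from .reads import CrosslinkSite
    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms])
    probs = lens / lens.sum()
    idx = rng.choice(len(chroms), size=n_sites, p=probs)
    out = []
    for i in idx:
        pos = int(rng.integers(0, lens[i]))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(CrosslinkSite(chroms[i], strand, pos, 1))
    return out


# ---------------------------------------------------------------------------
# Crosslink reads
# ---------------------------------------------------------------------------

def _motif_instances(genome: dict[str, str], annotation: Annotation,
                     cfg: SimConfig) -> list[tuple[Gene, int]]:
    """(gene, crosslink position) for motif instances in exonic sequence.

    The crosslink nucleotide sits ``cfg.crosslink_offset`` into the motif in
    transcript orientation. Instances whose read would run past the gene end
    are excluded when ``restrict_to_full_inserts`` is set.
    """
    insert_len = cfg.read_len - BARCODE_BLOCK
    out = []
    for g in annotation.genes:
        chrom_seq = genome[g.chrom]
        for s, e in g.exon_blocks():
            seq = chrom_seq[s:e]
            if g.strand == "-":
                seq = revcomp(seq)
            i = seq.find(cfg.crosslink_motif)
            while i != -1:
                k = i + cfg.crosslink_offset
                pos = s + k if g.strand == "+" else e - 1 - k
                if cfg.restrict_to_full_inserts:
                    ok = (pos + 1 + insert_len <= g.end if g.strand == "+"
                          else pos - insert_len >= g.start)
                else:
                    ok = (pos + 1 < g.end if g.strand == "+"
                          else pos > g.start)
                if ok:
                    out.append((g, pos))
                i = seq.find(cfg.crosslink_motif, i + 1)
    return out


def _background_pool(annotation: Annotation, cfg: SimConfig
                     ) -> list[tuple[Gene, int, int]]:
    """(gene, lo, hi) candidate crosslink position ranges per gene."""
    insert_len = cfg.read_len - BARCODE_BLOCK
    pool = []
    for g in annotation.genes:
        if cfg.restrict_to_full_inserts:
            lo, hi = ((g.start, g.end - insert_len - 1) if g.strand == "+"
                      else (g.start + insert_len, g.end))
        else:
            lo, hi = ((g.start, g.end - 1) if g.strand == "+"
                      else (g.start + 1, g.end))
        if hi > lo:
            pool.append((g, lo, hi))
    return pool


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def plant_crosslink_reads(
    genome: dict[str, str],
    annotation: Annotation,
    cfg: SimConfig,
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Generate barcoded FASTQ reads from planted crosslink events.

    Each unique cDNA gets one random barcode and ``1 + Poisson(mean)``
    identical reads; the insert starts at the nucleotide immediately 3' of
    the crosslink on the transcript strand. Barcodes are drawn distinct per
    truncation position so the planted unique-cDNA count is exactly
    recoverable by deduplication. Returns ``(reads, truth)`` where reads are
    (read_id, sequence, quality) triples.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    insert_len = cfg.read_len - BARCODE_BLOCK
    motif_fraction = cfg.motif_site_fraction
    motif_pool = _motif_instances(genome, annotation, cfg)
    if motif_fraction > 0 and not motif_pool:
        logger.warning("crosslink motif %r absent from exonic sequence; "
                       "motif_site_fraction forced to 0", cfg.crosslink_motif)
        motif_fraction = 0.0
    bg_pool = _background_pool(annotation, cfg)
    if not bg_pool and motif_fraction < 1.0:
        raise SimSizingError("no gene-body positions can host a full read")

    bg_weights = np.array([hi - lo for _, lo, hi in bg_pool], dtype=float)
    bg_weights /= bg_weights.sum()

    truth = SimTruth()
    reads: list[tuple[str, str, str]] = []
    used_barcodes: dict[tuple[str, str, int], set[str]] = {}
    for i in range(cfg.n_crosslink_events):
        from_motif = motif_fraction > 0 and rng.random() < motif_fraction
        if from_motif:
            g, pos = motif_pool[int(rng.integers(len(motif_pool)))]
        else:
            gi = int(rng.choice(len(bg_pool), p=bg_weights))
            g, lo, hi = bg_pool[gi]
            pos = int(rng.integers(lo, hi))
        key = (g.chrom, g.strand, pos)
        used = used_barcodes.setdefault(key, set())
        if len(used) >= 4 ** 5:
            raise SimSizingError(f"barcode space exhausted at {key}")
        while True:
            barcode = "".join(rng.choice(BASES, size=5))
            if barcode not in used:
                used.add(barcode)
                break

        chrom_seq = genome[g.chrom]
        if g.strand == "+":
            ins_start = pos + 1
            ins_end = min(pos + 1 + insert_len, g.end)
            insert = chrom_seq[ins_start:ins_end]
        else:
            ins_end = pos
            ins_start = max(pos - insert_len, g.start)
            insert = revcomp(chrom_seq[ins_start:ins_end])
        truncated = len(insert) < insert_len

        n_copies = 1 + int(rng.poisson(cfg.pcr_duplication_mean))
        base_read = (barcode[:2] + cfg.barcode_index + barcode[2:] + insert)
        for j in range(n_copies):
            seq = _apply_errors(base_read, cfg.sequencing_error_rate, rng)
            reads.append((f"cdna{i:06d}_copy{j}", seq, "I" * len(seq)))

        truth.planted_crosslinks.append(key)
        truth.cdna_records.append(CdnaRecord(
            g.chrom, g.strand, pos, barcode, n_copies, truncated, from_motif))
    truth.unique_cdna_count = len(truth.cdna_records)
    # shuffle so file order carries no signal
    order = rng.permutation(len(reads))
    reads = [reads[k] for k in order]
    return reads, truth


def truth_sites(truth: SimTruth):
    """Collapse truth cDNA records into the expected CrosslinkSite set."""
    from .reads import CrosslinkSite
    counts: dict[tuple[str, str, int], int] = {}
    for rec in truth.cdna_records:
        counts[(rec.chrom, rec.strand, rec.position)] = counts.get(
            (rec.chrom, rec.strand, rec.position), 0) + 1
    sites = [CrosslinkSite(c, s, p, n) for (c, s, p), n in counts.items()]
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


# ---------------------------------------------------------------------------
# Exon sets with planted pair motifs
# ---------------------------------------------------------------------------

_PLANT_WINDOW = 50


def _plant_pair(seq: str, rng: np.random.Generator) -> tuple[str, int, int, str]:
    """Insert an AGA then a downstream target trimer in the last 50 nt."""
    L = len(seq)
    w0 = L - _PLANT_WINDOW
    up = int(rng.integers(w0, L - 6 + 1))
    down = int(rng.integers(up + 3, L - 3 + 1))
    down_tri = str(rng.choice(["AGA", "AAG", "GAA"]))
    chars = list(seq)
    chars[up:up + 3] = "AGA"
    chars[down:down + 3] = down_tri
    return "".join(chars), up, down, down_tri


def make_exon_sets(cfg: SimConfig) -> tuple[dict[str, list[ExonRecord]], SimTruth]:
    """Generate up/down/control/population exon sets.

    Down-regulated exons receive, with probability ``pair_plant_rate``, an
    AGA followed >= 3 nt downstream by a target trimer inside their last
    50 nt; all other sequence is background composition. MiDAS-style
    p-values are < 0.05 for regulated sets and > 0.95 for controls.
    """
    if cfg.exon_len_range[0] < 100:
        raise ValueError("exon sets require exon lengths >= 100 nt")
    rng = np.random.default_rng(cfg.seed + 2)
    truth = SimTruth()
    sizes = {"up": cfg.n_regulated_exons, "down": cfg.n_regulated_exons,
             "control": cfg.n_control_exons,
             "population": cfg.n_population_exons}
    sets: dict[str, list[ExonRecord]] = {}
    cursor = 0
    for label in ("up", "down", "control", "population"):
        records = []
        for i in range(sizes[label]):
            L = int(rng.integers(*cfg.exon_len_range))
            seq = _rand_seq(rng, L, cfg.base_composition)
            exon_id = f"{label}_{i:05d}"
            if label == "down" and rng.random() < cfg.pair_plant_rate:
                seq, up_pos, down_pos, down_tri = _plant_pair(seq, rng)
                truth.planted_pair_exons.append(
                    (exon_id, up_pos, down_pos, down_tri))
            if label == "up":
                p, fold = rng.uniform(0, 0.05), rng.uniform(2.2, 6.0)
            elif label == "down":
                p, fold = rng.uniform(0, 0.05), -rng.uniform(2.2, 6.0)
            elif label == "control":
                p, fold = rng.uniform(0.9500001, 1.0), rng.uniform(-1.2, 1.2)
            else:
                p, fold = rng.uniform(0.05, 0.95), rng.uniform(-1.2, 1.2)
            records.append(ExonRecord(
                exon_id=exon_id, gene_id=f"g_{exon_id}", chrom="simE",
                start=cursor, end=cursor + L, strand="+", sequence=seq,
                upstream_intron_seq=_rand_seq(rng, cfg.intron_flank_len,
                                              cfg.base_composition),
                downstream_intron_seq=_rand_seq(rng, cfg.intron_flank_len,
                                                cfg.base_composition),
                midas_p=float(p), fold_change=float(fold), class_label=label))
            cursor += L + 100
        sets[label] = records
    return sets, truth


# ---------------------------------------------------------------------------
# Control-selection cohort with per-filter planted outcomes
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    genome: dict[str, str]
    annotation: Annotation
    diff_table: pd.DataFrame
    expression: pd.DataFrame
    truth: SimTruth


def make_control_cohort(cfg: SimConfig) -> Cohort:
    """Genome + differential/expression tables with known qualifying exons.

    Every control-selection filter has planted passes and failures:
    low/high MiDAS p, expressed/unexpressed genes, terminal exons,
    sub-100-nt exons (use an ``exon_len_range`` dipping below 100),
    an overlapping exon pair, and one exon with an ambiguous nucleotide.
    ``truth.qualifying_control_exons`` lists the exon ids that survive all
    filters, derived from the planted construction.
    """
    geno_cfg = dataclasses.replace(cfg, ncrna_gene_fraction=0.0)
    genome, annotation = make_genome(geno_cfg)
    rng = np.random.default_rng(cfg.seed + 3)

    expr_rows = []
    expressed: dict[str, bool] = {}
    for g in annotation.genes:
        is_expr = bool(rng.random() < 0.7)
        expressed[g.gene_id] = is_expr
        if is_expr:
            counts = rng.integers(1200, 3000, size=6)
        else:
            ctrl = rng.integers(1200, 3000, size=3)
            kd = rng.integers(100, 900, size=3)  # sum < 3000: fails condition 2
            counts = np.concatenate([ctrl, kd])
        expr_rows.append([g.gene_id] + [int(x) for x in counts])
    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", "ctrl_1", "ctrl_2", "ctrl_3",
                            "kd_1", "kd_2", "kd_3"])

    diff_rows = []
    qualifying: set[str] = set()
    dup_budget = 2
    n_budget = 1
    chrom_chars = None  # lazily mutated copy for the ambiguous-nt plant
    for g in annotation.genes:
        blocks = g.exon_blocks()
        for bi, (s, e) in enumerate(blocks):
            internal = 0 < bi < len(blocks) - 1
            exon_id = f"{g.gene_id}_e{bi}"
            high_p = bool(rng.random() < 0.6)
            p = float(rng.uniform(0.9500001, 1.0)) if high_p \
                else float(rng.uniform(0.0, 0.95))
            fold = float(rng.uniform(-1.5, 1.5))
            diff_rows.append((exon_id, g.gene_id, g.chrom, s, e, g.strand,
                              p, fold))
            ok = (high_p and expressed[g.gene_id] and internal
                  and (e - s) >= 100)
            planted_defect = False
            if ok and dup_budget > 0 and (e - s) >= 110:
                # overlapping candidate inside this exon: both must be dropped
                dup_id = f"{exon_id}_dup"
                diff_rows.append((dup_id, g.gene_id, g.chrom, s + 5, s + 105,
                                  g.strand, float(rng.uniform(0.96, 1.0)),
                                  fold))
                dup_budget -= 1
                planted_defect = True
            elif ok and n_budget > 0:
                if chrom_chars is None:
                    chrom_chars = list(genome[g.chrom])
                chrom_chars[(s + e) // 2] = "N"
                n_budget -= 1
                planted_defect = True
            if ok and not planted_defect:
                qualifying.add(exon_id)
    if chrom_chars is not None:
        genome = dict(genome)
        genome[annotation.genes[0].chrom] = "".join(chrom_chars)

    diff_table = pd.DataFrame(
        diff_rows, columns=["exon_id", "gene_id", "chrom", "start", "end",
                            "strand", "midas_p", "fold_change"])
    truth = SimTruth(qualifying_control_exons=qualifying)
    return Cohort(genome, annotation, diff_table, expression, truth)
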