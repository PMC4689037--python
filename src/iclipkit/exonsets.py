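"""Construction of regulated and control cassette-exon sets.

``call_regulated`` labels exons from a differential-exon table
(p < 0.05 with an absolute fold change > 2). ``select_controls`` applies the
control-selection funnel: unchanged splicing (p > 0.95), moderate-to-high
gene expression (>= 3000 total reads in each condition), internal cassette
exon, length >= 100 nt, mutually non-overlapping, no ambiguous nucleotides.
``repeat_filter`` removes exons containing simple period-3 tandem repeats.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import Annotation, EXONIC_CLASSES
from .io import revcomp

logger = logging.getLogger(__name__)

DIFF_COLUMNS = ["exon_id", "gene_id", "chrom", "start", "end", "strand",
                "midas_p", "fold_change"]

MIN_CONTROL_EXON_LEN = 100
MIN_READS_PER_CONDITION = 3000
REGULATED_P = 0.05
CONTROL_P = 0.95
FOLD_THRESHOLD = 2.0


@dataclass
class ExonRecord:
    """A cassette exon with sequence, flanks, differential stats and label."""
    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    upstream_intron_seq: str = ""
    downstream_intron_seq: str = ""
    midas_p: float = float("nan")
    fold_change: float = float("nan")
    class_label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def signed_fold(values: pd.Series, convention: str) -> pd.Series:
    """Normalize fold changes to signed ratios (-3 = 3-fold down).

    ``signed`` passes through; ``log2`` converts log2 ratios, mapping
    negative log-folds to negative signed ratios.
    """
    if convention == "signed":
        return values.astype(float)
    if convention == "log2":
        mag = 2.0 ** values.abs()
        return mag.where(values >= 0, -mag)
    raise ValueError(f"unknown fold convention {convention!r}")


# ---------------------------------------------------------------------------
# Regulated exon calls
# ---------------------------------------------------------------------------

def call_regulated(
    diff_table: pd.DataFrame,
    fold_convention: str = "signed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a differential-exon table into (up, down) sets.

    up: midas_p < 0.05 and fold > +2; down: midas_p < 0.05 and fold < -2.
    Rows failing either threshold are left unlabeled (not returned).
    """
    missing = {"midas_p", "fold_change"} - set(diff_table.columns)
    if missing:
        raise ValueError(f"differential table missing columns: {sorted(missing)}")
    fold = signed_fold(diff_table["fold_change"], fold_convention)
    sig = diff_table["midas_p"] < REGULATED_P
    up = diff_table[sig & (fold > FOLD_THRESHOLD)].copy()
    down = diff_table[sig & (fold < -FOLD_THRESHOLD)].copy()
    return up.reset_index(drop=True), down.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Control selection funnel
# ---------------------------------------------------------------------------

def _internal_exon_intervals(annotation: Annotation) -> dict[str, list[tuple[int, int]]]:
    """Per-gene exon blocks flanked by introns on both sides."""
    out: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes:
        regions = sorted(g.regions, key=lambda r: r.start)
        blocks = g.exon_blocks()
        intron_edges = {(r.start, r.end) for r in regions
                        if r.region_class == "intron"}
        intron_starts = {s for s, _ in intron_edges}
        intron_ends = {e for _, e in intron_edges}
        internal = [(s, e) for s, e in blocks
                    if s in intron_ends and e in intron_starts]
        if internal:
            out[g.gene_id] = internal
    return out


def _extract_record(row, genome: dict[str, str], flank: int) -> ExonRecord:
    chrom_seq = genome[row.chrom]
    seq = chrom_seq[row.start:row.end]
    up = chrom_seq[max(0, row.start - flank):row.start]
    down = chrom_seq[row.end:row.end + flank]
    if row.strand == "-":
        seq, up, down = revcomp(seq), revcomp(down), revcomp(up)
    return ExonRecord(
        exon_id=str(row.exon_id), gene_id=str(row.gene_id), chrom=row.chrom,
        start=int(row.start), end=int(row.end), strand=row.strand,
        sequence=seq, upstream_intron_seq=up, downstream_intron_seq=down,
        midas_p=float(row.midas_p), fold_change=float(row.fold_change),
        class_label="control",
    )


def select_controls(
    diff_table: pd.DataFrame,
    expression: pd.DataFrame,
    annotation: Annotation,
    genome: dict[str, str],
    intron_flank: int = 150,
) -> tuple[list[ExonRecord], list[tuple[str, int]]]:
    """Build the control cassette-exon set; returns (records, filter funnel).

    Filters, in order, each logged with its survivor count:

    1. ``midas_p`` > 0.95 (splicing unchanged);
    2. gene expression >= 3000 total reads in *each* condition (expression
       table columns: ``gene_id`` then per-replicate count columns prefixed
       ``ctrl_`` and ``kd_``);
    3. exon internal to a transcript (annotated exon block with flanking
       introns on both sides, and the exon interval contained in it);
    4. exon length >= 100 nt;
    5. exons mutually non-overlapping (all members of an overlapping cluster
       are dropped);
    6. no ambiguous nucleotides in the exon sequence.

    An empty survivor set is a warning, not an error.
    """
    funnel: list[tuple[str, int]] = [("input", len(diff_table))]
    df = diff_table.copy()

    df = df[df["midas_p"] > CONTROL_P]
    funnel.append(("midas_p_gt_0.95", len(df)))

    ctrl_cols = [c for c in expression.columns if c.startswith("ctrl_")]
    kd_cols = [c for c in expression.columns if c.startswith("kd_")]
    if not ctrl_cols or not kd_cols:
        raise ValueError("expression table needs ctrl_* and kd_* count columns")
    expr_ok = expression[
        (expression[ctrl_cols].sum(axis=1) >= MIN_READS_PER_CONDITION)
        & (expression[kd_cols].sum(axis=1) >= MIN_READS_PER_CONDITION)
    ]["gene_id"]
    df = df[df["gene_id"].isin(set(expr_ok))]
    funnel.append(("expressed_genes", len(df)))

    internal = _internal_exon_intervals(annotation)
    def _is_internal(row) -> bool:
        for s, e in internal.get(row.gene_id, []):
            if s <= row.start and row.end <= e:
                return True
        return False
    df = df[np.array([_is_internal(r) for r in df.itertuples()], dtype=bool)]
    funnel.append(("internal_exon", len(df)))

    df = df[(df["end"] - df["start"]) >= MIN_CONTROL_EXON_LEN]
    funnel.append(("length_ge_100", len(df)))

    # drop every member of an overlapping cluster, by max-end sweep
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = list(df.itertuples())
    max_end = -1
    prev_chrom = None
    open_idx: list = []
    overlapping: set = set()
    for r in rows:
        if r.chrom != prev_chrom:
            prev_chrom, max_end, open_idx = r.chrom, -1, []
        if r.start < max_end:
            overlapping.add(r.Index)
            overlapping.update(i for i, e in open_idx if e > r.start)
        open_idx.append((r.Index, r.end))
        max_end = max(max_end, r.end)
    df = df.drop(index=sorted(overlapping))
    funnel.append(("non_overlapping", len(df)))

    records = [_extract_record(r, genome, intron_flank) for r in df.itertuples()]
    records = [r for r in records if set(r.sequence) <= set("ACGT")]
    funnel.append(("unambiguous", len(records)))

    if not records:
        logger.warning("control-exon funnel produced an empty set")
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records, funnel


# ---------------------------------------------------------------------------
# Simple tandem-repeat filter
# ---------------------------------------------------------------------------

def find_tandem_repeat(seq: str, min_run: int = 6) -> tuple[str, int, int] | None:
    """First perfect period-3 tandem run of >= min_run copies, or None.

    Returns (unit, start, end) of the run.
    """
    if min_run == float("inf"):
        return None
    pattern = re.compile(r"([ACGT]{3})\1{%d,}" % (int(min_run) - 1))
    m = pattern.search(seq)
    if m:
        return m.group(1), m.start(), m.end()
    return None


def repeat_filter(
    exons: list[ExonRecord],
    min_run: int | float = 6,
) -> tuple[list[ExonRecord], list[tuple[str, str, int, int]]]:
    """Drop exons containing a period-3 tandem repeat of >= min_run copies.

    Returns (retained exons, removed list of (exon_id, unit, start, end)).
    """
    kept, removed = [], []
    for ex in exons:
        hit = None if min_run == float("inf") else find_tandem_repeat(
            ex.sequence, min_run)
        if hit is None:
            kept.append(ex)
        else:
            unit, s, e = hit
            removed.append((ex.exon_id, unit, s, e))
    return kept, removed


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def exons_to_tables(exons: list[ExonRecord]) -> tuple[dict[str, str], pd.DataFrame]:
    """(FASTA dict, sidecar TSV frame) for a set of exon records."""
    fasta = {e.exon_id: e.sequence for e in exons}
    side = pd.DataFrame(
        [(e.exon_id, e.gene_id, e.chrom, e.start, e.end, e.strand,
          e.midas_p, e.fold_change, e.class_label,
          e.upstream_intron_seq, e.downstream_intron_seq) for e in exons],
        columns=["exon_id", "gene_id", "chrom", "start", "end", "strand",
                 "midas_p", "fold_change", "class", "upstream_intron_seq",
                 "downstream_intron_seq"])
    return fasta, side


def exons_from_tables(fasta: dict[str, str], side: pd.DataFrame) -> list[ExonRecord]:
    out = []
    for _, r in side.iterrows():
        out.append(ExonRecord(
            exon_id=str(r["exon_id"]), gene_id=str(r["gene_id"]),
            chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
            strand=str(r["strand"]), sequence=fasta[str(r["exon_id"])],
            upstream_intron_seq=str(r.get("upstream_intron_seq", "") or ""),
            downstream_intron_seq=str(r.get("downstream_intron_seq", "") or ""),
            midas_p=float(r["midas_p"]), fold_change=float(r["fold_change"]),
            class_label=str(r.get("class", "")),
        ))
    return out
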