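"""Barcoded iCLIP read processing: demultiplexing, toy-genome mapping, and
PCR-duplicate removal into single-nucleotide crosslink sites.

Read layout (5' to 3'): ``NN XXXX NNN insert`` — two random nucleotides, a
4-nt experiment index, three random nucleotides, then the cDNA insert. The
five random nucleotides (``NN`` + ``NNN``) form the random barcode used to
collapse PCR duplicates.

The mapper here is a naive exact / one-mismatch scanner intended for toy
genomes (up to a few Mb). Pre-aligned data can be supplied as 6-column BED
with the barcode appended to the name field (``readid#BARCODE``), bypassing
:func:`map_inserts` entirely.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

from .io import revcomp

logger = logging.getLogger(__name__)

BARCODE_BLOCK = 9          # NN + XXXX + NNN
INDEX_SLICE = slice(2, 6)  # 0-based positions of the 4-nt experiment index
UMI_SLICES = (slice(0, 2), slice(6, 9))


@dataclass(frozen=True)
class BarcodedRead:
    """A read split into its experiment index, random barcode and insert."""
    read_id: str
    experiment_index: str
    random_barcode: str
    insert: str


@dataclass(frozen=True)
class AlignedInsert:
    """A uniquely mapped insert (0-based half-open, at most one mismatch)."""
    chrom: str
    strand: str
    start: int
    end: int
    mismatches: int
    random_barcode: str
    read_id: str = ""


@dataclass(frozen=True)
class CrosslinkSite:
    """Strand-aware single-nucleotide position with a unique-cDNA count."""
    chrom: str
    strand: str
    position: int
    cdna_count: int


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def split_read(read_id: str, seq: str) -> BarcodedRead:
    """Split a raw read into barcode block components and insert.

    Raises ``ValueError`` for reads shorter than the 9-nt barcode block.
    """
    if len(seq) < BARCODE_BLOCK:
        raise ValueError(f"read {read_id!r} shorter than {BARCODE_BLOCK} nt")
    barcode = "".join(seq[s] for s in UMI_SLICES)
    return BarcodedRead(
        read_id=read_id,
        experiment_index=seq[INDEX_SLICE],
        random_barcode=barcode,
        insert=seq[BARCODE_BLOCK:],
    )


def demultiplex(
    reads: Iterable[tuple[str, str] | tuple[str, str, str]],
    index_map: dict[str, str],
) -> tuple[dict[str, list[BarcodedRead]], int]:
    """Assign reads to samples by exact match of the 4-nt experiment index.

    Parameters
    ----------
    reads
        Iterable of ``(read_id, sequence[, quality])`` tuples.
    index_map
        Mapping of 4-nt experiment index to sample name; indices must be
        distinct 4-nt strings.

    Returns
    -------
    (per-sample lists of :class:`BarcodedRead`, number of rejected reads).
    Reads are rejected when shorter than 9 nt or when their index matches no
    sample.
    """
    for idx in index_map:
        if len(idx) != 4:
            raise ValueError(f"experiment index {idx!r} is not 4 nt")
    if len(set(index_map)) != len(index_map):
        raise ValueError("experiment indices must be distinct")

    by_sample: dict[str, list[BarcodedRead]] = {s: [] for s in index_map.values()}
    rejected = 0
    for rec in reads:
        rid, seq = rec[0], rec[1]
        try:
            br = split_read(rid, seq)
        except ValueError:
            rejected += 1
            continue
        sample = index_map.get(br.experiment_index)
        if sample is None:
            rejected += 1
        else:
            by_sample[sample].append(br)
    return by_sample, rejected


# ---------------------------------------------------------------------------
# Naive mapping
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> Iterator[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _hamming_le1(a: str, genome: str, start: int) -> int:
    """Mismatch count of ``a`` vs genome[start:start+len(a)], or 2 if >1."""
    mm = 0
    for i, ch in enumerate(a):
        if genome[start + i] != ch:
            mm += 1
            if mm > 1:
                return 2
    return mm


def _candidate_hits(insert: str, genome: str) -> list[tuple[int, int]]:
    """(start, mismatches) for all 0/1-mismatch matches of insert in genome.

    Seed-and-extend by pigeonhole: a 1-mismatch hit matches at least one of
    the two halves exactly.
    """
    n, L = len(genome), len(insert)
    if L > n:
        return []
    h = L // 2
    starts: set[int] = set()
    for i in _find_all(genome, insert[:h]):
        if i + L <= n:
            starts.add(i)
    for i in _find_all(genome, insert[h:]):
        j = i - h
        if 0 <= j and j + L <= n:
            starts.add(j)
    hits = []
    for s in starts:
        mm = _hamming_le1(insert, genome, s)
        if mm <= 1:
            hits.append((s, mm))
    return hits


def map_inserts(
    reads: Iterable[BarcodedRead],
    genome: dict[str, str],
    min_insert: int = 15,
) -> tuple[list[AlignedInsert], dict[str, int]]:
    """Map inserts to the genome allowing at most one mismatch.

    Both strands are searched; inserts with more than one locus at their best
    mismatch count are discarded as multimappers. Each distinct insert
    sequence is scanned once and the result cached.

    Returns the alignments plus a ``{"mapped", "unmapped", "multimapped",
    "too_short"}`` counter dict.
    """
    cache: dict[str, tuple[str, str, int, int, int] | None] = {}
    stats = {"mapped": 0, "unmapped": 0, "multimapped": 0, "too_short": 0}
    out: list[AlignedInsert] = []

    for br in reads:
        ins = br.insert
        if len(ins) < min_insert:
            stats["too_short"] += 1
            continue
        if ins not in cache:
            hits: list[tuple[str, str, int, int]] = []  # chrom, strand, start, mm
            rc = revcomp(ins)
            for chrom, seq in genome.items():
                for s, mm in _candidate_hits(ins, seq):
                    hits.append((chrom, "+", s, mm))
                for s, mm in _candidate_hits(rc, seq):
                    hits.append((chrom, "-", s, mm))
            if not hits:
                cache[ins] = None
            else:
                best = min(mm for *_, mm in hits)
                best_hits = [h for h in hits if h[3] == best]
                # a palindromic insert reports the same locus on both strands
                if len({(c, s) for c, _, s, _ in best_hits}) > 1:
                    cache[ins] = "multi"  # type: ignore[assignment]
                else:
                    chrom, strand, s, mm = best_hits[0]
                    cache[ins] = (chrom, strand, s, s + len(ins), mm)
        hit = cache[ins]
        if hit is None:
            stats["unmapped"] += 1
        elif hit == "multi":
            stats["multimapped"] += 1
        else:
            chrom, strand, s, e, mm = hit
            out.append(AlignedInsert(chrom, strand, s, e, mm,
                                     br.random_barcode, br.read_id))
            stats["mapped"] += 1
    if stats["unmapped"] or stats["multimapped"]:
        logger.info("map_inserts: %(mapped)d mapped, %(unmapped)d unmapped, "
                    "%(multimapped)d multimapped, %(too_short)d too short", stats)
    return out, stats


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def truncation_position(aln: AlignedInsert, convention: str = "upstream") -> int:
    """Crosslink (truncation) nucleotide for an alignment.

    ``upstream`` (default iCLIP convention): the nucleotide immediately 5' of
    the read start on the read's strand — ``start - 1`` on "+", ``end`` on
    "-". ``start`` uses the first aligned nucleotide instead.
    """
    if convention == "upstream":
        return aln.start - 1 if aln.strand == "+" else aln.end
    if convention == "start":
        return aln.start if aln.strand == "+" else aln.end - 1
    raise ValueError(f"unknown convention {convention!r}")


def deduplicate(
    alignments: Iterable[AlignedInsert],
    convention: str = "upstream",
) -> list[CrosslinkSite]:
    """Collapse alignments sharing (chrom, strand, truncation position, barcode).

    The unique-cDNA count of a site is the number of distinct random barcodes
    observed among alignments truncating at that nucleotide.
    """
    barcodes: dict[tuple[str, str, int], set[str]] = defaultdict(set)
    for aln in alignments:
        pos = truncation_position(aln, convention)
        barcodes[(aln.chrom, aln.strand, pos)].add(aln.random_barcode)
    sites = [CrosslinkSite(chrom, strand, pos, len(bcs))
             for (chrom, strand, pos), bcs in barcodes.items()]
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


# ---------------------------------------------------------------------------
# Site / alignment serialization helpers
# ---------------------------------------------------------------------------

def sites_to_bed(sites: Iterable[CrosslinkSite]):
    for i, s in enumerate(sites):
        yield s.chrom, s.position, s.position + 1, f"site{i}", s.cdna_count, s.strand


def sites_from_bed(rows) -> list[CrosslinkSite]:
    return [CrosslinkSite(chrom, strand, start, int(score))
            for chrom, start, end, name, score, strand in rows]


def alignments_from_bed(rows) -> list[AlignedInsert]:
    """Parse pre-aligned inserts from BED6 with ``readid#BARCODE`` names."""
    out = []
    for chrom, start, end, name, score, strand in rows:
        rid, _, barcode = name.rpartition("#")
        out.append(AlignedInsert(chrom, strand, start, end, int(score), barcode, rid))
    return out
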