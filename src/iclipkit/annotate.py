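"""Gene models, region classification of crosslink sites, density/proportion
enrichment tables, and smoothed splice-junction RNA maps.

Region classes are ``ncRNA, ORF, UTR5, UTR3, intron, intergenic``. When
annotations overlap, a nucleotide is resolved by the precedence
``ncRNA > ORF > UTR5 > UTR3 > intron > intergenic``. Classification is
strand-aware: a site is genic only on the annotated strand.

RNA-map offset conventions (transcript orientation, documented in output):
at a 3' splice site offset 0 is the first exonic nucleotide (negative =
intron); at a 5' splice site offset 0 is the last exonic nucleotide
(negative = exon, positive = intron).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import REGION_COLUMNS
from .reads import CrosslinkSite

logger = logging.getLogger(__name__)

GENIC_CLASSES = ("ncRNA", "ORF", "UTR5", "UTR3", "intron")
PRECEDENCE = ("ncRNA", "ORF", "UTR5", "UTR3", "intron")
EXONIC_CLASSES = frozenset({"ncRNA", "ORF", "UTR5", "UTR3"})
ALL_CLASSES = PRECEDENCE + ("intergenic",)


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    region_class: str


@dataclass
class Gene:
    """A transcript model whose regions tile [start, end) without gaps."""
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    regions: list[Region] = field(default_factory=list)

    @property
    def coding(self) -> bool:
        return any(r.region_class == "ORF" for r in self.regions)

    def exon_blocks(self) -> list[tuple[int, int]]:
        """Maximal exonic intervals (adjacent exonic regions merged)."""
        blocks: list[list[int]] = []
        for r in sorted(self.regions, key=lambda r: r.start):
            if r.region_class in EXONIC_CLASSES:
                if blocks and blocks[-1][1] == r.start:
                    blocks[-1][1] = r.end
                else:
                    blocks.append([r.start, r.end])
        return [(s, e) for s, e in blocks]


@dataclass
class Annotation:
    genes: list[Gene]

    def to_frame(self) -> pd.DataFrame:
        rows = [(g.chrom, r.start, r.end, g.strand, g.gene_id, r.region_class)
                for g in self.genes for r in g.regions]
        return pd.DataFrame(rows, columns=REGION_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Annotation":
        genes = []
        for gid, grp in df.groupby("gene_id", sort=True):
            grp = grp.sort_values("start")
            genes.append(Gene(
                gene_id=str(gid),
                chrom=grp["chrom"].iloc[0],
                start=int(grp["start"].min()),
                end=int(grp["end"].max()),
                strand=grp["strand"].iloc[0],
                regions=[Region(int(r.start), int(r.end), r.region_class)
                         for r in grp.itertuples()],
            ))
        genes.sort(key=lambda g: (g.chrom, g.start))
        return cls(genes)


# ---------------------------------------------------------------------------
# Region classification & densities
# ---------------------------------------------------------------------------

class _ClassIndex:
    """Per (chrom, strand, class) merged sorted intervals for stabbing."""

    def __init__(self, annotation: Annotation):
        raw: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
        for g in annotation.genes:
            for r in g.regions:
                raw.setdefault((g.chrom, g.strand, r.region_class), []).append(
                    (r.start, r.end))
        self._index: dict[tuple[str, str, str], tuple[list[int], list[int]]] = {}
        self.class_lengths: dict[str, int] = {c: 0 for c in PRECEDENCE}
        for key, ivals in raw.items():
            merged = _merge_intervals(ivals)
            self._index[key] = ([s for s, _ in merged], [e for _, e in merged])
            self.class_lengths[key[2]] += sum(e - s for s, e in merged)

    def contains(self, chrom: str, strand: str, cls: str, pos: int) -> bool:
        entry = self._index.get((chrom, strand, cls))
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    out: list[list[int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def classify_sites(
    sites: list[CrosslinkSite],
    annotation: Annotation,
    chrom_lengths: dict[str, int],
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Assign a region class to every site and tabulate enrichment.

    Returns ``(per_site_classes, density_table, proportion_table)``.

    The density table has one row per region class with columns
    ``region_class, tag_count, total_length, density, enrichment`` where
    density = tag_count / total_length and enrichment = density divided by
    the genome-average density (total tags / total stranded genome length).
    Total length is counted per strand, so the genome denominator is twice
    the summed chromosome length. Sites on chromosomes absent from the
    annotation or the length table are classified intergenic with a warning.
    """
    index = _ClassIndex(annotation)
    known = set(chrom_lengths)
    classes: list[str] = []
    unknown = 0
    for s in sites:
        if s.chrom not in known:
            unknown += 1
            classes.append("intergenic")
            continue
        for cls in PRECEDENCE:
            if index.contains(s.chrom, s.strand, cls, s.position):
                classes.append(cls)
                break
        else:
            classes.append("intergenic")
    if unknown:
        logger.warning("%d sites on chromosomes absent from the models; "
                       "classified intergenic", unknown)

    counts = {c: 0 for c in ALL_CLASSES}
    for s, cls in zip(sites, classes):
        counts[cls] += s.cdna_count
    total_tags = sum(counts.values())

    genome_len = 2 * sum(chrom_lengths.values())  # both strands
    lengths = dict(index.class_lengths)
    lengths["intergenic"] = genome_len - sum(lengths.values())
    avg_density = total_tags / genome_len if genome_len else float("nan")

    rows = []
    for cls in ALL_CLASSES:
        n, ln = counts[cls], lengths[cls]
        density = n / ln if ln else float("nan")
        rows.append((cls, n, ln, density,
                     density / avg_density if avg_density else float("nan")))
    density_df = pd.DataFrame(
        rows, columns=["region_class", "tag_count", "total_length",
                       "density", "enrichment"])
    prop_df = pd.DataFrame({
        "region_class": list(ALL_CLASSES),
        "proportion": [counts[c] / total_tags if total_tags else float("nan")
                       for c in ALL_CLASSES],
    })
    return classes, density_df, prop_df


# ---------------------------------------------------------------------------
# Splice junctions & RNA maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    chrom: str
    strand: str
    anchor: str      # "3ss" or "5ss"
    position: int    # genomic coordinate of offset 0 (see module docstring)
    gene_start: int
    gene_end: int


def junctions(annotation: Annotation, anchor: str) -> list[Junction]:
    """Extract splice junctions of one type ("3ss" or "5ss") from the models."""
    if anchor not in ("3ss", "5ss"):
        raise ValueError("anchor must be '3ss' or '5ss'")
    out: list[Junction] = []
    for g in annotation.genes:
        regions = sorted(g.regions, key=lambda r: r.start)
        for left, right in zip(regions, regions[1:]):
            l_ex = left.region_class in EXONIC_CLASSES
            r_ex = right.region_class in EXONIC_CLASSES
            if l_ex == r_ex:
                continue
            if g.strand == "+":
                if l_ex:  # exon -> intron: 5'ss, 0 = last exonic nt
                    kind, pos = "5ss", left.end - 1
                else:     # intron -> exon: 3'ss, 0 = first exonic nt
                    kind, pos = "3ss", right.start
            else:
                if l_ex:  # transcript order: intron then exon -> 3'ss
                    kind, pos = "3ss", left.end - 1
                else:     # exon then intron in transcript order -> 5'ss
                    kind, pos = "5ss", right.start
            if kind == anchor:
                out.append(Junction(g.chrom, g.strand, kind, pos,
                                    g.start, g.end))
    return out


def boxcar_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with a fixed 1/window kernel (edges damped)."""
    if window % 2 != 1 or window < 1:
        raise ValueError("smooth window must be odd and >= 1")
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


@dataclass
class RnaMap:
    anchor: str
    offsets: np.ndarray       # -flank .. +flank
    raw: np.ndarray           # summed cdna counts per offset
    spanning: np.ndarray      # junctions whose gene covers each offset
    normalized: np.ndarray    # smoothed, 1e9-scaled per-spanning-junction rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "anchor": self.anchor, "offset": self.offsets, "raw": self.raw,
            "spanning_junctions": self.spanning, "normalized": self.normalized,
        })


def rna_map(
    sites: list[CrosslinkSite],
    annotation: Annotation,
    anchor: str,
    flank: int = 300,
    smooth_window: int = 5,
) -> RnaMap:
    """Crosslink profile around splice junctions of one type.

    For each junction, crosslink cdna counts within ±flank are accumulated at
    their transcript-orientation offset. Each offset's total is divided by
    the number of junctions whose gene body spans the corresponding absolute
    coordinate, scaled by 1e9 / total crosslink count (over all sites), and
    smoothed with a centered running mean.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    juncs = junctions(annotation, anchor)
    offsets = np.arange(-flank, flank + 1)
    raw = np.zeros(2 * flank + 1, dtype=float)
    spanning = np.zeros(2 * flank + 1, dtype=int)
    if not juncs:
        logger.warning("no %s junctions found; returning empty map", anchor)
        return RnaMap(anchor, offsets, raw, spanning, np.zeros_like(raw))

    by_key: dict[tuple[str, str], list[CrosslinkSite]] = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s)
    for key in by_key:
        by_key[key].sort(key=lambda s: s.position)

    total = sum(s.cdna_count for s in sites)
    for j in juncs:
        group = by_key.get((j.chrom, j.strand), [])
        positions = [s.position for s in group]
        lo = bisect_right(positions, j.position - flank - 1)
        hi = bisect_right(positions, j.position + flank)
        for s in group[lo:hi]:
            d = s.position - j.position
            if j.strand == "-":
                d = -d
            raw[d + flank] += s.cdna_count
        # spanning: gene body covers coordinate at each offset
        for i, d in enumerate(offsets):
            c = j.position + (d if j.strand == "+" else -d)
            if j.gene_start <= c < j.gene_end:
                spanning[i] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        per_junction = np.where(spanning > 0, raw / np.maximum(spanning, 1), 0.0)
    scaled = per_junction * (1e9 / total if total else 0.0)
    return RnaMap(anchor, offsets, raw, spanning,
                  boxcar_smooth(scaled, smooth_window))
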