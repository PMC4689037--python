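"""Plain-text genomics I/O helpers (FASTA, FASTQ, BED, TSV tables).

All coordinates are 0-based half-open; strand is "+" or "-".
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGION_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "region_class"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{name: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | os.PathLike, width: int = 60) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) triples."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq), qual


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed6(rows: Iterable[tuple[str, int, int, str, int | float, str]],
               path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | os.PathLike) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
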