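"""Readers and writers for the on-disk formats the pipeline exchanges.

Conventions: FASTA wrapped at 60 columns; GFF3 and SAM are 1-based on disk
per their standards; BED and BEDGRAPH are 0-based half-open. Internally
everything is 0-based half-open. Reading goes through the field-standard
libraries (pyfaidx, gffutils, pysam); writing is plain text.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pyfaidx

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3",
    "read_bed3",
    "write_bed3",
    "write_sam",
    "write_bedgraph",
    "write_tsv",
    "config_digest",
]

_FASTA_WIDTH = 60


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = _FASTA_WIDTH) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3 gene annotations
#
# Genes travel internally as tuples (scaffold, start, end, strand, gene_id,
# family) with 0-based half-open coordinates; GFF3 on disk is 1-based
# inclusive.

def write_gff3(genes: Iterable[tuple], path: str | Path, source: str = "karyoscope") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold, start, end, strand, gene_id, family in genes:
            attrs = f"ID={gene_id}"
            if family and family != ".":
                attrs += f";family={family}"
            fh.write(
                f"{scaffold}\t{source}\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_gff3_genes(path: str | Path) -> list[tuple]:
    """Parse ``gene`` features from GFF3 into internal gene tuples."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        family = feat.attributes.get("family", ["."])[0]
        genes.append(
            (feat.seqid, feat.start - 1, feat.end, feat.strand, feat.id, family)
        )
    return genes


# ---------------------------------------------------------------------------
# BED3 (repeats and cluster output)

def write_bed3(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write ``(scaffold, start, end[, name])`` rows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# ---------------------------------------------------------------------------
# SAM

def write_sam(
    placements_by_scaffold: Mapping[str, np.ndarray],
    scaffold_lengths: Mapping[str, int],
    read_length: int,
    path: str | Path,
    sample: str = "sample",
) -> int:
    """Write fixed-length single-end placements as a minimal sorted SAM.

    Records carry only what coverage needs: reference, 1-based POS, MAPQ 60
    and a ``<read_length>M`` CIGAR; SEQ/QUAL are ``*``. Returns the number
    of records written.
    """
    n_total = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in scaffold_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        fh.write(f"@RG\tID:{sample}\tSM:{sample}\n")
        cigar = f"{read_length}M"
        for name in scaffold_lengths:
            starts = placements_by_scaffold.get(name)
            if starts is None:
                continue
            starts = np.sort(np.asarray(starts))
            lines = [
                f"{sample}.r{n_total + i}\t0\t{name}\t{s + 1}\t60\t{cigar}\t*\t0\t0\t*\t*"
                for i, s in enumerate(starts)
            ]
            n_total += len(starts)
            if lines:
                fh.write("\n".join(lines))
                fh.write("\n")
    return n_total


# ---------------------------------------------------------------------------
# BEDGRAPH and TSV tracks

def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]],
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write ``(scaffold, start, end, value)`` rows as BEDGRAPH."""
    with open(path, "w") as fh:
        for scaffold, start, end, value in rows:
            fh.write(f"{scaffold}\t{start}\t{end}\t{value:.{precision}g}\n")


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str] = (),
    float_format: str = "%.6g",
) -> None:
    """Write a DataFrame as TSV, preceded by ``#``-prefixed header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=float_format)


def config_digest(mapping: Mapping) -> str:
    """Short stable hash of a flat configuration mapping."""
    payload = ";".join(f"{k}={mapping[k]}" for k in sorted(mapping))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
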