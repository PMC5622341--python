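"""Readers and writers for every external format the pipeline touches.

Formats: BED3/4 (summits as 1-bp records), bedGraph, FASTA, chrom.sizes,
GTF-lite gene tables (1-based inclusive, converted to 0-based half-open on
read), expression TSV, JASPAR-like PWM text and term-annotation TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ExpressionRecord, GeneModel, GenomicInterval, Pwm, Summit, TagTrack

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# BED


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3/BED4 into intervals, preserving input order.

    Coordinates are kept verbatim (BED is already 0-based half-open).
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand=strand, name=name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_summits(
    path: PathLike, source_condition: str = "", source_factor: str = ""
) -> List[Summit]:
    """Read a 1-bp BED summit file; multi-bp records use the interval midpoint."""
    summits = []
    for iv in read_bed(path):
        pos = iv.start if len(iv) == 1 else (iv.start + iv.end) // 2
        summits.append(
            Summit(iv.chrom, pos, source_condition=source_condition, source_factor=source_factor)
        )
    return summits


def write_bed(intervals: List[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def write_summits(summits: List[Summit], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in summits:
            label = s.source_factor or s.source_condition or "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{label}\n")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, n in sizes.items():
            fh.write(f"{chrom}\t{n}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: PathLike, chrom_sizes: Dict[str, int]) -> TagTrack:
    """Fill a per-base TagTrack from a bedGraph.

    Uncovered bases are 0; overlapping records sum (tracks are emitted as
    fragment pileups, so additivity is the physically sensible composition).
    """
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in counts:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if end > chrom_sizes[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} beyond {chrom} size {chrom_sizes[chrom]}"
                )
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            counts[chrom][start:end] += int(round(value))
    return TagTrack(counts)


def write_bedgraph(track: TagTrack, path: PathLike) -> None:
    """Write run-length-compressed bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom, vec in track.counts.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = int(vec[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models (GTF-lite tab table; 1-based inclusive on disk)


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Read a gene table (gene_id, chrom, start, end, strand; 1-based inclusive).

    Coordinates are converted to the internal 0-based half-open convention.
    """
    genes: List[GeneModel] = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "chrom", "start", "end", "strand"]
        if header[: len(required)] != required:
            raise FormatError(f"{path}:1: header must start with {required}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gene_id = f[0]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, f[1], int(f[2]) - 1, int(f[3]), f[4]))
    return genes


def write_gene_models(genes: List[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start + 1}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(
    path: PathLike,
    p_column: str = "p_value",
    length_column: str = "length",
) -> List[ExpressionRecord]:
    """Read a gene-level expression TSV.

    All columns other than gene_id, the p-value column and the length column
    are treated as per-sample FPKM. Missing p-values ("NA"/blank) default to
    1.0 — never significant — so incomplete rows cannot leak into DE lists.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", p_column, length_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    sample_cols = [c for c in df.columns if c not in ("gene_id", p_column, length_column)]
    records = []
    for _, row in df.iterrows():
        p = row[p_column]
        p = 1.0 if pd.isna(p) else float(p)
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                fpkm_by_sample={c: float(row[c]) for c in sample_cols},
                p_value=p,
                transcript_length=int(row[length_column]),
            )
        )
    return records


def expression_to_frame(records: List[ExpressionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "length": r.transcript_length, "p_value": r.p_value}
        row.update(r.fpkm_by_sample)
        rows.append(row)
    return pd.DataFrame(rows)


def write_expression_table(records: List[ExpressionRecord], path: PathLike) -> None:
    expression_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWM text (JASPAR-like count matrices)

_ROW_RE = re.compile(r"^\s*([ACGT])\s*\[?\s*([-\d.\s]+?)\s*\]?\s*$")


def read_pwm(
    path: PathLike,
    pseudo: float = 0.8,
    background: Optional[np.ndarray] = None,
) -> List[Pwm]:
    """Read JASPAR-style count matrices (4 rows A/C/G/T per ``>name`` block).

    Counts are smoothed to probabilities with a background-split pseudo-count
    (default 0.8, split by the background composition).
    """
    motifs: List[Pwm] = []
    name: Optional[str] = None
    rows: Dict[str, List[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(f"{path}:{lineno}: motif {name!r} missing base rows")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"{path}:{lineno}: motif {name!r} has unequal row lengths")
        counts = np.array([rows[b] for b in "ACGT"]).T
        motifs.append(Pwm.from_counts(name, counts, pseudo=pseudo, background=background))
        name, rows = None, {}

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0]
                continue
            m = _ROW_RE.match(line)
            if m is None:
                raise FormatError(f"{path}:{lineno}: unparseable PWM row")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
        flush(lineno)
    return motifs


def write_pwm_counts(named_counts: Dict[str, np.ndarray], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, counts in named_counts.items():
            fh.write(f">{name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(str(int(v)) for v in np.asarray(counts)[:, i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# term annotations (term_id, term_name, gene_id)


def read_annotations(path: PathLike) -> pd.DataFrame:
    """Read a term-annotation TSV into a tidy frame (one gene/term per row)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def annotations_to_sets(df: pd.DataFrame) -> Dict[Tuple[str, str], set]:
    """Group the tidy annotation frame into {(term_id, term_name): gene set}."""
    out: Dict[Tuple[str, str], set] = {}
    for (tid, tname), grp in df.groupby(["term_id", "term_name"], sort=True):
        out[(tid, tname)] = set(grp["gene_id"])
    return out
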