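"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open (BED convention). Inputs in 1-based
inclusive conventions (the GTF-lite gene table) are converted on read, so no
other module ever sees mixed conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic region [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Summit:
    """Single-base position of maximum signal within a called peak."""

    chrom: str
    pos: int
    source_condition: str = ""
    source_factor: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


class TagTrack:
    """Per-chromosome base-resolution tag coverage.

    Counts are stored as one non-negative integer vector per chromosome;
    ``total_tags`` is always the sum over all chromosomes.
    """

    def __init__(self, counts: Mapping[str, np.ndarray]):
        self.counts: Dict[str, np.ndarray] = {}
        for chrom, vec in counts.items():
            arr = np.asarray(vec, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"counts for {chrom} must be 1-D")
            if (arr < 0).any():
                raise ValueError(f"negative tag count on {chrom}")
            self.counts[chrom] = arr

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int]) -> "TagTrack":
        return cls({c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()})

    @property
    def total_tags(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.counts.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.counts

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.counts[chrom]


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its strand-implied transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class ExpressionRecord:
    """Gene-level FPKM across samples plus a differential P-value."""

    gene_id: str
    fpkm_by_sample: Dict[str, float]
    p_value: float
    transcript_length: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fpkm_by_sample.values()):
            raise ValueError(f"{self.gene_id}: FPKM must be >= 0")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.gene_id}: p-value outside [0, 1]")
        if self.transcript_length <= 0:
            raise ValueError(f"{self.gene_id}: transcript length must be > 0")


_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class Pwm:
    """Position weight matrix with log-odds (bits) scoring.

    ``matrix`` holds per-position base probabilities (rows = positions,
    columns = A, C, G, T) after pseudo-count smoothing; ``background`` is the
    genomic base composition the odds are taken against.
    """

    def __init__(
        self,
        name: str,
        matrix: np.ndarray,
        background: Optional[np.ndarray] = None,
        pseudo: float = 0.0,
    ):
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("matrix must have shape (L, 4)")
        if mat.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        sums = mat.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        self.name = name
        self.matrix = mat
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, float)
        )
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        self.pseudo = pseudo

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudo: float = 0.8,
        background: Optional[np.ndarray] = None,
    ) -> "Pwm":
        """Convert a count matrix to probabilities with background-split smoothing.

        Each cell becomes (count + pseudo * bg_base) / (column_total + pseudo).
        """
        cnt = np.asarray(counts, dtype=float)
        if cnt.ndim != 2 or cnt.shape[1] != 4:
            raise ValueError("count matrix must have shape (L, 4)")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        totals = cnt.sum(axis=1, keepdims=True)
        if (totals == 0).any() and pseudo == 0:
            raise ValueError("zero-count column requires pseudo > 0")
        prob = (cnt + pseudo * bg) / (totals + pseudo)
        return cls(name, prob, background=bg, pseudo=pseudo)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background); zero-probability cells -> -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            self.name,
            self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudo=self.pseudo,
        )


@dataclass(frozen=True)
class MotifHit:
    """A PWM match on genomic (or window) coordinates."""

    pwm_name: str
    chrom: str
    start: int
    strand: str
    score: float
    offset_from_center: Optional[int] = None


@dataclass(frozen=True)
class CompositeHit:
    """Two motif cores at constrained spacing (a bipartite motif)."""

    pwm_name_1: str
    pwm_name_2: str
    chrom: str
    start_1: int
    start_2: int
    strand_1: str
    strand_2: str
    gap: int


@dataclass
class PeakSet:
    """A labelled set of peaks (intervals + their summits + per-peak signal)."""

    label: str
    intervals: List[GenomicInterval]
    summits: List[Summit]
    signal: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.summits):
            raise ValueError("intervals and summits must be parallel lists")
        for iv, s in zip(self.intervals, self.summits):
            if not (iv.chrom == s.chrom and iv.start <= s.pos < iv.end):
                raise ValueError(f"summit {s} not inside its interval {iv}")
        if self.signal is not None:
            self.signal = np.asarray(self.signal, dtype=float)
            if len(self.signal) != len(self.intervals):
                raise ValueError("signal must be parallel to intervals")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class GeneLink:
    """Assignment of a peak to a gene with the geometric rule used."""

    peak_id: str
    gene_id: Optional[str]
    link_rule: str  # contains_peak | nearest_5prime | nearest_3prime | none
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.link_rule == "contains_peak" and self.distance != 0:
            raise ValueError("containing link must have distance 0")
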