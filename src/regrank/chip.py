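"""Multi-factor ChIP peak integration.

Intersection of two or three peak sets with Venn sector counts, signal-based
ranking of summits, cross-factor window matrices sharing one row order, and
genomic-location fractionation of peaks (promoter / intragenic / intergenic).

Venn counts are peak-centric on a declared reference set: peak boundaries
differ between factors, so region merging would change the totals each circle
reports. A merged-region mode is provided for comparison.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .accessibility import count_tags, window_matrix
from .model import GeneModel, GenomicInterval, PeakSet, Summit, TagTrack


def _overlap_any(iv: GenomicInterval, others: "ChromIndex") -> bool:
    return others.overlaps_interval(iv)


class ChromIndex:
    """Sorted per-chromosome interval index for overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: x.start)
            self._starts[chrom] = np.array([x.start for x in ivs], dtype=int)
            # running max of ends supports overlap queries on possibly nested intervals
            self._ends[chrom] = np.maximum.accumulate(np.array([x.end for x in ivs], dtype=int))

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._starts:
            return False
        starts, ends = self._starts[iv.chrom], self._ends[iv.chrom]
        # candidates with start < iv.end; any of them still open past iv.start?
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and ends[i - 1] > iv.start

    def near_summit(self, s: Summit, d: int) -> bool:
        if s.chrom not in self._starts:
            return False
        starts = self._starts[s.chrom]
        i = int(np.searchsorted(starts, s.pos))
        for j in (i - 1, i):
            if 0 <= j < len(starts) and abs(int(starts[j]) - s.pos) <= d:
                return True
        return False


def intersect_peak_sets(
    sets: Sequence[PeakSet],
    criterion: str = "overlap",
    summit_distance: int = 100,
) -> dict:
    """Annotate peak membership across 2-3 sets and count Venn sectors.

    ``criterion`` is "overlap" (>=1 bp interval overlap, the default) or
    "summit" (summits within ``summit_distance``, compared against the other
    set's summit positions). Sector counts are reported per reference set: for
    reference A of (A, B, C) the sectors partition A's peaks exactly.
    """
    if not (2 <= len(sets) <= 3):
        raise ValueError("intersect_peak_sets handles 2 or 3 peak sets")
    labels = [ps.label for ps in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("peak-set labels must be unique")

    if criterion == "overlap":
        indexes = {ps.label: ChromIndex(ps.intervals) for ps in sets}

        def hits(ps: PeakSet, i: int, other: PeakSet) -> bool:
            return indexes[other.label].overlaps_interval(ps.intervals[i])

    elif criterion == "summit":
        summit_ivs = {
            ps.label: ChromIndex(
                [GenomicInterval(s.chrom, s.pos, s.pos + 1) for s in ps.summits]
            )
            for ps in sets
        }

        def hits(ps: PeakSet, i: int, other: PeakSet) -> bool:
            return summit_ivs[other.label].near_summit(ps.summits[i], summit_distance)

    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    membership: Dict[str, pd.DataFrame] = {}
    sectors: Dict[str, Dict[str, int]] = {}
    for ps in sets:
        others = [o for o in sets if o.label != ps.label]
        cols = {"chrom": [iv.chrom for iv in ps.intervals],
                "start": [iv.start for iv in ps.intervals],
                "end": [iv.end for iv in ps.intervals]}
        flags = {}
        for other in others:
            flags[f"in_{other.label}"] = np.array(
                [hits(ps, i, other) for i in range(len(ps))], dtype=bool
            )
        df = pd.DataFrame({**cols, **flags})
        membership[ps.label] = df
        sec: Dict[str, int] = {}
        flag_mat = np.column_stack([flags[f"in_{o.label}"] for o in others]) \
            if others else np.zeros((len(ps), 0), dtype=bool)
        for combo in range(2 ** len(others)):
            mask = np.ones(len(ps), dtype=bool)
            present = []
            for j, other in enumerate(others):
                want = bool((combo >> j) & 1)
                mask &= flag_mat[:, j] == want
                if want:
                    present.append(other.label)
            key = "&".join([ps.label] + present) if present else f"{ps.label}_only"
            sec[key] = int(mask.sum())
        sectors[ps.label] = sec
    return {"membership": membership, "sectors": sectors, "labels": labels}


def triple_overlap_peaks(result: dict, reference: Optional[str] = None) -> pd.DataFrame:
    """Rows of the reference set overlapped by every other set."""
    ref = reference or result["labels"][0]
    df = result["membership"][ref]
    flag_cols = [c for c in df.columns if c.startswith("in_")]
    return df[df[flag_cols].all(axis=1)].reset_index(drop=True)


def merged_region_venn(sets: Sequence[PeakSet]) -> Dict[str, int]:
    """Venn on union-merged regions: each merged region is one countable unit."""
    events: Dict[str, List[Tuple[int, int, int]]] = {}
    for si, ps in enumerate(sets):
        for iv in ps.intervals:
            events.setdefault(iv.chrom, []).append((iv.start, iv.end, si))
    counts: Dict[frozenset, int] = {}
    for chrom, ivs in events.items():
        ivs.sort()
        cur_start, cur_end, members = None, None, set()
        for start, end, si in ivs:
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    key = frozenset(members)
                    counts[key] = counts.get(key, 0) + 1
                cur_start, cur_end, members = start, end, {si}
            else:
                cur_end = max(cur_end, end)
                members.add(si)
        if cur_end is not None:
            key = frozenset(members)
            counts[key] = counts.get(key, 0) + 1
    labels = [ps.label for ps in sets]
    return {
        "&".join(labels[i] for i in sorted(k)): v for k, v in counts.items()
    }


def rank_chip_peaks(peak_set: PeakSet, track: TagTrack, halfwidth: int = 100) -> PeakSet:
    """Order peaks by descending summit tag count (ties keep coordinate order)."""
    signal = np.array(
        [count_tags(track, s.chrom, s.pos, halfwidth) for s in peak_set.summits], dtype=float
    )
    order = sorted(
        range(len(peak_set)),
        key=lambda i: (-signal[i], peak_set.summits[i].chrom, peak_set.summits[i].pos),
    )
    return PeakSet(
        label=peak_set.label,
        intervals=[peak_set.intervals[i] for i in order],
        summits=[peak_set.summits[i] for i in order],
        signal=signal[order],
    )


def crossrank_matrix(
    ordering_peaks: PeakSet,
    tracks: Mapping[str, TagTrack],
    halfwidth: int = 1000,
    binsize: int = 10,
) -> dict:
    """Window matrices for several tracks, all in one fixed peak order.

    Returns per-track matrices plus their column-mean average profiles; the
    shared row order makes side-by-side heatmaps directly comparable.
    """
    centers = [(s.chrom, s.pos) for s in ordering_peaks.summits]
    matrices = {
        name: window_matrix(track, centers, halfwidth=halfwidth, binsize=binsize)
        for name, track in tracks.items()
    }
    profiles = {
        name: (m.mean(axis=0) if len(m) else np.zeros(m.shape[1]))
        for name, m in matrices.items()
    }
    return {"matrices": matrices, "profiles": profiles, "centers": centers}


PROMOTER = "promoter"
INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"


def annotate_peak_locations(
    peak_set: PeakSet,
    gene_models: Sequence[GeneModel],
    promoter_halfwidth: int = 2000,
) -> pd.DataFrame:
    """Label each peak summit promoter / intragenic / intergenic.

    Promoter (summit within +/-promoter_halfwidth of any TSS) takes precedence
    over gene-body containment; everything else is intergenic.
    """
    rows = []
    for iv, s in zip(peak_set.intervals, peak_set.summits):
        label = INTERGENIC
        chrom_genes = [g for g in gene_models if g.chrom == s.chrom]
        if any(abs(s.pos - g.tss) <= promoter_halfwidth for g in chrom_genes):
            label = PROMOTER
        elif any(g.start <= s.pos < g.end for g in chrom_genes):
            label = INTRAGENIC
        rows.append((s.chrom, s.pos, iv.start, iv.end, label))
    return pd.DataFrame(rows, columns=["chrom", "pos", "start", "end", "location"])


def location_fractions(annotation: pd.DataFrame) -> Dict[str, float]:
    n = len(annotation)
    if n == 0:
        return {PROMOTER: 0.0, INTRAGENIC: 0.0, INTERGENIC: 0.0}
    counts = annotation["location"].value_counts()
    return {k: float(counts.get(k, 0)) / n for k in (PROMOTER, INTRAGENIC, INTERGENIC)}
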