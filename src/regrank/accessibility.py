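"""Differential chromatin-accessibility ranking between two conditions.

The workflow: concatenate the summit calls from both conditions into a union,
sum tag counts in a window (default +/-100 bp, inclusive on both ends) around
each summit in each condition's track, form the log2 fold change
log2((B + pc) / (A + pc)), sort by increasing fold change, and classify each
site as A-enriched, shared or B-enriched against a fold-change threshold.

Counts are depth-normalised to tags-per-10-million by default so libraries of
unequal depth are comparable; classification is invariant to any common
scaling of both tracks.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import Summit, TagTrack

A_ENRICHED = "A_enriched"
B_ENRICHED = "B_enriched"
SHARED = "shared"


def count_tags(track: TagTrack, chrom: str, center: int, halfwidth: int) -> int:
    """Sum of tags in [center - halfwidth, center + halfwidth], inclusive.

    The window is truncated at chromosome bounds; an unknown chromosome is an
    error rather than a silent zero.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if chrom not in track:
        raise KeyError(f"chromosome {chrom!r} not in track")
    vec = track[chrom]
    lo = max(0, center - halfwidth)
    hi = min(len(vec), center + halfwidth + 1)
    if hi <= lo:
        return 0
    return int(vec[lo:hi].sum())


def build_summit_union(
    summits_a: Sequence[Summit],
    summits_b: Sequence[Summit],
    merge_distance: int = 0,
    track: Optional[TagTrack] = None,
    halfwidth: int = 100,
) -> List[Summit]:
    """Concatenate two summit lists into the analysis union.

    With ``merge_distance`` 0 (default) this is a pure concatenation. With a
    positive distance, summits within that distance on the same chromosome are
    collapsed to the one with the higher local tag count (requires ``track``;
    ties go to the smaller coordinate). Provenance labels are retained.
    """
    union = list(summits_a) + list(summits_b)
    if merge_distance <= 0:
        return union

    def local_count(s: Summit) -> int:
        if track is None:
            return 0
        return count_tags(track, s.chrom, s.pos, halfwidth)

    by_chrom: dict = {}
    for s in union:
        by_chrom.setdefault(s.chrom, []).append(s)

    kept: List[Summit] = []
    for chrom in by_chrom:
        pending = sorted(by_chrom[chrom], key=lambda s: s.pos)
        # Greedy single-link clustering along the chromosome, then pick the
        # strongest member of each cluster.
        clusters: List[List[Summit]] = []
        for s in pending:
            if clusters and s.pos - clusters[-1][-1].pos <= merge_distance:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        for cl in clusters:
            best = max(cl, key=lambda s: (local_count(s), -s.pos))
            kept.append(best)
    kept.sort(key=lambda s: (s.chrom, s.pos))
    return kept


def rank_sites(
    union: Sequence[Summit],
    track_a: TagTrack,
    track_b: TagTrack,
    halfwidth: int = 100,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Rank union sites by increasing log2 B/A fold change.

    Returns the ranked site table with columns chrom, pos, source_condition,
    count_a, count_b, log2fc and rank (1..n). The sort is stable: ties keep
    (chrom, pos) order, so heatmap row order is reproducible.
    """
    rows = []
    for s in union:
        ca = count_tags(track_a, s.chrom, s.pos, halfwidth)
        cb = count_tags(track_b, s.chrom, s.pos, halfwidth)
        rows.append((s.chrom, s.pos, s.source_condition, ca, cb))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "source_condition", "count_a", "count_b"])
    ca = df["count_a"].to_numpy(dtype=float)
    cb = df["count_b"].to_numpy(dtype=float)
    if normalize and len(df):
        ca = ca * 1e7 / max(track_a.total_tags, 1)
        cb = cb * 1e7 / max(track_b.total_tags, 1)
    df["norm_a"] = ca
    df["norm_b"] = cb
    df["log2fc"] = np.log2((cb + pseudocount) / (ca + pseudocount))
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    df = df.sort_values("log2fc", kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def classify_sites(table: pd.DataFrame, log2_threshold: float = 1.0) -> pd.DataFrame:
    """Label sites by fold change: < -t -> A_enriched, > +t -> B_enriched.

    Inequalities are strict, so a site at exactly +/-threshold is shared. Adds
    a ``class_label`` column and returns the table (class counts partition n).
    """
    if log2_threshold < 0:
        raise ValueError("log2_threshold must be >= 0")
    fc = table["log2fc"].to_numpy()
    labels = np.full(len(table), SHARED, dtype=object)
    labels[fc < -log2_threshold] = A_ENRICHED
    labels[fc > log2_threshold] = B_ENRICHED
    out = table.copy()
    out["class_label"] = labels
    return out


def class_counts(table: pd.DataFrame) -> dict:
    counts = table["class_label"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in (A_ENRICHED, SHARED, B_ENRICHED)}


def window_matrix(
    track: TagTrack,
    ordered_centers: Iterable[tuple],
    halfwidth: int = 1000,
    binsize: int = 10,
) -> np.ndarray:
    """Binned tag counts around each (chrom, pos) center, in the given order.

    Row i covers [pos_i - halfwidth, pos_i + halfwidth) in ``binsize`` bins;
    windows clipped by a chromosome edge are zero-padded so every row has the
    same shape. This is the heatmap substrate: pass centers in ranked order.
    """
    if (2 * halfwidth) % binsize != 0:
        raise ValueError("2*halfwidth must be divisible by binsize")
    n_bins = (2 * halfwidth) // binsize
    centers = list(ordered_centers)
    mat = np.zeros((len(centers), n_bins), dtype=np.int64)
    for i, (chrom, pos) in enumerate(centers):
        if chrom not in track:
            continue
        vec = track[chrom]
        lo, hi = pos - halfwidth, pos + halfwidth
        src_lo, src_hi = max(0, lo), min(len(vec), hi)
        if src_hi <= src_lo:
            continue
        window = np.zeros(2 * halfwidth, dtype=np.int64)
        window[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
        mat[i] = window.reshape(n_bins, binsize).sum(axis=1)
    return mat
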