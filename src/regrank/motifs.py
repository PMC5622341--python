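"""PWM scanning, bipartite composite detection and motif co-localization.

Scores are log-odds in bits against the PWM's background composition; the
scan threshold is expressed as a fraction of the motif's maximum attainable
score (default 0.80) so one setting behaves comparably across matrices of
different length and information content. Both strands are scanned and, per
window, the better-scoring strand is reported.

The bootstrap co-localization test asks whether the top-ranked fraction of a
differential-accessibility table carries BOTH motifs of a pair more often
than equally sized site sets drawn from the whole union.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import CompositeHit, MotifHit, Pwm

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in sequence.upper()), dtype=np.int8,
                       count=len(sequence))


def _scores_forward(codes: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Score every window start on the forward strand; N contributes 0 bits."""
    L = len(pwm)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.zeros(0)
    lom = pwm.log_odds  # (L, 4)
    scores = np.zeros(n_win)
    for i in range(L):
        base = codes[i : i + n_win]
        contrib = np.where(base == 4, 0.0, lom[i, np.minimum(base, 3)])
        scores += contrib
    return scores


def resolve_threshold(pwm: Pwm, threshold: Optional[float], frac_of_max: float) -> float:
    if threshold is not None:
        return float(threshold)
    return frac_of_max * pwm.max_score


def scan_pwm(
    sequence: str,
    pwm: Pwm,
    threshold: Optional[float] = None,
    frac_of_max: float = 0.8,
    chrom: str = "seq",
) -> List[MotifHit]:
    """Scan one sequence with one PWM on both strands.

    ``threshold`` is an absolute score in bits; when omitted, the threshold is
    ``frac_of_max * pwm.max_score``. Per window only the better strand is
    reported (ties go to +). A threshold above the maximum score yields an
    empty result with a warning rather than an error.
    """
    thr = resolve_threshold(pwm, threshold, frac_of_max)
    if thr > pwm.max_score:
        warnings.warn(
            f"threshold {thr:.3f} exceeds max score {pwm.max_score:.3f} of {pwm.name}; "
            "no hit can pass",
            stacklevel=2,
        )
        return []
    codes = _encode(sequence)
    fwd = _scores_forward(codes, pwm)
    rev = _scores_forward(codes, pwm.reverse_complement())
    hits: List[MotifHit] = []
    for start in np.flatnonzero(np.maximum(fwd, rev) >= thr):
        if fwd[start] >= rev[start]:
            score, strand = fwd[start], "+"
        else:
            score, strand = rev[start], "-"
        hits.append(MotifHit(pwm.name, chrom, int(start), strand, float(score)))
    return hits


def scan_around_sites(
    genome: Mapping[str, str],
    sites: Sequence[Tuple[str, int]],
    pwms: Sequence[Pwm],
    halfwidth: int = 1000,
    threshold: Optional[float] = None,
    frac_of_max: float = 0.8,
) -> Dict[Tuple[str, int], List[MotifHit]]:
    """Scan a +/-halfwidth window around each (chrom, pos) site.

    Returns per-site hit lists with genomic ``start`` and a signed
    ``offset_from_center`` (hit midpoint minus summit position).
    """
    out: Dict[Tuple[str, int], List[MotifHit]] = {}
    for chrom, pos in sites:
        seq = genome[chrom]
        lo = max(0, pos - halfwidth)
        hi = min(len(seq), pos + halfwidth + 1)
        window = seq[lo:hi]
        site_hits: List[MotifHit] = []
        for pwm in pwms:
            for h in scan_pwm(window, pwm, threshold=threshold,
                              frac_of_max=frac_of_max, chrom=chrom):
                gstart = lo + h.start
                offset = gstart + len(pwm) // 2 - pos
                if abs(offset) <= halfwidth:
                    site_hits.append(
                        MotifHit(pwm.name, chrom, gstart, h.strand, h.score,
                                 offset_from_center=offset)
                    )
        site_hits.sort(key=lambda h: (h.start, h.pwm_name))
        out[(chrom, pos)] = site_hits
    return out


def composite_scan(
    sequence: str,
    pwm1: Pwm,
    pwm2: Pwm,
    min_gap: int = 0,
    max_gap: int = 20,
    threshold: Optional[float] = None,
    frac_of_max: float = 0.8,
    chrom: str = "seq",
) -> List[CompositeHit]:
    """Find bipartite motifs: a pwm1 and a pwm2 core with an inner gap in range.

    Both orders along the sequence count (pwm1 then pwm2, and pwm2 then pwm1)
    and duplicates are removed; overlapping cores never pair (gap >= 0 is
    enforced through ``min_gap >= 0``).
    """
    if not (0 <= min_gap <= max_gap):
        raise ValueError("need 0 <= min_gap <= max_gap")
    hits1 = scan_pwm(sequence, pwm1, threshold=threshold, frac_of_max=frac_of_max, chrom=chrom)
    hits2 = scan_pwm(sequence, pwm2, threshold=threshold, frac_of_max=frac_of_max, chrom=chrom)
    out: List[CompositeHit] = []
    seen = set()
    for first_hits, second_hits, len1, len2 in (
        (hits1, hits2, len(pwm1), len(pwm2)),
        (hits2, hits1, len(pwm2), len(pwm1)),
    ):
        starts2 = np.array([h.start for h in second_hits], dtype=int)
        for h1 in first_hits:
            end1 = h1.start + len1
            lo = np.searchsorted(starts2, end1 + min_gap, side="left")
            hi = np.searchsorted(starts2, end1 + max_gap, side="right")
            for j in range(lo, hi):
                h2 = second_hits[j]
                gap = h2.start - end1
                key = (h1.pwm_name, h1.start, h2.pwm_name, h2.start)
                rkey = (h2.pwm_name, h2.start, h1.pwm_name, h1.start)
                if key in seen or rkey in seen:
                    continue
                seen.add(key)
                out.append(
                    CompositeHit(h1.pwm_name, h2.pwm_name, chrom, h1.start, h2.start,
                                 h1.strand, h2.strand, gap)
                )
    out.sort(key=lambda c: (c.start_1, c.start_2))
    return out


def motif_matrix(
    hits_by_site: Mapping[Tuple[str, int], List[MotifHit]],
    ordered_sites: Sequence[Tuple[str, int]],
    halfwidth: int = 1000,
    binsize: int = 10,
    pwm_name: Optional[str] = None,
    binary: bool = True,
) -> np.ndarray:
    """Motif-occurrence matrix over ranked sites (rows) and position bins.

    Row order follows ``ordered_sites`` (the ranked-site order); bin b covers
    offsets [-halfwidth + b*binsize, -halfwidth + (b+1)*binsize).
    """
    if (2 * halfwidth) % binsize != 0:
        raise ValueError("2*halfwidth must be divisible by binsize")
    n_bins = (2 * halfwidth) // binsize
    mat = np.zeros((len(ordered_sites), n_bins), dtype=np.int64)
    for i, site in enumerate(ordered_sites):
        for h in hits_by_site.get(site, ()):  # sites with no hits stay zero
            if pwm_name is not None and h.pwm_name != pwm_name:
                continue
            if h.offset_from_center is None:
                continue
            b = (h.offset_from_center + halfwidth) // binsize
            if 0 <= b < n_bins:
                mat[i, b] += 1
    return (mat > 0).astype(np.int64) if binary else mat


def class_profiles(
    matrix: np.ndarray,
    class_labels: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> Dict[str, np.ndarray]:
    """Column-wise mean profile per site class.

    An empty class yields an all-NaN profile (flagged, not an exception) so
    plots can show the gap explicitly.
    """
    labels = np.asarray(class_labels, dtype=object)
    if len(labels) != matrix.shape[0]:
        raise ValueError("class_labels must have one entry per matrix row")
    if classes is None:
        classes = list(dict.fromkeys(labels))
    profiles: Dict[str, np.ndarray] = {}
    for cls in classes:
        rows = matrix[labels == cls]
        if rows.shape[0] == 0:
            profiles[cls] = np.full(matrix.shape[1], np.nan)
        else:
            profiles[cls] = rows.mean(axis=0)
    return profiles


def bootstrap_colocalization(
    ranked_table: pd.DataFrame,
    hits_by_site: Mapping[Tuple[str, int], List[MotifHit]],
    motif_pair: Tuple[str, str],
    top_fraction: float = 0.10,
    window: Optional[int] = None,
    n_boot: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> dict:
    """Bootstrap test for motif co-localization in top-ranked sites.

    The statistic is the fraction of the top ``top_fraction`` of ranked sites
    whose window contains hits of BOTH motifs. The null resamples equally
    sized site sets from the full union (without replacement by default, to
    avoid duplicate-site artefacts at small sampling fractions).
    empirical_p = (1 + #{null >= observed}) / (n_boot + 1).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n = len(ranked_table)
    k = max(1, int(round(top_fraction * n)))
    if k > n:
        raise ValueError("top set larger than the site union")
    name1, name2 = motif_pair

    def within(h: MotifHit) -> bool:
        return window is None or (
            h.offset_from_center is not None and abs(h.offset_from_center) <= window
        )

    has_both = np.zeros(n, dtype=bool)
    for i, (chrom, pos) in enumerate(zip(ranked_table["chrom"], ranked_table["pos"])):
        names = {h.pwm_name for h in hits_by_site.get((chrom, pos), ()) if within(h)}
        has_both[i] = name1 in names and name2 in names

    observed = float(has_both[:k].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(n, size=k, replace=replace)
        null[b] = has_both[idx].mean()
    empirical_p = (1 + int((null >= observed).sum())) / (n_boot + 1)
    return {
        "observed_stat": observed,
        "null_distribution": null,
        "empirical_p": float(empirical_p),
        "n_top": k,
        "n_boot": n_boot,
        "seed": seed,
    }
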