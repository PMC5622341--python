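"""Linking peaks to genes and binding strength to differential expression.

Implements the differential-expression gene filter (P < 0.05, transcript
longer than 200 bp, FPKM > 10 in at least one sample; all strict), summit-to-
nearest-gene assignment, peak-rank-ordered fold-change tables, direction
fractions and >fold-change tallies.

"Nearest" is measured from the peak summit to the closer gene boundary (the
side-based 5'/3' reading), not to the TSS; a TSS mode is available. Genes
linked by several peaks appear once per peak occurrence in rank tables,
flagged, because those tables are peak-indexed.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ExpressionRecord, GeneLink, GeneModel, PeakSet, Summit


def de_filter(
    records: Sequence[ExpressionRecord],
    p_max: float = 0.05,
    min_length: int = 200,
    min_fpkm: float = 10.0,
) -> List[str]:
    """Differentially expressed gene filter; all three predicates are strict.

    Keeps genes with p < p_max AND transcript length > min_length AND FPKM >
    min_fpkm in at least one sample.
    """
    kept = []
    for r in records:
        if (
            r.p_value < p_max
            and r.transcript_length > min_length
            and max(r.fpkm_by_sample.values(), default=0.0) > min_fpkm
        ):
            kept.append(r.gene_id)
    return kept


def _boundary_distance(pos: int, gene: GeneModel) -> int:
    """Distance from a summit to the nearer gene boundary (0 if inside)."""
    if gene.start <= pos < gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - (gene.end - 1)


def nearest_gene(
    peak: Summit,
    gene_models: Sequence[GeneModel],
    mode: str = "boundary",
) -> GeneLink:
    """Assign a peak summit to its gene.

    A summit inside a gene body links to that gene (smallest enclosing span if
    nested) with rule ``contains_peak``. Otherwise the gene at minimum
    distance wins; ``mode`` chooses the distance anchor ("boundary" — the
    nearer gene edge, the default — or "tss"). Exact ties go to the upstream
    (5'-side, lower-coordinate) gene. A chromosome without genes links to
    nothing, flagged with rule ``none``.
    """
    peak_id = f"{peak.chrom}:{peak.pos}"
    candidates = [g for g in gene_models if g.chrom == peak.chrom]
    if not candidates:
        return GeneLink(peak_id, None, "none", 0)
    containing = [g for g in candidates if g.start <= peak.pos < g.end]
    if containing:
        best = min(containing, key=lambda g: (g.end - g.start, g.start, g.gene_id))
        return GeneLink(peak_id, best.gene_id, "contains_peak", 0)

    def dist(g: GeneModel) -> int:
        if mode == "tss":
            return abs(peak.pos - g.tss)
        return _boundary_distance(peak.pos, g)

    def side_key(g: GeneModel) -> int:
        # 0 for the 5'-side (gene left of summit) so ties prefer upstream
        return 0 if g.end <= peak.pos else 1

    best = min(candidates, key=lambda g: (dist(g), side_key(g), g.start, g.gene_id))
    rule = "nearest_5prime" if best.end <= peak.pos else "nearest_3prime"
    return GeneLink(peak_id, best.gene_id, rule, dist(best))


def link_peaks(
    peak_set: PeakSet, gene_models: Sequence[GeneModel], mode: str = "boundary"
) -> List[GeneLink]:
    return [nearest_gene(s, gene_models, mode=mode) for s in peak_set.summits]


def mean_fpkm(
    records: Sequence[ExpressionRecord], sample_prefix: Optional[str] = None
) -> Dict[str, float]:
    """Per-gene mean FPKM, optionally restricted to samples with a prefix."""
    out = {}
    for r in records:
        vals = [
            v
            for k, v in r.fpkm_by_sample.items()
            if sample_prefix is None or k.startswith(sample_prefix)
        ]
        if not vals:
            raise ValueError(f"no samples matching prefix {sample_prefix!r}")
        out[r.gene_id] = float(np.mean(vals))
    return out


def fc_by_rank_table(
    ranked_peaks: PeakSet,
    links: Sequence[GeneLink],
    expr_by_stage: Mapping[str, Sequence[ExpressionRecord]],
    cond_a_prefix: str,
    cond_b_prefix: str,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-gene log2(FPKM_A / FPKM_B) in peak-rank order, one column per stage.

    Rows follow the peak ranking; a gene linked by several peaks appears once
    per peak, with ``duplicate_gene`` set on repeats.
    """
    if len(links) != len(ranked_peaks):
        raise ValueError("links must be parallel to the ranked peaks")
    stage_means = {
        stage: (mean_fpkm(recs, cond_a_prefix), mean_fpkm(recs, cond_b_prefix))
        for stage, recs in expr_by_stage.items()
    }
    rows = []
    seen: set = set()
    for rank, (summit, link) in enumerate(zip(ranked_peaks.summits, links), start=1):
        if link.gene_id is None:
            continue
        row = {
            "rank": rank,
            "chrom": summit.chrom,
            "pos": summit.pos,
            "gene_id": link.gene_id,
            "link_rule": link.link_rule,
            "signal": float(ranked_peaks.signal[rank - 1])
            if ranked_peaks.signal is not None
            else np.nan,
            "duplicate_gene": link.gene_id in seen,
        }
        seen.add(link.gene_id)
        for stage, (ma, mb) in stage_means.items():
            if link.gene_id not in ma:
                raise KeyError(f"gene {link.gene_id!r} missing from stage {stage!r}")
            row[f"log2fc_{stage}"] = float(
                np.log2((ma[link.gene_id] + pseudocount) / (mb[link.gene_id] + pseudocount))
            )
        rows.append(row)
    return pd.DataFrame(rows)


def direction_fraction(
    gene_list: Sequence[str],
    expr_x: Sequence[ExpressionRecord],
    expr_y: Sequence[ExpressionRecord],
    sample_prefix_x: Optional[str] = None,
    sample_prefix_y: Optional[str] = None,
) -> dict:
    """Fraction of genes with higher mean FPKM in X than in Y (strict).

    Ties count toward neither direction and are reported separately.
    """
    if len(gene_list) == 0:
        raise ValueError("gene list is empty")
    mx = mean_fpkm(expr_x, sample_prefix_x)
    my = mean_fpkm(expr_y, sample_prefix_y)
    n_x = n_y = n_tie = 0
    for g in gene_list:
        if g not in mx or g not in my:
            raise KeyError(f"gene {g!r} missing from an expression table")
        if mx[g] > my[g]:
            n_x += 1
        elif my[g] > mx[g]:
            n_y += 1
        else:
            n_tie += 1
    n = len(gene_list)
    return {
        "fraction_x_higher": n_x / n,
        "fraction_y_higher": n_y / n,
        "fraction_tied": n_tie / n,
        "n": n,
    }


def fold_change_tally(
    linked_genes: Sequence[str],
    expr_a: Sequence[ExpressionRecord],
    expr_b: Sequence[ExpressionRecord],
    fold: float = 4.0,
    pseudocount: float = 0.1,
    sample_prefix_a: Optional[str] = None,
    sample_prefix_b: Optional[str] = None,
) -> dict:
    """Count genes changed more than ``fold``-fold in either direction.

    n_up counts FPKM_A / (FPKM_B + pc) > fold; n_down is symmetric; a ratio of
    exactly ``fold`` counts in neither (strict inequalities).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    ma = mean_fpkm(expr_a, sample_prefix_a)
    mb = mean_fpkm(expr_b, sample_prefix_b)
    n_up = n_down = 0
    for g in linked_genes:
        a, b = ma[g], mb[g]
        if a / (b + pseudocount) > fold:
            n_up += 1
        if b / (a + pseudocount) > fold:
            n_down += 1
    return {"n_up": n_up, "n_down": n_down, "n": len(linked_genes)}
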