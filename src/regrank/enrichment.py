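"""Local term enrichment with the EASE statistic and redundancy filtering.

The EASE score is a conservative variant of the one-sided Fisher exact test:
the list-hit count is decremented by one before taking the hypergeometric
upper tail, so a single-gene overlap can never look significant (its p is
exactly 1). Reporting mirrors the conventional recipe: keep terms with p
below a cutoff, drop terms redundant with an already-kept better term
(greedy gene-set Jaccard filter), and present the top 10.

No multiple-testing correction is applied by default — the raw P < 0.05 rule
is the convention being reproduced — but a Benjamini-Hochberg column can be
requested.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def ease_p_value(n_list_hits: int, n_list: int, n_background_hits: int, n_background: int) -> float:
    """EASE p: hypergeometric P(X >= n_list_hits - 1) with original margins.

    The floor: one list hit decrements to zero, whose upper tail is 1.
    """
    if not (0 <= n_list_hits <= n_list <= n_background):
        raise ValueError("inconsistent table margins")
    if n_list_hits > n_background_hits:
        raise ValueError("list hits exceed background hits")
    k = n_list_hits - 1
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_background, n_background_hits, n_list))


def fisher_p_value(n_list_hits: int, n_list: int, n_background_hits: int, n_background: int) -> float:
    """Plain one-sided Fisher exact p (hypergeometric upper tail)."""
    if n_list_hits <= 0:
        return 1.0
    return float(stats.hypergeom.sf(n_list_hits - 1, n_background, n_background_hits, n_list))


def ease_enrichment(
    gene_list: Sequence[str],
    background: Sequence[str],
    annotations: Mapping[Tuple[str, str], Set[str]],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Score every annotated term against a gene list.

    ``annotations`` maps (term_id, term_name) to gene sets. Terms with zero
    list hits are omitted. Results are sorted by ease_p (ties by term_id);
    ``bh_correct=True`` adds a Benjamini-Hochberg ``ease_q`` column without
    changing the ordering.
    """
    list_set = set(gene_list)
    bg_set = set(background)
    if not list_set <= bg_set:
        missing = sorted(list_set - bg_set)[:3]
        raise ValueError(f"gene list is not a subset of the background (e.g. {missing})")
    n_list, n_bg = len(list_set), len(bg_set)
    rows = []
    for (term_id, term_name), genes in annotations.items():
        term_bg = genes & bg_set
        hits = genes & list_set
        if not hits:
            continue
        k, K = len(hits), len(term_bg)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "n_list_hits": k,
                "n_list": n_list,
                "n_background_hits": K,
                "n_background": n_bg,
                "ease_p": ease_p_value(k, n_list, K, n_bg),
                "fisher_p": fisher_p_value(k, n_list, K, n_bg),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "n_list_hits", "n_list",
            "n_background_hits", "n_background", "ease_p", "fisher_p",
        ],
    )
    df = df.sort_values(["ease_p", "term_id"], kind="mergesort").reset_index(drop=True)
    if bh_correct and len(df):
        df["ease_q"] = stats.false_discovery_control(df["ease_p"].to_numpy())
    return df


def report_terms(
    results: pd.DataFrame,
    annotations: Mapping[Tuple[str, str], Set[str]],
    p_max: float = 0.05,
    jaccard_max: float = 0.5,
    top_k: int = 10,
    background: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Significance + redundancy filter, truncated to the top terms.

    Walks the results in ascending ease_p, keeps a term only if its p is
    below ``p_max`` and its gene set's Jaccard similarity with every
    already-kept term is at most ``jaccard_max``, and stops after ``top_k``
    terms. Gene sets are restricted to the background when one is given.
    """
    bg = set(background) if background is not None else None
    sets: Dict[str, Set[str]] = {}
    for (tid, _), genes in annotations.items():
        sets[tid] = genes & bg if bg is not None else set(genes)
    kept_rows = []
    kept_sets: list = []
    for _, row in results.sort_values(["ease_p", "term_id"], kind="mergesort").iterrows():
        if row["ease_p"] >= p_max:
            continue
        gs = sets.get(row["term_id"], set())
        redundant = False
        for other in kept_sets:
            union = gs | other
            jac = len(gs & other) / len(union) if union else 1.0
            if jac > jaccard_max:
                redundant = True
                break
        if redundant:
            continue
        kept_rows.append(row)
        kept_sets.append(gs)
        if len(kept_rows) >= top_k:
            break
    return pd.DataFrame(kept_rows).reset_index(drop=True)
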