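"""Primary-target enrichment among hit compounds.

For every annotated primary-target gene, a one-sided Fisher's exact test
asks whether the gene is over-represented among the hit compounds relative
to all screened compounds; p-values are corrected across genes with the
Benjamini-Hochberg step-up procedure.  Compounds without annotation are
excluded from the per-gene counts (and reported); compounds with several
primary targets contribute once to each target's count.

The annotation table is a tidy CSV/DataFrame with one row per
compound-gene: ``compound_id, gene`` plus free-text ``moa`` and
``indication`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_gene", "bh_adjust", "enrich_targets"]


def fisher_gene(gene: str, hit_ids: set[str], screened_ids: set[str],
                annotations: pd.DataFrame) -> tuple[float, float]:
    """One-sided Fisher's exact test (over-representation) for one gene.

    The 2x2 table crosses gene-annotation with hit status over the
    annotated screened compounds.  Returns ``(p, odds_ratio)``; the p-value
    is the hypergeometric upper tail P(X >= observed hit count among the
    gene's compounds).
    """
    ann = annotations[annotations["compound_id"].isin(screened_ids)]
    annotated = set(ann["compound_id"])
    if not annotated:
        raise ValueError("no annotated screened compounds")
    gene_ids = set(ann.loc[ann["gene"] == gene, "compound_id"])
    if not gene_ids:
        raise KeyError(f"gene {gene!r} absent from annotations")
    hits = hit_ids & annotated
    n_total = len(annotated)
    n_gene = len(gene_ids)
    n_hit = len(hits)
    k = len(gene_ids & hits)
    p = float(hypergeom.sf(k - 1, n_total, n_gene, n_hit))
    a, b = k, n_hit - k
    c, d = n_gene - k, n_total - n_gene - n_hit + k
    odds = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else a * d / (b * c))
    return p, float(odds)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_targets(hit_ids, screened_ids, annotations: pd.DataFrame,
                   min_count: int = 2, alpha: float = 0.05,
                   significant_if: str = "less") -> pd.DataFrame:
    """Ranked per-gene enrichment table for a hit list.

    Returns one row per gene with the 2x2 counts, odds ratio, raw and
    BH-adjusted p, a ``significant`` flag (p_adj < alpha by default;
    ``significant_if="greater"`` applies the literal opposite reading) and
    a ``displayed`` flag suppressing genes backed by fewer than
    ``min_count`` hit compounds from display output while retaining them
    in the full table.  Rows are sorted by adjusted then raw p.
    """
    hit_ids = set(hit_ids)
    screened_ids = set(screened_ids)
    if not hit_ids <= screened_ids:
        raise ValueError("hit set must be a subset of the screened set")
    ann = annotations[annotations["compound_id"].isin(screened_ids)]
    if ann.empty or not hit_ids:
        return pd.DataFrame(columns=[
            "gene", "hits_with_gene", "hits_total", "screened_with_gene",
            "screened_total", "odds_ratio", "p", "p_adj", "significant",
            "displayed", "n_unannotated"])
    annotated = set(ann["compound_id"])
    n_unann = len(screened_ids - annotated)
    hits = hit_ids & annotated
    n_total, n_hit = len(annotated), len(hits)
    dedup = ann.drop_duplicates(["compound_id", "gene"])
    per_gene = dedup.groupby("gene")["compound_id"].agg(
        K="nunique", k=lambda ids: ids.isin(hits).sum())
    k = per_gene["k"].to_numpy(int)
    K = per_gene["K"].to_numpy(int)
    p = hypergeom.sf(k - 1, n_total, K, n_hit)
    a, b = k, n_hit - k
    c, d = K - k, n_total - K - n_hit + k
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(b * c == 0,
                        np.where(a * d > 0, np.inf, np.nan),
                        a * d / np.maximum(b * c, 1))
    out = pd.DataFrame({"gene": per_gene.index, "hits_with_gene": k,
                        "hits_total": n_hit, "screened_with_gene": K,
                        "screened_total": n_total, "odds_ratio": odds,
                        "p": p})
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    if significant_if == "less":
        out["significant"] = out["p_adj"] < alpha
    elif significant_if == "greater":
        out["significant"] = out["p_adj"] > alpha
    else:
        raise ValueError(f"unknown significant_if {significant_if!r}")
    out["displayed"] = out["hits_with_gene"] >= min_count
    out["n_unannotated"] = n_unann
    return out.sort_values(["p_adj", "p", "gene"]).reset_index(drop=True)
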