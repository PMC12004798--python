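"""Hypergeometric enrichment of annotation categories among CNVR overlaps.

For a universe of N annotation units (QTLs, or genes in gene-set mode) of
which m overlap CNVRs, a category containing S units with k of them
overlapping is scored with the hypergeometric upper tail

    P = 1 - sum_{i=0}^{k-1} C(S, i) C(N-S, m-i) / C(N, m),

computed in log-gamma space. P-values over all tested categories are
adjusted with the Benjamini-Hochberg step-up procedure; a category is
enriched when the adjusted value is below alpha (default 5%).

Units are counted distinctly: a QTL hit by several regions counts once in
both m and k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, S: int, N: int, m: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, S, m), stable in log space.

    Parameters follow the QTL-enrichment convention: N units in the
    universe, S in the category, m overlapping regions, k overlapping units
    in the category.
    """
    k, S, N, m = int(k), int(S), int(N), int(m)
    if not (0 <= S <= N and 0 <= m <= N):
        raise ValueError(f"invalid universe: S={S}, m={m}, N={N}")
    if k < 0 or k > min(S, m):
        if k <= 0:
            return 1.0
        raise ValueError(f"k={k} exceeds min(S, m)={min(S, m)}")
    if k == 0:
        return 1.0
    imin = max(0, m - (N - S))
    imax = min(S, m)
    if k <= imin:
        return 1.0
    i = np.arange(imin, imax + 1)
    log_terms = (_log_comb(np.full_like(i, S), i)
                 + _log_comb(np.full_like(i, N - S), m - i))
    # self-normalizing ratio of sums: the shared log C(N, m) scale cancels,
    # leaving near machine-precision tails
    upper = log_terms[i >= k]
    if len(upper) == 0:
        return 0.0
    p = np.exp(logsumexp(upper) - logsumexp(log_terms))
    return float(min(1.0, max(0.0, p)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def enrich(counts: pd.DataFrame, N: int, m: int,
           alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Score every category and adjust jointly.

    Parameters
    ----------
    counts
        One row per category with columns (category, S, k): S distinct units
        in the category, k of them overlapping.
    N, m
        Universe size and number of overlapping units (distinct ids).

    Returns one row per category with raw and FDR-adjusted p-values and the
    enriched flag, sorted by adjusted p-value.
    """
    if N <= 0:
        raise ValueError("empty universe")
    counts = counts[counts["S"] >= 1].reset_index(drop=True)
    p = np.array([
        hypergeom_upper_tail(int(r.k), int(r.S), N, m)
        for r in counts.itertuples(index=False)
    ])
    out = counts.copy()
    out["m"] = m
    out["N"] = N
    out["p_value"] = p
    out["p_fdr"] = bh_fdr(p) if len(p) else p
    out["enriched"] = out["p_fdr"] < alpha
    return out.sort_values(["p_fdr", "p_value", "category"],
                           kind="mergesort").reset_index(drop=True)


def qtl_enrichment(qtls: pd.DataFrame, overlaps: pd.DataFrame,
                   alpha: float = DEFAULT_ALPHA,
                   id_col: str = "qtl_id",
                   category_col: str = "trait") -> pd.DataFrame:
    """Trait-level enrichment of QTLs overlapping CNVRs.

    ``qtls`` is the full annotation table (the universe: every record with
    usable coordinates); ``overlaps`` is the overlap table from the
    annotator (``annotation_id`` column). Counting is on distinct unit ids.
    """
    universe = qtls.drop_duplicates(subset=id_col)
    N = len(universe)
    hit_ids = set(overlaps["annotation_id"].unique())
    is_hit = universe[id_col].isin(hit_ids)
    m = int(is_hit.sum())
    counts = (universe.assign(hit=is_hit)
              .groupby(category_col)
              .agg(S=(id_col, "nunique"), k=("hit", "sum"))
              .reset_index()
              .rename(columns={category_col: "category"}))
    counts["k"] = counts["k"].astype(int)
    return enrich(counts, N=N, m=m, alpha=alpha)


def geneset_enrichment(term_to_genes: dict[str, set[str]],
                       universe_genes, overlapping_genes,
                       alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Term-level enrichment with the identical machinery, gene universe.

    N = genes in the universe, m = universe genes overlapping CNVRs,
    S = universe genes in the term, k = overlapping genes in the term.
    """
    universe = set(universe_genes)
    hits = set(overlapping_genes) & universe
    rows = []
    for term, genes in sorted(term_to_genes.items()):
        members = set(genes) & universe
        rows.append({"category": term, "S": len(members),
                     "k": len(members & hits)})
    return enrich(pd.DataFrame(rows), N=len(universe), m=len(hits), alpha=alpha)
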