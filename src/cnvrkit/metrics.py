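"""Truth-aware evaluation metrics for the synthetic caller benchmarks."""

from __future__ import annotations

import numpy as np
import pandas as pd


def breakpoint_recovery(truth: pd.DataFrame, calls: pd.DataFrame,
                        snp_map: pd.DataFrame, tol_snps: int = 2) -> float:
    """Fraction of planted events recovered with both breakpoints within
    ``tol_snps`` SNP indices of truth.

    An event counts as recovered when the same sample has a call of the same
    copy-number class (loss/gain) on the same chromosome whose start and end
    SNP indices are each within the tolerance.
    """
    if truth.empty:
        return float("nan")
    pos_by_chrom = {c: g["position"].to_numpy()
                    for c, g in snp_map.groupby("chrom")}

    def to_idx(chrom, p):
        return int(np.searchsorted(pos_by_chrom[chrom], p))

    calls_by_sample: dict[str, list] = {}
    for c in calls.itertuples(index=False):
        calls_by_sample.setdefault(c.sample_id, []).append(c)

    hit = 0
    for t in truth.itertuples(index=False):
        t_i0 = to_idx(t.chrom, t.start)
        t_i1 = to_idx(t.chrom, t.end)
        t_loss = t.state < 2
        for c in calls_by_sample.get(t.sample_id, ()):
            if c.chrom != t.chrom or (c.state < 2) != t_loss:
                continue
            if abs(to_idx(c.chrom, c.start) - t_i0) <= tol_snps \
                    and abs(to_idx(c.chrom, c.end) - t_i1) <= tol_snps:
                hit += 1
                break
    return hit / len(truth)
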