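"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: per-base arrays, exhaustive path
enumeration, quadratic joins, exact combinatorics. None of it shares code
with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd


def per_base_regions(events: pd.DataFrame, density: float,
                     min_segment: int = 1) -> pd.DataFrame:
    """Density-trimmed regions via an explicit per-base coverage array."""
    rows = []
    for chrom in events["chrom"].unique():
        g = events[events["chrom"] == chrom]
        lo = int(g["start"].min())
        hi = int(g["end"].max())
        cov = np.zeros(hi - lo + 2, dtype=int)
        for r in g.itertuples(index=False):
            cov[r.start - lo:r.end - lo + 1] += 1
        # candidate merged regions = maximal runs of coverage > 0
        covered = cov > 0
        i = 0
        while i < len(covered):
            if not covered[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(covered) and covered[j + 1]:
                j += 1
            cand_lo, cand_hi = lo + i, lo + j
            contrib = g[(g["start"] <= cand_hi) & (g["end"] >= cand_lo)]
            n = len(contrib)
            keep = cov[i:j + 1] / n >= density
            k = 0
            while k < len(keep):
                if not keep[k]:
                    k += 1
                    continue
                k2 = k
                while k2 + 1 < len(keep) and keep[k2 + 1]:
                    k2 += 1
                seg_s, seg_e = cand_lo + k, cand_lo + k2
                if seg_e - seg_s + 1 >= min_segment:
                    over = contrib[(contrib["start"] <= seg_e)
                                   & (contrib["end"] >= seg_s)]
                    states = over["state"].tolist()
                    if all(s < 2 for s in states):
                        typ = "deletion"
                    elif all(s > 2 for s in states):
                        typ = "duplication"
                    else:
                        typ = "complex"
                    rows.append({"chrom": chrom, "start": seg_s, "end": seg_e,
                                 "type": typ, "n_calls": len(over)})
                k = k2 + 1
            i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "type",
                                       "n_calls"]
                        ).sort_values(["chrom", "start"]).reset_index(drop=True)


def exhaustive_best_path(log_emis: np.ndarray, log_init: np.ndarray,
                         log_trans: list[np.ndarray]):
    """Max path score (and all argmax paths) over all 5^n state sequences."""
    n = log_emis.shape[0]
    best_score = -np.inf
    best_paths = []
    for path in itertools.product(range(5), repeat=n):
        score = log_init[path[0]] + log_emis[0, path[0]]
        for t in range(1, n):
            score += log_trans[t - 1][path[t - 1], path[t]] + log_emis[t, path[t]]
        if score > best_score + 1e-12:
            best_score = score
            best_paths = [path]
        elif abs(score - best_score) <= 1e-12:
            best_paths.append(path)
    return best_score, best_paths


def exhaustive_best_path_vectorized(log_emis: np.ndarray,
                                    log_init: np.ndarray,
                                    log_trans: list[np.ndarray]):
    """Vectorized enumeration of all 5^n paths; returns (best score, paths)."""
    n = log_emis.shape[0]
    paths = np.indices((5,) * n).reshape(n, -1).T  # (5^n, n)
    scores = log_init[paths[:, 0]] + log_emis[0, paths[:, 0]]
    for t in range(1, n):
        scores = scores + log_trans[t - 1][paths[:, t - 1], paths[:, t]] \
            + log_emis[t, paths[:, t]]
    best = scores.max()
    winners = paths[scores >= best - 1e-12]
    return best, {tuple(int(x) for x in w) for w in winners}


def quadratic_overlap_join(cnvrs: pd.DataFrame,
                           anns: pd.DataFrame) -> set[tuple]:
    """All-pairs interval join; returns {(cnvr_idx, ann_idx, overlap_bp)}."""
    out = set()
    for i, c in cnvrs.iterrows():
        for j, a in anns.iterrows():
            if c["chrom"] != a["chrom"]:
                continue
            bp = min(c["end"], a["end"]) - max(c["start"], a["start"]) + 1
            if bp > 0:
                out.add((i, j, bp))
    return out


def hypergeom_tail_by_enumeration(k: int, S: int, N: int, m: int) -> float:
    """P(X >= k) by enumerating every m-subset of an N-unit universe."""
    marked = set(range(S))
    total = 0
    hits = 0
    for subset in itertools.combinations(range(N), m):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return hits / total if total else 1.0


def hypergeom_tail_by_pmf(k: int, S: int, N: int, m: int) -> float:
    """P(X >= k) by exact rational pmf summation."""
    denom = comb(N, m)
    num = sum(comb(S, i) * comb(N - S, m - i)
              for i in range(k, min(S, m) + 1) if m - i <= N - S)
    return num / denom


def sv_union_coverage_per_base(region, svs: pd.DataFrame) -> int:
    """Bases of a region covered by >=1 SV, by explicit marking."""
    lo, hi = int(region["start"]), int(region["end"])
    mark = np.zeros(hi - lo + 1, dtype=bool)
    for s in svs.itertuples(index=False):
        if s.chrom != region["chrom"]:
            continue
        a = max(s.start, lo)
        b = min(s.end, hi)
        if a <= b:
            mark[a - lo:b - lo + 1] = True
    return int(mark.sum())
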