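"""Population CNV regions (CNVRs): interval union with density trimming.

Overlapping calls (sharing at least 1 bp) are transitively merged into
candidate regions; within each candidate, bases supported by fewer than
``density`` (default 10%) of the candidate's contributing calls are trimmed
away. Each maximal retained segment becomes one region, classified as
deletion, duplication or complex from the types of the calls overlapping it.
The construction is an endpoint sweep, exact with respect to the per-base
coverage profile, and invariant to the order of the input calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBuild

log = logging.getLogger(__name__)

#: length-class bin upper bounds in kb, inclusive ("200 kb or shorter", ...)
LENGTH_BINS_KB = (200, 400, 600)


def classify_states(states) -> str:
    """deletion if every state < 2, duplication if every state > 2, else complex."""
    states = list(states)
    if not states:
        raise ValueError("cannot classify a region with no contributing events")
    if all(s < 2 for s in states):
        return "deletion"
    if all(s > 2 for s in states):
        return "duplication"
    return "complex"


def _sweep_segments(starts: np.ndarray, ends: np.ndarray):
    """Coverage profile via endpoint sweep.

    Yields (seg_start, seg_end, coverage) for maximal constant-coverage
    segments over the union of [start, end] inclusive intervals.
    """
    events = np.concatenate([
        np.stack([starts, np.ones_like(starts)], axis=1),
        np.stack([ends + 1, -np.ones_like(ends)], axis=1),
    ])
    events = events[np.lexsort((events[:, 1], events[:, 0]))]
    bps = np.unique(events[:, 0])
    delta = np.zeros(len(bps), dtype=np.int64)
    idx = np.searchsorted(bps, events[:, 0])
    np.add.at(delta, idx, events[:, 1])
    cov = np.cumsum(delta)
    for i in range(len(bps) - 1):
        if cov[i] > 0:
            yield int(bps[i]), int(bps[i + 1] - 1), int(cov[i])


def build_cnvrs(events: pd.DataFrame, density: float = 0.1,
                min_segment: int = 1_000) -> pd.DataFrame:
    """Merge calls into density-trimmed regions.

    Parameters
    ----------
    events
        Calls or non-redundant events with columns (chrom, start, end,
        state); optional ``sample_id`` (distinct carriers counted) or
        ``carrier_count`` (summed) for carrier reporting.
    density
        Minimum supported fraction: a base is kept iff its coverage divided
        by the candidate region's contributing-call count is >= density.
        The denominator is the pre-trim candidate count; contributing calls
        are recomputed per retained segment for reporting only.
    min_segment
        Retained segments shorter than this are dropped (logged), echoing
        the 1 kb call-level rule.

    Returns a DataFrame (chrom, start, end, type, n_calls, n_carriers,
    length), disjoint within chromosome, sorted by (chrom, start).
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if events.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "type",
                                     "n_calls", "n_carriers", "length"])
    if (events["start"] > events["end"]).any():
        raise ValueError("malformed interval: start > end")

    rows = []
    n_dropped = 0
    for chrom, g in events.groupby("chrom", sort=False):
        g = g.sort_values(["start", "end"], kind="mergesort")
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        # transitive merge into candidate regions (>=1 shared bp)
        run_end = np.maximum.accumulate(e)
        breaks = np.flatnonzero(s[1:] > run_end[:-1] + 0) + 1
        bounds = np.concatenate([[0], breaks, [len(g)]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            cand = g.iloc[b0:b1]
            n_contrib = len(cand)
            cs, ce = s[b0:b1], e[b0:b1]
            # keep bases with coverage / n_contrib >= density; merge adjacency
            kept: list[list[int]] = []
            for seg_s, seg_e, cov in _sweep_segments(cs, ce):
                if cov / n_contrib >= density:
                    if kept and kept[-1][1] + 1 == seg_s:
                        kept[-1][1] = seg_e
                    else:
                        kept.append([seg_s, seg_e])
            for seg_s, seg_e in kept:
                if seg_e - seg_s + 1 < min_segment:
                    n_dropped += 1
                    continue
                over = cand[(cand["start"] <= seg_e) & (cand["end"] >= seg_s)]
                if "sample_id" in over.columns:
                    carriers = over["sample_id"].nunique()
                elif "carrier_count" in over.columns:
                    carriers = int(over["carrier_count"].sum())
                else:
                    carriers = len(over)
                rows.append({
                    "chrom": chrom, "start": seg_s, "end": seg_e,
                    "type": classify_states(over["state"]),
                    "n_calls": len(over), "n_carriers": carriers,
                    "length": seg_e - seg_s + 1,
                })
    if n_dropped:
        log.info("dropped %d trimmed segments shorter than %d bp",
                 n_dropped, min_segment)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "type",
                                      "n_calls", "n_carriers", "length"])
    return out.sort_values(["chrom", "start"], kind="mergesort",
                           ).reset_index(drop=True)


@dataclass
class CnvrSummary:
    """Count/length/coverage summaries of a region set."""
    counts_by_type: pd.Series
    total_length_bp: int
    genome_length_bp: int
    coverage_pct: float
    per_chromosome: pd.DataFrame
    length_histogram: pd.DataFrame
    length_stats: pd.DataFrame

    def to_text(self) -> str:
        lines = [f"regions: {int(self.counts_by_type.sum())}"]
        for t, c in self.counts_by_type.items():
            lines.append(f"  {t}: {c}")
        lines.append(f"covered: {self.total_length_bp / 1e6:.2f} Mb of "
                     f"{self.genome_length_bp / 1e6:.2f} Mb "
                     f"({self.coverage_pct:.2f}%)")
        for row in self.length_histogram.itertuples(index=False):
            lines.append(f"  {row.length_class}: {row.count} ({row.pct:.2f}%)")
        return "\n".join(lines)


def summarize(cnvrs: pd.DataFrame, genome: GenomeBuild) -> CnvrSummary:
    """Summaries of a disjoint region set against a genome build.

    Coverage percent is 100 x covered bp / genome bp rounded to 2 decimals.
    Length classes use inclusive upper bounds: (0, 200], (200, 400],
    (400, 600] and > 600 kb.
    """
    for row in cnvrs.itertuples(index=False):
        if row.chrom not in genome or row.start < 1 \
                or row.end > genome.length(row.chrom):
            raise ValueError(
                f"region {row.chrom}:{row.start}-{row.end} outside genome bounds")
    lengths = (cnvrs["end"] - cnvrs["start"] + 1) if len(cnvrs) \
        else pd.Series(dtype="int64")
    total = int(lengths.sum())
    coverage = round(100.0 * total / genome.total_length, 2)

    counts_by_type = cnvrs["type"].value_counts() if len(cnvrs) \
        else pd.Series(dtype="int64")

    per_chrom_rows = []
    for chrom in genome.names:
        sub = cnvrs[cnvrs["chrom"] == chrom] if len(cnvrs) else cnvrs
        covered = int((sub["end"] - sub["start"] + 1).sum()) if len(sub) else 0
        per_chrom_rows.append({
            "chrom": chrom, "count": len(sub), "covered_bp": covered,
            "coverage_pct": round(100.0 * covered / genome.length(chrom), 2),
        })
    per_chromosome = pd.DataFrame(per_chrom_rows)

    edges = [0] + [b * 1_000 for b in LENGTH_BINS_KB]
    labels = [f"(0,{LENGTH_BINS_KB[0]}]kb"] + [
        f"({a},{b}]kb" for a, b in zip(LENGTH_BINS_KB[:-1], LENGTH_BINS_KB[1:])
    ] + [f">{LENGTH_BINS_KB[-1]}kb"]
    hist_counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hist_counts.append(int(((lengths > lo) & (lengths <= hi)).sum()))
    hist_counts.append(int((lengths > edges[-1]).sum()))
    n = max(len(cnvrs), 1)
    length_histogram = pd.DataFrame({
        "length_class": labels, "count": hist_counts,
        "pct": [100.0 * c / n if len(cnvrs) else 0.0 for c in hist_counts],
    })

    stats_rows = []
    for t in ("deletion", "duplication", "complex"):
        sub = lengths[cnvrs["type"] == t] if len(cnvrs) else lengths
        if len(sub):
            stats_rows.append({"type": t, "count": len(sub),
                               "mean_bp": float(sub.mean()),
                               "min_bp": int(sub.min()),
                               "max_bp": int(sub.max())})
    length_stats = pd.DataFrame(stats_rows,
                                columns=["type", "count", "mean_bp",
                                         "min_bp", "max_bp"])
    return CnvrSummary(counts_by_type, total, genome.total_length, coverage,
                       per_chromosome, length_histogram, length_stats)
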