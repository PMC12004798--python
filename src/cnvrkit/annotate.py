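"""Interval annotation of CNVRs against genes, QTLs and known SVs.

All arithmetic is 1-based inclusive: two intervals overlap when they share
at least one base, and the shared length is ``min(ends) - max(starts) + 1``.
Gene overlaps are classified complete (gene contained in the region) or
partial; novelty against a structural-variant catalogue uses the union of
overlapping SV bases, so stacked SV records never count twice.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


def overlap_bp(start1: int, end1: int, start2: int, end2: int) -> int:
    """Shared bases of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(end1, end2) - max(start1, start2) + 1)


def _check(df: pd.DataFrame, what: str) -> None:
    bad = df[df["start"] > df["end"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"malformed {what} interval {r.get('id', '?')}: "
            f"{r['chrom']}:{r['start']}-{r['end']}")


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, g in df.groupby("chrom", sort=False):
        t = IntervalTree()
        for row in g.itertuples():
            # half-open tree coordinates: [start, end+1)
            t.addi(int(row.start), int(row.end) + 1, row.Index)
        trees[chrom] = t
    return trees


def cnvr_ids(cnvrs: pd.DataFrame) -> pd.Series:
    """Stable region identifiers chrom:start-end."""
    return (cnvrs["chrom"].astype(str) + ":" + cnvrs["start"].astype(str)
            + "-" + cnvrs["end"].astype(str))


def overlap(cnvrs: pd.DataFrame, annotations: pd.DataFrame,
            kind: str = "annotation") -> pd.DataFrame:
    """All (region, annotation) pairs sharing at least one base.

    Returns one record per pair with the shared length in bp, the percentage
    of the annotation covered, the percentage of the region covered, and —
    for gene annotations — whether the gene is completely contained in the
    region.
    """
    _check(cnvrs, "cnvr")
    _check(annotations, kind)
    trees = _trees(annotations)
    ids = cnvr_ids(cnvrs)
    rows = []
    for row in cnvrs.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(row.start), int(row.end) + 1)):
            ann = annotations.loc[hit.data]
            bp = overlap_bp(row.start, row.end, ann["start"], ann["end"])
            ann_len = int(ann["end"] - ann["start"] + 1)
            cnvr_len = int(row.end - row.start + 1)
            rows.append({
                "cnvr_id": ids.loc[row.Index],
                "cnvr_type": getattr(row, "type", ""),
                "annotation_id": ann.get("id", ann.get("qtl_id", str(hit.data))),
                "kind": kind,
                "overlap_bp": bp,
                "pct_of_annotation": 100.0 * bp / ann_len,
                "pct_of_cnvr": 100.0 * bp / cnvr_len,
                "completeness": ("complete"
                                 if ann["start"] >= row.start
                                 and ann["end"] <= row.end else "partial")
                if kind == "gene" else "",
            })
    return pd.DataFrame(rows, columns=["cnvr_id", "cnvr_type", "annotation_id",
                                       "kind", "overlap_bp",
                                       "pct_of_annotation", "pct_of_cnvr",
                                       "completeness"])


def classify_gene_overlap(record: pd.Series | dict) -> str:
    """complete iff the gene is contained in the region (pct_of_annotation 100)."""
    return "complete" if record["pct_of_annotation"] >= 100.0 else "partial"


def classify_novelty(cnvrs: pd.DataFrame, sv_db: pd.DataFrame) -> pd.DataFrame:
    """Categorize regions against a known-SV catalogue.

    ``novel``: no shared base with any SV; ``majority_known``: the union of
    overlapping SV bases covers at least half the region; else
    ``minority_known``. The three categories partition the region set.
    """
    _check(cnvrs, "cnvr")
    _check(sv_db, "sv")
    trees = _trees(sv_db)
    rows = []
    ids = cnvr_ids(cnvrs)
    for row in cnvrs.itertuples():
        tree = trees.get(row.chrom)
        hits = tree.overlap(int(row.start), int(row.end) + 1) if tree else ()
        # union of overlapping SV bases within the region
        pieces = sorted(
            (max(int(h.begin), int(row.start)),
             min(int(h.end) - 1, int(row.end))) for h in hits)
        covered = 0
        cur_s, cur_e = None, None
        for s, e in pieces:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s + 1
        length = int(row.end - row.start + 1)
        frac = covered / length
        if covered == 0:
            cat = "novel"
        elif frac >= 0.5:
            cat = "majority_known"
        else:
            cat = "minority_known"
        rows.append({"cnvr_id": ids.loc[row.Index], "chrom": row.chrom,
                     "start": row.start, "end": row.end,
                     "sv_overlap_bp": covered,
                     "sv_overlap_fraction": frac, "category": cat})
    return pd.DataFrame(rows, columns=["cnvr_id", "chrom", "start", "end",
                                       "sv_overlap_bp", "sv_overlap_fraction",
                                       "category"])


def drop_unplaced(annotations: pd.DataFrame, what: str = "QTL") -> pd.DataFrame:
    """Drop records without usable coordinates, logging the count."""
    ok = annotations["start"].notna() & annotations["end"].notna() \
        & annotations["chrom"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d %s records without coordinates", n_dropped, what)
    out = annotations.loc[ok].copy()
    out["start"] = out["start"].astype("int64")
    out["end"] = out["end"].astype("int64")
    return out
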