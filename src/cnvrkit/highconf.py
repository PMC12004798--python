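"""High-confidence CNVs from the dual-dataset intersection.

A call is high-confidence when the same sample carries a call with the exact
same chromosome, start and end (and, by default, the same copy-number state)
in both independently processed genotype datasets. Identical-coordinate
calls are then collapsed into a non-redundant event table with carrier
counts.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

_KEY = ["sample_id", "chrom", "start", "end", "state"]


def intersect_datasets(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                       match_state: bool = True) -> pd.DataFrame:
    """Exact-coordinate intersection of the two call sets.

    Samples present in only one dataset contribute nothing. Duplicate
    identical records within one dataset are deduplicated with a warning.
    With ``match_state=True`` (default) the copy-number state must also agree
    — stricter than coordinates alone, preventing a deletion in one dataset
    matching a duplication in the other.

    Symmetric and idempotent; returns one record per retained (sample, event)
    with dataset-A metadata (numsnp, SNP ids).
    """
    key = _KEY if match_state else [k for k in _KEY if k != "state"]

    def dedup(df: pd.DataFrame, tag: str) -> pd.DataFrame:
        out = df.drop_duplicates(subset=_KEY)
        if len(out) != len(df):
            log.warning("dataset %s: %d duplicate identical records removed",
                        tag, len(df) - len(out))
        return out

    a = dedup(calls_a, "A")
    b = dedup(calls_b, "B")
    shared = set(a["sample_id"]) & set(b["sample_id"])
    a = a[a["sample_id"].isin(shared)]
    b = b[b["sample_id"].isin(shared)]
    merged = a.merge(b[key].drop_duplicates(), on=key, how="inner")
    out = merged.copy()
    out["dataset"] = "AB"
    return out.sort_values(["chrom", "start", "end", "sample_id"],
                           kind="mergesort").reset_index(drop=True)


def collapse_nonredundant(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse high-confidence calls into distinct events with carrier counts.

    One record per distinct (chrom, start, end, type); type is deletion for
    copy number < 2, duplication otherwise. The sum of carrier counts equals
    the number of input calls (each call is carried by exactly one sample).
    """
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "type", "state",
                                     "carrier_count", "carriers", "numsnp"])
    df = calls.copy()
    df["type"] = df["state"].map(lambda s: "deletion" if s < 2 else "duplication")
    grouped = df.groupby(["chrom", "start", "end", "type"], sort=False)
    out = grouped.agg(
        state=("state", "min"),
        carrier_count=("sample_id", "nunique"),
        carriers=("sample_id", lambda s: ",".join(sorted(set(s)))),
        numsnp=("numsnp", "max"),
    ).reset_index()
    return out.sort_values(["chrom", "start", "end"],
                           kind="mergesort").reset_index(drop=True)


def cohort_summary(calls: pd.DataFrame, nonredundant: pd.DataFrame) -> dict:
    """Population-level summary ratios of the high-confidence set.

    Returns total/non-redundant counts, deletion/duplication shares and
    ratios, mean calls per carrier animal and mean carriers per distinct
    event, and mean lengths by type (bp).
    """
    total = len(calls)
    n_events = len(nonredundant)
    n_carrier_animals = calls["sample_id"].nunique() if total else 0
    is_del = calls["state"] < 2 if total else pd.Series(dtype=bool)
    n_del = int(is_del.sum()) if total else 0
    n_dup = total - n_del
    lengths = (calls["end"] - calls["start"] + 1) if total else pd.Series(dtype=float)
    nr_del = int((nonredundant["type"] == "deletion").sum()) if n_events else 0
    nr_dup = n_events - nr_del

    def mean_len(mask) -> float:
        return float(lengths[mask].mean()) if total and mask.any() else float("nan")

    return {
        "total_calls": total,
        "nonredundant_events": n_events,
        "carrier_animals": n_carrier_animals,
        "deletion_calls": n_del,
        "duplication_calls": n_dup,
        "deletion_pct": 100.0 * n_del / total if total else float("nan"),
        "duplication_pct": 100.0 * n_dup / total if total else float("nan"),
        "del_dup_ratio": n_del / n_dup if n_dup else float("inf"),
        "nonredundant_deletions": nr_del,
        "nonredundant_duplications": nr_dup,
        "nonredundant_del_dup_ratio": nr_del / nr_dup if nr_dup else float("inf"),
        "mean_calls_per_animal": total / n_carrier_animals
        if n_carrier_animals else float("nan"),
        "mean_carriers_per_event": total / n_events if n_events else float("nan"),
        "mean_del_length": mean_len(is_del),
        "mean_dup_length": mean_len(~is_del),
    }
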