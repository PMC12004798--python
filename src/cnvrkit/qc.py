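"""Three-step quality control for samples and calls.

Step one/two: per-sample signal metrics (LRR standard deviation, BAF drift,
waviness factor, CNV count) against inclusive thresholds. Step three:
call-level structural filters (SNP support, length, carrier count).

The BAF-drift and waviness formulas used here are documented operational
proxies: BAF drift is the fraction of SNPs whose BAF falls in the drift
bands [0.2, 0.25] or [0.75, 0.8]; waviness is the standard deviation of
per-1-Mb-window median LRR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WAVINESS_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class SampleQcThresholds:
    """Inclusive sample-level thresholds (a sample passes at the boundary)."""
    max_lrr_sd: float = 0.30
    max_baf_drift: float = 0.01
    max_waviness: float = 0.05
    max_cnv_count: int = 1_000


@dataclass(frozen=True)
class CallFilterConfig:
    """Structural call filters: SNP support, length, and carrier count."""
    min_snps: int = 10
    min_length: int = 1_000
    min_carriers: int = 5

    def __post_init__(self) -> None:
        if min(self.min_snps, self.min_length, self.min_carriers) < 1:
            raise ValueError("call filter thresholds must be >= 1")


def compute_sample_metrics(track: pd.DataFrame, calls: pd.DataFrame,
                           sample_id: str) -> dict:
    """Signal-quality metrics for one sample.

    lrr_sd: sd of autosomal LRR. baf_drift: fraction of SNPs with BAF in
    [0.2, 0.25] or [0.75, 0.8]. waviness: sd of per-1Mb-window median LRR.
    cnv_count: number of calls attributed to the sample.
    """
    if track.empty:
        raise ValueError(f"empty signal track for sample {sample_id}")
    lrr = track["lrr"].to_numpy(float)
    baf = track["baf"].to_numpy(float)
    lrr_sd = float(np.std(lrr))
    drift = float(np.mean(((baf >= 0.2) & (baf <= 0.25))
                          | ((baf >= 0.75) & (baf <= 0.8))))
    window = (track["position"].to_numpy() - 1) // WAVINESS_WINDOW_BP
    med = pd.Series(lrr).groupby(
        [track["chrom"].to_numpy(), window]).median().to_numpy()
    waviness = float(np.std(med)) if len(med) > 1 else 0.0
    n_calls = int((calls["sample_id"] == sample_id).sum()) if len(calls) else 0
    return {"sample_id": sample_id, "lrr_sd": lrr_sd, "baf_drift": drift,
            "waviness": waviness, "cnv_count": n_calls}


def filter_samples(
    records: pd.DataFrame,
    thresholds: SampleQcThresholds = SampleQcThresholds(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply the inclusive sample thresholds; returns (passing ids, report).

    The report lists every sample with its metrics, a pass flag, and the
    names of the failing metrics for excluded samples.
    """
    report = records.copy()
    fails = []
    for row in records.itertuples(index=False):
        failed = []
        if row.lrr_sd > thresholds.max_lrr_sd:
            failed.append("lrr_sd")
        if row.baf_drift > thresholds.max_baf_drift:
            failed.append("baf_drift")
        if row.waviness > thresholds.max_waviness:
            failed.append("waviness")
        if row.cnv_count > thresholds.max_cnv_count:
            failed.append("cnv_count")
        fails.append(",".join(failed))
    report["failed_metrics"] = fails
    report["pass"] = [f == "" for f in fails]
    passing = report.loc[report["pass"], "sample_id"].tolist()
    return passing, report


def _carrier_counts(calls: pd.DataFrame) -> pd.Series:
    """Distinct-sample count per identical (chrom, start, end, state) event."""
    return calls.groupby(["chrom", "start", "end", "state"])["sample_id"].nunique()


def _reciprocal_carrier_counts(kept: pd.DataFrame, r: float) -> np.ndarray:
    """Distinct samples sharing a same-type call at >= r reciprocal overlap."""
    counts = np.zeros(len(kept), dtype=int)
    kept = kept.reset_index(drop=True)
    is_del = kept["state"] < 2
    for _, idx in kept.groupby([kept["chrom"], is_del]).groups.items():
        sub = kept.loc[idx]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        samp = sub["sample_id"].to_numpy()
        for i in range(len(sub)):
            ov = np.minimum(e, e[i]) - np.maximum(s, s[i]) + 1
            ok = (ov >= r * (e - s + 1)) & (ov >= r * (e[i] - s[i] + 1))
            counts[idx[i]] = len(set(samp[ok]))
    return counts


def filter_calls(calls: pd.DataFrame,
                 config: CallFilterConfig = CallFilterConfig(),
                 carrier_mode: str = "exact",
                 reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Retain calls with enough SNPs, length, and carriers.

    A call survives iff numsnp >= min_snps, length >= min_length (1-based
    inclusive), and its event occurs in at least min_carriers distinct
    samples. With the default ``carrier_mode="exact"`` events are identical
    (chrom, start, end, state) tuples; ``"reciprocal"`` instead counts
    same-type calls sharing at least ``reciprocal_overlap`` of both lengths.
    Idempotent; order-independent.
    """
    if carrier_mode not in ("exact", "reciprocal"):
        raise ValueError(f"unknown carrier_mode {carrier_mode!r}")
    if calls.empty:
        return calls.copy()
    length = calls["end"] - calls["start"] + 1
    keep = (calls["numsnp"] >= config.min_snps) & (length >= config.min_length)
    kept = calls.loc[keep]
    if carrier_mode == "exact":
        counts = _carrier_counts(kept)
        key = pd.MultiIndex.from_frame(kept[["chrom", "start", "end", "state"]])
        enough = counts.reindex(key).to_numpy() >= config.min_carriers
    else:
        enough = _reciprocal_carrier_counts(kept, reciprocal_overlap) \
            >= config.min_carriers
    out = kept.loc[enough].reset_index(drop=True)
    log.info("call filters: %d of %d calls retained", len(out), len(calls))
    return out
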