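"""Simplified hidden-Markov-model CNV caller for LRR/BAF signal tracks.

Five copy-number states {0, 1, 2, 3, 4} (no loss-of-heterozygosity state).
Emissions combine a Gaussian LRR term with a BAF genotype-mixture term whose
components sit at k/c for a copy number c, weighted binomially by the
population B-allele frequency (PFB). Transitions depend on inter-SNP
distance: the further apart two probes are, the less a copy-number state
persists. Decoding is Viterbi in log space; maximal runs of non-diploid
states become calls.

This is a deliberately small caller meant to recover planted events on
synthetic tracks; it makes no claim of numerical compatibility with
production callers on real array data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

log = logging.getLogger(__name__)

STATES = (0, 1, 2, 3, 4)
DIPLOID = 2

#: conventional SNP-array LRR means per copy number
DEFAULT_LRR_MEANS = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}

PFB_FLOOR = 0.01
PFB_CEILING = 0.99


def compile_pfb(baf: pd.DataFrame) -> pd.Series:
    """Estimate the population frequency of the B allele per SNP.

    Parameters
    ----------
    baf
        Samples x SNPs matrix of BAF values (columns = SNP ids); missing
        values are ignored.

    Returns
    -------
    Per-SNP mean BAF clamped to [0.01, 0.99]. SNPs with no non-missing value
    are excluded with a warning.
    """
    means = baf.mean(axis=0, skipna=True)
    missing = means.index[means.isna()]
    if len(missing):
        warnings.warn(f"excluding {len(missing)} SNPs with all-missing BAF")
        means = means.drop(missing)
    return means.clip(PFB_FLOOR, PFB_CEILING).rename("pfb")


def gc_correct(track: pd.DataFrame, gc: pd.Series | None = None) -> pd.DataFrame:
    """Remove the GC wave from a sample's LRR by linear regression.

    Fits lrr ~ gc (the percent GC in a 1 Mb window centred on each SNP,
    i.e. 500 kb up- and downstream), replaces lrr with the residuals, and
    re-centres so the corrected median equals the pre-correction median.
    If GC is constant the correction is skipped (identity).
    """
    track = track.copy()
    gcv = track["gc"].to_numpy(float) if gc is None else \
        track["snp_id"].map(gc).to_numpy(float)
    ok = ~np.isnan(gcv)
    if ok.mean() < 0.90:
        raise ValueError("GC content missing for more than 10% of SNPs")
    if np.nanstd(gcv) == 0.0:
        log.info("GC constant across SNPs; wave correction skipped")
        return track
    lrr = track["lrr"].to_numpy(float)
    med = np.median(lrr[ok])
    slope, intercept = np.polyfit(gcv[ok], lrr[ok], 1)
    corrected = lrr - (slope * np.where(ok, gcv, 0.0) + intercept * ok)
    corrected = corrected - np.median(corrected[ok]) + med
    track["lrr"] = np.where(ok, corrected, lrr)
    return track


def _binom_weights(c: int, p: np.ndarray) -> np.ndarray:
    """Binomial(c, p) pmf over k=0..c for an array of probabilities p."""
    k = np.arange(c + 1)
    logw = ((gammaln(c + 1) - gammaln(k + 1) - gammaln(c - k + 1))[:, None]
            + k[:, None] * np.log(p)[None, :]
            + (c - k)[:, None] * np.log1p(-p)[None, :])
    return np.exp(logw)  # (c+1, n_snps)


@dataclass
class HmmModel:
    """Emission and transition parameters of the caller.

    ``expected_stay_bp`` (D) and ``switch_weight`` (theta) set the
    distance-dependent stay probability ``1 - theta * (1 - exp(-d/D))``;
    off-diagonal mass is split among the other states with
    ``diploid_extra_weight``-fold extra weight on the diploid state, keeping
    diploid the prior default.
    """

    lrr_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    lrr_sd: float = 0.2
    baf_sd: float = 0.04
    expected_stay_bp: float = 100_000.0   # D
    switch_weight: float = 0.01           # theta
    diploid_extra_weight: float = 4.0
    diploid_prior: float = 0.99

    def __post_init__(self) -> None:
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("emission standard deviations must be positive")
        if not 0 < self.switch_weight < 1:
            raise ValueError("switch_weight must be in (0, 1)")

    # -- transitions --------------------------------------------------------

    def log_transition(self, d: float) -> np.ndarray:
        """5x5 log transition matrix for an inter-SNP distance of d bp."""
        move = self.switch_weight * (1.0 - np.exp(-max(d, 1.0) / self.expected_stay_bp))
        T = np.empty((5, 5))
        for i, si in enumerate(STATES):
            w = np.array([self.diploid_extra_weight if sj == DIPLOID else 1.0
                          for sj in STATES])
            w[i] = 0.0
            w = w / w.sum() * move
            T[i] = w
            T[i, i] = 1.0 - move
        return np.log(T)

    def log_initial(self) -> np.ndarray:
        p = np.full(5, (1.0 - self.diploid_prior) / 4.0)
        p[STATES.index(DIPLOID)] = self.diploid_prior
        return np.log(p)

    # -- emissions ----------------------------------------------------------

    def log_emissions(self, track: pd.DataFrame, pfb: pd.Series) -> np.ndarray:
        """(n_snps, 5) matrix of per-state log emission densities."""
        lrr = track["lrr"].to_numpy(float)
        baf = track["baf"].to_numpy(float)
        p = track["snp_id"].map(pfb).to_numpy(float)
        p = np.clip(np.where(np.isnan(p), 0.5, p), PFB_FLOOR, PFB_CEILING)

        n = len(lrr)
        out = np.empty((n, 5))
        # truncated-normal normaliser on [0, 1] for the BAF components
        for j, c in enumerate(STATES):
            lrr_ll = norm.logpdf(lrr, self.lrr_means[c], self.lrr_sd)
            if c == 0:
                baf_like = np.ones(n)  # uniform on [0, 1]
            else:
                centers = np.arange(c + 1) / c
                weights = _binom_weights(c, p)          # (c+1, n)
                dens = np.zeros(n)
                for k, mu in enumerate(centers):
                    z = (norm.cdf(1.0, mu, self.baf_sd)
                         - norm.cdf(0.0, mu, self.baf_sd))
                    dens += weights[k] * norm.pdf(baf, mu, self.baf_sd) / z
                baf_like = np.maximum(dens, 1e-300)
            out[:, j] = lrr_ll + np.log(baf_like)
        return out


# preference order for tie-breaking: closest to diploid, then lower copy
_TIE_ORDER = np.array([2, 1, 3, 0, 4])


def _viterbi_path(log_emis: np.ndarray, log_init: np.ndarray,
                  log_trans: list[np.ndarray]) -> np.ndarray:
    """Max-probability state path; ties broken toward diploid, then lower cn."""
    n = log_emis.shape[0]
    # work in tie-preference order so argmax picks the preferred state on ties
    order = _TIE_ORDER
    inv = np.argsort(order)
    emis = log_emis[:, order]
    init = log_init[order]
    trans = [T[np.ix_(order, order)] for T in log_trans]

    delta = init + emis[0]
    back = np.zeros((n, 5), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + trans[t - 1]          # (from, to)
        best = np.argmax(cand, axis=0)                 # first max = preferred
        back[t] = best
        delta = cand[best, np.arange(5)] + emis[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return order[path]  # map back to copy numbers via preference order


def viterbi_call(track: pd.DataFrame, pfb: pd.Series, model: HmmModel,
                 sample_id: str = "sample", dataset: str = "") -> pd.DataFrame:
    """Decode the copy-number path and emit calls for non-diploid runs.

    The track must be position-sorted within chromosomes. Chromosomes with
    fewer than two SNPs yield no calls. Each maximal run of a constant
    non-diploid state becomes one call with ``numsnp`` equal to the run
    length and start/end at the first/last SNP positions of the run.
    """
    rows = []
    for chrom, g in track.groupby("chrom", sort=False):
        pos = g["position"].to_numpy()
        if len(pos) < 2:
            log.info("chromosome %s has <2 SNPs; skipped", chrom)
            continue
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        emis = model.log_emissions(g, pfb)
        trans = [model.log_transition(d) for d in np.diff(pos)]
        path = _viterbi_path(emis, model.log_initial(), trans)

        snp_ids = g["snp_id"].to_numpy()
        i = 0
        n = len(path)
        while i < n:
            s = path[i]
            j = i
            while j + 1 < n and path[j + 1] == s:
                j += 1
            if s != DIPLOID:
                rows.append({
                    "sample_id": sample_id, "chrom": chrom,
                    "start": int(pos[i]), "end": int(pos[j]),
                    "state": int(s), "numsnp": j - i + 1,
                    "startsnp": snp_ids[i], "endsnp": snp_ids[j],
                    "dataset": dataset,
                })
            i = j + 1
    cols = ["sample_id", "chrom", "start", "end", "state", "numsnp",
            "startsnp", "endsnp", "dataset"]
    return pd.DataFrame(rows, columns=cols)
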