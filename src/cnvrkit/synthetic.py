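"""Synthetic SNP-array CNV cohort generator.

Emulates the inputs of a large dairy-cattle CNV mapping study: a cohort
genotyped on a dense SNP array, processed twice (dataset A = every animal and
SNP; dataset B = the same cohort after sample/SNP quality control), with
copy-number loci planted at known coordinates. Deletions outnumber
duplications roughly 78:22 and are shorter on average. Every downstream stage
— calling, QC, dual-dataset intersection, region construction, annotation,
enrichment — can therefore be tested against known ground truth without any
external download.

All outputs are deterministic functions of the single config seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .genome import GenomeBuild
from .hmm import DEFAULT_LRR_MEANS


class PlacementError(RuntimeError):
    """Raised when loci or annotations cannot be placed under the constraints."""


def make_genome(config: SimulationConfig) -> GenomeBuild:
    """Build the synthetic autosome set from configured chromosome lengths."""
    lengths = [int(round(mb * 1_000_000)) for mb in config.chromosome_lengths_mb]
    if any(l <= 0 for l in lengths):
        raise ConfigError("chromosome lengths must be positive")
    names = config.chromosome_names or tuple(
        str(i + 1) for i in range(len(lengths)))
    if len(names) != len(lengths):
        raise ConfigError("chromosome_names and chromosome_lengths_mb differ in length")
    return GenomeBuild(tuple(zip(names, lengths)))


def make_snp_map(genome: GenomeBuild, config: SimulationConfig) -> pd.DataFrame:
    """Place SNPs uniformly at the configured probe density.

    Returns a DataFrame (snp_id, chrom, position), positions strictly
    increasing within each chromosome and chromosomes in genome order.
    """
    if config.snp_density_per_mb <= 0:
        raise ConfigError("snp_density_per_mb must be positive")
    rng = config.rng("genome")
    frames = []
    for chrom, length in genome.chromosomes:
        n = max(2, int(round(length / 1e6 * config.snp_density_per_mb)))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n, length),
                                 replace=False))
        frames.append(pd.DataFrame({
            "snp_id": [f"snp_{chrom}_{i}" for i in range(len(pos))],
            "chrom": chrom,
            "position": pos.astype("int64"),
        }))
    return pd.concat(frames, ignore_index=True)


def _lognormal_lengths(rng: np.random.Generator, n: int, mean: float,
                       log_sd: float, floor: int) -> np.ndarray:
    # mu chosen so the arithmetic mean of the (untruncated) draw equals `mean`
    mu = np.log(mean) - log_sd**2 / 2.0
    lengths = rng.lognormal(mu, log_sd, size=n)
    return np.maximum(np.round(lengths).astype("int64"), floor)


def plant_loci(genome: GenomeBuild, config: SimulationConfig) -> pd.DataFrame:
    """Plant non-overlapping CNV loci with the configured deletion:duplication mix.

    Returns a DataFrame (locus_id, chrom, start, end, state,
    carrier_frequency). States: deletions are copy 1 (a configured fraction
    copy 0), duplications copy 3 (a fraction copy 4).
    """
    rng = config.rng("loci")
    n = config.n_loci
    if n == 0:
        return pd.DataFrame(columns=["locus_id", "chrom", "start", "end",
                                     "state", "carrier_frequency"])
    is_del = rng.random(n) < config.deletion_fraction
    lengths = np.where(
        is_del,
        _lognormal_lengths(rng, n, config.del_mean_length, config.length_log_sd,
                           config.min_locus_length),
        _lognormal_lengths(rng, n, config.dup_mean_length, config.length_log_sd,
                           config.min_locus_length),
    )
    sub = rng.random(n)
    states = np.where(is_del,
                      np.where(sub < config.homozygous_del_fraction, 0, 1),
                      np.where(sub < config.double_dup_fraction, 4, 3))
    freqs = rng.uniform(config.carrier_freq_min, config.carrier_freq_max, size=n)

    chrom_names = genome.names
    chrom_lengths = np.array([genome.length(c) for c in chrom_names], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    rows = []
    max_attempts = 200 * n
    attempts = 0
    for j in range(n):
        L = int(lengths[j])
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {n} non-overlapping loci "
                    f"(placed {len(rows)}); genome too small for the "
                    f"requested number/length of loci")
            ci = rng.choice(len(chrom_names), p=chrom_weights)
            chrom = chrom_names[ci]
            clen = int(chrom_lengths[ci])
            if L > clen:
                continue
            start = int(rng.integers(1, clen - L + 2))
            end = start + L - 1
            if any(s <= end and start <= e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            rows.append({
                "locus_id": f"locus{j:04d}", "chrom": chrom,
                "start": start, "end": end, "state": int(states[j]),
                "carrier_frequency": float(freqs[j]),
            })
            break
    df = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(chrom_names)}
    return df.sort_values(["chrom", "start"],
                          key=lambda s: s.map(order) if s.name == "chrom" else s
                          ).reset_index(drop=True)


def _snap_to_snps(positions: np.ndarray, start: int, end: int):
    """Indices of the first/last SNP inside [start, end], or None if empty."""
    i0 = int(np.searchsorted(positions, start, side="left"))
    i1 = int(np.searchsorted(positions, end, side="right")) - 1
    if i1 < i0:
        return None
    return i0, i1


def simulate_samples(
    loci: pd.DataFrame,
    genome: GenomeBuild,
    snp_map: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw carriers per locus and emit the two paired call sets.

    Each sample carries each locus independently with the locus's carrier
    frequency. Dataset A snaps call boundaries to the full SNP map; dataset B
    drops a fraction of samples and SNPs (emulating sample/genotype QC) and
    additionally perturbs a configured fraction of its calls by one SNP index
    — the exact failure mode the exact-coordinate high-confidence
    intersection is designed to reject.

    Returns ``(calls_a, calls_b, truth)``.
    """
    if loci.empty:
        raise ConfigError("loci must be non-empty")
    rng = config.rng("samples")
    n = config.n_samples
    samples = [f"HOL{i:04d}" for i in range(n)]

    pos_by_chrom = {c: g["position"].to_numpy() for c, g in snp_map.groupby("chrom")}
    ids_by_chrom = {c: g["snp_id"].to_numpy() for c, g in snp_map.groupby("chrom")}
    # dataset-B SNP retention mask (per chromosome, shared across samples)
    keep_by_chrom = {
        c: rng.random(len(p)) >= config.b_snp_drop_rate
        for c, p in pos_by_chrom.items()
    }
    in_b = rng.random(n) >= config.b_sample_drop_rate

    rows_a, rows_b, rows_t = [], [], []
    for locus in loci.itertuples(index=False):
        pos = pos_by_chrom[locus.chrom]
        ids = ids_by_chrom[locus.chrom]
        snapped = _snap_to_snps(pos, locus.start, locus.end)
        if snapped is None:
            continue  # locus falls between probes; invisible to the array
        i0, i1 = snapped
        keep = keep_by_chrom[locus.chrom]
        kept_idx = np.flatnonzero(keep[i0:i1 + 1]) + i0
        carriers = np.flatnonzero(rng.random(n) < locus.carrier_frequency)
        perturb = rng.random(len(carriers)) < config.perturbation_fraction
        shift_start = rng.random(len(carriers)) < 0.5
        for ci, si in enumerate(carriers):
            sample = samples[si]
            rows_a.append((sample, locus.chrom, int(pos[i0]), int(pos[i1]),
                           int(locus.state), i1 - i0 + 1,
                           ids[i0], ids[i1], "A"))
            b_changed = False
            if in_b[si] and len(kept_idx) >= 1:
                j0, j1 = int(kept_idx[0]), int(kept_idx[-1])
                perturbed = False
                if perturb[ci] and j1 - j0 >= 1:
                    # one-SNP boundary shift: creates a non-identical call
                    nk = len(kept_idx)
                    if shift_start[ci]:
                        j0 = int(kept_idx[1])
                        nk -= 1
                    else:
                        j1 = int(kept_idx[-2])
                        nk -= 1
                    perturbed = True
                else:
                    nk = len(kept_idx)
                rows_b.append((sample, locus.chrom, int(pos[j0]), int(pos[j1]),
                               int(locus.state), nk, ids[j0], ids[j1], "B"))
                b_changed = perturbed or (pos[j0] != pos[i0]) or (pos[j1] != pos[i1])
            rows_t.append({
                "sample_id": sample, "locus_id": locus.locus_id,
                "chrom": locus.chrom, "start": int(pos[i0]), "end": int(pos[i1]),
                "truth_start": int(locus.start), "truth_end": int(locus.end),
                "state": int(locus.state), "numsnp": i1 - i0 + 1,
                "in_b": bool(in_b[si]),
                "b_coords_differ": bool(b_changed),
            })

    cols = ["sample_id", "chrom", "start", "end", "state", "numsnp",
            "startsnp", "endsnp", "dataset"]
    calls_a = pd.DataFrame(rows_a, columns=cols)
    calls_b = pd.DataFrame(rows_b, columns=cols)
    truth = pd.DataFrame(rows_t)
    return calls_a, calls_b, truth


def simulate_signals(
    truth: pd.DataFrame,
    genome: GenomeBuild,
    snp_map: pd.DataFrame,
    config: SimulationConfig,
    sample_ids: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate per-sample LRR/BAF tracks consistent with the truth table.

    Inside a planted event the LRR mean shifts to the copy-number value of
    :data:`DEFAULT_LRR_MEANS` and the BAF clusters match the genotypes
    possible at that copy number; elsewhere the track is diploid (LRR mean 0,
    BAF clusters {0, 0.5, 1}). An optional GC wave adds
    ``gc_wave_slope * (gc - gc_mean)`` to the LRR.

    Each sample's track is seeded independently of the others, so any subset
    of samples reproduces bitwise.
    """
    if config.snp_density_per_mb <= 0:
        raise ConfigError("SNP density must be positive")
    if sample_ids is None:
        sample_ids = [f"HOL{i:04d}" for i in range(config.n_samples)]

    # per-SNP population B-allele frequency and GC content (cohort-level)
    rng_map = config.rng("signals")
    n_snps = len(snp_map)
    popfreq = rng_map.uniform(0.05, 0.95, size=n_snps)
    gc = np.clip(rng_map.normal(config.gc_mean, config.gc_sd, size=n_snps), 20, 75)

    positions = snp_map["position"].to_numpy()
    chroms = snp_map["chrom"].to_numpy()
    events_by_sample = {
        s: g for s, g in truth.groupby("sample_id")} if len(truth) else {}

    sample_index = {f"HOL{i:04d}": i for i in range(config.n_samples)}
    tracks: dict[str, pd.DataFrame] = {}
    for sample in sample_ids:
        srng = np.random.default_rng(
            [int(config.seed), 3, sample_index.get(sample, hash(sample) % 2**31)])
        copy = np.full(n_snps, 2, dtype="int64")
        ev = events_by_sample.get(sample)
        if ev is not None:
            for e in ev.itertuples(index=False):
                mask = (chroms == e.chrom) & (positions >= e.start) & (positions <= e.end)
                copy[mask] = e.state
        # genotype B-allele count given copy number
        g = srng.binomial(copy, popfreq)
        with np.errstate(invalid="ignore", divide="ignore"):
            baf_mean = np.where(copy > 0, g / np.maximum(copy, 1), 0.0)
        baf = np.clip(baf_mean + srng.normal(0.0, config.baf_sd, n_snps), 0.0, 1.0)
        baf = np.where(copy == 0, srng.uniform(0.0, 1.0, n_snps), baf)
        lrr_mean = np.array([DEFAULT_LRR_MEANS[c] for c in (0, 1, 2, 3, 4)])[copy]
        lrr = (lrr_mean + srng.normal(0.0, config.lrr_sd, n_snps)
               + config.gc_wave_slope * (gc - config.gc_mean))
        tracks[sample] = pd.DataFrame({
            "snp_id": snp_map["snp_id"].to_numpy(),
            "chrom": chroms,
            "position": positions,
            "lrr": lrr,
            "baf": baf,
            "gc": gc,
        })
    return tracks


def _anchored_interval(rng: np.random.Generator, region, length: int,
                       chrom_len: int) -> tuple[int, int]:
    """Place an interval of `length` guaranteed to overlap `region` by >=1 bp."""
    lo = max(1, region.start - length + 1)
    hi = min(region.end, chrom_len - length + 1)
    if hi < lo:
        start = max(1, min(region.start, chrom_len - length + 1))
    else:
        start = int(rng.integers(lo, hi + 1))
    return start, min(start + length - 1, chrom_len)


def _uniform_interval(rng: np.random.Generator, genome: GenomeBuild,
                      weights: np.ndarray, length: int) -> tuple[str, int, int]:
    ci = rng.choice(len(genome.names), p=weights)
    chrom = genome.names[ci]
    clen = genome.length(chrom)
    L = min(length, clen)
    start = int(rng.integers(1, clen - L + 2))
    return chrom, start, start + L - 1


def simulate_annotations(
    genome: GenomeBuild,
    regions: pd.DataFrame,
    config: SimulationConfig,
    return_novel_truth: bool = False,
):
    """Generate gene models, a QTL table and a known-SV catalogue.

    QTLs of the configured enriched trait are anchored to overlap the truth
    regions with probability ``enriched_overlap_prob``; every other trait's
    QTLs are placed uniformly. A ``novel_fraction`` of truth regions is kept
    free of known SVs (the planted "novel" regions); the rest receive an SV
    covering at least half of the region.

    Returns ``(genes, qtls, known_svs)``.
    """
    if regions.empty:
        raise PlacementError("cannot plant annotations without truth regions")
    rng = config.rng("annotations")
    chrom_lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
    weights = chrom_lengths / chrom_lengths.sum()
    region_list = list(regions.itertuples(index=False))

    # genes: a third anchored on truth regions so overlap classes are populated
    gene_rows = []
    lengths = _lognormal_lengths(rng, config.n_genes, config.gene_mean_length,
                                 0.8, 1_000)
    biotypes = np.where(rng.random(config.n_genes) < config.protein_coding_fraction,
                        "protein_coding",
                        rng.choice(["lncRNA", "miRNA", "pseudogene"],
                                   size=config.n_genes))
    for i in range(config.n_genes):
        L = int(lengths[i])
        if rng.random() < 0.33:
            r = region_list[rng.integers(len(region_list))]
            clen = genome.length(r.chrom)
            if rng.random() < 0.5 and (r.end - r.start + 1) > L:
                # fully inside the region -> a completely-overlapped gene
                start = int(rng.integers(r.start, r.end - L + 2))
                chrom, end = r.chrom, start + L - 1
            else:
                start, end = _anchored_interval(rng, r, L, clen)
                chrom = r.chrom
        else:
            chrom, start, end = _uniform_interval(rng, genome, weights, L)
        gene_rows.append({"chrom": chrom, "start": start, "end": end,
                          "id": f"GENE{i:04d}", "biotype": biotypes[i]})
    genes = pd.DataFrame(gene_rows)

    # QTLs
    qtl_rows = []
    qtl_types = ["Milk", "Reproduction", "Meat and Carcass",
                 "Production", "Exterior", "Health"]
    traits = [(config.enriched_trait, config.enriched_trait_size, True, "Milk")]
    for t in range(config.n_background_traits):
        traits.append((f"Trait_{t:02d}", config.qtls_per_trait, False,
                       qtl_types[t % len(qtl_types)]))
    qid = 0
    for trait, size, enriched, qtl_type in traits:
        lens = _lognormal_lengths(rng, size, config.qtl_mean_length, 0.7, 2_000)
        for i in range(size):
            L = int(lens[i])
            if enriched and rng.random() < config.enriched_overlap_prob:
                r = region_list[rng.integers(len(region_list))]
                start, end = _anchored_interval(rng, r, L, genome.length(r.chrom))
                chrom = r.chrom
            else:
                chrom, start, end = _uniform_interval(rng, genome, weights, L)
            qtl_rows.append({"chrom": chrom, "start": start, "end": end,
                             "qtl_id": f"QTL{qid:05d}", "trait": trait,
                             "qtl_type": qtl_type})
            qid += 1
    qtls = pd.DataFrame(qtl_rows)

    # known SVs: regions designated novel get none; the rest get >=50% cover
    novel = rng.random(len(region_list)) < config.novel_fraction
    sv_rows = []
    sid = 0
    for flag, r in zip(novel, region_list):
        if flag:
            continue
        rlen = r.end - r.start + 1
        frac = rng.uniform(0.5, 1.2)
        L = max(1, int(round(rlen * frac)))
        clen = genome.length(r.chrom)
        # anchor so the SV covers at least half the region
        lo = max(1, r.start - max(0, L - rlen))
        hi = max(lo, min(r.start + rlen // 2, clen - L + 1))
        start = int(rng.integers(lo, hi + 1))
        sv_rows.append({"chrom": r.chrom, "start": start,
                        "end": min(start + L - 1, clen), "id": f"SV{sid:05d}"})
        sid += 1
    # background SVs away from novel regions
    novel_regions = [r for flag, r in zip(novel, region_list) if flag]
    n_background = len(region_list)
    attempts = 0
    while n_background > 0 and attempts < 50 * len(region_list) + 100:
        attempts += 1
        L = int(_lognormal_lengths(rng, 1, 80_000, 0.8, 1_000)[0])
        chrom, start, end = _uniform_interval(rng, genome, weights, L)
        if any(r.chrom == chrom and start <= r.end and r.start <= end
               for r in novel_regions):
            continue
        sv_rows.append({"chrom": chrom, "start": start, "end": end,
                        "id": f"SV{sid:05d}"})
        sid += 1
        n_background -= 1
    svs = pd.DataFrame(sv_rows)

    if return_novel_truth:
        truth_novel = regions.copy().reset_index(drop=True)
        truth_novel["planted_novel"] = novel
        return genes, qtls, svs, truth_novel
    return genes, qtls, svs


def simulate_overlap_universe(
    rng: np.random.Generator,
    n_categories: int = 200,
    category_size: int = 50,
    background_prob: float = 0.1,
    planted: tuple[str, int, float] | None = None,
) -> pd.DataFrame:
    """Draw per-unit overlap indicators for enrichment calibration studies.

    Each annotation unit overlaps a region independently: with
    ``background_prob`` for background categories, or with the planted
    probability for the planted category ``(name, size, prob)``. Returns a
    category table with columns (category, S, k) from which N and m follow.
    """
    rows = []
    for c in range(n_categories):
        k = int(rng.binomial(category_size, background_prob))
        rows.append({"category": f"cat{c:03d}", "S": category_size, "k": k})
    if planted is not None:
        name, size, prob = planted
        rows.append({"category": name, "S": size,
                     "k": int(rng.binomial(size, prob))})
    return pd.DataFrame(rows)
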