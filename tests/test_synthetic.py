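"""Tests of the synthetic cohort generator: determinism, mixture
convergence, paired-dataset structure, and signal-model correctness."""

import numpy as np
import pandas as pd
import pytest

import cnvrkit as ck
from cnvrkit.synthetic import PlacementError


class TestMakeGenome:
    def test_deterministic_across_calls(self):
        cfg = ck.SimulationConfig(seed=1, chromosome_lengths_mb=(10.0, 10.0, 10.0))
        assert ck.make_genome(cfg) == ck.make_genome(cfg)

    def test_full_autosome_total_length(self):
        # 29 autosomes summing to the bovine autosomal total of 2,489.39 Mb
        lengths = [85.84] * 28 + [2489.39 - 85.84 * 28]
        cfg = ck.SimulationConfig(chromosome_lengths_mb=tuple(lengths))
        genome = ck.make_genome(cfg)
        assert len(genome.chromosomes) == 29
        assert genome.total_length == pytest.approx(2_489_390_000, abs=29)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(Exception, match="positive"):
            ck.SimulationConfig(chromosome_lengths_mb=(0.0,))


class TestPlantLoci:
    def test_pure_deletion_mixture(self):
        cfg = ck.SimulationConfig(seed=5, n_loci=50, deletion_fraction=1.0,
                                  chromosome_lengths_mb=(50.0, 50.0))
        loci = ck.plant_loci(ck.make_genome(cfg), cfg)
        assert (loci["state"] < 2).all()

    def test_realized_deletion_fraction_within_binomial_bound(self):
        lengths = tuple([85.0] * 29)
        cfg = ck.SimulationConfig(seed=7, n_loci=5_000, deletion_fraction=0.78,
                                  chromosome_lengths_mb=lengths)
        loci = ck.plant_loci(ck.make_genome(cfg), cfg)
        frac = (loci["state"] < 2).mean()
        sd = np.sqrt(0.78 * 0.22 / 5_000)
        assert abs(frac - 0.78) <= 3 * sd

    def test_deletions_shorter_than_duplications_on_average(self):
        cfg = ck.SimulationConfig(seed=9, n_loci=2_000,
                                  chromosome_lengths_mb=tuple([85.0] * 20))
        loci = ck.plant_loci(ck.make_genome(cfg), cfg)
        lengths = loci["end"] - loci["start"] + 1
        assert lengths[loci["state"] < 2].mean() < lengths[loci["state"] > 2].mean()

    def test_infeasible_placement_raises(self):
        cfg = ck.SimulationConfig(seed=1, n_loci=2,
                                  chromosome_lengths_mb=(0.001,),
                                  min_locus_length=10_000)
        with pytest.raises(PlacementError):
            ck.plant_loci(ck.make_genome(cfg), cfg)

    def test_loci_within_bounds_and_disjoint(self, small_cohort):
        loci, genome = small_cohort["loci"], small_cohort["genome"]
        assert (loci["start"] >= 1).all()
        for r in loci.itertuples(index=False):
            assert r.end <= genome.length(r.chrom)
        for _, g in loci.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()


class TestSimulateSamples:
    def test_no_drop_no_perturbation_gives_identical_datasets(self):
        cfg = ck.SimulationConfig(seed=3, n_samples=30, n_loci=10,
                                  chromosome_lengths_mb=(30.0,),
                                  b_sample_drop_rate=0.0, b_snp_drop_rate=0.0,
                                  perturbation_fraction=0.0)
        g = ck.make_genome(cfg)
        m = ck.make_snp_map(g, cfg)
        loci = ck.plant_loci(g, cfg)
        a, b, _ = ck.simulate_samples(loci, g, m, cfg)
        cols = ["sample_id", "chrom", "start", "end", "state", "numsnp"]
        pd.testing.assert_frame_equal(a[cols].reset_index(drop=True),
                                      b[cols].reset_index(drop=True))

    def test_full_perturbation_empties_exact_intersection(self):
        cfg = ck.SimulationConfig(seed=3, n_samples=30, n_loci=10,
                                  chromosome_lengths_mb=(30.0,),
                                  b_sample_drop_rate=0.0, b_snp_drop_rate=0.0,
                                  perturbation_fraction=1.0)
        g = ck.make_genome(cfg)
        m = ck.make_snp_map(g, cfg)
        loci = ck.plant_loci(g, cfg)
        a, b, _ = ck.simulate_samples(loci, g, m, cfg)
        key = ["sample_id", "chrom", "start", "end", "state"]
        tuples_a = set(map(tuple, a[key].itertuples(index=False)))
        tuples_b = set(map(tuple, b[key].itertuples(index=False)))
        assert not tuples_a & tuples_b

    def test_carrier_count_within_binomial_bound(self):
        cfg = ck.SimulationConfig(seed=3, n_samples=100, n_loci=1,
                                  chromosome_lengths_mb=(30.0,))
        g = ck.make_genome(cfg)
        m = ck.make_snp_map(g, cfg)
        loci = pd.DataFrame([{"locus_id": "locus0000", "chrom": "1",
                              "start": 5_000_000, "end": 5_200_000,
                              "state": 1, "carrier_frequency": 0.2}])
        a, _, _ = ck.simulate_samples(loci, g, m, cfg)
        sd = np.sqrt(100 * 0.2 * 0.8)
        assert abs(len(a) - 20) <= 3 * sd

    def test_truth_and_calls_mutually_consistent(self, small_cohort):
        # every A-call maps to exactly one truth event of the same sample
        a, truth = small_cohort["calls_a"], small_cohort["truth"]
        key = ["sample_id", "chrom", "start", "end", "state"]
        truth_keys = truth[key].apply(tuple, axis=1)
        assert truth_keys.is_unique
        call_keys = a[key].apply(tuple, axis=1)
        assert call_keys.isin(set(truth_keys)).all()
        assert len(call_keys) == len(truth)

    def test_bitwise_determinism(self, small_config, small_cohort):
        g = ck.make_genome(small_config)
        m = ck.make_snp_map(g, small_config)
        loci = ck.plant_loci(g, small_config)
        a, b, truth = ck.simulate_samples(loci, g, m, small_config)
        pd.testing.assert_frame_equal(a, small_cohort["calls_a"])
        pd.testing.assert_frame_equal(b, small_cohort["calls_b"])
        pd.testing.assert_frame_equal(truth, small_cohort["truth"])


class TestSimulateSignals:
    def _one_locus_setup(self, state, lrr_sd, baf_sd):
        cfg = ck.SimulationConfig(seed=4, n_samples=2, n_loci=1,
                                  chromosome_lengths_mb=(5.0,),
                                  lrr_sd=lrr_sd, baf_sd=baf_sd)
        g = ck.make_genome(cfg)
        m = ck.make_snp_map(g, cfg)
        truth = pd.DataFrame([{"sample_id": "HOL0000", "locus_id": "l0",
                               "chrom": "1", "start": 1_000_000,
                               "end": 1_100_000, "state": state}])
        return cfg, g, m, truth

    def test_noiseless_diploid_lrr_exactly_zero(self):
        cfg, g, m, _ = self._one_locus_setup(1, 0.0, 0.0)
        tracks = ck.simulate_signals(pd.DataFrame(), g, m, cfg,
                                     sample_ids=["HOL0001"])
        assert (tracks["HOL0001"]["lrr"] == 0.0).all()

    def test_noiseless_hemizygous_baf_is_homozygous_only(self):
        cfg, g, m, truth = self._one_locus_setup(1, 0.0, 0.0)
        track = ck.simulate_signals(truth, g, m, cfg,
                                    sample_ids=["HOL0000"])["HOL0000"]
        inside = track[(track["position"] >= 1_000_000)
                       & (track["position"] <= 1_100_000)]
        assert len(inside) > 0
        assert inside["baf"].isin([0.0, 1.0]).all()
        assert (inside["lrr"] == -0.66).all()

    def test_deletion_lrr_mean_within_standard_error(self):
        cfg, g, m, truth = self._one_locus_setup(1, 0.15, 0.03)
        track = ck.simulate_signals(truth, g, m, cfg,
                                    sample_ids=["HOL0000"])["HOL0000"]
        inside = track[(track["position"] >= 1_000_000)
                       & (track["position"] <= 1_100_000)]
        n = len(inside)
        assert n >= 20
        assert abs(inside["lrr"].mean() + 0.66) <= 3 * 0.15 / np.sqrt(n)

    def test_zero_density_rejected(self):
        with pytest.raises(Exception):
            ck.SimulationConfig(snp_density_per_mb=0.0)


class TestSimulateAnnotations:
    def test_null_planting_leaves_planted_trait_unenriched(self):
        cfg = ck.SimulationConfig(seed=21, n_samples=30, n_loci=30,
                                  chromosome_lengths_mb=(40.0, 40.0),
                                  enriched_overlap_prob=0.0)
        g = ck.make_genome(cfg)
        loci = ck.plant_loci(g, cfg)
        regions = loci[["chrom", "start", "end", "state"]]
        genes, qtls, svs = ck.simulate_annotations(g, regions, cfg)
        cnvrs = regions.assign(type="deletion")
        ov = ck.overlap(cnvrs, qtls.rename(columns={"qtl_id": "id"}), kind="qtl")
        res = ck.qtl_enrichment(qtls, ov)
        planted = res[res["category"] == cfg.enriched_trait].iloc[0]
        assert planted["p_fdr"] > 0.05

    def test_planted_overlap_count_near_expectation(self):
        cfg = ck.SimulationConfig(seed=22, n_samples=30, n_loci=30,
                                  chromosome_lengths_mb=(40.0, 40.0),
                                  enriched_trait_size=50,
                                  enriched_overlap_prob=0.9)
        g = ck.make_genome(cfg)
        loci = ck.plant_loci(g, cfg)
        regions = loci[["chrom", "start", "end", "state"]]
        _, qtls, _ = ck.simulate_annotations(g, regions, cfg)
        enriched = qtls[qtls["trait"] == cfg.enriched_trait]
        cnvrs = regions.assign(type="deletion")
        ov = ck.overlap(cnvrs, enriched.rename(columns={"qtl_id": "id"}),
                        kind="qtl")
        k = ov["annotation_id"].nunique()
        sd = np.sqrt(50 * 0.9 * 0.1)
        # anchored placement guarantees >= the planted Bernoulli draws;
        # chance overlap can only add hits
        assert k >= 45 - 3 * sd

    def test_novel_fraction_matches_binomial_expectation(self):
        cfg = ck.SimulationConfig(seed=23, n_samples=10, n_loci=10,
                                  chromosome_lengths_mb=tuple([80.0] * 10),
                                  novel_fraction=0.17)
        g = ck.make_genome(cfg)
        rng = np.random.default_rng(0)
        starts = []
        for i in range(1_000):
            chrom = str(i % 10 + 1)
            s = 50_000 + (i // 10) * 700_000
            starts.append({"chrom": chrom, "start": s, "end": s + 50_000,
                           "state": 1})
        regions = pd.DataFrame(starts)
        genes, qtls, svs, novel_truth = ck.simulate_annotations(
            g, regions, cfg, return_novel_truth=True)
        novelty = ck.classify_novelty(regions, svs)
        n_novel = (novelty["category"] == "novel").sum()
        sd = np.sqrt(1_000 * 0.17 * 0.83)
        assert abs(n_novel - 170) <= 3 * sd
        # planted-novel regions are exactly the zero-overlap ones
        assert (novel_truth["planted_novel"].to_numpy()
                == (novelty["category"] == "novel").to_numpy()).all()
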