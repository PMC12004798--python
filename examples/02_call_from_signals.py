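"""Call CNVs from simulated LRR/BAF tracks with the HMM caller.

Simulates signal tracks for a few carriers, estimates the population
B-allele frequency (PFB) from the cohort BAF matrix, and decodes each
sample's copy-number path by Viterbi. Planted events appear as runs of
non-diploid states; their boundaries land on the first/last supporting SNP.
"""

import pandas as pd

import cnvrkit as ck

config = ck.SimulationConfig(seed=7, n_samples=8, n_loci=12,
                             chromosome_lengths_mb=(10.0,),
                             min_locus_length=60_000,
                             carrier_freq_min=0.2, carrier_freq_max=0.5,
                             lrr_sd=0.15, baf_sd=0.03)
genome = ck.make_genome(config)
snp_map = ck.make_snp_map(genome, config)
loci = ck.plant_loci(genome, config)
_, _, truth = ck.simulate_samples(loci, genome, snp_map, config)

samples = sorted(truth["sample_id"].unique())
tracks = ck.simulate_signals(truth, genome, snp_map, config, sample_ids=samples)
pfb = ck.compile_pfb(pd.DataFrame(
    {s: t.set_index("snp_id")["baf"] for s, t in tracks.items()}).T)

model = ck.HmmModel(lrr_sd=0.2, baf_sd=0.05)
calls = pd.concat([ck.viterbi_call(tracks[s], pfb, model, sample_id=s)
                   for s in samples], ignore_index=True)

recovery = ck.breakpoint_recovery(truth, calls, snp_map, tol_snps=2)
print(f"{len(truth)} planted events in {len(samples)} carriers")
print(f"{len(calls)} calls decoded; breakpoint recovery (+-2 SNPs): "
      f"{recovery:.0%}")
print(calls.head(5)[["sample_id", "chrom", "start", "end", "state", "numsnp"]])
# state is the copy number (1 = hemizygous deletion, 3 = single-copy gain);
# numsnp is the number of consecutive probes supporting the call.
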