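"""Three-step quality control: sample signal metrics and call filters.

Sample level: LRR standard deviation <= 0.30, BAF drift <= 0.01, waviness
<= 0.05 and at most 1,000 calls per sample (all inclusive). Call level:
>= 10 supporting SNPs, >= 1 kb, and the identical event in >= 5 animals.
"""

import pandas as pd

import cnvrkit as ck

config = ck.SimulationConfig(seed=3, n_samples=80, n_loci=40,
                             chromosome_lengths_mb=(30.0, 25.0))
genome = ck.make_genome(config)
snp_map = ck.make_snp_map(genome, config)
loci = ck.plant_loci(genome, config)
calls_a, _, truth = ck.simulate_samples(loci, genome, snp_map, config)

# sample metrics on a couple of signal tracks
samples = ["HOL0000", "HOL0001"]
tracks = ck.simulate_signals(truth, genome, snp_map, config, sample_ids=samples)
metrics = pd.DataFrame([
    ck.compute_sample_metrics(tracks[s], calls_a, s) for s in samples])
passing, report = ck.filter_samples(metrics)
print(report[["sample_id", "lrr_sd", "baf_drift", "waviness",
              "cnv_count", "pass"]].to_string(index=False))

filtered = ck.filter_calls(calls_a)
print(f"\ncall filters: {len(filtered)} of {len(calls_a)} calls retained")
# Removed calls lack SNP support, are shorter than 1 kb, or are carried by
# fewer than five animals at identical coordinates.
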