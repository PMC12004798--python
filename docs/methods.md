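# Methods

This note documents the models, parameter choices and numerical decisions
behind cnvrkit, and what the synthetic studies do and do not establish.

## Signal model and caller

The caller is a deliberately small five-state HMM over copy numbers
{0, 1, 2, 3, 4}; there is no loss-of-heterozygosity state (copy-neutral LOH
is indistinguishable in LRR and rare enough on autosomal CNV scans that the
simplification costs little on the synthetic benchmarks; it is a documented
departure from production array callers).

**Emissions.** LRR is Gaussian per state with means (−3.5, −0.66, 0.0,
0.40, 0.68) — conventional SNP-array values, configurable — and a common
standard deviation (default 0.2, intentionally wider than the generator's
0.15 so that mild model misspecification is part of every benchmark). BAF
for copy number *c* ≥ 1 is a mixture with components at *k/c*
(*k* = 0..*c*), weights Binomial(*c*, PFB), each component a normal
(default sd 0.04) truncated to [0, 1]; the truncation normalizer keeps the
homozygous components at 0 and 1 proper despite the boundary. Copy number 0
emits uniform BAF (pure noise). PFB is the cohort mean BAF per SNP clamped
to [0.01, 0.99], the standard guard against degenerate priors.

**Transitions.** For inter-SNP distance *d*, the stay probability is
1 − θ(1 − e^(−d/D)) with D = 100 kb and θ = 0.01; leaving mass is split
over the other four states with 4× extra weight on diploid. This keeps
diploid the default at long gaps and makes state runs cohere at array
densities (~300 probes/Mb). Initial distribution: 0.99 diploid.

**Decoding.** Viterbi in log space per chromosome. Ties are broken toward
the state closest to copy 2, then toward the lower copy number, by running
the recursion in that preference order so `argmax` returns the preferred
state — decoding is therefore deterministic and, as tested, invariant to
multiplying all emission densities by a positive constant. Chromosomes
with fewer than two probes are skipped. Maximal non-diploid runs become
calls with `numsnp` = run length and boundaries at the first/last probe of
the run.

**GC-wave correction.** A per-sample linear regression of LRR on the
percent GC in a 1 Mb window centred on each probe; LRR is replaced by the
residuals re-centred to the pre-correction median. Constant GC makes the
correction the identity (logged). GC missing for >10% of probes is an
error rather than a silent partial fit.

## Quality control

Sample metrics are operational proxies for the usual array QC quantities,
flagged as such in output metadata: LRR sd is the plain standard deviation
of autosomal LRR; BAF drift is the fraction of probes with BAF in
[0.2, 0.25] ∪ [0.75, 0.8] (mass between genotype clusters); waviness is
the standard deviation of per-1 Mb-window median LRR (long-range
oscillation). Thresholds (0.30 / 0.01 / 0.05 / 1,000 calls) are inclusive.
Call filters: ≥ 10 SNPs, ≥ 1 kb (1-based inclusive length), and the
identical (chromosome, start, end, state) tuple in ≥ 5 distinct samples.
Carrier counting on identical tuples matches the non-redundant event
definition downstream; a reciprocal-overlap mode (≥ 50% both ways, same
copy-number class) exists behind a flag for callers with noisier
boundaries, but is off by default.

## High-confidence intersection

A call is high-confidence iff the same sample carries a call with
identical coordinates in both processed datasets. Coordinate identity
alone would let a deletion in one dataset certify a duplication in the
other, so state equality is also required by default (`match_state=False`
restores the coordinate-only reading). Samples present in only one dataset
are excluded. Collapsing to non-redundant events groups identical
(chromosome, start, end, type) tuples; the sum of carrier counts equals
the number of high-confidence calls, a conservation law asserted in tests.

## CNVR construction

Candidate regions are transitive merges of calls sharing ≥ 1 bp. The
coverage profile within a candidate is computed by an endpoint sweep
(+1 at start, −1 at end+1, cumulative sum over sorted breakpoints), which
is exact; tests verify equality with a brute-force per-base array on
hundreds of random instances. A base is retained iff
coverage / *n* ≥ density, where *n* is the candidate's pre-trim
contributing-call count — the denominator deliberately stays fixed even
when trimming splits the candidate, so "10% of the contributing CNVs"
keeps one meaning; per-segment contributing lists are recomputed for
reporting only. density → 0⁺ degenerates to the plain union; density = 1
keeps only bases covered by every call. Retained segments shorter than a
floor (default 1 kb, echoing the call-level rule) are dropped with a log
entry. Classification: deletion if every contributing state < 2,
duplication if every state > 2, otherwise complex.

Summary statistics use inclusive upper bin bounds for the length histogram
((0, 200], (200, 400], (400, 600], > 600 kb) and report genome coverage as
100 × covered bp / genome bp to two decimals.

## Annotation

All arithmetic is 1-based inclusive; shared length is
min(ends) − max(starts) + 1 (the +1 convention is pinned by a worked
gene-overlap example in the tests). The join uses an interval tree per
chromosome and is verified against a quadratic all-pairs scan. Gene
completeness is judged on the full gene span, not exon structure. Novelty
against a known-SV catalogue uses the union of overlapping SV bases — a
base covered by several stacked SV records counts once — with categories:
novel (zero shared bp), majority_known (union ≥ 50% of the region length,
inclusive), minority_known (the rest); the three partition the region set.
QTL records without usable coordinates are dropped with a logged count.

## Enrichment

The hypergeometric upper tail P(X ≥ k) is computed from log-gamma binomial
coefficients as a ratio of logsumexp sums over the support — the shared
log C(N, m) scale cancels, which keeps absolute error below 1e−12 against
exact rational arithmetic even at N = 10⁴ (a direct single-sum log-space
evaluation is an order of magnitude less accurate near P = 1).
Benjamini–Hochberg adjustment is delegated to statsmodels and checked
against a hand-applied step-up rule. Units are counted distinctly: a QTL
hit by several regions counts once in both *m* and *k*. The universe is
whatever annotation table the caller supplies (every record with usable
coordinates); the FDR family is all categories with S ≥ 1. Gene-set mode
reuses the identical machinery with genes as units and terms as
categories; term→gene mappings are taken as given, with no ontology-graph
propagation.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: one cohort
genotyped on a dense array, processed twice — dataset A with every sample
and SNP, dataset B after emulated sample/SNP QC (2% sample drop, 2% SNP
drop) plus a one-probe boundary shift on 10% of its calls. The shift is
the exact failure mode the exact-coordinate intersection rejects; how
often the real datasets disagreed is not knowable from published
summaries, so the perturbation fraction is an explicit knob, not an
estimate.

Default conditions (desk scale): 300 samples on 5 autosomes of 60–40 Mb —
a tenth of a ~3,000-animal, 29-autosome design — with 150 planted loci,
78% deletions, log-normal lengths with means 60 kb (deletions) and 93 kb
(duplications) and log-sd 0.6, minimum 5 kb, probe density 300 SNPs/Mb.
Deletions are copy 1 (10% copy 0); duplications copy 3 (10% copy 4);
diploid is never emitted as a call. Carrier frequencies are uniform on
[0.03, 0.35]: at a large-cohort scale carrier counts of 5–1,000 animals
correspond to much lower frequencies, but at n = 300 this range keeps
most loci above the 5-carrier filter while leaving some below it, so the
filter has work to do. Loci are placed non-overlapping, length-weighted
across chromosomes.

Signals: per-SNP population B-allele frequency uniform on [0.05, 0.95];
genotypes Binomial(copy, p); BAF = genotype fraction + N(0, 0.03) clipped
to [0, 1] (uniform for copy 0); LRR = state mean + N(0, 0.15) + optional
GC wave. Annotations: an enriched trait ("Milk yield", 50 QTLs) anchored
to overlap truth regions with probability 0.9, background traits placed
uniformly; 17% of truth regions kept free of known SVs; a third of genes
anchored on regions so both complete and partial overlap classes occur.

One global seed determines everything; stages draw from generators derived
by fixed offsets, and each sample's signal track is seeded independently,
so any subset reproduces bitwise.

**What the generator does not model:** linkage disequilibrium, pedigree or
inheritance (carriers are independent draws), raw intensity artifacts,
batch/plate effects, segmental-duplication probe bias, and real breakpoint
uncertainty beyond the one-probe shift. Passing benchmarks therefore show
the machinery is correct and calibrated under the stated model — not that
the caller matches production callers on real array data, a claim the
package deliberately does not make.

## Benchmarks and problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen to exercise every code path in seconds: exhaustive Viterbi
enumeration on tracks of ≤ 8 probes (100 seeded tracks), per-base region
oracles on 200 random instances, hypergeometric checks against exact
rational arithmetic up to N = 10⁴, a 200-category null calibration
(rejection rate ≈ 5% within 3σ binomial bounds), 200 power replicates
(planted trait, S = 50, overlap 0.9 vs 0.1 background — power ≈ 100%),
caller breakpoint recovery (≥ 95% within ±2 probes on ≥ 20-SNP events at
LRR shift ≥ 0.4, noise sd 0.15), and the full 300-sample pipeline run
twice to certify digest-identical manifests.

## Known limitations

- The caller's parameters are not fitted; they are fixed conventional
  values. No claim of numerical compatibility with production HMM callers.
- No X/Y model, no trio or joint calling.
- `filter_calls` counts carriers before/after independently of sample QC;
  callers must pass sample-filtered call sets in (the pipeline does).
- Whether trimming-induced region splits should be counted as one region
  or several is a genuinely open convention; each retained segment is
  reported separately here, preserving the density guarantee per region.
- Molecular-consequence prediction (VEP-style) is out of scope; novelty
  and gene overlap are purely coordinate-based.
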