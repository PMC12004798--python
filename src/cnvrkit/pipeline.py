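"""End-to-end orchestration: simulate -> [call] -> qc -> intersect ->
regions -> annotate -> enrich, with a reproducible run manifest.

Every stage's outputs are plain text files under the run directory and pure
functions of the declared inputs plus the config; the manifest records
SHA-256 digests of all outputs, so two runs with the same seed and config
produce identical digests (timings excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import annotate, highconf, hmm, io, qc, regions
from . import synthetic
from .enrich import qtl_enrichment
from .config import ConfigError, SimulationConfig

log = logging.getLogger(__name__)

STAGES = ["simulate", "call", "qc", "intersect", "regions", "annotate", "enrich"]


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    warnings: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "config_digest": self.config_digest,
            "version": self.version, "digests": self.digests,
            "timings": self.timings, "stages_run": self.stages_run,
            "warnings": self.warnings,
        }, indent=2, sort_keys=True)


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


class _Run:
    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = outdir
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(
            seed=int(config.get("seed", config.get("simulation", {})
                                .get("seed", 0))),
            config_digest=_digest_config(config),
            version=__version__)

    def emit(self, name: str, writer, *args) -> Path:
        path = self.outdir / name
        writer(*args, path)
        self.manifest.digests[name] = _digest_file(path)
        return path


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> RunManifest:
    """Execute the pipeline described by ``config`` into ``outdir``.

    Synthetic mode (a ``simulation`` section) generates the cohort; file
    mode (an ``inputs`` section with calls_a/calls_b plus annotation paths)
    starts from user-provided call sets. Stages whose inputs are supplied
    downstream are skipped. Fails fast naming the offending stage.
    """
    outdir = Path(outdir)
    run = _Run(config, outdir)
    t0 = time.time()

    # ---- simulate ---------------------------------------------------------
    inputs = config.get("inputs", {})
    sim_section = config.get("simulation")
    if sim_section is not None:
        t = time.time()
        sim = SimulationConfig.from_dict(dict(sim_section))
        genome = synthetic.make_genome(sim)
        snp_map = synthetic.make_snp_map(genome, sim)
        loci = synthetic.plant_loci(genome, sim)
        calls_a, calls_b, truth = synthetic.simulate_samples(
            loci, genome, snp_map, sim)
        truth_regions = loci[["chrom", "start", "end", "state"]]
        genes, qtls, svs = synthetic.simulate_annotations(genome, truth_regions, sim)
        run.emit("genome.tsv", io.write_genome, genome)
        run.emit("loci.tsv", io.write_tsv, loci)
        run.emit("truth.tsv", io.write_tsv, truth)
        run.emit("calls_a.rawcnv", io.write_rawcnv, calls_a)
        run.emit("calls_b.rawcnv", io.write_rawcnv, calls_b)
        run.emit("genes.gff3", io.write_gff3, genes)
        run.emit("qtls.tsv", io.write_qtls, qtls)
        run.emit("known_svs.bed", io.write_bed, svs)
        run.manifest.timings["simulate"] = time.time() - t
        run.manifest.stages_run.append("simulate")
    else:
        for key in ("calls_a", "calls_b", "genome", "genes", "qtls", "svs"):
            if key not in inputs:
                raise ConfigError(
                    f"stage simulate skipped but inputs.{key} not provided")
        genome = io.read_genome(inputs["genome"])
        calls_a = io.read_rawcnv(inputs["calls_a"], dataset="A")
        calls_b = io.read_rawcnv(inputs["calls_b"], dataset="B")
        genes = io.read_gff3_genes(inputs["genes"])
        qtls = io.read_qtls(inputs["qtls"])
        svs = io.read_bed(inputs["svs"])

    # ---- call (optional: only when signal tracks are supplied) ------------
    signal_tracks: dict[str, pd.DataFrame] | None = None
    if "signals_dir" in inputs:
        t = time.time()
        sig_dir = Path(inputs["signals_dir"])
        tracks = dict(io.read_signal_tsv(p) for p in sorted(sig_dir.glob("*.tsv")))
        pfb = io.read_pfb(inputs["pfb"]) if "pfb" in inputs else \
            hmm.compile_pfb(pd.DataFrame(
                {s: tr.set_index("snp_id")["baf"] for s, tr in tracks.items()}).T)
        model = hmm.HmmModel(**config.get("hmm", {}))
        gcmodel = io.read_gcmodel(inputs["gcmodel"]) if "gcmodel" in inputs else None
        called = []
        for sample, track in tracks.items():
            if gcmodel is not None:
                track = hmm.gc_correct(track, gcmodel)
            called.append(hmm.viterbi_call(track, pfb, model, sample_id=sample,
                                           dataset="A"))
        calls_a = pd.concat(called, ignore_index=True) if called else io.empty_calls()
        signal_tracks = tracks
        run.emit("called.rawcnv", io.write_rawcnv, calls_a)
        run.manifest.timings["call"] = time.time() - t
        run.manifest.stages_run.append("call")
    else:
        log.info("call stage skipped: calls provided directly")

    # ---- qc ---------------------------------------------------------------
    t = time.time()
    qc_cfg = config.get("qc", {})
    call_filter = qc.CallFilterConfig(
        min_snps=int(qc_cfg.get("min_snps", 10)),
        min_length=int(qc_cfg.get("min_length", 1_000)),
        min_carriers=int(qc_cfg.get("min_carriers", 5)))
    if signal_tracks is not None:
        thresholds = qc.SampleQcThresholds(
            max_lrr_sd=float(qc_cfg.get("max_lrr_sd", 0.30)),
            max_baf_drift=float(qc_cfg.get("max_baf_drift", 0.01)),
            max_waviness=float(qc_cfg.get("max_waviness", 0.05)),
            max_cnv_count=int(qc_cfg.get("max_cnv_count", 1_000)))
        metrics = pd.DataFrame([
            qc.compute_sample_metrics(track, calls_a, sample)
            for sample, track in signal_tracks.items()])
        passing, report = qc.filter_samples(metrics, thresholds)
        run.emit("sample_qc.tsv", io.write_tsv, report)
        calls_a = calls_a[calls_a["sample_id"].isin(passing)]
        calls_b = calls_b[calls_b["sample_id"].isin(passing)]
    else:
        log.info("sample-level QC skipped: no signal tracks supplied")
    filtered_a = qc.filter_calls(calls_a, call_filter)
    filtered_b = qc.filter_calls(calls_b, call_filter)
    run.emit("filtered_a.rawcnv", io.write_rawcnv, filtered_a)
    run.emit("filtered_b.rawcnv", io.write_rawcnv, filtered_b)
    run.manifest.timings["qc"] = time.time() - t
    run.manifest.stages_run.append("qc")

    # ---- intersect --------------------------------------------------------
    t = time.time()
    hc = highconf.intersect_datasets(filtered_a, filtered_b)
    nonredundant = highconf.collapse_nonredundant(hc)
    run.emit("highconf.rawcnv", io.write_rawcnv, hc)
    run.emit("nonredundant.tsv", io.write_tsv, nonredundant)
    run.manifest.timings["intersect"] = time.time() - t
    run.manifest.stages_run.append("intersect")

    # ---- regions ----------------------------------------------------------
    t = time.time()
    reg_cfg = config.get("regions", {})
    cnvrs = regions.build_cnvrs(
        hc, density=float(reg_cfg.get("density", 0.1)),
        min_segment=int(reg_cfg.get("min_segment", 1_000)))
    summary = regions.summarize(cnvrs, genome)
    run.emit("cnvrs.tsv", io.write_tsv, cnvrs)
    run.emit("cnvrs.bed", lambda df, p: io.write_bed(
        df.assign(id=annotate.cnvr_ids(df)), p), cnvrs)
    run.emit("cnvr_summary.txt",
             lambda s, p: Path(p).write_text(s.to_text() + "\n"), summary)
    run.emit("cnvr_length_histogram.tsv", io.write_tsv, summary.length_histogram)
    run.emit("cnvr_per_chromosome.tsv", io.write_tsv, summary.per_chromosome)
    run.manifest.timings["regions"] = time.time() - t
    run.manifest.stages_run.append("regions")

    # ---- annotate ---------------------------------------------------------
    t = time.time()
    qtls = annotate.drop_unplaced(qtls, "QTL")
    gene_overlaps = annotate.overlap(cnvrs, genes, kind="gene")
    qtl_overlaps = annotate.overlap(
        cnvrs, qtls.rename(columns={"qtl_id": "id"}), kind="qtl")
    novelty = annotate.classify_novelty(cnvrs, svs)
    run.emit("overlaps_genes.tsv", io.write_tsv, gene_overlaps)
    run.emit("overlaps_qtls.tsv", io.write_tsv, qtl_overlaps)
    run.emit("novelty.tsv", io.write_tsv, novelty)
    run.manifest.timings["annotate"] = time.time() - t
    run.manifest.stages_run.append("annotate")

    # ---- enrich -----------------------------------------------------------
    t = time.time()
    alpha = float(config.get("enrichment", {}).get("alpha", 0.05))
    results = qtl_enrichment(qtls, qtl_overlaps, alpha=alpha)
    run.emit("enrichment.tsv", io.write_tsv, results)
    run.manifest.timings["enrich"] = time.time() - t
    run.manifest.stages_run.append("enrich")

    run.manifest.timings["total"] = time.time() - t0
    (outdir / "manifest.json").write_text(run.manifest.to_json() + "\n")
    return run.manifest
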