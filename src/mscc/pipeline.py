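"""End-to-end orchestration: simulate -> digest -> map -> quantify -> annotate
-> differential -> profiles, with a checksummed run manifest.

Each stage writes plain-text tables into the output directory. A stage that
fails raises :class:`StageError` naming the stage, and any outputs it already
wrote are kept with a ``.partial`` suffix. Re-running with an unchanged
config and seed skips stages whose recorded outputs are intact.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_sites, stratum_means
from .config import PipelineConfig, SimulationConfig
from .differential import (
    compare_all_units,
    make_cgi_units,
    make_windows,
    site_level_consistency,
)
from .digest import build_tag_library, find_ccgg_sites, sites_to_frame, write_sites, write_tag_library
from .errors import ConfigurationError, StageError
from .io import read_bed, read_fasta, read_fastq, read_genes, read_tsv, write_tsv
from .mapping import map_reads
from .profiles import (
    expression_tertile_profiles,
    metagene_profile,
    peak_overlap_summary,
    shortrna_proximity_summary,
)
from .quantify import chromosome_summary, normalize_and_call
from .simulate import Annotations, MethylomeTruth, make_standard_tags, write_simulation

logger = logging.getLogger(__name__)

PRESETS = ("null_emt", "planted_dmr", "expression_coupled", "tiny")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _row_count(path: Path) -> int:
    try:
        with open(path) as fh:
            return sum(1 for _ in fh)
    except UnicodeDecodeError:
        return -1


def load_annotations(dirpath: str | Path) -> Annotations:
    """Read an annotation directory in the layout the simulator writes."""
    dirpath = Path(dirpath)
    genes = read_genes(dirpath / "genes.bed12")
    cgis = read_bed(dirpath / "cgis.bed")
    peaks = {
        p.stem.removeprefix("peaks_"): read_bed(p) for p in sorted(dirpath.glob("peaks_*.bed"))
    }
    shortrna = read_bed(dirpath / "shortrna.bed")
    expression = read_tsv(dirpath / "expression.tsv")
    return Annotations(genes, cgis, peaks, shortrna, expression)


class _Runner:
    """Executes stages, tracking outputs, skipping and failure attribution."""

    def __init__(self, outdir: Path, previous: dict | None, config_hash: str, force: bool):
        self.outdir = outdir
        self.previous = previous if previous and previous.get("config_hash") == config_hash and not force else None
        self.stages: list[dict] = []

    def _prev_outputs(self, name: str) -> list[dict] | None:
        if not self.previous:
            return None
        for st in self.previous.get("stages", []):
            if st["name"] == name:
                return st["outputs"]
        return None

    def run(self, name: str, fn, expected_outputs: list[Path]):
        prev = self._prev_outputs(name)
        if prev is not None and all(
            Path(o["path"]).exists() and _sha256(Path(o["path"])) == o["sha256"] for o in prev
        ):
            logger.info("stage %s: outputs current, skipped", name)
            self.stages.append({"name": name, "outputs": prev, "skipped": True})
            return None
        try:
            result = fn()
        except Exception as exc:
            for p in expected_outputs:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise StageError(name, str(exc)) from exc
        outputs = [
            {"path": str(p), "sha256": _sha256(p), "rows": _row_count(p)}
            for p in expected_outputs
            if p.exists()
        ]
        self.stages.append({"name": name, "outputs": outputs, "skipped": False})
        return result


def run_all(config: PipelineConfig, seed: int | None = None, force: bool = False) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simcfg: SimulationConfig = config.simulation
    if seed is not None:
        simcfg = simcfg.model_copy(update={"seed": seed})
    cfg_snapshot = json.loads(config.model_dump_json())
    cfg_snapshot["simulation"]["seed"] = simcfg.seed
    config_hash = hashlib.sha256(json.dumps(cfg_snapshot, sort_keys=True).encode()).hexdigest()

    manifest_path = outdir / "manifest.json"
    previous = None
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
    runner = _Runner(outdir, previous, config_hash, force)

    sim_dir = outdir / "sim"
    state: dict = {}

    # --- simulate ---------------------------------------------------------
    if config.simulate:
        def _simulate():
            return write_simulation(
                simcfg, config.scenario, sim_dir,
                n_dmrs=config.n_dmrs, dmr_delta=config.dmr_delta,
                dmr_width=config.dmr_width,
                expression_offset=config.expression_offset,
                with_reads=config.reads_fastq is None and config.with_reads,
            )

        sim_outputs = [sim_dir / n for n in (
            "genome.fa", "genes.bed12", "cgis.bed", "shortrna.bed", "expression.tsv",
            "truth.tsv", "true_counts.tsv", "true_spike.tsv", "reads.fastq",
            "sites.tsv", "tags.tsv", "index_table.tsv", "standard_tags.tsv", "dmr_truth.tsv",
        )]
        runner.run("simulate", _simulate, sim_outputs)
        state["genome_path"] = sim_dir / "genome.fa"
        state["ann_dir"] = sim_dir
    else:
        if config.reads_fastq is None:
            raise ConfigurationError("simulate=false requires reads_fastq and input paths")
        if config.genome_fasta is None or config.annotations_dir is None:
            raise ConfigurationError("simulate=false requires genome_fasta and annotations_dir")
        state["genome_path"] = Path(config.genome_fasta)
        state["ann_dir"] = Path(config.annotations_dir)

    # --- digest -----------------------------------------------------------
    def _digest():
        genome = read_fasta(state["genome_path"])
        sites = find_ccgg_sites(genome)
        library = build_tag_library(genome, sites, simcfg.tag_length)
        std_path = Path(state["ann_dir"]) / "standard_tags.tsv"
        if std_path.exists():
            std = read_tsv(std_path)
            library.standard_tags = dict(zip(std["tag"], std["library"]))
        else:
            library.standard_tags = make_standard_tags(simcfg.tag_length, seed=simcfg.seed)
        write_sites(sites, outdir / "sites.tsv")
        write_tag_library(library, outdir / "tags.tsv", outdir / "ambiguous_tags.txt")
        state["sites"] = sites_to_frame(sites)
        state["library"] = library
        state["chrom_lengths"] = {name: len(seq) for name, seq in genome.items()}

    runner.run("digest", _digest, [outdir / "sites.tsv", outdir / "tags.tsv", outdir / "ambiguous_tags.txt"])
    if "sites" not in state:  # stage skipped: reload from disk
        genome = read_fasta(state["genome_path"])
        sites = find_ccgg_sites(genome)
        library = build_tag_library(genome, sites, simcfg.tag_length)
        std_path = Path(state["ann_dir"]) / "standard_tags.tsv"
        if std_path.exists():
            std = read_tsv(std_path)
            library.standard_tags = dict(zip(std["tag"], std["library"]))
        state["sites"] = sites_to_frame(sites)
        state["library"] = library
        state["chrom_lengths"] = {name: len(seq) for name, seq in genome.items()}

    # --- map (or adopt simulator count tables) ------------------------------
    reads_path = config.reads_fastq
    if reads_path is None and config.simulate and config.with_reads:
        reads_path = sim_dir / "reads.fastq"

    def _map():
        if reads_path is not None:
            index_table = read_tsv(Path(state["ann_dir"]) / "index_table.tsv") if config.reads_fastq is None \
                else read_tsv(config.index_table)
            counts, spike, report, unassigned = map_reads(
                read_fastq(reads_path), state["library"], index_table, config.mapping.max_mismatch
            )
            report["unassigned_total"] = unassigned
        else:
            counts = read_tsv(sim_dir / "true_counts.tsv")
            spike = read_tsv(sim_dir / "true_spike.tsv")
            report = pd.DataFrame(
                [{"sample": "*", "library": "*", "total": int(counts[["u", "m"]].to_numpy().sum()),
                  "mapped": int(counts[["u", "m"]].to_numpy().sum()),
                  "standard": int(spike["count"].sum()), "no_hit": 0, "ambiguous": 0}]
            )
        write_tsv(counts, outdir / "counts.tsv")
        write_tsv(spike, outdir / "spikein.tsv")
        write_tsv(report, outdir / "mapping_report.tsv")

    runner.run("map", _map, [outdir / "counts.tsv", outdir / "spikein.tsv", outdir / "mapping_report.tsv"])

    # --- quantify -----------------------------------------------------------
    def _quantify():
        counts = read_tsv(outdir / "counts.tsv")
        spike = read_tsv(outdir / "spikein.tsv")
        calls = normalize_and_call(
            counts, spike, config.quantify.min_depth, config.quantify.scale_constant,
            sites=state["sites"],
        )
        write_tsv(calls, outdir / "calls.tsv")
        write_tsv(chromosome_summary(calls, state["sites"]), outdir / "chromosome_summary.tsv")

    runner.run("quantify", _quantify, [outdir / "calls.tsv", outdir / "chromosome_summary.tsv"])

    # --- annotate -----------------------------------------------------------
    ann = load_annotations(state["ann_dir"])

    def _annotate():
        annot = annotate_sites(
            state["sites"], ann.genes, ann.cgis,
            config.annotate.tss_halfwidth, config.annotate.flank, config.annotate.shore_width,
        )
        write_tsv(annot, outdir / "annotation.tsv")
        calls = read_tsv(outdir / "calls.tsv")
        base = calls[calls["sample"] == simcfg.samples[0]]
        for axis in ("cgi_context", "gene_context"):
            write_tsv(stratum_means(base, annot, axis), outdir / f"stratum_means_{axis}.tsv")

    runner.run(
        "annotate",
        _annotate,
        [outdir / "annotation.tsv", outdir / "stratum_means_cgi_context.tsv",
         outdir / "stratum_means_gene_context.tsv"],
    )

    # --- differential --------------------------------------------------------
    def _diff():
        calls = read_tsv(outdir / "calls.tsv")
        by_sample = {s: g.reset_index(drop=True) for s, g in calls.groupby("sample")}
        units = pd.concat(
            [make_windows(state["chrom_lengths"], config.diff.window), make_cgi_units(ann.cgis)],
            ignore_index=True,
        )
        comparisons, dmr = compare_all_units(
            units, by_sample, baseline=simcfg.samples[0],
            delta_cutoff=config.diff.delta_cutoff, q_cutoff=config.diff.q_cutoff,
            min_sites=config.diff.min_sites, delta_only=config.diff.delta_only,
        )
        write_tsv(comparisons, outdir / "comparisons.tsv")
        write_tsv(dmr, outdir / "dmr.tsv")
        _, summary = site_level_consistency(
            by_sample, baseline=simcfg.samples[0],
            delta_cutoff=config.diff.delta_cutoff, strict_sign=config.diff.strict_sign,
        )
        (outdir / "site_consistency.json").write_text(json.dumps(summary, indent=2) + "\n")

    runner.run(
        "diff", _diff,
        [outdir / "comparisons.tsv", outdir / "dmr.tsv", outdir / "site_consistency.json"],
    )

    # --- profiles -------------------------------------------------------------
    def _profiles():
        calls = read_tsv(outdir / "calls.tsv")
        base = calls[calls["sample"] == simcfg.samples[0]].reset_index(drop=True)
        pc = config.profiles
        write_tsv(
            metagene_profile(base, ann.genes, pc.body_bins, pc.flank_bins, pc.ma_window),
            outdir / "metagene.tsv",
        )
        tert_profiles, contrast = expression_tertile_profiles(
            base, ann.genes, ann.expression, pc.body_bins, pc.flank_bins, pc.ma_window,
            config.annotate.tss_halfwidth,
        )
        for label, prof in tert_profiles.items():
            write_tsv(prof, outdir / f"metagene_{label}.tsv")
        write_tsv(contrast, outdir / "tertile_contrast.tsv")
        write_tsv(peak_overlap_summary(base, ann.peaks), outdir / "peak_overlap.tsv")
        write_tsv(
            shortrna_proximity_summary(base, ann.shortrna, pc.shortrna_flank),
            outdir / "shortrna_proximity.tsv",
        )

    runner.run(
        "profiles", _profiles,
        [outdir / "metagene.tsv", outdir / "tertile_contrast.tsv",
         outdir / "peak_overlap.tsv", outdir / "shortrna_proximity.tsv"]
        + [outdir / f"metagene_{t}.tsv" for t in ("low", "mid", "high")],
    )

    manifest = {
        "tool": "mscc",
        "version": __version__,
        "seed": simcfg.seed,
        "config": cfg_snapshot,
        "config_hash": config_hash,
        "stages": runner.stages,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def make_fixtures(preset: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write a self-contained fixture directory for one scenario preset."""
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    outdir = Path(outdir)
    if preset == "tiny":
        sim = SimulationConfig(
            seed=seed, n_chroms=1, chrom_length=60_000, cgi_count=4, gene_count=6,
            shortrna_count=2, repressive_peaks_per_chrom=1, mean_depth=40.0,
            seq_error_rate=0.0,
        )
        cfg = PipelineConfig(outdir=outdir, simulation=sim, scenario="null", with_reads=True)
    elif preset == "null_emt":
        cfg = PipelineConfig(outdir=outdir, simulation=SimulationConfig(seed=seed), scenario="null")
    elif preset == "planted_dmr":
        cfg = PipelineConfig(
            outdir=outdir, simulation=SimulationConfig(seed=seed), scenario="planted_dmr"
        )
    else:
        cfg = PipelineConfig(
            outdir=outdir, simulation=SimulationConfig(seed=seed), scenario="expression_coupled"
        )
    run_all(cfg)
    return outdir
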