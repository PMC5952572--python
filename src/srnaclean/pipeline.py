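"""End-to-end orchestration: configuration, logging and report bundles.

The pipeline embodies the recommended workflow for artefact-aware sRNA
sequencing of low-biomass samples: sequence extraction controls alongside
study samples, flag control-derived sequences as artefacts, normalise to a
spike-in for absolute levels, and filter exogenous candidates through the
multi-criteria cascade.  Every run writes its resolved configuration and a
log of parameters, library sizes and per-stage survivor counts, and is
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import attribution, contaminants, exogenous, quant, synthdata
from ._util import read_fasta, read_fastq, write_fasta, write_fastq
from .preprocess import (
    CountTable,
    LibraryMeta,
    TRUSEQ_SMALL_RNA_ADAPTER,
    build_count_table,
    preprocess_library,
)

logger = logging.getLogger("srnaclean")

MODES = ("simulate", "analyze", "screen", "qpcr", "titrate")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults equal the study values wherever one exists: 30-count retention,
    Q30/90% quality rule, 14-nt primer identity overlap, the 90%-absence /
    10-copy / 3-read / 7-of-28 cascade, the 100-cpm titration threshold and
    the 40,000 copies/uL spike-in.
    """

    mode: str
    outdir: str = "srnaclean_out"
    seed: int = 0

    # inputs (analyze / screen / qpcr / titrate)
    fastq: list[str] = field(default_factory=list)
    fastq_dir: str | None = None
    metadata: str | None = None
    host_fasta: str | None = None
    nonhost_fasta: str | None = None
    assay_panel: str | None = None
    curves_csv: str | None = None
    standards_csv: str | None = None
    cpm_table: str | None = None

    # shared parameters
    adapters: list[str] = field(default_factory=lambda: [TRUSEQ_SMALL_RNA_ADAPTER])
    q_min: int = 30
    p_min: float = 90.0
    min_len: int = 15
    trim_min_overlap: int = 10
    study_min_total: int = 30
    primer_min_overlap: int = 14
    max_mismatches: int = 2
    presence_frac: float = 0.5
    threshold_cpm: float = 100.0
    spikein_name: str = synthdata.SPIKE_IN_NAME
    spikein_sequence: str = synthdata.SPIKE_IN_SEQUENCE
    spikein_copies_per_uL: float = 40_000.0
    cascade: exogenous.CascadeParams = field(default_factory=exogenous.CascadeParams)

    # simulate parameters
    total_reads: int = 50_000
    ultraclean_factor: float = synthdata.DEFAULT_ULTRACLEAN_FACTOR
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config {path} is not a mapping")
        data = dict(data)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cascade = data.pop("cascade", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cascade:
            cfg.cascade = exogenous.CascadeParams(**cascade)
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)


def _setup_run(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    (outdir / "resolved_config.yaml").write_text(config.to_yaml())
    logger.info("mode=%s seed=%d outdir=%s", config.mode, config.seed, outdir)
    return outdir


def run(config: RunConfig) -> dict[str, Any]:
    """Execute one pipeline run; returns the report bundle as a dict of
    result objects, with all artefacts written under ``config.outdir``."""
    outdir = _setup_run(config)
    try:
        if config.mode == "simulate":
            return _run_simulate(config, outdir)
        if config.mode == "analyze":
            return _run_analyze(config, outdir)
        if config.mode == "screen":
            return _run_screen(config, outdir)
        if config.mode == "qpcr":
            return _run_qpcr(config, outdir)
        return _run_titrate(config, outdir)
    finally:
        for h in list(logger.handlers):
            if isinstance(h, logging.FileHandler):
                logger.removeHandler(h)
                h.close()


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _run_simulate(config: RunConfig, outdir: Path) -> dict[str, Any]:
    refs = synthdata.make_references(synthdata.ReferenceConfig(), config.seed)
    designs = synthdata.simulate_study(
        refs, config.seed, total_reads=config.total_reads,
        ultraclean_factor=config.ultraclean_factor, error_rate=config.error_rate,
    )
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    for design in designs:
        records = synthdata.simulate_library(design, refs)
        write_fastq(records, fastq_dir / f"{design.meta.library_id}.fastq")
    meta = synthdata.metadata_frame(designs)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_fasta(refs.host_genome.items(), outdir / "host.fasta")
    write_fasta(refs.nonhost_genomes.items(), outdir / "nonhost.fasta")
    write_fasta(
        list(refs.contaminant_panel.items()) + [refs.spike_in], outdir / "panels.fasta"
    )
    logger.info("simulated %d libraries", len(designs))
    return {"refs": refs, "designs": designs, "metadata": meta}


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[LibraryMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            LibraryMeta(
                library_id=str(row["library_id"]),
                type=str(row["type"]),
                column=str(row.get("column", "regular")),
                batch=str(row.get("batch", "1")),
                volume_uL=float(row.get("volume_uL", 0.0)),
                spikein_name=str(row["spikein_name"]) if row.get("spikein_name") else None,
                spikein_copies_per_uL=float(row.get("spikein_copies_per_uL", 0.0)),
            )
        )
    return metas


def build_table_from_fastq(
    metas: list[LibraryMeta], fastq_dir: str | Path, config: RunConfig, mode: str = "study"
) -> CountTable:
    per_library = []
    for meta in metas:
        path = Path(fastq_dir) / f"{meta.library_id}.fastq"
        reads = [(seq, qual) for _, seq, qual in read_fastq(path)]
        collapsed = preprocess_library(
            reads, config.adapters, config.trim_min_overlap, 1,
            config.min_len, config.q_min, config.p_min,
        )
        logger.info("library %s: %d reads, %d unique after preprocessing",
                    meta.library_id, len(reads), len(collapsed))
        per_library.append((meta, collapsed))
    return build_count_table(per_library, mode=mode, study_min_total=config.study_min_total)


def analyze_count_table(
    table: CountTable,
    config: RunConfig,
    host_genome: Mapping[str, str] | None = None,
    nonhost_genomes: Mapping[str, str] | None = None,
    nonhost_taxa: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, Any]:
    """Core contaminant-aware analysis of an assembled count table."""
    if not table.control_ids():
        raise ConfigError(
            "no control libraries in metadata: extraction controls should always "
            "be sequenced with the study samples"
        )
    if not table.plasma_ids():
        raise ConfigError("no plasma libraries in metadata")
    assays = contaminants.load_assays(config.assay_panel)
    assignment = contaminants.match_contaminants(
        table.counts.index, assays, config.primer_min_overlap
    )
    spike = contaminants.SpikeInSpec(
        config.spikein_name, config.spikein_sequence, config.spikein_copies_per_uL
    )
    flagged = contaminants.flag_control_sequences(
        table, config.presence_frac, spike_sequences=[spike.sequence]
    )
    rpm = contaminants.assay_rpm(table, assays, config.primer_min_overlap)
    copies, unnormalisable = contaminants.spikein_normalize(table, spike)

    host_hits = None
    host_sequences = None
    if host_genome:
        host_hits = attribution.map_reads(
            table.counts.index, host_genome, config.max_mismatches
        )
        host_sequences, _ = attribution.attribute_host(list(table.counts.index), host_hits)

    best_hit_genus = None
    nonhost_results: dict[str, Any] = {}
    if nonhost_genomes:
        seqs = list(table.counts.index)
        if host_sequences is not None:
            seqs = [s for s in seqs if s not in set(host_sequences)]
        retained = attribution.decoy_filter(
            seqs, nonhost_genomes, config.seed, config.max_mismatches
        )
        nh_hits = attribution.map_reads(
            seqs, {g: nonhost_genomes[g] for g in retained}, config.max_mismatches
        )
        counts_map = {s: int(table.counts.loc[s].sum()) for s in seqs}
        loci = attribution.build_loci(nh_hits, counts_map)
        incidence: dict[str, list[str]] = {}
        for h in nh_hits:
            for l in loci:
                if (l.reference_id == h.reference_id and l.strand == h.strand
                        and l.start <= h.position < l.end):
                    incidence.setdefault(h.sequence, []).append(l.locus_id)
        incidence = {r: sorted(set(ls)) for r, ls in incidence.items()}
        corr = attribution.crossmap_correct(incidence, counts_map)
        for l in loci:
            l.corrected_count = corr.corrected.get(l.locus_id, 0.0)
        nonhost_results = {"retained_genomes": retained, "loci": loci, "crossmap": corr}
        if nonhost_taxa:
            genus_best = exogenous._best_hits(nh_hits)
            best_hit_genus = {
                s: nonhost_taxa[h.reference_id][1] for s, h in genus_best.items()
            }

    contaminant_set = set(assignment) | flagged
    report = exogenous.run_cascade(
        table, contaminant_set, config.cascade,
        host_sequences=host_sequences, best_hit_genus=best_hit_genus,
    )
    logger.info("cascade survivors: %s", report.survivor_counts)
    return {
        "table": table,
        "assignment": assignment,
        "flagged_control_sequences": flagged,
        "assay_rpm": rpm,
        "copies": copies,
        "libraries_without_spike": unnormalisable,
        "cascade": report,
        "host_sequences": host_sequences,
        **nonhost_results,
    }


def _run_analyze(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if not config.metadata or not (config.fastq_dir or config.fastq):
        raise ConfigError("analyze mode needs metadata and fastq_dir")
    metas = read_metadata(config.metadata)
    table = build_table_from_fastq(metas, config.fastq_dir, config)
    host = read_fasta(config.host_fasta) if config.host_fasta else None
    nonhost = read_fasta(config.nonhost_fasta) if config.nonhost_fasta else None
    results = analyze_count_table(table, config, host, nonhost)
    table.to_tsv(outdir / "count_table.tsv")
    results["assay_rpm"].to_csv(outdir / "assay_rpm.tsv", sep="\t")
    results["copies"].to_csv(outdir / "copies_per_uL.tsv", sep="\t")
    (outdir / "control_flagged_sequences.txt").write_text(
        "\n".join(sorted(results["flagged_control_sequences"])) + "\n"
    )
    report: exogenous.CascadeReport = results["cascade"]
    report.to_frame().to_csv(outdir / "cascade_report.tsv", sep="\t")
    (outdir / "cascade_summary.json").write_text(
        json.dumps(report.survivor_counts, indent=2)
    )
    (outdir / "candidates.txt").write_text("\n".join(report.candidates) + "\n")
    if "loci" in results:
        (outdir / "loci.bed").write_text(attribution.loci_to_bed(results["loci"]))
        (outdir / "retained_genomes.txt").write_text(
            "\n".join(results["retained_genomes"]) + "\n"
        )
    return results


# ---------------------------------------------------------------------------
# screen / qpcr / titrate
# ---------------------------------------------------------------------------

def _run_screen(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if not config.fastq:
        raise ConfigError("screen mode needs at least one FASTQ path")
    assays = contaminants.load_assays(config.assay_panel)
    cols = {}
    for path in config.fastq:
        rpm = contaminants.screen_dataset(path, assays, config.adapters, config.primer_min_overlap)
        cols[Path(path).name] = rpm
    rpm_table = pd.DataFrame(cols)
    rpm_table.rename_axis("assay").to_csv(outdir / "screen_rpm.tsv", sep="\t")
    logger.info("screened %d datasets", len(cols))
    return {"rpm": rpm_table}


def _run_qpcr(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if not config.curves_csv:
        raise ConfigError("qpcr mode needs curves_csv (cycle column + one column per reaction)")
    curves = pd.read_csv(config.curves_csv)
    if "cycle" not in curves.columns:
        raise ConfigError("curves_csv must have a 'cycle' column")
    cycles = curves["cycle"].to_numpy(dtype=float)
    reactions = [c for c in curves.columns if c != "cycle"]
    cps = {r: quant.call_cp(curves[r].to_numpy(dtype=float), cycles) for r in reactions}
    cp_table = pd.DataFrame(
        {
            "reaction": reactions,
            "cp": [cps[r].cp for r in reactions],
            "flagged": [cps[r].flagged for r in reactions],
            "reason": [cps[r].reason or "" for r in reactions],
        }
    ).set_index("reaction")
    results: dict[str, Any] = {"cp_table": cp_table}
    if config.standards_csv:
        standards = pd.read_csv(config.standards_csv).set_index("reaction")
        pairs = [
            (float(standards.loc[r, "copies"]), cps[r].cp)
            for r in standards.index
            if r in cps and not cps[r].flagged
        ]
        curve = quant.fit_standard_curve(pairs)
        unknowns = [r for r in reactions if r not in standards.index]
        cp_table["copies"] = [
            quant.quantify(cps[r], curve) if r in unknowns else float("nan")
            for r in reactions
        ]
        results["standard_curve"] = curve
        (outdir / "standard_curve.json").write_text(
            json.dumps(
                {"m": curve.m, "b": curve.b, "efficiency": curve.efficiency,
                 "r_squared": curve.r_squared},
                indent=2,
            )
        )
    cp_table.to_csv(outdir / "cp_table.tsv", sep="\t")
    return results


def _run_titrate(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if config.cpm_table:
        cpm = pd.read_csv(config.cpm_table, sep="\t")
    elif config.metadata and config.fastq_dir:
        metas = read_metadata(config.metadata)
        plasma = [m for m in metas if m.type == "plasma"]
        table = build_table_from_fastq(metas, config.fastq_dir, config)
        assays = contaminants.load_assays(config.assay_panel)
        rpm = contaminants.assay_rpm(table, assays, config.primer_min_overlap)
        rows = []
        for m in plasma:
            for assay in rpm.index:
                rows.append(
                    dict(contaminant=assay, volume_uL=m.volume_uL,
                         cpm=rpm.loc[assay, m.library_id],
                         library_size=int(table.library_sizes[m.library_id]))
                )
        cpm = pd.DataFrame(rows)
    else:
        raise ConfigError("titrate mode needs cpm_table or metadata + fastq_dir")
    fit = quant.safe_input_volume(cpm, config.threshold_cpm)
    (outdir / "titration_fit.json").write_text(fit.to_json())
    logger.info("overall safe volume: %.1f uL (fit), %.1f uL (tested)",
                fit.overall_safe_volume, fit.overall_safe_volume_tested)
    return {"fit": fit, "cpm": cpm}
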