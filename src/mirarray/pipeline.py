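"""Stage orchestration behind the command-line interface.

Each stage reads its inputs from, and writes its artifacts to, the
configured output directory. Every TSV artifact carries ``#`` metadata
header lines (package version, config hash, RNG seed) and stages never
mutate another stage's artifacts, so a rerun with the same configuration
reproduces every file byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cohorts import run_all_comparisons, venn_partition_by_tissue, venn_cells_frame
from .errors import InputError
from .expression import DesignTable, IntensityMatrix, lowess_normalize, subtract_background
from .io import read_fasta, read_tsv, write_fasta, write_tsv
from .orfs import Contig, annotate_contigs
from .duplex import default_energy_model, load_energy_model
from .simulate import simulate_all
from .targets import predict_targets, summarize_by_process

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "mirnas": "mirnas.fasta",
    "contigs": "contigs.fasta",
    "design": "design.tsv",
    "intensities": "intensities.tsv",
    "truth_orfs": "truth_orfs.tsv",
    "truth_sites": "truth_sites.tsv",
    "truth_de": "truth_de.tsv",
    "normalized": "normalized.tsv",
    "de_results": "de_results.tsv",
    "comparison_counts": "comparison_counts.tsv",
    "venn_cells": "venn_cells.tsv",
    "orfs": "orfs.tsv",
    "utrs": "utrs.fasta",
    "targets": "targets.tsv",
    "diagrams": "duplex_diagrams.txt",
    "process_summary": "process_summary.tsv",
    "report": "report.txt",
}

STAGE_OF = {  # artifact -> stage that produces it, for actionable errors
    "mirnas": "simulate", "contigs": "simulate", "design": "simulate",
    "intensities": "simulate", "normalized": "normalize", "de_results": "de",
    "comparison_counts": "sets", "venn_cells": "sets", "orfs": "annotate-utr",
    "utrs": "annotate-utr", "targets": "targets",
}


def _path(cfg: PipelineConfig, key: str) -> Path:
    return Path(cfg.out_dir) / ARTIFACTS[key]


def _require(cfg: PipelineConfig, key: str) -> Path:
    p = _path(cfg, key)
    if not p.exists():
        raise InputError(
            f"missing artifact {p.name}: run the {STAGE_OF[key]!r} stage first"
        )
    return p


def _metadata(cfg: PipelineConfig) -> dict:
    return {"mirarray_version": __version__, "config_hash": cfg.config_hash(),
            "rng_seed": str(cfg.seed)}


def stage_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim
    sim.rng_seed = cfg.seed
    mirnas, contigs, design, matrix, truth = simulate_all(sim)
    meta = _metadata(cfg)
    write_fasta(mirnas, _path(cfg, "mirnas"))
    write_fasta(contigs, _path(cfg, "contigs"))
    write_tsv(design, _path(cfg, "design"), meta)
    matrix.to_tsv(_path(cfg, "intensities"), meta)
    write_tsv(truth.orfs_frame(), _path(cfg, "truth_orfs"), meta)
    write_tsv(truth.sites_frame(), _path(cfg, "truth_sites"), meta)
    write_tsv(truth.de_frame(), _path(cfg, "truth_de"), meta)
    logger.info("simulate: %d miRNAs, %d contigs, %d samples, %d probes",
                len(mirnas), len(contigs), len(design), matrix.foreground.shape[0])


def stage_normalize(cfg: PipelineConfig) -> None:
    matrix = IntensityMatrix.from_tsv(_require(cfg, "intensities"))
    corrected = subtract_background(matrix)
    normalized = lowess_normalize(corrected, span=cfg.span)
    out = normalized.copy()
    out.insert(0, "mirna_name", matrix.probe_to_mirna.loc[normalized.index].values)
    out.index.name = "probe_id"
    write_tsv(out, _path(cfg, "normalized"), _metadata(cfg), index=True)
    logger.info("normalize: %d probes x %d samples", *normalized.shape)


def _load_normalized(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.Series]:
    df = read_tsv(_require(cfg, "normalized")).set_index("probe_id")
    probe_map = df["mirna_name"]
    return df.drop(columns=["mirna_name"]), probe_map


def stage_de(cfg: PipelineConfig) -> None:
    normalized, probe_map = _load_normalized(cfg)
    design = DesignTable(read_tsv(_require(cfg, "design")))
    counts, results = run_all_comparisons(normalized, design, probe_map,
                                          alpha=cfg.alpha_mirna)
    write_tsv(results, _path(cfg, "de_results"), _metadata(cfg))
    logger.info("de: %d comparisons, %d result rows", len(counts), len(results))


def stage_sets(cfg: PipelineConfig) -> None:
    results = read_tsv(_require(cfg, "de_results"))
    counts = (results.groupby("comparison", sort=False)["significant"].sum()
              .astype(int).reset_index(name="n_de"))
    partitions = venn_partition_by_tissue(results)
    meta = _metadata(cfg)
    write_tsv(counts, _path(cfg, "comparison_counts"), meta)
    write_tsv(venn_cells_frame(partitions), _path(cfg, "venn_cells"), meta)
    logger.info("sets: %d comparisons, %d venn cells", len(counts),
                sum(len(c) for c in partitions.values()))


def stage_annotate_utr(cfg: PipelineConfig) -> None:
    contigs = [Contig(name, seq) for name, seq in read_fasta(_require(cfg, "contigs"))]
    orfs, utrs = annotate_contigs(contigs, cfg.min_orf_codons, cfg.min_utr_len)
    orf_frame = pd.DataFrame(
        [{"contig_id": o.contig_id, "start": o.start, "end": o.end,
          "frame": o.frame, "complete": o.complete} for o in orfs])
    write_tsv(orf_frame, _path(cfg, "orfs"), _metadata(cfg))
    write_fasta([(f"{u.contig_id}|{u.utr_start}", u.sequence) for u in utrs],
                _path(cfg, "utrs"))
    logger.info("annotate-utr: %d ORFs, %d UTRs from %d contigs",
                len(orfs), len(utrs), len(contigs))


def _load_utrs(cfg: PipelineConfig):
    from .orfs import UtrRecord
    records = []
    for header, seq in read_fasta(_require(cfg, "utrs")):
        contig_id, utr_start = header.rsplit("|", 1)
        records.append(UtrRecord(contig_id, int(utr_start), seq))
    return records


def stage_targets(cfg: PipelineConfig) -> None:
    mirnas = read_fasta(_require(cfg, "mirnas"))
    utrs = _load_utrs(cfg)
    de_path = _path(cfg, "de_results")
    if de_path.exists():
        results = read_tsv(de_path)
        de_names = set(results.loc[results["significant"], "mirna_name"])
        mirnas = [(n, s) for n, s in mirnas if n in de_names]
        logger.info("targets: restricting scan to %d differentially expressed miRNAs",
                    len(mirnas))
    else:
        logger.warning("targets: no DE results found; scanning every miRNA")
    model = (load_energy_model(cfg.energy_model_path) if cfg.energy_model_path
             else default_energy_model())
    table, duplexes = predict_targets(mirnas, utrs, model=model,
                                      mfe_threshold=cfg.mfe_threshold,
                                      flank=cfg.site_flank, seed_mode=cfg.seed_mode)
    meta = _metadata(cfg)
    write_tsv(table, _path(cfg, "targets"), meta)
    blocks = []
    for row, dup in zip(table.itertuples(index=False), duplexes):
        blocks.append(f"> {row.mirna_name} :: {row.contig_id} utr_pos={row.utr_pos} "
                      f"mfe={dup.mfe:.2f} kcal/mol\n{dup.diagram}\n")
    _path(cfg, "diagrams").write_text("\n".join(blocks))
    if cfg.annotation_path:
        annotation = read_tsv(cfg.annotation_path)
        summary = summarize_by_process(table, annotation)
        write_tsv(summary, _path(cfg, "process_summary"), meta)
    logger.info("targets: %d retained sites for %d miRNAs",
                len(table), table["mirna_name"].nunique() if len(table) else 0)


def stage_report(cfg: PipelineConfig) -> None:
    counts = read_tsv(_require(cfg, "comparison_counts"))
    venn = read_tsv(_require(cfg, "venn_cells"))
    lines = ["mirarray pipeline report",
             f"config hash: {cfg.config_hash()}  seed: {cfg.seed}", "",
             "Differentially expressed miRNAs per comparison",
             "(all cohort pairs are reported uniformly for both tissues):"]
    for row in counts.itertuples(index=False):
        n = row.n_de if pd.notna(row.n_de) else "n/a"
        lines.append(f"  {row.comparison:<32} {n}")
    lines += ["", "Venn cells (DE vs S-, R+/S+ shared duplicates excluded):"]
    for row in venn.itertuples(index=False):
        lines.append(f"  {row.tissue:<9} {row.direction:<5} {row.cell:<10} {row.size}")
    selected = int(venn["size"].sum())
    lines += ["", f"miRNAs entering the Venn partition (both tissues, both directions): "
                  f"{selected}"]
    targets_path = _path(cfg, "targets")
    if targets_path.exists():
        targets = read_tsv(targets_path)
        lines += ["", "Confirmed targets per miRNA (MFE-filtered seed sites):"]
        if len(targets):
            per = targets.groupby("mirna_name")["contig_id"].nunique()
            for name, n in per.items():
                lines.append(f"  {name:<24} {n}")
            lines += ["", f"total: {per.sum()} target contigs for {len(per)} miRNAs"]
        else:
            lines.append("  (none)")
    _path(cfg, "report").write_text("\n".join(lines) + "\n")
    logger.info("report: written")


STAGES = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "de": stage_de,
    "sets": stage_sets,
    "annotate-utr": stage_annotate_utr,
    "targets": stage_targets,
    "report": stage_report,
}
STAGE_ORDER = ["simulate", "normalize", "de", "sets", "annotate-utr", "targets", "report"]


def run(subcommand: str, cfg: PipelineConfig) -> None:
    """Run one stage, or every stage in dependency order for ``all``."""
    cfg.validate()
    if subcommand == "all":
        for name in STAGE_ORDER:
            STAGES[name](cfg)
    elif subcommand in STAGES:
        STAGES[subcommand](cfg)
    else:
        raise InputError(f"unknown stage {subcommand!r}")
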