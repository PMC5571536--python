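"""End-to-end orchestration: data -> contrasts -> overlap -> SOM -> enrichment.

A single :class:`PipelineConfig` (usually loaded from YAML) describes the
whole run: either a synthetic-data configuration or paths to an FPKM
matrix and metadata, the list of pairwise contrasts with their roles
(disease = control -> diabetic, treatment = diabetic -> treated), the SOM
settings, and the enrichment inputs.  One master seed drives every stage;
per-stage seeds are derived from it by hashing the stage name, so a fixed
config and seed reproduce every output byte for byte.

Outputs are written to the configured directory as TSV tables (one per
stage) plus ``summary.json`` holding the run's headline numbers: DEG
counts per contrast, shared counts and reversal percentages per tissue,
SOM cluster memberships and the top enrichment per gene list.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import io as rio
from .differential import DEGSet, call_degs, extract_deg_set
from .enrichment import fisher_enrichment
from .exceptions import ConfigurationError
from .overlap import classify_overlap, cross_tissue_compare, stratify_disease_degs
from .simulate import (
    DEFAULT_MODULE_CONDITIONS,
    SimulationConfig,
    generate_dataset,
    generate_gene_sets,
)
from .som import (
    assign_modules,
    compute_umatrix,
    merge_by_correlation,
    preprocess_for_som,
    train_som,
)

__all__ = ["ContrastSpec", "PipelineConfig", "run_pipeline", "default_config"]

logger = logging.getLogger("reversom")

SEED_MODULUS = 2**31


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master_seed) + zlib.crc32(stage.encode("utf-8"))) % SEED_MODULUS


@dataclass(frozen=True)
class ContrastSpec:
    tissue: str
    ref: str
    alt: str
    role: str  # "disease" or "treatment"

    def __post_init__(self) -> None:
        if self.role not in ("disease", "treatment"):
            raise ConfigurationError(f"contrast role {self.role!r} must be disease or treatment")

    @property
    def slug(self) -> str:
        clean = lambda s: s.replace("/", "").replace("+", "p").replace(" ", "_")
        return f"{clean(self.tissue)}_{clean(self.ref)}_vs_{clean(self.alt)}"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    output_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    metadata_path: str | None = None
    gene_sets_path: str | None = None  # GMT; None with simulation => planted sets
    contrasts: tuple[ContrastSpec, ...] = ()
    alpha: float = 0.05
    som_width: int = 7
    som_height: int = 7
    som_epochs: int = 50
    som_min_fpkm: float = 3.0
    som_conditions: tuple[tuple[str, str], ...] = DEFAULT_MODULE_CONDITIONS
    merge_correlation: float = 0.8
    n_decoy_sets: int = 20
    decoy_set_size: int = 50

    def validate(self) -> None:
        if self.simulation is None and (self.matrix_path is None or self.metadata_path is None):
            raise ConfigurationError(
                "config needs either a simulation block or matrix/metadata paths"
            )
        if self.simulation is None and self.gene_sets_path is None:
            raise ConfigurationError("non-simulated runs need a gene_sets_path (GMT)")
        if not self.contrasts:
            raise ConfigurationError("no contrasts configured")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1)")
        by_tissue: dict[str, set[str]] = {}
        for c in self.contrasts:
            by_tissue.setdefault(c.tissue, set()).add(c.role)
        for tissue, roles in by_tissue.items():
            if "treatment" in roles and "disease" not in roles:
                raise ConfigurationError(
                    f"tissue {tissue!r} has a treatment contrast but no disease "
                    "contrast; the reversal classification needs both"
                )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim_block = data.pop("simulation", None)
        simulation = None
        if sim_block is not None:
            sim_block = dict(sim_block)
            if "module_conditions" in sim_block:
                sim_block["module_conditions"] = tuple(
                    tuple(c) for c in sim_block["module_conditions"]
                )
            for key in ("tissues", "groups"):
                if key in sim_block:
                    sim_block[key] = tuple(sim_block[key])
            simulation = SimulationConfig(**sim_block)
        contrasts = tuple(
            ContrastSpec(**c) if isinstance(c, Mapping) else c
            for c in data.pop("contrasts", ())
        )
        if "som_conditions" in data:
            data["som_conditions"] = tuple(tuple(c) for c in data["som_conditions"])
        return cls(simulation=simulation, contrasts=contrasts, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(output_dir: str, seed: int = 0, **sim_overrides) -> PipelineConfig:
    """The standard simulated study: 4 tissues x 4 groups, n = 6 per cell.

    Disease (db/+ -> db/db) and treatment (db/db -> db/db PIO) contrasts
    for every tissue, the six-condition SOM over nerve and glomeruli, and
    planted gene sets with random decoys.
    """
    sim = SimulationConfig(seed=stage_seed(seed, "simulate"), **sim_overrides)
    contrasts = []
    for tissue in sim.tissues:
        contrasts.append(ContrastSpec(tissue, "db/+", "db/db", "disease"))
        contrasts.append(ContrastSpec(tissue, "db/db", "db/db PIO", "treatment"))
    return PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        simulation=sim,
        contrasts=tuple(contrasts),
    )


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the JSON summary."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    summary: dict[str, Any] = {"seed": int(config.seed)}
    t0 = time.perf_counter()

    # --- stage: data
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        matrix, truth = generate_dataset(sim)
        rio.write_expression_matrix(matrix, outdir / "matrix.tsv", outdir / "metadata.tsv")
        rio.write_table(truth.to_frame(), outdir / "truth.tsv")
        if config.gene_sets_path is not None:
            gene_sets = rio.read_gene_sets(config.gene_sets_path)
        else:
            gene_sets = generate_gene_sets(
                truth,
                n_decoy_sets=config.n_decoy_sets,
                set_size=config.decoy_set_size,
                seed=stage_seed(config.seed, "gene_sets"),
            )
            rio.write_gene_sets(gene_sets, outdir / "sets.gmt")
        logger.info("simulated matrix: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    else:
        matrix = rio.read_expression_matrix(config.matrix_path, config.metadata_path)
        gene_sets = rio.read_gene_sets(config.gene_sets_path)
        logger.info("loaded matrix: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    summary["n_genes"] = matrix.n_genes
    summary["n_samples"] = matrix.n_samples

    # --- stage: contrasts
    deg_sets: dict[tuple[str, str], DEGSet] = {}
    contrast_rows = {}
    for spec in config.contrasts:
        result = call_degs(matrix, spec.tissue, spec.ref, spec.alt, alpha=config.alpha)
        rio.write_table(result.to_frame(), outdir / f"contrast_{spec.slug}.tsv")
        deg = extract_deg_set(result)
        deg_sets[(spec.tissue, spec.role)] = deg
        contrast_rows[result.contrast_name] = {
            "role": spec.role,
            "n_significant": result.n_significant,
            "n_up": sum(1 for s in deg.members.values() if s > 0),
            "n_down": sum(1 for s in deg.members.values() if s < 0),
        }
        logger.info("contrast %s: %d DEGs", result.contrast_name, result.n_significant)
    summary["contrasts"] = contrast_rows

    # --- stage: overlap classification per tissue
    strata = {}
    classifications = {}
    class_summaries = {}
    for tissue in sorted({c.tissue for c in config.contrasts}):
        if (tissue, "disease") not in deg_sets or (tissue, "treatment") not in deg_sets:
            continue
        disease = deg_sets[(tissue, "disease")]
        treatment = deg_sets[(tissue, "treatment")]
        cls = classify_overlap(disease, treatment)
        classifications[tissue] = cls
        class_summaries[tissue] = cls.summary()
        rows = []
        for category, genes in (
            ("reversed", cls.reversed),
            ("exacerbated", cls.exacerbated),
            ("disease_only", cls.disease_only),
            ("treatment_only", cls.treatment_only),
        ):
            for gene in sorted(genes):
                rows.append(
                    {
                        "gene": gene,
                        "category": category,
                        "sign_disease": disease.members.get(gene, 0),
                        "sign_treatment": treatment.members.get(gene, 0),
                    }
                )
        rio.write_table(pd.DataFrame(rows), outdir / f"classification_{tissue}.tsv")
        strata[tissue] = stratify_disease_degs(cls, disease)
        logger.info(
            "tissue %s: %d shared, %.1f%% reversed",
            tissue, len(cls.shared), cls.pct_reversed,
        )
    summary["classification"] = class_summaries

    # --- stage: cross-tissue stratum overlaps (each stratum vs. other tissues' Reversed)
    overlap_rows = []
    tissues_with_strata = sorted(strata)
    for t_a in tissues_with_strata:
        for t_b in tissues_with_strata:
            if t_a == t_b:
                continue
            for stratum in ("db/db only", "Exacerbated", "Reversed"):
                report = cross_tissue_compare(strata[t_a][stratum], strata[t_b]["Reversed"])
                overlap_rows.append(report.summary())
    if overlap_rows:
        rio.write_table(pd.DataFrame(overlap_rows), outdir / "cross_tissue_overlaps.tsv")
    summary["cross_tissue"] = {
        f"{r['label_a']} & {r['label_b']}": r["n_shared"] for r in overlap_rows
    }

    # --- stage: SOM
    som_input = preprocess_for_som(matrix, config.som_conditions, min_fpkm=config.som_min_fpkm)
    grid = train_som(
        som_input,
        width=config.som_width,
        height=config.som_height,
        epochs=config.som_epochs,
        seed=stage_seed(config.seed, "som"),
    )
    assignment = assign_modules(grid, som_input)
    codebook = grid.codebook_frame().reset_index()
    rio.write_table(codebook, outdir / "som_codebook.tsv")
    rio.write_table(assignment.to_frame(), outdir / "som_assignment.tsv")
    rio.write_table(compute_umatrix(grid), outdir / "som_umatrix.tsv")
    clusters = merge_by_correlation(grid, assignment, threshold=config.merge_correlation)
    cluster_rows = [
        {
            "cluster": c.label,
            "modules": "+".join(str(m) for m in sorted(c.module_ids)),
            "n_genes": len(c.member_genes),
        }
        for c in clusters
    ]
    rio.write_table(pd.DataFrame(cluster_rows), outdir / "som_clusters.tsv")
    summary["som"] = {
        "n_genes_mapped": som_input.n_genes,
        "quantization_error": assignment.quantization_error,
        "n_clusters": len(clusters),
        "clusters": {c.label: sorted(c.module_ids) for c in clusters},
    }
    logger.info(
        "SOM: %d genes on %dx%d lattice, QE %.4f, %d clusters",
        som_input.n_genes, config.som_width, config.som_height,
        assignment.quantization_error, len(clusters),
    )

    # --- stage: enrichment (strata against all matrix genes; clusters against mapped genes)
    enrichment_frames = []
    top_hits = {}
    matrix_universe = frozenset(matrix.gene_ids)
    for tissue in tissues_with_strata:
        for stratum_sets in (strata[tissue],):
            for stratum in ("db/db only", "Exacerbated", "Reversed"):
                labeled = stratum_sets[stratum]
                if not labeled.genes:
                    continue
                table = fisher_enrichment(labeled.genes, matrix_universe, gene_sets, alpha=config.alpha)
                table.insert(0, "list", labeled.label)
                enrichment_frames.append(table)
    som_universe = frozenset(som_input.gene_ids)
    for cluster in clusters:
        if not cluster.member_genes:
            continue
        table = fisher_enrichment(cluster.member_genes, som_universe, gene_sets, alpha=config.alpha)
        table.insert(0, "list", cluster.label)
        enrichment_frames.append(table)
    if enrichment_frames:
        combined = pd.concat(enrichment_frames, ignore_index=True)
        rio.write_table(combined, outdir / "enrichment.tsv")
        for label, block in combined.groupby("list"):
            best = block.sort_values(["q_value", "set"]).iloc[0]
            top_hits[str(label)] = {
                "set": str(best["set"]),
                "q_value": float(best["q_value"]),
                "significant": bool(best["significant"]),
            }
    summary["enrichment_top"] = top_hits

    if truth is not None:
        summary["planted"] = {
            tissue: {
                "pct_reversed": truth.planted_pct_reversed(tissue),
                **{f"n_{k}": v for k, v in truth.role_counts(tissue).items()},
            }
            for tissue in sorted({c.tissue for c in config.contrasts})
        }

    with open(outdir / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return summary
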