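"""End-to-end orchestration from a single YAML-able config.

Stages run in order: load or generate inputs -> low-count filter -> TMM +
log-CPM -> batch adjustment -> differential expression -> co-expression
modules -> hierarchical enrichment (single-list, pooled, combined) ->
regulator sets -> layering -> mediation -> randomization test. A manifest
(config hash, seeds, stage row counts, output file hashes) is written so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .coexpression import (compute_eigengenes, detect_modules, module_deg_enrichment,
                           module_ses_association, pick_soft_power)
from .enrichment import combined_enrichment, ora, pool_to_parents
from .expression import (batch_adjust, differential_expression, filter_low_counts,
                         log_cpm, tmm_factors)
from .mediation import layer_mediation_summary, mediate_genome
from .randomization import randomization_test
from .synth import (CohortConfig, CountsConfig, GroundTruth, NetworkConfig,
                    OntologyConfig, generate_cohort, generate_counts,
                    generate_networks, generate_ontology)
from .upstream import assign_layers, count_pathway_contributions, derive_sets

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "sex", "race", "age", "pregnancy", "anti_inflammatory_use",
    "recent_symptoms", "recent_illness", "fasting_hours", "plate",
]
DEFAULT_MEDIATORS = [
    "bmi", "waist", "perceived_stress", "smoking", "alcohol",
    "financial_stress", "insurance",
]


@dataclass
class SyntheticBlock:
    n_samples: int = 500
    n_genes: int = 2000
    n_tfs: int = 100
    n_roots: int = 3
    branching: int = 3


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; exactly one input mode.

    Either ``inputs`` (paths to counts/metadata/grn/ppi/gmt/hierarchy files)
    or ``synthetic`` (generation block) must be present.
    """

    outdir: str = "results/run"
    seed: int = 0
    inputs: dict | None = None
    synthetic: SyntheticBlock | None = None
    alpha: float = 0.05
    tf_threshold: float = 0.4
    ppi_threshold: float = 0.7
    layer_bins: tuple[int, int, int] = (10, 5, 1)
    exposure: str = "ses"
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    mediators: list | None = field(default_factory=lambda: list(DEFAULT_MEDIATORS))
    mediation_covariates: list = field(default_factory=lambda: ["sex", "race", "age"])
    min_cpm: float = 1.0
    min_sample_frac: float = 0.2
    min_module_size: int = 20
    cut_height: float = 0.99
    n_sim: int = 1000
    n_replicates: int = 1000
    max_mediation_genes: int = 200

    def validate(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of inputs / synthetic must be set")
        for name, v in (("alpha", self.alpha), ("tf_threshold", self.tf_threshold),
                        ("ppi_threshold", self.ppi_threshold)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of range: {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticBlock(**raw["synthetic"])
        if "layer_bins" in raw:
            raw["layer_bins"] = tuple(raw["layer_bins"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_or_generate(cfg: PipelineConfig):
    if cfg.inputs is not None:
        counts = sio.read_counts(cfg.inputs["counts"])
        samples = sio.read_metadata(cfg.inputs["metadata"])
        grn = sio.read_edge_list(cfg.inputs["grn"], kind="grn")
        ppi = sio.read_edge_list(cfg.inputs["ppi"], kind="ppi")
        annotations = sio.read_gmt(cfg.inputs["gmt"])
        hierarchy = sio.read_hierarchy(cfg.inputs["hierarchy"])
        tf_universe = set(grn["tf"])
        truth = None
    else:
        sb = cfg.synthetic
        samples = generate_cohort(sb.n_samples, CohortConfig(), seed=cfg.seed)
        counts, truth = generate_counts(
            samples, CountsConfig(n_genes=sb.n_genes), seed=cfg.seed
        )
        grn, ppi, tf_universe, truth = generate_networks(
            sb.n_tfs, sb.n_genes, truth, NetworkConfig(), seed=cfg.seed
        )
        pool = list(counts.index) + sorted(set(ppi["protein_a"]) | set(ppi["protein_b"]))
        hierarchy, annotations, _ = generate_ontology(
            sb.n_roots, sb.branching, pool, OntologyConfig(), seed=cfg.seed, truth=truth
        )
        tf_universe = set(tf_universe)
    return counts, samples, grn, ppi, annotations, hierarchy, tf_universe, truth


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and write artifacts + manifest under cfg.outdir."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    counts, samples, grn, ppi, annotations, hierarchy, tf_universe, truth = (
        _load_or_generate(cfg)
    )
    manifest["stages"]["load"] = {
        "n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1]),
        "n_grn_edges": int(len(grn)), "n_ppi_edges": int(len(ppi)),
        "n_pathways": len(annotations),
    }

    filtered = filter_low_counts(counts, cfg.min_cpm, cfg.min_sample_frac)
    factors = tmm_factors(filtered)
    norm = log_cpm(filtered, factors)
    if "batch" in samples.columns and samples["batch"].nunique() > 1:
        cov_design = samples[[c for c in cfg.covariates if c in samples.columns]]
        norm = batch_adjust(norm, samples["batch"], cov_design)
    manifest["stages"]["normalize"] = {
        "n_genes_kept": int(filtered.shape[0]),
        "factors_range": [float(factors.min()), float(factors.max())],
    }

    de = differential_expression(norm, samples, cfg.exposure, cfg.covariates, cfg.alpha)
    de.to_csv(out / "de_results.tsv", sep="\t", index_label="gene")
    factors.to_frame().to_csv(out / "norm_factors.tsv", sep="\t", index_label="sample_id")
    n_up = int((de["direction"] == "up").sum())
    n_down = int((de["direction"] == "down").sum())
    manifest["stages"]["de"] = {"n_de": n_up + n_down, "n_up": n_up, "n_down": n_down}

    power = pick_soft_power(norm)
    modules = detect_modules(norm, power, cfg.min_module_size, cfg.cut_height)
    modules = compute_eigengenes(norm, modules)
    assoc = module_ses_association(modules, samples, cfg.exposure, cfg.covariates)
    enr_up = module_deg_enrichment(modules, de, "up")
    enr_down = module_deg_enrichment(modules, de, "down")
    modules.assignment.to_frame().to_csv(out / "modules.tsv", sep="\t", index_label="gene")
    modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample_id")
    assoc.to_csv(out / "module_ses.tsv", sep="\t")
    pd.concat([enr_up, enr_down]).to_csv(out / "module_deg_enrichment.tsv", sep="\t")
    manifest["stages"]["modules"] = {
        "soft_power": float(power), "n_modules": len(modules.labels),
    }

    universe = set(de.index)
    set_a_up = set(de.index[de["direction"] == "up"])
    set_a_down = set(de.index[de["direction"] == "down"])
    query = set_a_up | set_a_down
    enrichment_res = (
        ora(query, universe, annotations, cfg.alpha)
        if query
        else pd.DataFrame()
    )
    sets = derive_sets(de, grn, ppi, tf_universe, cfg.tf_threshold,
                       cfg.ppi_threshold, cfg.alpha)
    if len(enrichment_res):
        pooled = pool_to_parents(enrichment_res, hierarchy)
        lists = {
            "up": set_a_up, "down": set_a_down,
            "tf": sets.set_b | sets.set_d, "ppi": sets.set_c,
        }
        lists = {k: v for k, v in lists.items() if v}
        comb_universe = universe | set().union(*lists.values())
        combined = combined_enrichment(lists, comb_universe, annotations, cfg.alpha)
        enrichment_res.to_csv(out / "enrichment.tsv", sep="\t")
        pooled.to_csv(out / "enrichment_pooled.tsv", sep="\t")
        combined.drop(columns=["per_list_contribution"]).to_csv(
            out / "enrichment_combined.tsv", sep="\t"
        )
    else:
        pooled = combined = pd.DataFrame()
        logger.warning("no DE genes; enrichment skipped")
    manifest["stages"]["enrichment"] = {
        "n_tested": int(len(enrichment_res)),
        "n_significant": int(enrichment_res["significant"].sum()) if len(enrichment_res) else 0,
    }

    sets.to_frame().to_csv(out / "regulator_sets.tsv", sep="\t", index=False)
    manifest["stages"]["upstream"] = {
        k: len(getattr(sets, k)) for k in ("set_a", "set_b", "set_c", "set_d")
    }

    if len(combined):
        counts_series = count_pathway_contributions(combined, sets.all_molecules())
        layers = assign_layers(counts_series[counts_series > 0], cfg.layer_bins)
    else:
        layers = pd.DataFrame(columns=["pathway_count", "layer"])
    layers.to_csv(out / "layers.tsv", sep="\t", index_label="molecule")
    manifest["stages"]["layers"] = {
        "n_molecules": int(len(layers)),
        "per_layer": {int(k): int(v) for k, v in layers["layer"].value_counts().items()}
        if len(layers) else {},
    }

    if cfg.mediators:
        med_genes = [g for g in layers.index if g in set(de.index)]
        if cfg.max_mediation_genes and len(med_genes) > cfg.max_mediation_genes:
            med_genes = med_genes[: cfg.max_mediation_genes]
        if med_genes:
            med = mediate_genome(
                norm, samples, cfg.mediators, med_genes,
                cfg.exposure, cfg.mediation_covariates, cfg.n_sim, cfg.seed,
            )
            med.to_csv(out / "mediation.tsv", sep="\t", index=False)
            summary = layer_mediation_summary(med, layers, cfg.alpha)
            summary.to_csv(out / "mediation_layers.tsv", sep="\t", index=False)
            manifest["stages"]["mediation"] = {
                "n_pairs": int(len(med)), "n_cells": int(len(summary)),
            }
        else:
            logger.warning("no layered DE genes to mediate; stage skipped")
            manifest["stages"]["mediation"] = {"skipped": True}
    else:
        logger.info("no mediators configured; mediation stage skipped")
        manifest["stages"]["mediation"] = {"skipped": True}

    rand = randomization_test(
        sets, universe, grn, ppi, tf_universe, cfg.tf_threshold,
        cfg.ppi_threshold, cfg.n_replicates, cfg.seed,
    )
    rand.per_gene.to_csv(out / "randomization_per_gene.tsv", sep="\t", index=False)
    rand.per_set.to_csv(out / "randomization_per_set.tsv", sep="\t", index=False)
    (out / "randomization_per_set.json").write_text(
        rand.per_set.to_json(orient="records", indent=2)
    )
    manifest["stages"]["randomization"] = {
        "n_replicates": rand.n_replicates,
        "combined_p": dict(zip(rand.per_set["set"], rand.per_set["combined_p"])),
    }

    manifest["outputs"] = {
        f.name: _file_hash(f) for f in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
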