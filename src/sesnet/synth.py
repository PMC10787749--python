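"""Synthetic cohorts, counts, networks and ontologies with planted truth.

The generators emulate the statistical structure of a population
transcriptomic study of socioeconomic status (SES): a continuous SES
composite (a sum of standardized indicators, simulated directly as a
standardized score), behavioral/physiological mediators correlated with SES
through a Gaussian copula, negative-binomially distributed mRNA-seq counts in
which SES effects are routed partly through a BMI mediation path, a scored
transcription-factor regulatory network and protein-protein interaction
network with planted true regulators, and a three-level pathway hierarchy.

All generators are pure functions of (config, seed); the planted ground
truth is returned so downstream recovery can be quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "CohortConfig",
    "NetworkConfig",
    "OntologyConfig",
    "CountsConfig",
    "generate_cohort",
    "generate_networks",
    "generate_ontology",
    "generate_counts",
]


@dataclass
class GroundTruth:
    """Planted generative truth for recovery checks.

    effect_sizes are signed log2-fold-changes per SD of SES; mediated_fraction
    is the fraction of each gene's SES effect routed through the BMI path
    (closed-form ACME/total); module_assignment labels the planted
    co-expression blocks; pathway_truth maps pathway ids to annotated genes.
    """

    de_genes: set = field(default_factory=set)
    effect_sizes: dict = field(default_factory=dict)
    true_tfs: set = field(default_factory=set)
    mediated_fraction: dict = field(default_factory=dict)
    module_assignment: dict = field(default_factory=dict)
    pathway_truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        for g in self.de_genes:
            if self.effect_sizes.get(g, 0.0) == 0.0:
                raise ValueError(f"DE gene {g} has zero effect size")
        for g, f in self.mediated_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mediated_fraction out of [0,1] for {g}")


@dataclass
class CohortConfig:
    """Population parameters for the simulated cohort.

    ses_bmi_corr is the Gaussian-copula correlation between the SES composite
    and BMI (negative: lower SES, higher BMI, as observed in US cohorts).
    Mediator-SES correlations are mild by design; BMI carries the planted
    mediation path in the count model.
    """

    ses_bmi_corr: float = -0.3
    ses_stress_corr: float = -0.2
    ses_smoking_corr: float = -0.25
    ses_alcohol_corr: float = 0.05
    ses_finstress_corr: float = -0.3
    ses_insurance_corr: float = 0.25
    bmi_mean: float = 28.0
    bmi_sd: float = 6.0
    waist_bmi_corr: float = 0.85
    age_low: float = 33.0
    age_high: float = 43.0
    n_plates: int = 4
    n_batches: int = 2
    smoking_rate: float = 0.25
    pregnancy_rate: float = 0.02
    anti_inflammatory_rate: float = 0.15
    recent_symptoms_rate: float = 0.2
    recent_illness_rate: float = 0.15
    financial_stress_rate: float = 0.2
    insurance_rate: float = 0.85


ALCOHOL_LEVELS = ["0", "1-2", "3-5", ">5"]


def _latent_binary(rng, latent: np.ndarray, rate: float) -> np.ndarray:
    """Threshold a standard-normal latent at the (1-rate) quantile."""
    from scipy.stats import norm

    return (latent > norm.ppf(1 - rate)).astype(int)


def generate_cohort(
    n_samples: int, config: CohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate the per-sample table: SES composite, covariates, mediators, batch.

    SES is a standardized continuous composite (mean ~0, SD ~1). Mediators are
    tied to SES through latent Gaussian correlations, then thresholded
    (binary/ordinal) or rescaled (BMI, waist, stress).
    """
    if n_samples < 0:
        raise ValueError("n_samples must be nonnegative")
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))

    cols = {}
    ses = rng.standard_normal(n_samples)
    cols["ses"] = ses

    def corr_latent(rho: float) -> np.ndarray:
        return rho * ses + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n_samples)

    bmi_lat = corr_latent(config.ses_bmi_corr)
    cols["bmi"] = config.bmi_mean + config.bmi_sd * bmi_lat
    waist_lat = config.waist_bmi_corr * bmi_lat + np.sqrt(
        1 - config.waist_bmi_corr**2
    ) * rng.standard_normal(n_samples)
    cols["waist"] = 95.0 + 13.0 * waist_lat
    cols["perceived_stress"] = np.clip(
        np.round(20 + 6 * corr_latent(config.ses_stress_corr)), 0, 40
    )
    cols["smoking"] = _latent_binary(
        rng, corr_latent(config.ses_smoking_corr), config.smoking_rate
    )
    alc_lat = corr_latent(config.ses_alcohol_corr)
    qs = np.array([-0.2, 0.7, 1.4])  # population cutpoints for the 4 categories
    alc_idx = np.searchsorted(qs, alc_lat)
    alcohol = pd.Categorical.from_codes(
        alc_idx, categories=ALCOHOL_LEVELS, ordered=True
    )
    cols["alcohol"] = alcohol
    cols["financial_stress"] = _latent_binary(
        rng, corr_latent(config.ses_finstress_corr), config.financial_stress_rate
    )
    cols["insurance"] = _latent_binary(
        rng, corr_latent(config.ses_insurance_corr), config.insurance_rate
    )

    sex = rng.integers(0, 2, n_samples)
    cols["sex"] = pd.Categorical.from_codes(sex, categories=["female", "male"])
    cols["race"] = pd.Categorical.from_codes(
        rng.choice(4, n_samples, p=[0.55, 0.2, 0.15, 0.1]),
        categories=["white", "black", "hispanic", "other"],
    )
    cols["age"] = rng.uniform(config.age_low, config.age_high, n_samples)
    preg = _latent_binary(rng, rng.standard_normal(n_samples), config.pregnancy_rate)
    cols["pregnancy"] = np.where(sex == 0, preg, 0)
    cols["anti_inflammatory_use"] = _latent_binary(
        rng, rng.standard_normal(n_samples), config.anti_inflammatory_rate
    )
    cols["recent_symptoms"] = _latent_binary(
        rng, rng.standard_normal(n_samples), config.recent_symptoms_rate
    )
    cols["recent_illness"] = _latent_binary(
        rng, rng.standard_normal(n_samples), config.recent_illness_rate
    )
    cols["fasting_hours"] = np.clip(rng.normal(9, 3, n_samples), 0, 24)
    cols["plate"] = pd.Categorical.from_codes(
        rng.integers(0, config.n_plates, n_samples),
        categories=[f"plate{i+1}" for i in range(config.n_plates)],
    )
    cols["batch"] = pd.Categorical.from_codes(
        rng.integers(0, config.n_batches, n_samples),
        categories=[f"batch{i+1}" for i in range(config.n_batches)],
    )

    idx = pd.Index([f"S{i+1:05d}" for i in range(n_samples)], name="sample_id")
    table = pd.DataFrame(cols, index=idx)
    # enforce column order / schema even when empty
    order = [
        "ses", "sex", "race", "age", "pregnancy", "anti_inflammatory_use",
        "recent_symptoms", "recent_illness", "fasting_hours", "plate", "batch",
        "bmi", "waist", "perceived_stress", "smoking", "alcohol",
        "financial_stress", "insurance",
    ]
    return table[order]


@dataclass
class NetworkConfig:
    """Planted-regulator wiring of the GRN and PPI edge lists.

    True TFs are wired to DE targets with confidence ``true_conf`` (> 0.4, so
    a medium-confidence filter keeps them). Decoy GRN edges onto DE targets
    are drawn below the 0.4 filter so the planted regulator set is exactly
    recoverable; decoys onto non-DE targets span [0, 1]. PPI true-neighbor
    edges sit above the 0.7 high-confidence cut; decoy PPI scores span
    [0, ppi_decoy_score_max].
    """

    n_true_tfs: int = 5
    targets_per_tf: int = 10
    true_conf: float = 0.9
    decoy_edges_per_tf: int = 20
    decoy_conf_max_on_de: float = 0.4
    decoy_conf_max_off_de: float = 1.0
    ppi_neighbors_per_tf: int = 8
    ppi_true_score: float = 0.9
    ppi_decoy_edges: int = 3000
    ppi_decoy_score_max: float = 1.0


def generate_networks(
    n_tfs: int,
    n_genes: int,
    truth: GroundTruth,
    config: NetworkConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], GroundTruth]:
    """Scored TF->gene regulatory edges and undirected PPI edges.

    Transcription factors are genes themselves (the last ``n_tfs`` ids of the
    G0001.. namespace), so a TF can be differentially expressed; PPI partner
    proteins P0001.. extend the namespace. Returns (grn, ppi, tf_universe,
    truth) with truth.true_tfs filled in.
    """
    config = config or NetworkConfig()
    if n_tfs < 1 or n_genes < 1:
        raise ValueError("need at least one TF and one gene")
    if n_tfs > n_genes:
        raise ValueError("n_tfs cannot exceed n_genes (TFs are genes)")
    if config.n_true_tfs > n_tfs:
        raise ValueError("more true TFs requested than TFs available")
    if config.n_true_tfs > 0 and not truth.de_genes:
        raise ValueError("true regulators requested but truth has no DE genes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E]))

    genes = [f"G{i+1:04d}" for i in range(n_genes)]
    tfs = genes[n_genes - n_tfs :]
    de = sorted(g for g in truth.de_genes if g not in set(tfs[: config.n_true_tfs]))
    true_tfs = tfs[: config.n_true_tfs]

    rows: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()

    def add(tf: str, tgt: str, conf: float) -> None:
        if tf != tgt and (tf, tgt) not in seen:
            seen.add((tf, tgt))
            rows.append((tf, tgt, float(conf)))

    for tf in true_tfs:
        k = min(config.targets_per_tf, len(de))
        for tgt in rng.choice(de, size=k, replace=False):
            add(tf, tgt, config.true_conf)
    de_set = set(de)
    for tf in tfs:
        for tgt in rng.choice(genes, size=min(config.decoy_edges_per_tf, n_genes), replace=False):
            if (tf, tgt) in seen:
                continue
            hi = (
                config.decoy_conf_max_on_de
                if tgt in de_set
                else config.decoy_conf_max_off_de
            )
            add(tf, tgt, rng.uniform(0, hi))
    grn = pd.DataFrame(rows, columns=["tf", "target", "confidence"])

    prows: list[tuple[str, str, float]] = []
    pseen: set[frozenset] = set()

    def padd(a: str, b: str, score: float) -> None:
        key = frozenset((a, b))
        if a != b and key not in pseen:
            pseen.add(key)
            prows.append((a, b, float(score)))

    n_partners = max(config.ppi_neighbors_per_tf * n_tfs, 1)
    partners = [f"P{i+1:04d}" for i in range(n_partners)]
    for tf in true_tfs:
        for p in rng.choice(partners, size=config.ppi_neighbors_per_tf, replace=False):
            padd(tf, p, config.ppi_true_score)
    pool = tfs + partners
    for _ in range(config.ppi_decoy_edges):
        a, b = rng.choice(pool, size=2, replace=False)
        padd(a, b, rng.uniform(0, config.ppi_decoy_score_max))
    ppi = pd.DataFrame(prows, columns=["protein_a", "protein_b", "score"])

    truth = replace(truth, true_tfs=set(true_tfs))
    return grn, ppi, list(tfs), truth


@dataclass
class OntologyConfig:
    min_genes: int = 10
    max_genes: int = 40
    superset: bool = True
    de_enriched_leaves: int = 6  # leaves whose annotation is stacked with DE genes
    de_gene_frac: float = 0.6


def generate_ontology(
    n_roots: int,
    branching: int,
    genes: list[str],
    config: OntologyConfig | None = None,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, dict[str, set], pd.DataFrame]:
    """A pathway hierarchy of depth exactly 3 below the roots, with annotations.

    Returns (hierarchy, annotations, nodes): hierarchy is a (parent, child)
    edge table; annotations map every node to its gene set (parents are
    supersets of their children's union when config.superset); nodes lists
    ids and display names. A few leaves are enriched for planted DE genes so
    over-representation analysis has signal to find.
    """
    config = config or OntologyConfig()
    if branching < 1:
        raise ValueError("branching must be >= 1")
    if len(genes) < config.min_genes:
        raise ValueError("fewer genes than min_genes per leaf")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x07]))

    edges: list[tuple[str, str]] = []
    level_nodes: dict[int, list[str]] = {0: [f"R{i+1:02d}" for i in range(n_roots)]}
    counter = 0
    for level in (1, 2, 3):
        level_nodes[level] = []
        for parent in level_nodes[level - 1]:
            for _ in range(branching):
                counter += 1
                child = f"PW{counter:04d}"
                edges.append((parent, child))
                level_nodes[level].append(child)

    leaves = level_nodes[3]
    annotations: dict[str, set] = {}
    de = sorted(truth.de_genes) if truth is not None else []
    n_enriched = min(config.de_enriched_leaves, len(leaves)) if de else 0
    for i, leaf in enumerate(leaves):
        size = int(rng.integers(config.min_genes, config.max_genes + 1))
        size = min(size, len(genes))
        if i < n_enriched:
            n_de = min(int(round(size * config.de_gene_frac)), len(de))
            chosen = set(rng.choice(de, size=n_de, replace=False))
            rest = [g for g in genes if g not in chosen]
            chosen |= set(rng.choice(rest, size=size - n_de, replace=False))
        else:
            chosen = set(rng.choice(genes, size=size, replace=False))
        annotations[leaf] = chosen
    for level in (2, 1, 0):
        for node in level_nodes[level]:
            kids = [c for p, c in edges if p == node]
            union: set = set()
            for k in kids:
                union |= annotations.get(k, set())
            annotations[node] = set(union) if config.superset else set(union)

    hierarchy = pd.DataFrame(edges, columns=["parent", "child"])
    all_nodes = [n for lvl in sorted(level_nodes) for n in level_nodes[lvl]]
    nodes = pd.DataFrame(
        {"pathway": all_nodes, "name": [f"Pathway {n}" for n in all_nodes]}
    )
    if truth is not None:
        truth.pathway_truth = {k: set(v) for k, v in annotations.items()}
    return hierarchy, annotations, nodes


@dataclass
class CountsConfig:
    """Negative-binomial count model with planted SES and module structure.

    Per gene g and sample i the log2 mean is
        baseline_g + effect_g * [(1-f_g) * ses_i + f_g * bmi_path_i]
        + module factor + batch and covariate offsets + log2 library factor,
    where f_g is the planted mediated fraction and bmi_path is standardized
    BMI divided by the SES-BMI copula correlation, so the linear-mediation
    closed form ACME/total equals f_g exactly.
    """

    n_genes: int = 2000
    de_frac: float = 0.05
    effect_low: float = 0.3
    effect_high: float = 1.0
    mediated_fraction: float = 0.5
    mediated_gene_frac: float = 0.5  # fraction of DE genes given the BMI path
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.1
    dispersion_sd: float = 0.05
    lib_log2_sd: float = 0.25
    n_modules: int = 5
    module_size: int = 100
    module_factor_sd: float = 0.4
    batch_shift: float = 0.2
    sex_shift: float = 0.1
    lib_factors: tuple | None = None  # explicit per-sample depth multipliers


def generate_counts(
    samples: pd.DataFrame,
    config: CountsConfig | None = None,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial gene-by-sample counts with planted structure.

    If ``truth`` already carries de_genes/effect_sizes (e.g. wired to a GRN),
    those are respected; otherwise DE genes, effects, mediated fractions and
    module labels are planted here and returned in the GroundTruth.
    """
    config = config or CountsConfig()
    if config.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA]))
    n = len(samples)
    genes = [f"G{i+1:04d}" for i in range(config.n_genes)]

    if truth is None or not truth.de_genes:
        truth = truth or GroundTruth()
        n_de = int(round(config.n_genes * config.de_frac))
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        mags = rng.uniform(config.effect_low, config.effect_high, n_de)
        truth.de_genes = {genes[i] for i in de_idx}
        truth.effect_sizes = {
            genes[i]: float(signs[k] * mags[k]) for k, i in enumerate(de_idx)
        }
        n_med = int(round(n_de * config.mediated_gene_frac))
        med_genes = [genes[i] for i in de_idx[:n_med]]
        truth.mediated_fraction = {g: config.mediated_fraction for g in med_genes}
    if not truth.module_assignment:
        labels = {}
        gi = 0
        for m in range(1, config.n_modules + 1):
            for _ in range(config.module_size):
                if gi >= config.n_genes:
                    break
                labels[genes[gi]] = m
                gi += 1
        truth.module_assignment = labels
    truth.validate()

    effect = np.array([truth.effect_sizes.get(g, 0.0) for g in genes])
    medfrac = np.array([truth.mediated_fraction.get(g, 0.0) for g in genes])

    ses = samples["ses"].to_numpy(dtype=float) if n else np.empty(0)
    rho = CohortConfig().ses_bmi_corr
    if "bmi" in samples and n:
        bmi = samples["bmi"].to_numpy(dtype=float)
        bmi_std = (bmi - bmi.mean()) / (bmi.std() if bmi.std() > 0 else 1.0)
        bmi_path = bmi_std / rho if rho != 0 else np.zeros(n)
    else:
        bmi_path = np.zeros(n)
    if np.any(medfrac > 0) and rho == 0:
        raise ValueError("mediated fractions planted but SES-BMI correlation is zero")

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    disp = np.clip(
        rng.normal(config.dispersion, config.dispersion_sd, config.n_genes), 1e-3, None
    )
    if config.lib_factors is not None:
        lib_factor = np.asarray(config.lib_factors, dtype=float)
        if lib_factor.shape != (n,):
            raise ValueError("lib_factors must have one entry per sample")
    else:
        lib_factor = 2.0 ** rng.normal(0.0, config.lib_log2_sd, n)

    signal = np.outer(effect * (1 - medfrac), ses) + np.outer(effect * medfrac, bmi_path)

    module_ids = sorted(set(truth.module_assignment.values()))
    mod_latent = {m: rng.standard_normal(n) for m in module_ids}
    mod_load = np.zeros((config.n_genes, n))
    for gi, g in enumerate(genes):
        m = truth.module_assignment.get(g)
        if m is not None:
            mod_load[gi] = config.module_factor_sd * mod_latent[m]

    offsets = np.zeros(n)
    if n and "batch" in samples:
        codes = pd.Categorical(samples["batch"]).codes
        offsets = offsets + config.batch_shift * (codes - codes.mean())
    if n and "sex" in samples:
        codes = pd.Categorical(samples["sex"]).codes
        offsets = offsets + config.sex_shift * (codes - codes.mean())

    log2_mu = baseline[:, None] + signal + mod_load + offsets[None, :]
    mu = (2.0**log2_mu) * lib_factor[None, :]
    size = 1.0 / disp
    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p) if n else np.zeros(
        (config.n_genes, 0), dtype=int
    )
    mat = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples.index)
    return mat, truth
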