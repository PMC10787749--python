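"""Generate the synthetic study inputs and write them to disk.

Produces the full input bundle for the downstream analyses: a 500-person
cohort with a standardized SES composite and correlated mediators, 2000-gene
negative-binomial counts with planted SES effects (half of them routed
through BMI), a scored TF regulatory network with 5 planted true regulators,
a protein-interaction edge list, and a 3-level pathway hierarchy.

Writes: results/inputs/{counts.tsv, counts.mtx, metadata.tsv, grn.tsv,
ppi.tsv, pathways.gmt, hierarchy.tsv, truth.json}
"""

import json
from pathlib import Path

from sesnet import io as sio
from sesnet.synth import (CohortConfig, CountsConfig, NetworkConfig,
                          OntologyConfig, generate_cohort, generate_counts,
                          generate_networks, generate_ontology)

SEED = 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    samples = generate_cohort(500, CohortConfig(), seed=SEED)
    counts, truth = generate_counts(samples, CountsConfig(n_genes=2000), seed=SEED)
    grn, ppi, tfs, truth = generate_networks(100, 2000, truth, NetworkConfig(), seed=SEED)
    pool = list(counts.index) + sorted(set(ppi["protein_a"]) | set(ppi["protein_b"]))
    hierarchy, annotations, _ = generate_ontology(
        3, 3, pool, OntologyConfig(), seed=SEED, truth=truth
    )

    sio.write_counts(counts, OUT / "counts.tsv")
    sio.write_counts_mtx(counts, OUT / "counts")
    sio.write_metadata(samples, OUT / "metadata.tsv")
    sio.write_edge_list(grn, OUT / "grn.tsv")
    sio.write_edge_list(ppi, OUT / "ppi.tsv")
    sio.write_gmt(annotations, OUT / "pathways.gmt")
    sio.write_hierarchy(hierarchy, OUT / "hierarchy.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "de_genes": sorted(truth.de_genes),
        "effect_sizes": dict(sorted(truth.effect_sizes.items())),
        "true_tfs": sorted(truth.true_tfs),
        "mediated_fraction": dict(sorted(truth.mediated_fraction.items())),
        "module_assignment": dict(sorted(truth.module_assignment.items())),
        "tf_universe": sorted(tfs),
    }, indent=2))

    print(f"cohort: {samples.shape[0]} samples, SES mean {samples['ses'].mean():+.3f}")
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples")
    print(f"planted: {len(truth.de_genes)} DE genes "
          f"({sum(1 for v in truth.effect_sizes.values() if v > 0)} up), "
          f"{len(truth.true_tfs)} true TFs, "
          f"{len(truth.mediated_fraction)} BMI-mediated genes")
    print(f"networks: {len(grn)} GRN edges, {len(ppi)} PPI edges; "
          f"ontology: {len(annotations)} pathways")


if __name__ == "__main__":
    main()
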