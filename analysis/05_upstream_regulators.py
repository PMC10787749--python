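"""Upstream regulator sets and relevance layers.

Builds the four regulator sets from the DE results and the scored networks
(A: SES-DEGs; B: DE transcription factors with medium-confidence GRN edges;
C: high-confidence PPI neighbors of Set B; D: TFs with medium-confidence
edges onto Set A), runs the combined multi-list enrichment, counts each
molecule's contributions to significantly enriched pathways, and assigns
the four relevance layers (>10 pathways innermost, exactly 1 outermost).

Writes: results/upstream/{regulator_sets.tsv, enrichment_combined.tsv,
layers.tsv}
"""

import json
from pathlib import Path

from sesnet import io as sio
from sesnet.enrichment import combined_enrichment
from sesnet.expression import (batch_adjust, differential_expression,
                               filter_low_counts, log_cpm, tmm_factors)
from sesnet.pipeline import DEFAULT_COVARIATES
from sesnet.upstream import (assign_layers, count_pathway_contributions,
                             derive_sets)

IN = Path("results/inputs")
OUT = Path("results/upstream")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = sio.read_counts(IN / "counts.tsv")
    samples = sio.read_metadata(IN / "metadata.tsv")
    grn = sio.read_edge_list(IN / "grn.tsv", kind="grn")
    ppi = sio.read_edge_list(IN / "ppi.tsv", kind="ppi")
    annotations = sio.read_gmt(IN / "pathways.gmt")
    truth = json.loads((IN / "truth.json").read_text())

    filtered = filter_low_counts(counts)
    norm = log_cpm(filtered, tmm_factors(filtered))
    norm = batch_adjust(norm, samples["batch"], samples[DEFAULT_COVARIATES])
    de = differential_expression(norm, samples, "ses", DEFAULT_COVARIATES)

    sets = derive_sets(de, grn, ppi, set(truth["tf_universe"]))
    sets.to_frame().to_csv(OUT / "regulator_sets.tsv", sep="\t", index=False)

    lists = {
        "up": set(de.index[de["direction"] == "up"]),
        "down": set(de.index[de["direction"] == "down"]),
        "tf": sets.set_b | sets.set_d,
        "ppi": sets.set_c,
    }
    lists = {k: v for k, v in lists.items() if v}
    universe = set(de.index) | set().union(*lists.values())
    combined = combined_enrichment(lists, universe, annotations)
    combined.drop(columns=["per_list_contribution"]).to_csv(
        OUT / "enrichment_combined.tsv", sep="\t"
    )

    pathway_counts = count_pathway_contributions(combined, sets.all_molecules())
    layers = assign_layers(pathway_counts[pathway_counts > 0])
    layers.to_csv(OUT / "layers.tsv", sep="\t", index_label="molecule")

    print(f"Set A (SES-DEGs): {len(sets.set_a)}; Set B (DE TFs): "
          f"{len(sets.set_b)}; Set C (PPI neighbors): {len(sets.set_c)}; "
          f"Set D (modulating TFs): {len(sets.set_d)}")
    overlap_bd = sets.set_b & sets.set_d
    print(f"Set B/D overlap: {len(overlap_bd)}")
    print(f"planted true TFs found in Set D: "
          f"{len(sets.set_d & set(truth['true_tfs']))}/{len(truth['true_tfs'])}")
    for layer in (1, 2, 3, 4):
        n = int((layers["layer"] == layer).sum())
        print(f"layer {layer}: {n} molecules")


if __name__ == "__main__":
    main()
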