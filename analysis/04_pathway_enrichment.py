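"""Hierarchical pathway enrichment of the SES-DEGs.

Runs one-sided hypergeometric over-representation of the SES-DEGs against
the 3-level pathway ontology, pools child results onto ancestors (a parent
is as significant as its most significant child), and reports Cramér's V
effect sizes.

Writes: results/enrichment/{enrichment.tsv, enrichment_pooled.tsv}
"""

from pathlib import Path

import pandas as pd

from sesnet import io as sio
from sesnet.enrichment import ora, pool_to_parents
from sesnet.expression import (batch_adjust, differential_expression,
                               filter_low_counts, log_cpm, tmm_factors)
from sesnet.pipeline import DEFAULT_COVARIATES

IN = Path("results/inputs")
OUT = Path("results/enrichment")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = sio.read_counts(IN / "counts.tsv")
    samples = sio.read_metadata(IN / "metadata.tsv")
    annotations = sio.read_gmt(IN / "pathways.gmt")
    hierarchy = sio.read_hierarchy(IN / "hierarchy.tsv")

    filtered = filter_low_counts(counts)
    norm = log_cpm(filtered, tmm_factors(filtered))
    norm = batch_adjust(norm, samples["batch"], samples[DEFAULT_COVARIATES])
    de = differential_expression(norm, samples, "ses", DEFAULT_COVARIATES)

    universe = set(de.index)
    query = set(de.index[de["direction"] != "ns"])
    res = ora(query, universe, annotations)
    pooled = pool_to_parents(res, hierarchy)

    res.to_csv(OUT / "enrichment.tsv", sep="\t")
    pooled.to_csv(OUT / "enrichment_pooled.tsv", sep="\t")

    sig = res[res["significant"]]
    print(f"{len(query)} SES-DEGs tested against {len(res)} annotated "
          f"pathways; {len(sig)} significant at FDR<0.05")
    top = sig.nsmallest(5, "p_value")
    for pw, row in top.iterrows():
        print(f"  {pw}: overlap {row['overlap']}/{row['pathway_size']}, "
              f"q {row['q_value']:.2g}, Cramer's V {row['cramers_v']:.2f}")
    n_anc = (pooled["n_pooled"] > 1).sum()
    print(f"pooling onto ancestors gave {len(pooled)} nodes "
          f"({n_anc} pooled from more than one child)")


if __name__ == "__main__":
    main()
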