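"""Whole-genome co-expression modules and their relation to SES.

Re-derives the normalized matrix, picks a soft-thresholding power by
scale-free fit, clusters topological-overlap dissimilarity, summarizes each
module by its eigengene, tests eigengene-SES association with the same
covariate-adjusted model as the per-gene analysis, and tests each module
for over-representation of up-/down-regulated SES-DEGs (one-sided Fisher).

Writes: results/modules/{modules.tsv, eigengenes.tsv, module_ses.tsv,
module_deg_enrichment.tsv}
"""

from pathlib import Path

import pandas as pd

from sesnet import io as sio
from sesnet.coexpression import (compute_eigengenes, detect_modules,
                                 module_deg_enrichment, module_ses_association,
                                 pick_soft_power)
from sesnet.expression import (batch_adjust, differential_expression,
                               filter_low_counts, log_cpm, tmm_factors)
from sesnet.pipeline import DEFAULT_COVARIATES

IN = Path("results/inputs")
OUT = Path("results/modules")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = sio.read_counts(IN / "counts.tsv")
    samples = sio.read_metadata(IN / "metadata.tsv")
    filtered = filter_low_counts(counts)
    norm = log_cpm(filtered, tmm_factors(filtered))
    norm = batch_adjust(norm, samples["batch"], samples[DEFAULT_COVARIATES])
    de = differential_expression(norm, samples, "ses", DEFAULT_COVARIATES)

    power = pick_soft_power(norm)
    modules = compute_eigengenes(norm, detect_modules(norm, power))
    assoc = module_ses_association(modules, samples, "ses", DEFAULT_COVARIATES)
    enr = pd.concat([
        module_deg_enrichment(modules, de, "up"),
        module_deg_enrichment(modules, de, "down"),
    ])

    modules.assignment.to_frame().to_csv(OUT / "modules.tsv", sep="\t",
                                         index_label="gene")
    modules.eigengenes.to_csv(OUT / "eigengenes.tsv", sep="\t",
                              index_label="sample_id")
    assoc.to_csv(OUT / "module_ses.tsv", sep="\t")
    enr.to_csv(OUT / "module_deg_enrichment.tsv", sep="\t")

    sizes = modules.assignment.value_counts().drop(0, errors="ignore")
    print(f"soft power {power}; {len(modules.labels)} modules, "
          f"sizes {sizes.sort_index().to_dict()}")
    sig = assoc[assoc["q_value"] < 0.05]
    print(f"modules with significant eigengene-SES association: "
          f"{list(sig.index)}")
    sig_enr = enr[enr["q_value"] < 0.05]
    for (mod, row) in sig_enr.iterrows():
        print(f"module {mod} enriched for SES-{row['direction']}regulated "
              f"genes (OR {row['odds_ratio']:.1f}, q {row['q_value']:.2g})")


if __name__ == "__main__":
    main()
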