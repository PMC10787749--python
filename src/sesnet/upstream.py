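"""Regulator sets A-D from DE results plus scored GRN/PPI networks, and
relevance layering by enriched-pathway contribution counts.

Set A: differentially expressed genes. Set B: DE transcription factors that
appear as sources of at least one medium-confidence edge in the tissue GRN.
Set C: high-confidence PPI neighbors of Set B. Set D: transcription factors
with a medium-confidence regulatory edge onto a Set A gene. Score filters
are strict inequalities (confidence > 0.4 for the GRN, score > 0.7 for the
PPI by default). Each recruited molecule carries the DE direction tag(s) of
the gene(s) that recruited it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorSets",
    "derive_sets",
    "NetworkIndex",
    "count_pathway_contributions",
    "assign_layers",
]


@dataclass
class RegulatorSets:
    set_a: set = field(default_factory=set)
    set_b: set = field(default_factory=set)
    set_c: set = field(default_factory=set)
    set_d: set = field(default_factory=set)
    direction_tag: dict = field(default_factory=dict)  # molecule -> set of tags

    def all_molecules(self) -> set:
        return self.set_a | self.set_b | self.set_c | self.set_d

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("set_a", "set_b", "set_c", "set_d"):
            for mol in sorted(getattr(self, name)):
                tags = ",".join(sorted(self.direction_tag.get(mol, set())))
                rows.append((mol, name[-1].upper(), tags))
        return pd.DataFrame(rows, columns=["molecule", "set", "direction_tag"])


@dataclass
class NetworkIndex:
    """Threshold-filtered adjacency indexes reused across many derivations.

    Precomputing these makes the randomization test (thousands of repeated
    set derivations over the same networks) cheap set algebra.
    """

    target_to_tfs: dict  # gene -> set of TFs with edge conf > tf_threshold
    tf_sources: set  # TFs with >= 1 above-threshold outgoing edge
    tf_neighbors: dict  # TF -> set of PPI partners with score > ppi_threshold
    tf_universe: set

    @classmethod
    def build(
        cls,
        grn: pd.DataFrame,
        ppi: pd.DataFrame,
        tf_universe,
        tf_threshold: float = 0.4,
        ppi_threshold: float = 0.7,
    ) -> "NetworkIndex":
        if not (0 <= tf_threshold <= 1 and 0 <= ppi_threshold <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        target_to_tfs: dict = {}
        tf_sources: set = set()
        strong = grn[grn["confidence"] > tf_threshold]
        for tf, tgt in strong[["tf", "target"]].itertuples(index=False, name=None):
            target_to_tfs.setdefault(tgt, set()).add(tf)
            tf_sources.add(tf)
        tf_neighbors: dict = {}
        strong_ppi = ppi[ppi["score"] > ppi_threshold]
        for a, b in strong_ppi[["protein_a", "protein_b"]].itertuples(index=False, name=None):
            tf_neighbors.setdefault(a, set()).add(b)
            tf_neighbors.setdefault(b, set()).add(a)
        return cls(
            target_to_tfs=target_to_tfs,
            tf_sources=tf_sources,
            tf_neighbors=tf_neighbors,
            tf_universe=set(tf_universe),
        )

    def derive(self, set_a: set, tags: dict | None = None) -> RegulatorSets:
        """Sets B/C/D for a given Set A (tags: gene -> direction tag set)."""
        tags = tags or {}
        out_tags: dict = {g: set(tags.get(g, set())) for g in set_a}

        def tag(mol, source_gene):
            out_tags.setdefault(mol, set()).update(tags.get(source_gene, set()))

        set_d: set = set()
        for g in set_a:
            for tf in self.target_to_tfs.get(g, ()):
                set_d.add(tf)
                tag(tf, g)
        set_b = {g for g in set_a if g in self.tf_universe and g in self.tf_sources}
        set_c: set = set()
        for b in set_b:
            for nb in self.tf_neighbors.get(b, ()):
                set_c.add(nb)
                tag(nb, b)
        return RegulatorSets(
            set_a=set(set_a), set_b=set_b, set_c=set_c, set_d=set_d,
            direction_tag=out_tags,
        )


def derive_sets(
    de: pd.DataFrame,
    grn: pd.DataFrame,
    ppi: pd.DataFrame,
    tf_universe,
    tf_threshold: float = 0.4,
    ppi_threshold: float = 0.7,
    alpha: float = 0.05,
) -> RegulatorSets:
    """Regulator sets A-D from a DE table and scored edge lists.

    Edges naming ids outside the DE gene universe union the declared TF/PPI
    namespaces are kept (networks legitimately extend past the measured
    genes); strict > comparisons are applied at both score thresholds.
    """
    known = set(de.index)
    unknown = ~grn["target"].isin(known)
    if unknown.any():
        logger.warning(
            "skipping %d GRN edge(s) with targets outside the measured gene universe",
            int(unknown.sum()),
        )
        grn = grn[~unknown]
    idx = NetworkIndex.build(grn, ppi, tf_universe, tf_threshold, ppi_threshold)
    sig = de[de["q_value"] < alpha]
    set_a = set(sig.index)
    tags = {g: {d} for g, d in sig["direction"].items() if d in ("up", "down")}
    return idx.derive(set_a, tags)


def count_pathway_contributions(
    enrichment: pd.DataFrame, molecules: set, significant_only: bool = True
) -> pd.Series:
    """Number of (significantly) enriched pathways each molecule contributes to.

    ``enrichment`` must carry a ``contributing_genes`` column (e.g. pooled
    output); molecules contributing to no pathway get count 0 (they are
    excluded later by assign_layers).
    """
    use = enrichment
    if significant_only and "q_value" in enrichment.columns:
        use = enrichment[enrichment["q_value"] < 0.05]
    counts = dict.fromkeys(molecules, 0)
    for genes in use["contributing_genes"]:
        for g in set(genes):
            if g in counts:
                counts[g] += 1
    return pd.Series(counts, name="pathway_count").sort_index()


def assign_layers(
    counts: pd.Series, bin_edges: tuple[int, int, int] = (10, 5, 1)
) -> pd.DataFrame:
    """Relevance layers from pathway-contribution counts.

    Defaults: layer 1 (innermost) for counts > 10, layer 2 for 6-10, layer 3
    for 2-5, layer 4 (outermost) for exactly 1. Molecules with zero counts
    must be excluded before calling.
    """
    hi, mid, lo = bin_edges
    counts = counts[counts > 0]
    if (counts <= 0).any():
        raise ValueError("pathway counts must be >= 1")
    def layer(c: int) -> int:
        if c > hi:
            return 1
        if c > mid:
            return 2
        if c > lo:
            return 3
        return 4
    out = pd.DataFrame(
        {"pathway_count": counts.astype(int), "layer": counts.map(layer).astype(int)}
    )
    out.index.name = "molecule"
    return out
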