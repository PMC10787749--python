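"""Weighted co-expression modules, eigengenes, and their SES association.

The workflow follows the standard weighted gene co-expression recipe:
unsigned adjacency |cor|^power, topological-overlap dissimilarity,
average-linkage hierarchical clustering with a static cut, module eigengenes
(first right singular vector of the gene-standardized module submatrix), a
linear eigengene-exposure model sharing the differential-expression design,
and a one-sided Fisher exact test for module enrichment of exposure-DEGs.

Module labels are integers ordered by size (1 = largest); label 0 marks
unassigned genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import NormalizedMatrix, bh_fdr, differential_expression

__all__ = [
    "ModuleSet",
    "pick_soft_power",
    "scale_free_fit",
    "detect_modules",
    "module_eigengene",
    "compute_eigengenes",
    "eigengene_variance_explained",
    "module_ses_association",
    "module_deg_enrichment",
]


@dataclass
class ModuleSet:
    assignment: pd.Series  # gene -> int label, 0 = unassigned
    soft_power: float
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    module_ses: pd.DataFrame = field(default_factory=pd.DataFrame)
    deg_enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment) - {0})


def _adjacency(values: np.ndarray, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power with unit diagonal (genes x genes)."""
    cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-frequency regression.

    Connectivities are binned, and log10(p(k)) is regressed on log10(mean k)
    per occupied bin; the R^2 is signed by the slope so that only decaying
    degree distributions count as scale-free-like.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def pick_soft_power(
    matrix: NormalizedMatrix,
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
    target_fit: float = 0.8,
) -> int:
    """Smallest candidate whose scale-free-topology fit reaches target_fit.

    Falls back to the candidate with the maximal fit when none reaches it.
    """
    if matrix.values.shape[0] < 10:
        raise ValueError("need at least 10 genes to assess scale-free fit")
    vals = matrix.values.to_numpy(dtype=float)
    cor = np.abs(np.nan_to_num(np.corrcoef(vals), nan=0.0))
    np.fill_diagonal(cor, 0.0)
    fits = {}
    for p in candidate_powers:
        k = (cor**p).sum(axis=1)
        fits[p] = scale_free_fit(k)
        if fits[p] >= target_fit:
            return int(p)
    return int(max(fits, key=lambda p: (fits[p], -p)))


def _tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological-overlap dissimilarity 1 - TOM."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (l + a) / np.where(denom == 0, 1.0, denom)
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    d = (d + d.T) / 2
    np.clip(d, 0.0, None, out=d)
    np.fill_diagonal(d, 0.0)
    return d


def detect_modules(
    matrix: NormalizedMatrix,
    power: float,
    min_module_size: int = 20,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Static-cut average-linkage clustering of TOM dissimilarity.

    ``cut_height`` is the absolute dissimilarity height at which the
    dendrogram is cut (0.99 is the classic static-cut default: correlated
    blocks merge far below it, while unstructured genes merge essentially at
    1 and fall apart). Clusters smaller than ``min_module_size`` are left
    unassigned (label 0); surviving modules are renumbered by decreasing
    size.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = matrix.genes
    vals = matrix.values.to_numpy(dtype=float)
    adj = _adjacency(vals, power)
    diss = _tom_dissimilarity(adj)
    condensed = squareform(diss, checks=False)
    height = float(cut_height)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sizes.loc[keep].sort_values(ascending=False).index
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel.get(r, 0) for r in raw])
    return ModuleSet(
        assignment=pd.Series(labels, index=genes, name="module"),
        soft_power=power,
    )


def module_eigengene(matrix: NormalizedMatrix, member_genes) -> pd.Series:
    """First right singular vector of the gene-standardized module submatrix.

    Scaled to unit variance; the sign is fixed so the eigengene correlates
    positively with the module's mean standardized expression profile.
    """
    member_genes = list(member_genes)
    if len(member_genes) == 0:
        raise ValueError("empty module")
    sub = matrix.values.loc[member_genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    mean_profile = z.mean(axis=0)
    c = float(v @ mean_profile)
    if c < 0 or (c == 0 and (v[v != 0][0] if np.any(v != 0) else 1) < 0):
        v = -v
    sd_v = v.std(ddof=1)
    if sd_v > 0:
        v = (v - 0.0) / sd_v
    return pd.Series(v, index=matrix.samples, name="eigengene")


def eigengene_variance_explained(matrix: NormalizedMatrix, member_genes) -> float:
    sub = matrix.values.loc[list(member_genes)].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    s = np.linalg.svd(z, compute_uv=False)
    total = float((s**2).sum())
    return float(s[0] ** 2 / total) if total > 0 else 0.0


def compute_eigengenes(matrix: NormalizedMatrix, modules: ModuleSet) -> ModuleSet:
    eig = {
        m: module_eigengene(matrix, modules.assignment.index[modules.assignment == m])
        for m in modules.labels
    }
    modules.eigengenes = pd.DataFrame(eig)
    return modules


def module_ses_association(
    modules: ModuleSet,
    samples: pd.DataFrame,
    exposure: str = "ses",
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Eigengene ~ exposure + covariates, same design as the per-gene model."""
    if modules.eigengenes.empty:
        raise ValueError("eigengenes not computed")
    fake = NormalizedMatrix(
        values=modules.eigengenes.T,
        norm_factors=pd.Series(1.0, index=modules.eigengenes.index),
    )
    res = differential_expression(fake, samples, exposure, covariates, alpha)
    res = res[["beta", "se", "t_stat", "p_value"]].copy()
    res["q_value"] = bh_fdr(res["p_value"].to_numpy())
    res.index.name = "module"
    modules.module_ses = res
    return res


def module_deg_enrichment(
    modules: ModuleSet, de: pd.DataFrame, direction: str, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided Fisher exact test: module membership vs DE in a direction.

    The gene universes of the module assignment and the DE table must match.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if set(modules.assignment.index) != set(de.index):
        raise ValueError("gene universes of modules and DE results differ")
    de_dir = de["direction"].reindex(modules.assignment.index) == direction
    rows = []
    for m in modules.labels:
        in_mod = modules.assignment == m
        a = int((in_mod & de_dir).sum())
        b = int((in_mod & ~de_dir).sum())
        c = int((~in_mod & de_dir).sum())
        d = int((~in_mod & ~de_dir).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((m, direction, a, a + b, a + c, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["module", "direction", "overlap", "module_size", "n_de", "odds_ratio", "p_value"],
    ).set_index("module")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out
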