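"""Count normalization and covariate-adjusted differential expression.

The chain mirrors the standard bulk RNA-seq workflow for association studies
with a continuous exposure: low-count filtering, trimmed-mean-of-M-values
(TMM) library normalization, log2 counts-per-million, empirical-Bayes batch
adjustment, and a per-gene ordinary-least-squares model of expression on the
exposure plus covariates with Benjamini-Hochberg FDR control.

Counts are held as a pandas DataFrame with genes as rows and samples as
columns; normalized matrices keep the same layout in log2-CPM units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedMatrix",
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
    "batch_adjust",
    "differential_expression",
    "bh_fdr",
]


@dataclass
class NormalizedMatrix:
    """log2-CPM expression with the per-sample TMM scale factors.

    ``values``: genes x samples DataFrame of log2 counts-per-million computed
    against effective library sizes (library size x norm factor).
    ``norm_factors``: positive per-sample factors with geometric mean 1.
    """

    values: pd.DataFrame
    norm_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")
        log_gm = float(np.log(self.norm_factors.to_numpy()).mean())
        if abs(log_gm) > 1e-9:
            raise ValueError("norm_factors must have geometric mean 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return counts.div(lib, axis=1) * 1e6


def filter_low_counts(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_sample_frac: float = 0.2
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_sample_frac`` of samples."""
    if min_cpm < 0 or min_sample_frac < 0:
        raise ValueError("thresholds must be nonnegative")
    if counts.size == 0:
        import logging

        logging.getLogger(__name__).warning("filter_low_counts: empty matrix")
        return counts
    if min_cpm == 0:
        return counts
    ok = (_cpm(counts) >= min_cpm).mean(axis=1) >= min_sample_frac
    return counts.loc[ok]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Two-sample TMM factor (log2 scale returned as linear factor).

    M/A values are computed on genes expressed in both samples; both tails of
    the M distribution are trimmed by ``trim_m`` and of the A distribution by
    ``trim_a`` (rank-based double trimming); the surviving M values are
    averaged with inverse asymptotic-binomial-variance weights.
    """
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    if o.size == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic variance of M (delta method on binomial counts)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    fin = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[fin], a[fin], w[fin]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors, renormalized to geometric mean 1.

    The reference sample (if not given) is the one whose upper-quartile CPM is
    closest to the mean upper-quartile across samples.
    """
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    x = counts.to_numpy(dtype=float)
    libv = lib.to_numpy()
    if ref is None:
        uq = np.array(
            [np.quantile(x[:, j], 0.75) / libv[j] for j in range(x.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref not in counts.columns:
            raise ValueError(f"unknown reference sample {ref!r}")
        ref_idx = counts.columns.get_loc(ref)
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], libv[j], libv[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def log_cpm(
    counts: pd.DataFrame, factors: pd.Series, prior_count: float = 0.5
) -> NormalizedMatrix:
    """log2 counts-per-million against effective (factor-scaled) library sizes."""
    if not counts.columns.equals(factors.index):
        if set(counts.columns) != set(factors.index):
            raise ValueError("factors do not match the sample set of the counts")
        factors = factors.reindex(counts.columns)
    eff = counts.sum(axis=0).astype(float) * factors
    vals = np.log2(
        counts.add(prior_count).div(eff + 2 * prior_count, axis=1) * 1e6
    )
    return NormalizedMatrix(values=vals, norm_factors=factors.copy())


def batch_adjust(
    matrix: NormalizedMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> NormalizedMatrix:
    """Parametric empirical-Bayes location-scale batch correction.

    Per gene, batch location and scale effects are estimated jointly with any
    covariate effects to preserve, shrunk toward common batch priors
    (normal prior for locations, inverse-gamma for scales), and removed. With
    a single batch the input is returned unchanged.
    """
    y = matrix.values
    batch = batch.reindex(y.columns)
    levels = batch.unique()
    if len(levels) == 1:
        return NormalizedMatrix(values=y.copy(), norm_factors=matrix.norm_factors)
    sizes = batch.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batch(es) with a single sample: {list(small.index)}")

    n = y.shape[1]
    b_design = pd.get_dummies(batch, dtype=float)[list(levels)]
    parts = [b_design.to_numpy()]
    if covariates is not None and covariates.shape[1] > 0:
        cov = _encode_design(covariates.reindex(y.columns), intercept=False)
        cov = cov - cov.mean(axis=0)
        # constant covariates (zero after centering) carry no design information
        keep_cols = np.linalg.norm(cov, axis=0) > 1e-10
        cov = cov[:, keep_cols]
        if cov.shape[1]:
            parts.append(cov)
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch design is rank deficient (covariate confounded with batch)")

    Y = y.to_numpy(dtype=float)  # genes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # p x genes
    nb = len(levels)
    grand = (sizes[list(levels)].to_numpy() / n) @ beta[:nb]  # pooled intercept per gene
    resid = Y.T - X @ beta
    var_pooled = (resid**2).mean(axis=0)  # per gene
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)

    keep = X[:, nb:] @ beta[nb:] if X.shape[1] > nb else 0.0
    stand_mean = grand[None, :] + keep
    Z = (Y.T - stand_mean) / sd[None, :]  # samples x genes, standardized

    Zadj = np.empty_like(Z)
    for lev in levels:
        idx = (batch == lev).to_numpy()
        ni = idx.sum()
        g_hat = Z[idx].mean(axis=0)
        d_hat = Z[idx].var(axis=0, ddof=1)
        d_hat = np.where(d_hat <= 0, 1e-12, d_hat)
        # parametric priors across genes
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        d_bar, s2 = d_hat.mean(), d_hat.var(ddof=1)
        lam = (2 * s2 + d_bar**2) / max(s2, 1e-12)  # inverse-gamma prior shape
        th = (d_bar * s2 + d_bar**3) / max(s2, 1e-12)  # prior scale
        g_star, d_star = g_hat, d_hat
        for _ in range(100):  # EM-style iteration to the joint posterior modes
            g_new = (ni * t2 * g_hat + d_star * g_bar) / (ni * t2 + d_star)
            ssq = ((Z[idx] - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (th + 0.5 * ssq) / (ni / 2 + lam - 1)
            if np.max(np.abs(g_new - g_star)) < 1e-8 and np.max(np.abs(d_new - d_star)) < 1e-8:
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        Zadj[idx] = (Z[idx] - g_star[None, :]) / np.sqrt(d_star)[None, :]

    out = (Zadj * sd[None, :] + stand_mean).T
    # a location-scale batch correction should not move any gene's grand mean
    out = out + (Y.mean(axis=1) - out.mean(axis=1))[:, None]
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=y.index, columns=y.columns),
        norm_factors=matrix.norm_factors,
    )


def _encode_design(covariates: pd.DataFrame, intercept: bool = True) -> np.ndarray:
    """Numeric design from a mixed-type covariate frame (one-hot, drop-first)."""
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            cols.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            if dummies.shape[1]:
                cols.append(dummies.to_numpy())
    parts = [np.ones((len(covariates), 1))] if intercept else []
    parts += cols
    if not parts:
        return np.empty((len(covariates), 0))
    return np.column_stack(parts)


def _design_matrix(
    samples: pd.DataFrame, exposure: str, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + exposure + encoded covariates; errors on rank deficiency."""
    names = ["intercept", exposure]
    blocks = [
        np.ones((len(samples), 1)),
        samples[exposure].to_numpy(dtype=float)[:, None],
    ]
    import logging

    for name in covariates:
        col = samples[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            arr = col.to_numpy(dtype=float)
            if np.ptp(arr) == 0:  # constant covariate carries no information
                logging.getLogger(__name__).warning(
                    "dropping constant covariate %r from the design", name
                )
                continue
            blocks.append(arr[:, None])
            names.append(name)
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for c in dummies.columns:
                names.append(f"{name}[{c}]")
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy())
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        offenders = _collinear_columns(X, names)
        raise ValueError(f"design matrix rank deficient; collinear columns: {offenders}")
    return X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.where(diag < tol)[0]]


def differential_expression(
    matrix: NormalizedMatrix,
    samples: pd.DataFrame,
    exposure: str = "ses",
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of normalized expression on the exposure plus covariates.

    Returns a DataFrame indexed by gene with columns beta, se, t_stat,
    p_value, q_value (BH across all tested genes) and direction in
    {up, down, ns}; 'up' means a positive exposure association at q < alpha.
    Genes with zero residual variance are reported with beta=0, p=1 and
    flagged in the ``degenerate`` column rather than dropped.
    """
    covariates = covariates or []
    samples = samples.loc[matrix.samples]
    X, _ = _design_matrix(samples, exposure, covariates)
    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than samples")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ X.T @ Y  # p x genes
    resid = Y - X @ beta_all
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    c_exp = xtx_inv[1, 1]
    beta = beta_all[1]
    se = np.sqrt(c_exp * s2)
    degenerate = s2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, beta / np.where(se == 0, np.nan, se))
    t = np.nan_to_num(t)
    pvals = 2 * stats.t.sf(np.abs(t), df)
    beta = np.where(degenerate, 0.0, beta)
    pvals = np.where(degenerate, 1.0, pvals)
    q = bh_fdr(pvals)
    direction = np.where(
        q < alpha, np.where(beta > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {
            "beta": beta,
            "se": np.where(degenerate, 0.0, se),
            "t_stat": t,
            "p_value": pvals,
            "q_value": q,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=matrix.genes,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
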