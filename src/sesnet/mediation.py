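"""Counterfactual mediation of exposure-expression associations.

For each (gene, mediator) pair two models are fitted: a mediator model
M ~ X + covariates (linear for continuous M, logistic for binary M) and an
outcome model Y ~ X + M + covariates (linear; expression outcomes are
continuous). Quasi-Bayesian Monte-Carlo draws from the normal approximation
to the coefficient sampling distributions yield the average causal mediation
effect (ACME), average direct effect (ADE), total effect and the proportion
mediated ACME/total, with percentile intervals and a two-sided p-value for
the ACME. Negative proportions indicate suppression (indirect and direct
paths of opposite sign).

Per-layer summaries report the median proportion mediated and a BH-adjusted
Fisher combination of the member genes' ACME p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .expression import NormalizedMatrix, _encode_design, bh_fdr
from .randomization import fisher_combine

logger = logging.getLogger(__name__)

__all__ = ["MediationResult", "mediate_single", "mediate_genome", "layer_mediation_summary"]

TOTAL_TOL = 1e-8
WINSOR = 5.0


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float  # nan when |total| below tolerance
    ci_low: float
    ci_high: float
    p_acme: float
    n_sim: int
    seed: int
    suppression: bool


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design in mediation model")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    return beta, s2 * xtx_inv


def _logit_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    return np.asarray(res.params), np.asarray(res.cov_params())


def mediate_single(
    outcome: np.ndarray,
    exposure: np.ndarray,
    mediator: np.ndarray,
    covariates: np.ndarray | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Quasi-Bayesian counterfactual mediation for one gene and one mediator.

    Effects are per unit of exposure. For a binary mediator the indirect
    effect integrates the logistic mediator model over the sample, using a
    unit exposure contrast centered on each observation.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if len({len(y), len(x), len(m)}) != 1:
        raise ValueError("outcome, exposure and mediator must be aligned")
    uniq = np.unique(y)
    if uniq.size <= 2 and set(uniq).issubset({0.0, 1.0}):
        raise ValueError("binary outcomes are not supported (expression is continuous)")
    n = len(y)
    cov = covariates if covariates is not None else np.empty((n, 0))
    Xm = np.column_stack([np.ones(n), x, cov])
    Xy = np.column_stack([np.ones(n), x, m, cov])

    binary_m = set(np.unique(m)).issubset({0.0, 1.0}) and np.unique(m).size == 2
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3E]))

    if binary_m and np.unique(m).size == 2:
        bm, Vm = _logit_fit(Xm, m)
    else:
        binary_m = False
        bm, Vm = _ols_fit(Xm, m)
    by, Vy = _ols_fit(Xy, y)

    Vm = (Vm + Vm.T) / 2  # guard against asymmetry from the GLM covariance
    bm_draws = rng.multivariate_normal(bm, Vm, size=n_sim, method="svd")
    by_draws = rng.multivariate_normal(by, Vy, size=n_sim, method="svd")

    b_draw = by_draws[:, 2]  # mediator coefficient in the outcome model
    cprime_draw = by_draws[:, 1]
    if binary_m:
        # E[M | x_i + 1/2] - E[M | x_i - 1/2], averaged over the sample
        base = Xm @ bm_draws.T  # n x n_sim linear predictor
        a_x = bm_draws[:, 1]
        dm = expit(base + 0.5 * a_x[None, :]) - expit(base - 0.5 * a_x[None, :])
        a_draw = dm.mean(axis=0)
    else:
        a_draw = bm_draws[:, 1]

    acme_draw = a_draw * b_draw
    ade_draw = cprime_draw
    total_draw = acme_draw + ade_draw
    acme = float(acme_draw.mean())
    ade = float(ade_draw.mean())
    total = float(total_draw.mean())
    ci_low, ci_high = (float(q) for q in np.quantile(acme_draw, [0.025, 0.975]))
    # two-sided MC p for the ACME with add-one smoothing
    tail = min((acme_draw <= 0).sum(), (acme_draw >= 0).sum())
    p_acme = min(1.0, 2 * (tail + 1) / (n_sim + 1))
    if abs(total) < TOTAL_TOL:
        prop = float("nan")
    else:
        prop = acme / total
    suppression = np.isfinite(prop) and prop < 0
    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        ci_low=ci_low, ci_high=ci_high, p_acme=float(p_acme),
        n_sim=n_sim, seed=int(seed), suppression=bool(suppression),
    )


def _mediator_vector(samples: pd.DataFrame, name: str) -> np.ndarray:
    col = samples[name]
    if isinstance(col.dtype, pd.CategoricalDtype):
        if col.cat.ordered:
            return col.cat.codes.to_numpy(dtype=float)  # ordered levels as 0..k-1
        raise ValueError(f"unordered categorical mediator {name!r} is not supported")
    return col.to_numpy(dtype=float)


def mediate_genome(
    matrix: NormalizedMatrix,
    samples: pd.DataFrame,
    mediators: list[str],
    genes: list[str] | None = None,
    exposure: str = "ses",
    covariates: list[str] | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """mediate_single per (gene, mediator) with a deterministic seed schedule."""
    missing = [m for m in mediators if m not in samples.columns]
    if missing:
        raise ValueError(f"unknown mediator column(s): {missing}")
    genes = list(genes) if genes is not None else list(matrix.genes)
    samples = samples.loc[matrix.samples]
    x = samples[exposure].to_numpy(dtype=float)
    cov = _encode_design(samples[covariates or []], intercept=False)
    rows = []
    for mi, med in enumerate(mediators):
        mvec = _mediator_vector(samples, med)
        if np.std(mvec) == 0:
            logger.warning("mediator %r is constant; ACME is structurally 0", med)
        for gi, gene in enumerate(genes):
            sub_seed = int((seed * 1_000_003 + mi * 65_537 + gi) % (2**31 - 1))
            y = matrix.values.loc[gene].to_numpy(dtype=float)
            if np.std(mvec) == 0:
                res = MediationResult(0.0, 0.0, 0.0, float("nan"), 0.0, 0.0, 1.0, n_sim, sub_seed, False)
            else:
                res = mediate_single(y, x, mvec, cov, n_sim=n_sim, seed=sub_seed)
            rows.append(
                (gene, med, res.acme, res.ade, res.total, res.prop_mediated,
                 res.ci_low, res.ci_high, res.p_acme, res.suppression, res.n_sim, res.seed)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "mediator", "acme", "ade", "total", "prop_mediated",
                 "ci_low", "ci_high", "p_acme", "suppression", "n_sim", "seed"],
    )


def layer_mediation_summary(
    results: pd.DataFrame,
    layers: pd.DataFrame,
    alpha: float = 0.05,
    winsor: float = WINSOR,
) -> pd.DataFrame:
    """Median proportion mediated per (layer, mediator) cell.

    Proportions are winsorized to [-winsor, winsor] before the median to tame
    near-zero totals; genes with undefined proportions are excluded from the
    median but counted. The aggregated q-value is a BH adjustment (across
    cells) of the Fisher combination of the cell's ACME p-values.
    """
    merged = results.merge(
        layers[["layer"]], left_on="gene", right_index=True, how="inner"
    )
    rows = []
    for (layer, med), grp in merged.groupby(["layer", "mediator"], sort=True):
        props = grp["prop_mediated"].to_numpy(dtype=float)
        defined = np.isfinite(props)
        if defined.sum() == 0:
            logger.info("layer %s x %s: no defined ratios; row omitted", layer, med)
            continue
        w = np.clip(props[defined], -winsor, winsor)
        stat, df, comb_p = fisher_combine(grp["p_acme"].to_numpy(dtype=float))
        rows.append(
            (int(layer), med, float(np.median(w)), comb_p, int(defined.sum()),
             int((~defined).sum()))
        )
    out = pd.DataFrame(
        rows,
        columns=["layer", "mediator", "median_prop_mediated", "combined_p",
                 "n_genes", "n_undefined"],
    )
    out["aggregated_q"] = bh_fdr(out["combined_p"].to_numpy()) if len(out) else []
    return out
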