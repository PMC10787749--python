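"""Normalization and differential-expression contracts.

The TMM oracle here enumerates M/A values and the double trim directly by
sorting, independently of the production path; the frozen two-sample factors
were computed with edgeR::calcNormFactors (method="TMM") on the same matrix.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sesnet.expression import (
    NormalizedMatrix,
    batch_adjust,
    bh_fdr,
    differential_expression,
    filter_low_counts,
    log_cpm,
    tmm_factors,
)
from tests.conftest import make_norm


def _df(cols: dict) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])


def tmm_pair_oracle(obs, ref, trim_m=0.30, trim_a=0.05):
    """Brute-force two-sample TMM: explicit sort-based double trim."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    no, nr = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    m = np.log2((o / no) / (r / nr))
    a = 0.5 * np.log2((o / no) * (r / nr))
    w = (no - o) / (no * o) + (nr - r) / (nr * r)
    n = len(m)
    if n == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    cut_m, cut_a = np.floor(n * trim_m), np.floor(n * trim_a)
    sel = (
        (rank_m > cut_m) & (rank_m <= n - cut_m)
        & (rank_a > cut_a) & (rank_a <= n - cut_a)
    )
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return 2.0**f


class TestFilter:
    def test_all_zero_gene_removed(self):
        c = _df({"a": [0, 10, 20], "b": [0, 15, 30]})
        out = filter_low_counts(c, min_cpm=1, min_sample_frac=0.5)
        assert "g0" not in out.index

    def test_zero_threshold_is_identity(self):
        c = _df({"a": [0, 10], "b": [5, 0]})
        pd.testing.assert_frame_equal(filter_low_counts(c, min_cpm=0), c)

    def test_matches_hand_computed_cpm(self):
        # libs: a=1000, b=2000; CPM g0: (1000, 500), g1: (999000, 1999000),
        # g2: (0, 500). min_cpm=600, frac=0.5 -> keep g0 (1 of 2 samples),
        # g1 (both), drop g2 (none)
        c = _df({"a": [1, 999, 0], "b": [1, 3998, 1]})
        out = filter_low_counts(c, min_cpm=600, min_sample_frac=0.5)
        assert list(out.index) == ["g0", "g1"]

    def test_empty_matrix_passthrough(self):
        c = pd.DataFrame(dtype=int)
        assert filter_low_counts(c, 1, 0.5).empty


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        c = _df({"a": [100, 50, 10, 500, 80, 20], "b": [100, 50, 10, 500, 80, 20]})
        f = tmm_factors(c)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_scaling_gives_unit_factors(self):
        col = np.array([100, 50, 10, 500, 80, 20])
        c = _df({"a": col, "b": 2 * col})
        f = tmm_factors(c)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_enumeration_oracle(self):
        a = np.array([100, 200, 50, 500, 1000, 20])
        b = np.array([300, 350, 180, 900, 2600, 25])
        c = _df({"a": a, "b": b})
        f = tmm_factors(c, ref="a")
        pair = tmm_pair_oracle(b, a)
        expected = np.array([1 / np.sqrt(pair), np.sqrt(pair)])
        assert np.allclose(f.to_numpy(), expected, atol=1e-12)

    def test_matches_edger_frozen_values(self):
        # edgeR 4.0.16 calcNormFactors(method="TMM") on this exact matrix
        c = _df({
            "s1": [100, 200, 50, 500, 1000, 20, 80, 300, 10, 700],
            "s2": [210, 380, 120, 950, 2100, 35, 150, 640, 25, 1500],
        })
        f = tmm_factors(c)
        assert np.allclose(
            f.to_numpy(), [1.001790567818, 0.998212632585], atol=1e-9
        )

    def test_scale_equivariance(self):
        # M and A values are depth-relative, so trimming decisions cannot
        # change; the factors move only through the inverse-variance weights
        # (the reference half of each weight does not rescale), which keeps
        # them equal to a few parts in a thousand
        rng = np.random.default_rng(5)
        c = pd.DataFrame(
            rng.poisson(100, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        f1 = tmm_factors(c, ref="a")
        scaled = c.copy()
        scaled["c"] = (scaled["c"] * 7).astype(int)
        f2 = tmm_factors(scaled, ref="a")
        assert np.allclose(f1, f2, atol=5e-3)
        pair_before = tmm_pair_oracle(c["c"], c["a"])
        pair_after = tmm_pair_oracle(scaled["c"], scaled["a"])
        assert abs(pair_before - pair_after) < 5e-3

    def test_all_zero_sample_is_an_error(self):
        c = _df({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            tmm_factors(c)


class TestLogCPM:
    def test_zero_count_plug_in(self):
        c = pd.DataFrame({"a": [0, 999_999]}, index=["g0", "g1"])
        f = pd.Series([1.0], index=["a"])
        norm = log_cpm(c, f, prior_count=0.5)
        expected = np.log2(0.5 / (999_999 + 1.0) * 1e6)
        assert abs(norm.values.loc["g0", "a"] - expected) < 1e-5

    def test_monotone_in_count(self):
        c = pd.DataFrame({"a": [10, 100], "b": [20, 100]}, index=["g0", "g1"])
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        norm = log_cpm(c, f)
        assert norm.values.loc["g0", "b"] > norm.values.loc["g0", "a"] - np.log2(
            c["b"].sum() / c["a"].sum()
        )

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        c = pd.DataFrame(
            rng.poisson(50, (20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abc"),
        )
        f = tmm_factors(c)
        norm = log_cpm(c, f, prior_count=0.5)
        eff = c.sum(axis=0) * f
        direct = np.log2((c + 0.5).div(eff + 1.0, axis=1) * 1e6)
        assert np.allclose(norm.values, direct, atol=1e-12)

    def test_mismatched_samples_rejected(self):
        c = pd.DataFrame({"a": [1]}, index=["g0"])
        with pytest.raises(ValueError):
            log_cpm(c, pd.Series([1.0], index=["zzz"]))


class TestBatchAdjust:
    def test_single_batch_identity(self):
        m = make_norm(np.random.default_rng(0).normal(size=(10, 8)))
        batch = pd.Series(["x"] * 8, index=m.samples)
        out = batch_adjust(m, batch)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_planted_mean_shift_removed(self):
        rng = np.random.default_rng(2)
        n_per = 100
        base = rng.normal(size=(40, 2 * n_per))
        base[:, n_per:] += 0.8  # pure batch shift on every gene
        m = make_norm(base)
        batch = pd.Series(["b1"] * n_per + ["b2"] * n_per, index=m.samples)
        out = batch_adjust(m, batch)
        diff = (
            out.values.iloc[:, n_per:].mean(axis=1)
            - out.values.iloc[:, :n_per].mean(axis=1)
        )
        # the systematic 0.8 shift is gone; what remains per gene is the
        # sampling noise of its batch means, which averages out across genes
        assert abs(diff.mean()) < 0.05
        assert np.abs(diff).max() < 0.5
        raw_diff = (
            m.values.iloc[:, n_per:].mean(axis=1)
            - m.values.iloc[:, :n_per].mean(axis=1)
        )
        assert abs(raw_diff.mean()) > 0.7  # the shift really was there

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 60))
        base[:, 30:] += rng.normal(0.5, 0.1, size=(30, 1))
        m = make_norm(base)
        batch = pd.Series(["b1"] * 30 + ["b2"] * 30, index=m.samples)
        out = batch_adjust(m, batch)
        assert np.allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), atol=1e-6
        )

    def test_singleton_batch_rejected(self):
        m = make_norm(np.zeros((5, 3)))
        batch = pd.Series(["a", "a", "b"], index=m.samples)
        with pytest.raises(ValueError, match="b"):
            batch_adjust(m, batch)


class TestDifferentialExpression:
    @staticmethod
    def _null_data(n_genes=200, n=200, seed=21):
        rng = np.random.default_rng(seed)
        m = make_norm(rng.normal(size=(n_genes, n)))
        samples = pd.DataFrame(
            {"ses": rng.standard_normal(n), "age": rng.uniform(30, 45, n)},
            index=m.samples,
        )
        return m, samples

    def test_null_type_i_error_calibrated(self):
        m, samples = self._null_data()
        de = differential_expression(m, samples, "ses", ["age"])
        frac = (de["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        ks = stats.kstest(de["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effect_called_up(self):
        rng = np.random.default_rng(22)
        n = 500
        ses = rng.standard_normal(n)
        vals = rng.normal(size=(50, n))
        vals[0] += 1.0 * ses  # +1 per SD of SES
        m = make_norm(vals)
        samples = pd.DataFrame({"ses": ses}, index=m.samples)
        de = differential_expression(m, samples, "ses", [])
        assert de.loc["g0", "direction"] == "up"
        assert de.loc["g0", "q_value"] < 0.05

    def test_beta_recovers_truth(self):
        rng = np.random.default_rng(23)
        n, n_genes = 500, 100
        ses = rng.standard_normal(n)
        truth = rng.uniform(-1, 1, n_genes)
        vals = truth[:, None] * ses[None, :] + rng.normal(size=(n_genes, n))
        m = make_norm(vals)
        samples = pd.DataFrame({"ses": ses}, index=m.samples)
        de = differential_expression(m, samples, "ses", [])
        assert np.corrcoef(de["beta"], truth)[0, 1] > 0.9

    def test_collinear_covariate_rejected(self):
        m, samples = self._null_data(20, 50)
        samples["ses2"] = 2 * samples["ses"]
        with pytest.raises(ValueError, match="collinear"):
            differential_expression(m, samples, "ses", ["ses2"])

    def test_constant_gene_flagged_degenerate(self):
        m, samples = self._null_data(5, 30)
        m.values.iloc[0] = 3.14
        de = differential_expression(m, samples, "ses", [])
        assert de.loc["g0", "degenerate"]
        assert de.loc["g0", "p_value"] == 1.0 and de.loc["g0", "beta"] == 0.0


class TestBH:
    def test_single_p_passthrough(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_q_dominates_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        assert (bh_fdr(p) >= p - 1e-12).all()
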