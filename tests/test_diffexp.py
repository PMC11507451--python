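"""Normalisation, dispersion, Wald testing and DEG calling."""

import math

import numpy as np
import pandas as pd
import pytest

from eisa.diffexp import (
    DiffExpError,
    NegativeBinomialDE,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    prefilter,
    size_factors,
    top_by_basemean,
    wald_test,
)

SAMPLES6 = [f"s{i}" for i in range(6)]
COND6 = {s: ("control" if i < 3 else "treated") for i, s in enumerate(SAMPLES6)}


def _df(rows, columns=None):
    columns = columns or SAMPLES6
    return pd.DataFrame(rows, columns=columns,
                        index=[f"g{i}" for i in range(len(rows))])


class TestPrefilter:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([2, 2, 2, 0, 0, 0], True),   # exactly 3 samples above 1
            ([5, 9, 0, 0, 0, 0], False),  # only 2 samples above 1
            ([1, 1, 1, 1, 1, 1], False),  # counts of 1 do not qualify
            ([2, 2, 0, 0, 0, 2], True),
        ],
    )
    def test_detection_rule(self, row, kept):
        out = prefilter(_df([row]))
        assert ("g0" in out.index) is kept


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _df([[10] * 6, [100] * 6, [7] * 6])
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_closed_form(self):
        counts = pd.DataFrame({"s1": [10, 20, 40, 5], "s2": [20, 40, 80, 10]})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert sf["s2"] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_scaling_one_sample_scales_its_factor(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(200, 4)) + 1,
                              columns=list("abcd"))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled["d"] *= 3
        sf2 = size_factors(scaled)
        # ratios to the geometric mean shift by 3 / 3**(1/4) for sample d
        assert sf2["d"] / sf["d"] == pytest.approx(3 / 3 ** 0.25, rel=1e-6)

    def test_no_reference_gene_is_an_error(self):
        counts = _df([[0, 1, 2, 3, 4, 5], [1, 0, 1, 1, 1, 1]])
        with pytest.raises(DiffExpError, match="reference gene"):
            size_factors(counts)

    def test_matches_pydeseq2_median_of_ratios(self, rng):
        """Independent cross-check against the DESeq2 reimplementation."""
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        counts = pd.DataFrame(rng.negative_binomial(20, 0.2, size=(300, 6)) + 1,
                              columns=SAMPLES6)
        meta = pd.DataFrame({"condition": [COND6[s] for s in SAMPLES6]}, index=SAMPLES6)
        dds = pydeseq2.DeseqDataSet(counts=counts.T, metadata=meta,
                                    design="~condition", quiet=True)
        dds.fit_size_factors()
        ours = size_factors(counts).to_numpy()
        theirs = np.asarray(dds.obs["size_factors"], dtype=float)
        assert np.allclose(ours, theirs, rtol=1e-6)


class TestDispersion:
    def test_poisson_data_collapses_to_alpha_min(self, rng):
        n = 1000
        counts = pd.DataFrame({f"s{i}": rng.poisson(1000, size=1) for i in range(n)})
        cond = {f"s{i}": ("control" if i < n // 2 else "treated") for i in range(n)}
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf, cond)
        assert alpha.iloc[0] < 1e-3

    def test_nb_dispersion_recovered_at_large_n(self, rng):
        n, true_alpha, mu = 500, 0.05, 500
        r = 1 / true_alpha
        data = rng.negative_binomial(r, r / (r + mu), size=(5, n))
        counts = pd.DataFrame(data, columns=[f"s{i}" for i in range(n)])
        cond = {f"s{i}": ("control" if i < n // 2 else "treated") for i in range(n)}
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf, cond)
        assert ((alpha > 0.025) & (alpha < 0.075)).all()

    def test_constant_counts_give_alpha_min(self):
        counts = _df([[50] * 6])
        sf = pd.Series(1.0, index=SAMPLES6)
        alpha = estimate_dispersion(counts, sf, COND6, prior_df=0.0)
        assert alpha.iloc[0] == pytest.approx(1e-8)

    def test_zero_mean_gene_excluded(self):
        counts = _df([[0] * 6, [10] * 6])
        sf = pd.Series(1.0, index=SAMPLES6)
        alpha = estimate_dispersion(counts, sf, COND6)
        assert np.isnan(alpha.loc["g0"]) and np.isfinite(alpha.loc["g1"])


class TestWald:
    def test_identical_groups_give_null_result(self):
        counts = _df([[100] * 6])
        sf = pd.Series(1.0, index=SAMPLES6)
        alpha = pd.Series(0.05, index=counts.index)
        tab = wald_test(counts, sf, alpha, COND6)
        assert tab["log2FC"].iloc[0] == 0
        assert tab["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_fourfold_change_recovered(self, rng):
        base = rng.poisson(2000, size=(200, 3))
        treated = rng.poisson(8000, size=(200, 3))
        counts = pd.DataFrame(np.hstack([base, treated]), columns=SAMPLES6)
        sf = pd.Series(1.0, index=SAMPLES6)
        alpha = pd.Series(1e-4, index=counts.index)
        tab = wald_test(counts, sf, alpha, COND6)
        assert tab["log2FC"].mean() == pytest.approx(2.0, abs=0.1)

    def test_needs_two_samples_per_group(self):
        counts = _df([[1, 2, 3, 4, 5, 6]])
        sf = pd.Series(1.0, index=SAMPLES6)
        cond = dict(COND6, s1="treated", s2="treated")  # 1 control / 5 treated
        with pytest.raises(DiffExpError, match=">=2 samples"):
            wald_test(counts, sf, pd.Series(0.05, index=counts.index), cond)

    def test_null_pvalues_roughly_uniform_at_larger_n(self, rng):
        """With 10v10 replicates the plug-in Wald test is close to exact."""
        n_genes, mu, alpha_true = 2000, 200, 0.05
        r = 1 / alpha_true
        data = rng.negative_binomial(r, r / (r + mu), size=(n_genes, 20))
        cols = [f"s{i}" for i in range(20)]
        counts = pd.DataFrame(data, columns=cols)
        cond = {c: ("control" if i < 10 else "treated") for i, c in enumerate(cols)}
        sf = pd.Series(1.0, index=cols)
        disp = estimate_dispersion(counts, sf, cond)
        tab = wald_test(counts, sf, disp, cond)
        frac = (tab["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04, atol=1e-15)

    def test_all_ones_stay_one(self):
        assert (bh_adjust(np.array([1.0, 1.0, 1.0])) == 1.0).all()

    def test_nan_propagates_without_affecting_others(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.02]))
        assert np.isnan(out.iloc[1])
        assert out.iloc[0] == pytest.approx(0.02)  # n=2 effective tests

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestDegCalling:
    @pytest.mark.parametrize(
        "fdr,lfc,deg",
        [
            (0.05, 0.58, True),    # inclusive boundaries
            (0.04, -0.60, True),   # sign-symmetric
            (0.051, 3.0, False),
            (0.01, 0.57, False),
        ],
    )
    def test_thresholds(self, fdr, lfc, deg):
        table = pd.DataFrame({"fdr": [fdr], "log2FC": [lfc]})
        assert call_degs(table).iloc[0] == deg

    def test_top_by_basemean_truncation_and_ties(self):
        table = pd.DataFrame(
            {"baseMean": [10.0, 9.0, 8.0, 8.0, 7.0]},
            index=["a", "b", "z", "c", "d"],
        )
        assert top_by_basemean(table, 3) == ["a", "b", "c"]  # tie -> smaller id
        assert top_by_basemean(table, 10_000) == ["a", "b", "c", "z", "d"]


class TestModelObject:
    def test_fit_produces_complete_table(self, sim_bundle):
        _, cm_exon, *_ = sim_bundle
        res = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
        assert set(res.table.columns) >= {"baseMean", "log2FC", "lfcSE", "pvalue",
                                          "fdr", "is_deg"}
        assert res.table["pvalue"].between(0, 1).all()
        assert res.table["fdr"].between(0, 1).all()
        assert "Negative-binomial DE results" in res.summary()

    def test_scale_invariance_of_estimates(self, sim_bundle):
        """Multiplying one sample's counts is absorbed by its size factor."""
        _, cm_exon, *_ = sim_bundle
        res1 = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
        scaled = cm_exon.counts.copy()
        scaled["hfd_1"] *= 4
        res2 = NegativeBinomialDE(scaled, cm_exon.condition, level="exon").fit()
        common = res1.table.index.intersection(res2.table.index)
        diff = (res1.table.loc[common, "log2FC"] - res2.table.loc[common, "log2FC"])
        assert diff.abs().mean() < 0.02

    def test_degs_direction_filter(self, de_results):
        _, res_ex, _ = de_results
        up, down = res_ex.degs("up"), res_ex.degs("down")
        assert set(up).isdisjoint(down)
        assert set(up) | set(down) == set(res_ex.degs())

    def test_recovery_of_known_effects(self, de_results):
        truth, res_ex, res_in = de_results
        up = truth.table[truth.table["group"] == "up"]
        tab = res_in.table.reindex(up.index).dropna()
        tab = tab[tab["baseMean"] >= 100]
        err = tab["log2FC"] - up["delta_t"].reindex(tab.index)
        assert abs(err.mean()) < 0.1
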