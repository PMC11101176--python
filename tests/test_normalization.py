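import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from sexbias.normalization import (
    bh_adjust,
    bonferroni_adjust,
    de_test,
    expression_floor,
    size_factors,
    tpm,
)
from sexbias.synthetic import _rnb

from conftest import make_norm


def mor_oracle(df: pd.DataFrame) -> np.ndarray:
    """Explicit-loop median-of-ratios, geometric mean rescaled to 1."""
    genes = [g for g in df.index if (df.loc[g] > 0).all()]
    geomeans = {g: float(np.exp(np.mean(np.log(df.loc[g])))) for g in genes}
    factors = []
    for s in df.columns:
        ratios = [df.at[g, s] / geomeans[g] for g in genes]
        factors.append(float(np.median(ratios)))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestSizeFactors:
    def test_doubled_sample_gets_exactly_double_factor(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=50)
        df = pd.DataFrame({"s1": base, "s2": 2 * base})
        s = size_factors(df)
        assert s["s2"] / s["s1"] == pytest.approx(2.0, abs=1e-9)

    def test_single_gene_matrix_hand_computation(self):
        # counts (10, 40): geomean 20, ratios (0.5, 2) — already geomean 1
        df = pd.DataFrame({"s1": [10], "s2": [40]})
        s = size_factors(df)
        assert s.tolist() == pytest.approx([0.5, 2.0])

    def test_identical_samples_get_equal_factors(self):
        df = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20], "s3": [5, 10, 20]})
        assert size_factors(df).tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.poisson(50, size=(100, 6)),
                          columns=[f"s{i}" for i in range(6)])
        s = size_factors(df)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.poisson(rng.uniform(5, 200, size=(50, 1)), size=(50, 8)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(8)],
        )
        np.testing.assert_allclose(size_factors(df), mor_oracle(df), rtol=1e-12)

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson(80, size=(40, 6)),
                          index=[f"g{i}" for i in range(40)],
                          columns=[f"s{i}" for i in range(6)])
        s = size_factors(df)
        perm = df.sample(frac=1, axis=0, random_state=0).sample(
            frac=1, axis=1, random_state=1
        )
        s_perm = size_factors(perm)
        np.testing.assert_allclose(s_perm[s.index], s, rtol=1e-12)

    def test_no_universally_expressed_gene_raises(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)


class TestTPM:
    def test_equal_counts_different_lengths(self):
        df = pd.DataFrame({"s": [10, 10]}, index=["short", "long"])
        lengths = pd.Series({"short": 1000, "long": 2000})
        t = tpm(df, lengths)
        assert t.at["short", "s"] / t.at["long", "s"] == pytest.approx(2.0)

    def test_single_expressed_gene_takes_all(self):
        df = pd.DataFrame({"s": [7, 0]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 500})
        assert tpm(df, lengths).at["g1", "s"] == pytest.approx(1e6)

    def test_three_gene_worked_example(self):
        # counts (10,10,30), lengths (1000,500,1000) -> kb rates (10,20,30)
        df = pd.DataFrame({"s": [10, 10, 30]}, index=["a", "b", "c"])
        lengths = pd.Series({"a": 1000, "b": 500, "c": 1000})
        t = tpm(df, lengths)["s"]
        np.testing.assert_allclose(
            t.to_numpy(), [1e6 / 6, 2e6 / 6, 3e6 / 6], rtol=1e-12
        )

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.poisson(40, size=(200, 5)))
        lengths = pd.Series(rng.integers(200, 5000, size=200), index=df.index)
        sums = tpm(df, lengths).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)

    def test_zero_length_rejected(self):
        df = pd.DataFrame({"s": [1]}, index=["g"])
        with pytest.raises(ValueError, match="length"):
            tpm(df, pd.Series({"g": 0}))


class TestExpressionFloor:
    def test_single_expressing_line_suffices(self, design_sheet):
        mat = pd.DataFrame(0.0, index=["g"], columns=design_sheet.sample_ids)
        f1 = design_sheet.select(cell_line="F1", timepoint="D0")
        mat.loc["g", f1] = 60.0
        assert expression_floor(mat, design_sheet, timepoint="D0").loc["g"]

    def test_threshold_is_strict(self, design_sheet):
        mat = pd.DataFrame(49.9, index=["g"], columns=design_sheet.sample_ids)
        assert not expression_floor(mat, design_sheet).loc["g"]
        mat.loc["g"] = 50.0
        assert expression_floor(mat, design_sheet).loc["g"]


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.04)), 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=100)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_padj_at_least_p_and_bonferroni_dominates(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (bonferroni_adjust(p) >= adj - 1e-15).all()


class TestDETest:
    def _norm(self, values, design_sheet):
        return make_norm(values, design_sheet)

    def test_identical_groups_give_zero_fc_and_p_one(self, design_sheet):
        xx = design_sheet.select(sex="XX", timepoint="D0")
        xy = design_sheet.select(sex="XY", timepoint="D0")
        mat = pd.DataFrame(
            np.tile([[10.0, 20.0, 30.0, 10.0, 20.0, 30.0, 5.0, 5.0, 5.0]], (3, 1)),
            index=["g1", "g2", "g3"],
            columns=xx,
        )
        mat = pd.concat([mat, mat.set_axis(xy, axis=1)], axis=1)
        de = de_test(self._norm(mat, design_sheet), xx, xy)
        assert (de["log2fc"] == 0).all()
        assert (de["p"] == 1.0).all()

    def test_label_symmetry(self, design_sheet):
        rng = np.random.default_rng(5)
        xx = design_sheet.select(sex="XX", timepoint="D0")
        xy = design_sheet.select(sex="XY", timepoint="D0")
        mat = pd.DataFrame(
            rng.poisson(100, size=(30, 18)).astype(float),
            index=[f"g{i}" for i in range(30)], columns=xx + xy,
        )
        norm = self._norm(mat, design_sheet)
        ab = de_test(norm, xx, xy)
        ba = de_test(norm, xy, xx)
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(ab["stat"], -ba["stat"], rtol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-12)

    @pytest.mark.parametrize("method", ["nb_wald", "welch_log"])
    def test_all_zero_group_stays_finite(self, design_sheet, method):
        xx = design_sheet.select(sex="XX", timepoint="D0")
        xy = design_sheet.select(sex="XY", timepoint="D0")
        mat = pd.DataFrame(0.0, index=["g"], columns=xx + xy)
        mat.loc["g", xy] = [100, 120, 80, 90, 110, 100, 95, 105, 100]
        de = de_test(self._norm(mat, design_sheet), xx, xy, method=method)
        assert np.isfinite(de["stat"]).all()
        assert np.isfinite(de["log2fc"]).all()

    def test_disjoint_groups_required(self, design_sheet):
        xx = design_sheet.select(sex="XX", timepoint="D0")
        mat = pd.DataFrame(1.0, index=["g"], columns=design_sheet.sample_ids)
        with pytest.raises(ValueError, match="disjoint"):
            de_test(make_norm(mat, design_sheet), xx, xx)

    def test_power_above_080_for_planted_twofold_effect(self, design_sheet):
        """Monte-Carlo: 500 genes, mu=200, dispersion 0.1, 9 vs 9 samples,
        true log2fc = 1 -> empirical power of nb_wald at p<0.05 exceeds 0.8."""
        rng = np.random.default_rng(42)
        n_genes = 500
        a = _rnb(rng, np.full((n_genes, 9), 200.0 * 2.0), np.full((n_genes, 9), 0.1))
        b = _rnb(rng, np.full((n_genes, 9), 200.0), np.full((n_genes, 9), 0.1))
        xx = design_sheet.select(sex="XX", timepoint="D0")
        xy = design_sheet.select(sex="XY", timepoint="D0")
        mat = pd.DataFrame(
            np.hstack([a, b]).astype(float),
            index=[f"g{i}" for i in range(n_genes)], columns=xx + xy,
        )
        de = de_test(make_norm(mat, design_sheet), xx, xy)
        assert (de["p"] < 0.05).mean() > 0.8
        assert (de["log2fc"] > 0).mean() > 0.95
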