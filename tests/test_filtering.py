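import numpy as np
import pandas as pd
import pytest

from sexbias.filtering import (
    FilterConfig,
    all_pairwise_rule,
    brute_force_filter,
    line_means,
    stringent_filter,
    table2_summary,
    within_sex_cv,
)
from sexbias.normalization import normalize, sex_contrast
from sexbias.synthetic import SimulationConfig, simulate

from conftest import make_norm


class TestLineMeans:
    def test_replicates_average(self, design_sheet):
        mat = pd.DataFrame(0.0, index=["g"], columns=design_sheet.sample_ids)
        mat.loc["g", design_sheet.select(cell_line="F1", timepoint="D0")] = [10, 20, 30]
        lm = line_means(mat, design_sheet, timepoint="D0")
        assert lm.at["g", "F1"] == pytest.approx(20.0)

    def test_invariant_to_replicate_order(self, design_sheet):
        sids = design_sheet.select(cell_line="F1", timepoint="D0")
        a = pd.DataFrame(0.0, index=["g"], columns=design_sheet.sample_ids)
        b = a.copy()
        a.loc["g", sids] = [10, 20, 30]
        b.loc["g", sids] = [30, 10, 20]
        assert (
            line_means(a, design_sheet, timepoint="D0").at["g", "F1"]
            == line_means(b, design_sheet, timepoint="D0").at["g", "F1"]
        )


class TestWithinSexCV:
    def test_constant_lines_have_zero_cv(self):
        lm = pd.DataFrame({"F1": [100.0], "F2": [100.0], "F3": [100.0]})
        assert within_sex_cv(lm).iloc[0] == 0.0

    def test_hand_computation_passes_threshold(self):
        # (50, 100, 150): population sd = sqrt(5000/3) = 40.82 -> cv 0.408
        lm = pd.DataFrame({"F1": [50.0], "F2": [100.0], "F3": [150.0]})
        assert within_sex_cv(lm).iloc[0] == pytest.approx(0.40825, abs=1e-4)

    def test_hand_computation_fails_threshold(self):
        # (10, 100, 190) -> cv ~ 0.735, above the 0.5 cutoff
        lm = pd.DataFrame({"F1": [10.0], "F2": [100.0], "F3": [190.0]})
        assert within_sex_cv(lm).iloc[0] == pytest.approx(0.7348, abs=1e-3)

    def test_uniformly_silent_gene_has_zero_cv(self):
        """All-zero line means are consistent non-expression (Y genes in XX
        lines must not be discarded by the CV rule)."""
        lm = pd.DataFrame({"F1": [0.0], "F2": [0.0], "F3": [0.0]})
        assert within_sex_cv(lm).iloc[0] == 0.0

    def test_requires_two_lines(self):
        with pytest.raises(ValueError):
            within_sex_cv(pd.DataFrame({"F1": [1.0]}))


class TestAllPairwiseRule:
    def _frames(self, xx, xy):
        return (
            pd.DataFrame([xx], columns=["F1", "F2", "F3"]),
            pd.DataFrame([xy], columns=["M1", "M2", "M3"]),
        )

    def test_clear_separation_passes(self):
        # worst pair (120, 200): d = 80/200 = 0.40
        ok, min_obs = all_pairwise_rule(*self._frames([100, 110, 120], [200, 210, 220]))
        assert ok.iloc[0]
        assert min_obs.iloc[0] == pytest.approx(0.40)

    def test_one_close_pair_fails(self):
        # pair (120, 130): d = 10/130 ~ 0.077
        ok, min_obs = all_pairwise_rule(*self._frames([100, 110, 120], [130, 210, 220]))
        assert not ok.iloc[0]
        assert min_obs.iloc[0] == pytest.approx(10 / 130, abs=1e-6)

    def test_identical_groups_fail(self):
        ok, min_obs = all_pairwise_rule(*self._frames([100, 100, 100], [100, 100, 100]))
        assert not ok.iloc[0]
        assert min_obs.iloc[0] == 0.0

    def test_sign_must_be_consistent(self):
        # large diffs but one XX line sits above one XY line
        ok, _ = all_pairwise_rule(*self._frames([100, 100, 400], [200, 210, 220]))
        assert not ok.iloc[0]

    def test_zero_pair_counts_as_zero_difference(self):
        ok, min_obs = all_pairwise_rule(*self._frames([0, 0, 0], [0, 0, 0]))
        assert not ok.iloc[0]
        assert min_obs.iloc[0] == 0.0


@pytest.fixture(scope="module")
def filtered_sim():
    cfg = SimulationConfig(
        n_autosomal=400, n_x=40, n_y=10, n_gametolog_pairs=3,
        n_planted_sexbiased=20, seed=10,
    )
    cm, truth = simulate(cfg)
    norm = normalize(cm)
    de = sex_contrast(norm, "D37")
    return cm, truth, norm, de


class TestStringentFilter:
    def test_matches_brute_force_oracle(self, filtered_sim):
        cm, _, norm, de = filtered_sim
        fast = stringent_filter(de, norm, cm.genes, "D37")["gene_id"].tolist()
        slow = brute_force_filter(de, norm, cm.genes, "D37")
        assert sorted(fast) == sorted(slow)

    def test_output_sorted_by_padj(self, filtered_sim):
        cm, _, norm, de = filtered_sim
        rec = stringent_filter(de, norm, cm.genes, "D37")
        assert rec["padj"].is_monotonic_increasing

    def test_y_genes_only_male_up(self, filtered_sim):
        cm, _, norm, de = filtered_sim
        rec = stringent_filter(de, norm, cm.genes, "D37")
        y = rec[rec["chrom_class"] == "Y"]
        assert len(y) > 0
        assert (y["direction"] == "male_up").all()

    def test_monotone_in_thresholds(self, filtered_sim):
        """Relaxing any single threshold never drops a retained gene."""
        cm, _, norm, de = filtered_sim
        base = set(stringent_filter(de, norm, cm.genes, "D37")["gene_id"])
        relaxed = [
            FilterConfig(min_count=25),
            FilterConfig(min_abs_log2fc=0.25),
            FilterConfig(max_padj=0.10),
            FilterConfig(max_cv=1.0),
            FilterConfig(min_pairwise_diff=0.10),
        ]
        for cfg in relaxed:
            wider = set(stringent_filter(de, norm, cm.genes, "D37", cfg)["gene_id"])
            assert base <= wider

    def test_wrong_contrast_rejected(self, filtered_sim):
        cm, _, norm, de = filtered_sim
        bad = de.assign(contrast="time_D37_vs_D0")
        with pytest.raises(ValueError, match="XX-vs-XY"):
            stringent_filter(bad, norm, cm.genes, "D37")

    def test_null_simulation_yields_almost_no_calls(self):
        cfg = SimulationConfig(n_autosomal=2000, n_x=0, n_y=0,
                               n_gametolog_pairs=0, seed=13)
        cm, _ = simulate(cfg)
        norm = normalize(cm)
        rec = stringent_filter(sex_contrast(norm, "D4"), norm, cm.genes, "D4")
        assert len(rec) <= 1


class TestTable2Summary:
    def test_empty_input_gives_empty_table(self):
        out = table2_summary(pd.DataFrame(columns=["timepoint", "direction", "chrom_class"]))
        assert out.empty

    def test_counts_by_class_and_direction(self):
        rec = pd.DataFrame(
            {
                "timepoint": ["D0"] * 3,
                "direction": ["male_up", "male_up", "female_up"],
                "chrom_class": ["Y", "autosomal", "X_escapee"],
            }
        )
        out = table2_summary(rec).set_index("direction")
        assert out.at["male_up", "total"] == 2
        assert out.at["female_up", "total"] == 1
        assert out.at["male_up", "chrY"] == 1
        assert out.at["female_up", "chrX_escapee"] == 1

    def test_totals_conserve_class_counts(self, filtered_sim):
        cm, _, norm, de = filtered_sim
        rec = stringent_filter(de, norm, cm.genes, "D37")
        out = table2_summary(rec)
        for row in out.itertuples(index=False):
            assert row.total == row.chrY + row.chrX + row.autosomal
        assert out["total"].sum() == len(rec)


class TestPairwiseDenominatorModes:
    def test_group_max_denominator_is_laxer_here(self):
        xx = pd.DataFrame([[100.0, 110.0, 120.0]], columns=["F1", "F2", "F3"])
        xy = pd.DataFrame([[130.0, 210.0, 220.0]], columns=["M1", "M2", "M3"])
        ok_pair, _ = all_pairwise_rule(xx, xy, 0.2, denominator="pair_max")
        ok_group, min_group = all_pairwise_rule(xx, xy, 0.2, denominator="group_max")
        assert not ok_pair.iloc[0]
        # worst pair (120, 130): |diff| 10 over the larger group mean 186.7
        assert min_group.iloc[0] == pytest.approx(10 / (560 / 3), abs=1e-9)

    def test_unknown_denominator_rejected(self):
        xx = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["F1", "F2", "F3"])
        with pytest.raises(ValueError, match="denominator"):
            all_pairwise_rule(xx, xx, 0.2, denominator="nope")
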