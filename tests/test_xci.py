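import numpy as np
import pandas as pd
import pytest

from sexbias.normalization import normalize
from sexbias.synthetic import SimulationConfig, simulate
from sexbias.xci import (
    XCIConfig,
    erosion_fraction,
    line_variance_ratio,
    x_to_a_ratio,
    xci_report,
    xx_xy_ratio,
)

from conftest import make_annotation


class TestXXXYRatio:
    def _tpm(self, design_sheet, xx_val, xy_val):
        mat = pd.DataFrame(np.nan, index=["g"], columns=design_sheet.sample_ids)
        mat.loc["g", design_sheet.select(sex="XX")] = xx_val
        mat.loc["g", design_sheet.select(sex="XY")] = xy_val
        return mat

    def test_pooled_ratio_value(self, design_sheet):
        ratios, _ = xx_xy_ratio(self._tpm(design_sheet, 22.0, 20.0), design_sheet)
        assert ratios.at["g", "ratio"] == pytest.approx(1.1)

    def test_boundary_ratio_is_not_above_threshold(self, design_sheet):
        """A ratio of exactly 1.1 sits at the boundary: strict > excludes it."""
        ratios, _ = xx_xy_ratio(self._tpm(design_sheet, 22.0, 20.0), design_sheet)
        thr = XCIConfig().ratio_threshold
        assert not (ratios["ratio"] > thr).iloc[0]

    def test_low_xy_expression_excluded_and_counted(self, design_sheet):
        mat = pd.concat(
            [
                self._tpm(design_sheet, 5.0, 0.5),   # below 1 TPM in XY
                self._tpm(design_sheet, 5.0, 5.0).set_axis(["h"]),
            ]
        )
        ratios, n_excl = xx_xy_ratio(mat, design_sheet, min_expression_tpm=1.0)
        assert n_excl == 1
        assert list(ratios.index) == ["h"]

    def test_per_line_mode_uses_pooled_xy_denominator(self, design_sheet):
        mat = self._tpm(design_sheet, 10.0, 10.0)
        mat.loc["g", design_sheet.select(cell_line="F1")] = 20.0
        ratios, _ = xx_xy_ratio(mat, design_sheet, mode="per_line")
        assert ratios.at["g", "F1"] == pytest.approx(2.0)
        assert ratios.at["g", "F2"] == pytest.approx(1.0)


class TestErosionFraction:
    def test_baseline_subtraction_arithmetic(self):
        """33% above threshold on X minus a 27% baseline leaves 6%."""
        x = pd.Series([1.5] * 33 + [1.0] * 67)
        base = pd.Series([1.5] * 27 + [1.0] * 73)
        res = erosion_fraction(x, base)
        assert res["frac_above_threshold"] == pytest.approx(0.33)
        assert res["baseline_frac"] == pytest.approx(0.27)
        assert res["erosion_attributable_frac"] == pytest.approx(0.06)
        assert res["n_attributable"] == 6

    def test_baseline_exceeding_x_clamps_to_zero(self):
        res = erosion_fraction(pd.Series([1.0] * 10), pd.Series([2.0] * 10))
        assert res["erosion_attributable_frac"] == 0.0

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.lognormal(0, 0.2, 200))
        base = pd.Series(rng.lognormal(0, 0.2, 300))
        a = erosion_fraction(x, base)
        b = erosion_fraction(x, base)  # ratios are scale-free by construction
        assert a == b

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            erosion_fraction(pd.Series([1.0]), pd.Series([], dtype=float))


class TestXToA:
    def _setup(self, design_sheet):
        genes = [f"x{i}" for i in range(5)] + [f"a{i}" for i in range(10)]
        chroms = {g: "X" for g in genes[:5]}
        chroms.update({g: "5" if i < 5 else "16" for i, g in enumerate(genes[5:])})
        ann = make_annotation(genes, chroms)
        mat = pd.DataFrame(10.0, index=genes, columns=design_sheet.sample_ids)
        return ann, mat

    def test_balanced_dosage_gives_unity(self, design_sheet):
        ann, mat = self._setup(design_sheet)
        ratios, mean = x_to_a_ratio(mat, design_sheet, ann, "F1")
        assert mean == pytest.approx(1.0)

    def test_doubling_x_doubles_ratio(self, design_sheet):
        ann, mat = self._setup(design_sheet)
        mat.loc[[f"x{i}" for i in range(5)]] *= 2
        ratios, mean = x_to_a_ratio(mat, design_sheet, ann, "F1")
        assert mean == pytest.approx(2.0)

    def test_generator_x_dosage_recovered(self):
        """XX X-dosage set to 0.55 of autosomal -> X:A near 0.55."""
        cfg = SimulationConfig(n_autosomal=1000, n_x=300, n_y=0, n_gametolog_pairs=0,
                               frac_escapee=0.0, x_dosage_xx=0.55,
                               sexes=("XX",), seed=15)
        cm, _ = simulate(cfg)
        tpm_mat = normalize(cm).tpm()
        _, mean = x_to_a_ratio(tpm_mat, cm.samples, cm.genes, "F1")
        assert mean == pytest.approx(0.55, abs=0.05)


class TestLineVariance:
    def _expr(self, design_sheet, line_levels):
        genes = [f"x{i}" for i in range(4)]
        ann = make_annotation(genes, {g: "X" for g in genes})
        mat = pd.DataFrame(np.nan, index=genes, columns=design_sheet.sample_ids)
        for line, level in line_levels.items():
            mat.loc[:, design_sheet.select(cell_line=line)] = level
        return ann, mat

    def test_sample_variance_hand_computation(self, design_sheet):
        # XX line averages (10, 12, 14): sample variance (n-1) = 4
        ann, mat = self._expr(
            design_sheet,
            {"F1": 10.0, "F2": 12.0, "F3": 14.0, "M1": 10.0, "M2": 20.0, "M3": 30.0},
        )
        res = line_variance_ratio(mat, design_sheet, ann)
        assert res["var_xx"] == pytest.approx(4.0)
        assert res["var_xy"] == pytest.approx(100.0)
        assert res["variance_ratio_xy_over_xx"] == pytest.approx(25.0)

    def test_identical_lines_have_zero_variance(self, design_sheet):
        ann, mat = self._expr(
            design_sheet,
            {"F1": 10.0, "F2": 10.0, "F3": 10.0, "M1": 5.0, "M2": 6.0, "M3": 7.0},
        )
        assert line_variance_ratio(mat, design_sheet, ann)["var_xx"] == 0.0

    def test_permuting_line_labels_within_sex_preserves_variance(self, design_sheet):
        ann, mat = self._expr(
            design_sheet,
            {"F1": 10.0, "F2": 12.0, "F3": 14.0, "M1": 1.0, "M2": 2.0, "M3": 3.0},
        )
        res_a = line_variance_ratio(mat, design_sheet, ann)
        ann_b, mat_b = self._expr(
            design_sheet,
            {"F1": 14.0, "F2": 10.0, "F3": 12.0, "M1": 3.0, "M2": 1.0, "M3": 2.0},
        )
        res_b = line_variance_ratio(mat_b, design_sheet, ann_b)
        assert res_a["var_xx"] == pytest.approx(res_b["var_xx"])
        assert res_a["var_xy"] == pytest.approx(res_b["var_xy"])


class TestXCIReport:
    def test_escapees_never_contribute_to_erosion_fraction(self, small_sim):
        cm, truth, norm = small_sim
        rep = xci_report(norm.tpm(), cm.samples, cm.genes)
        esc = set(cm.genes.escapees())
        flagged = set(rep.gene_ratios.index[rep.gene_ratios["possibly_eroded"]])
        assert not (flagged & esc)

    def test_frac_above_complements_frac_at_or_below(self, small_sim):
        cm, truth, norm = small_sim
        rep = xci_report(norm.tpm(), cm.samples, cm.genes)
        row = rep.line_summary.iloc[0]
        assert 0.0 <= row.frac_above_threshold <= 1.0
        assert row.erosion_attributable_frac <= row.frac_above_threshold + 1e-12

    def test_recovery_monotone_in_generating_erosion(self):
        """Recovered attributable fraction rises with the planted one."""
        recovered = []
        for e in (0.0, 0.1, 0.2):
            cfg = SimulationConfig(
                n_autosomal=600, n_x=300, n_y=0, n_gametolog_pairs=0,
                erosion_fraction_per_line={"F1": e, "F2": e, "F3": e},
                seed=21,
            )
            cm, _ = simulate(cfg, autosomes=("5", "16"))
            rep = xci_report(normalize(cm).tpm(), cm.samples, cm.genes)
            pooled = rep.line_summary[rep.line_summary.line == "pooled"].iloc[0]
            recovered.append(pooled.erosion_attributable_frac)
        assert recovered[0] < recovered[1] < recovered[2]


class TestBaselineModes:
    def test_mean_shift_mode_recentres_ratios(self):
        cfg = XCIConfig(baseline_mode="mean_shift")
        # baseline mean 1.2 deflates X ratios; only the 1.5 genes survive
        x = pd.Series([1.5] * 10 + [1.2] * 90)
        base = pd.Series([1.2] * 100)
        res = erosion_fraction(x, base, cfg)
        assert res["erosion_attributable_frac"] == pytest.approx(0.10)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="baseline_mode"):
            erosion_fraction(
                pd.Series([1.0]), pd.Series([1.0]), XCIConfig(baseline_mode="nope")
            )
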