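"""Negative-binomial differential expression: normalisation, Wald test, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from xtalk.deg import NegativeBinomialDE, deg_all, size_factors
from xtalk.deg import test_gene as nb_wald_test
from xtalk.errors import DesignError, MissingGroupError
from xtalk.io import CountMatrix, SampleSheet


def _sheet(n_chow, n_hfd, tissue="liver", time=6):
    rows = []
    for i in range(n_chow):
        rows.append((f"c{i}", f"ac{i}", tissue, "chow", time))
    for i in range(n_hfd):
        rows.append((f"h{i}", f"ah{i}", tissue, "HFD", time))
    return SampleSheet(
        pd.DataFrame(
            rows, columns=["sample_id", "animal_id", "tissue", "diet", "time_weeks"]
        )
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        frame = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20]}, index=list("abc"))
        assert np.allclose(size_factors(frame), 1.0)

    def test_doubled_library(self):
        # column 2 = 2 x column 1: geometric mean per gene is c*sqrt(2), so
        # the median ratios are 1/sqrt(2) and sqrt(2) — ratio exactly 2 and
        # geometric mean exactly 1
        frame = pd.DataFrame({"s1": [4, 10, 7], "s2": [8, 20, 14]}, index=list("abc"))
        sf = size_factors(frame)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert math.prod(sf) ** (1 / 2) == pytest.approx(1.0)

    def test_single_sample_unit_factor(self):
        frame = pd.DataFrame({"s1": [3, 9, 27]}, index=list("abc"))
        assert size_factors(frame)["s1"] == pytest.approx(1.0)

    def test_no_all_positive_gene_rejected(self):
        frame = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=list("ab"))
        with pytest.raises(DesignError):
            size_factors(frame)


class TestTestGene:
    def test_identical_groups_null(self):
        lfc, p = nb_wald_test([10, 11, 9, 10], [10, 11, 9, 10])
        assert lfc == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_fourfold_change(self):
        lfc, p = nb_wald_test([10, 10, 10, 10], [40, 40, 40, 40])
        assert lfc == pytest.approx(2.0, abs=0.1)  # pseudo-count effect < 0.1
        assert p < 0.01

    def test_all_zero_gene_flagged_not_raised(self):
        lfc, p = nb_wald_test([0, 0, 0], [0, 0, 0])
        assert (lfc, p) == (0.0, 1.0)

    def test_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(30, 6)
        b = rng.poisson(80, 15)
        lfc_ab, p_ab = nb_wald_test(a, b)
        lfc_ba, p_ba = nb_wald_test(b, a)
        assert lfc_ba == pytest.approx(-lfc_ab, abs=1e-9)
        assert p_ba == pytest.approx(p_ab, rel=1e-6)

    def test_matches_statsmodels_glm(self):
        """IRLS coefficients and SE agree with an independent GLM fit."""
        sm = pytest.importorskip("statsmodels.api")
        from xtalk.deg import _moments_dispersion, _nb_irls

        rng = np.random.default_rng(8)
        a = rng.poisson(50, 8).astype(float)
        b = rng.poisson(120, 8).astype(float)
        phi = _moments_dispersion([a, b], 1e-8)
        y = np.concatenate([a, b])
        grp = np.concatenate([np.zeros(8), np.ones(8)])
        beta, cov = _nb_irls(y, grp, phi)
        X = np.column_stack([np.ones(16), grp])
        fit = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=phi)
        ).fit()
        assert beta == pytest.approx(fit.params, rel=1e-5)
        assert math.sqrt(cov[1, 1]) == pytest.approx(fit.bse[1], rel=1e-4)


class TestDegAll:
    def test_empty_gene_list_gives_empty_table(self):
        sheet = _sheet(2, 2)
        cm = CountMatrix(
            pd.DataFrame(
                np.empty((0, 4), dtype=np.int64),
                index=pd.Index([], name="gene_id"),
                columns=sheet.frame["sample_id"],
            )
        )
        table = deg_all(cm, sheet)
        assert len(table) == 0

    def test_missing_diet_cell_rejected(self):
        sheet = _sheet(2, 0)
        cm = CountMatrix(
            pd.DataFrame(
                {"c0": [5, 6], "c1": [7, 8]}, index=["g1", "g2"]
            )
        )
        with pytest.raises(MissingGroupError):
            deg_all(cm, sheet)

    def test_sample_scaling_moves_relative_size_factor(self, toy_counts):
        """Scaling one sample's counts by c scales its size factor by c
        relative to every other sample (the median-of-ratios reference makes
        only factor ratios identifiable)."""
        frame, _ = toy_counts
        scaled = frame.copy()
        scaled["s3"] = scaled["s3"] * 5
        sf_base = size_factors(frame)
        sf_scaled = size_factors(scaled)
        for other in ("s1", "s2", "s4"):
            ratio_base = sf_base["s3"] / sf_base[other]
            ratio_scaled = sf_scaled["s3"] / sf_scaled[other]
            assert ratio_scaled == pytest.approx(5.0 * ratio_base)

    def test_matched_factor_scaling_exactly_invariant(self):
        """Scaling a sample's counts together with its size factor leaves
        (log2fc, p) exactly unchanged: the model sees normalised counts."""
        a = np.array([10, 12, 9, 11])
        b = np.array([40, 44, 39, 42])
        fa = np.ones(4)
        fb = np.ones(4)
        base = nb_wald_test(a, b, fa, fb)
        a2, fa2 = a.copy(), fa.copy()
        a2[0] *= 7
        fa2[0] *= 7
        scaled = nb_wald_test(a2, b, fa2, fb)
        assert scaled == base

    def test_planted_regulators_recovered(self, small_study):
        """Substantially shifted planted cells are flagged; background is calibrated."""
        table = deg_all(small_study.liver, small_study.sheet, deg_p=0.01)
        truth = small_study.truth
        lat_h = small_study.latent[("liver", "HFD")]
        lat_c = small_study.latent[("liver", "chow")]
        shift = (lat_h - lat_c).abs()
        flagged = table.set_index(["gene_id", "time_weeks"])["significant"]
        strong = [
            (g, t)
            for g in truth.source_genes
            for t in lat_h.columns
            if shift.loc[g, t] >= 1.0
        ]
        power = np.mean([flagged[cell] for cell in strong])
        assert power >= 0.9
        background = table[table["gene_id"].str.startswith("LB")]
        false_rate = background["significant"].mean()
        assert false_rate < 0.05  # loose bound around the 0.01 gate

    def test_estimator_api(self, toy_counts):
        frame, sheet_df = toy_counts
        est = NegativeBinomialDE(alpha=0.05)
        assert est.get_params()["alpha"] == 0.05
        est.fit(CountMatrix(frame), SampleSheet(sheet_df))
        assert set(est.results_["gene_id"]) == {"g1", "g2", "g3"}
        assert (est.results_["significant"] == (est.results_["p_value"] < 0.05)).all()
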