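"""Statistical layer: correlation, regression, agreement, tests, summaries."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from wristqct import (bland_altman, build_report, mann_whitney_u,
                      make_cohort, pearson_with_ci, shapiro_wilk,
                      simple_regression, summarize)
from wristqct.cohort_stats import summarize_column


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        r, _, p = pearson_with_ci(x, x)
        assert r == 1.0 and p < 1e-12
        r, _, _ = pearson_with_ci(x, -x)
        assert r == -1.0

    def test_hand_computed_example(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        r, (lo, hi), p = pearson_with_ci(x, y)
        assert r == pytest.approx(0.6)
        # stated formulas
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        assert p == pytest.approx(2 * sps.t.sf(t, 2))
        z = np.arctanh(0.6)
        assert lo == pytest.approx(np.tanh(z - 1.959964 / 1.0), abs=1e-4)
        # permutation oracle for the p-value's rank at n=4
        perms = [np.corrcoef(np.array(x)[list(pm)], y)[0, 1]
                 for pm in __import__("itertools").permutations(range(4))]
        frac_as_extreme = np.mean(np.abs(perms) >= 0.6 - 1e-12)
        assert 0 < frac_as_extreme < 1  # 0.6 is neither min nor max rank

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_row_permutation_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert pearson_with_ci(x, y)[0] == pytest.approx(
            pearson_with_ci(x[perm], y[perm])[0])


class TestRegression:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 10)
        slope, inter, r2 = simple_regression(x, 2 * x + 1)
        assert (slope, inter, r2) == (pytest.approx(2.0), pytest.approx(1.0),
                                      pytest.approx(1.0))

    def test_r2_equals_r_squared(self, rng):
        for _ in range(100):
            x = rng.normal(size=15)
            y = rng.normal(size=15) + 0.5 * x
            _, _, r2 = simple_regression(x, y)
            r, _, _ = pearson_with_ci(x, y)
            assert abs(r2 - r**2) < 1e-12

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            simple_regression([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identity_and_offset(self):
        x = np.arange(5.0)
        md, (lo, hi) = bland_altman(x, x)
        assert md == 0.0 and lo == 0.0 and hi == 0.0
        md, (lo, hi) = bland_altman(x + 0.84, x)
        assert md == pytest.approx(0.84) and lo == pytest.approx(0.84)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert bland_altman(x, y)[0] == pytest.approx(-bland_altman(y, x)[0])


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_swap_symmetry(self):
        x, y = [1.0, 5.0, 2.5, 7.0], [3.0, 4.0, 6.0]
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == len(x) * len(y)

    def test_identical_samples_no_evidence(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_exact_type_one_error_bounded(self):
        """Under the permutation null (exhaustive, n=m=3) the exact test
        rejects at alpha no more than alpha of the time."""
        pooled = [1.1, 2.3, 3.7, 4.2, 5.9, 6.4]
        alpha = 0.1
        rejections = 0
        total = comb(6, 3)
        for picks in combinations(range(6), 3):
            x = [pooled[i] for i in picks]
            y = [pooled[i] for i in range(6) if i not in picks]
            _, p = mann_whitney_u(x, y)
            rejections += p <= alpha
        assert rejections / total <= alpha + 1e-12

    def test_matches_scipy_large_sample(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1.0, size=25)
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-6)


class TestShapiroWilk:
    def test_near_normal_grid_high_w(self):
        x = sps.norm.ppf(np.linspace(0.02, 0.98, 30))
        w, p = shapiro_wilk(x)
        assert w > 0.98

    def test_bimodal_rejected(self):
        x = np.r_[np.zeros(25), np.ones(25)] + np.linspace(0, 1e-6, 50)
        w, p = shapiro_wilk(x)
        assert p < 0.01

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            x = rng.normal(size=n)
            w, p = shapiro_wilk(x)
            ref = sps.shapiro(x)
            assert abs(w - ref.statistic) < 1e-4
            assert abs(p - ref.pvalue) < 1e-4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])


class TestSummaries:
    def test_normal_column_mean_sd(self, rng):
        s = summarize_column(rng.normal(10, 2, size=60))
        assert s["style"] == "mean_sd"
        assert "±" in s["text"]

    def test_lognormal_column_median_iqr(self, rng):
        s = summarize_column(np.exp(rng.normal(0, 1.2, size=50)))
        assert s["style"] == "median_iqr"
        assert "[" in s["text"]

    def test_constant_column_skipped_in_table(self):
        df = pd.DataFrame({"sex": ["F"] * 4 + ["M"] * 4,
                           "ok": [1.0, 2, 3, 4, 5, 6, 7, 8],
                           "flat": [1.0] * 8})
        out = summarize(df)
        assert out["flat"]["Total"]["style"] == "skipped"
        assert out["ok"]["Total"]["style"] in ("mean_sd", "median_iqr")
        assert set(out["ok"]) == {"Total", "F", "M"}


class TestReport:
    def _table(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        cols = ["BMD_DXA", "BMC_DXA", "BMD_CBCT_whole", "BMD_CBCT_cort",
                "BMC_CBCT_whole", "BMC_CBCT_cort", "Stiffness", "Strength",
                "Fmax", "BVTV_trab", "Tb_Th", "Tb_Sc", "Tb_Nd", "C_Th", "TBV"]
        base = rng.normal(size=n)
        data = {c: base + rng.normal(scale=0.8, size=n) for c in cols}
        data["sex"] = rng.choice(["F", "M"], size=n)
        data["subject_id"] = [f"S{i}" for i in range(n)]
        return pd.DataFrame(data)

    def test_cell_count_matches_published_layout(self):
        rep = build_report(self._table())
        assert rep.n_cells() == 8 + 12 + 30

    def test_missing_column_marked_na(self):
        table = self._table().drop(columns=["Fmax"])
        rep = build_report(table)
        assert "Fmax" in rep.missing_columns
        cell = rep.cell("fe_vs_mineral", "BMC_CBCT_whole", "Fmax")
        assert cell["text"] == "NA"

    def test_zero_variance_column_na(self):
        table = self._table()
        table["Stiffness"] = 7.0
        rep = build_report(table)
        cell = rep.cell("fe_vs_mineral", "BMC_CBCT_whole", "Stiffness")
        assert cell.get("na") and "zero variance" in cell["reason"]

    def test_known_correlation_recovered(self):
        """Cohort built with population r = 0.9 between true BMC and the
        stiffness surrogate: at n = 200 the estimate lands in (0.86, 0.93)."""
        _, t = make_cohort(200, seed=77)
        r, _, _ = pearson_with_ci(t.true_bmc_g, t.stiffness_surrogate_N_per_mm)
        assert 0.86 < r < 0.93

    def test_markdown_and_json_roundtrip(self, tmp_path):
        rep = build_report(self._table())
        md = rep.to_markdown()
        assert "fe_vs_microstructure" in md
        rep.to_json(tmp_path / "rep.json")
        assert (tmp_path / "rep.json").stat().st_size > 100
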