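"""Voxelwise GLM group inference, clustering, permutation correction and the
demographic-table statistics."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from assomap.data_io import PhenotypeRecord, VoxelMap
from assomap.group_inference import (
    DesignMatrix,
    build_design,
    chi_square_2x2,
    cluster_extract,
    demographics_table,
    permutation_cluster_correction,
    summary_ttest,
    voxelwise_glm_ttest,
)


def _maps(values_list, mask, affine=None):
    aff = affine if affine is not None else np.diag([3.0, 3, 3, 1])
    return [VoxelMap(values=v, affine=aff, kind="asso_z", mask=mask)
            for v in values_list]


def _group_design(groups):
    n = len(groups)
    X = np.column_stack([np.ones(n), np.array(groups, dtype=float)])
    return DesignMatrix(X=X, columns=["intercept", "group"])


class TestVoxelwiseGlm:
    def test_equals_pooled_two_sample_t_without_covariates(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        groups = [1] * 10 + [0] * 12
        values = [rng.standard_normal((5, 5, 5)) + 0.3 * g for g in groups]
        stat = voxelwise_glm_ttest(_maps(values, mask), _group_design(groups))
        assert stat.df == 20
        y = np.stack([v[mask] for v in values])
        g = np.array(groups, dtype=bool)
        t_ref, _ = sp_stats.ttest_ind(y[g], y[~g], axis=0, equal_var=True)
        np.testing.assert_allclose(stat.values[mask], t_ref, atol=1e-8)

    def test_balanced_identical_groups_give_zero_t(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        base = [rng.standard_normal((4, 4, 4)) for _ in range(6)]
        values = base + [b.copy() for b in base]  # identical group means
        groups = [1] * 6 + [0] * 6
        stat = voxelwise_glm_ttest(_maps(values, mask), _group_design(groups))
        np.testing.assert_allclose(stat.values[mask], 0.0, atol=1e-10)

    def test_coefficients_match_normal_equations(self, rng):
        # 8-subject fixture with covariates against the explicit
        # (X'X)^{-1} X'y solution
        phen = [
            PhenotypeRecord(f"s{i}", "AD" if i < 4 else "HC",
                            60.0 + i, "M" if i % 2 else "F", 10.0 + (i % 3),
                            20, 20)
            for i in range(8)
        ]
        design = build_design(phen)
        y = rng.standard_normal(8)
        beta_ref = np.linalg.inv(design.X.T @ design.X) @ design.X.T @ y
        mask = np.ones((1, 1, 1), dtype=bool)
        maps = _maps([np.full((1, 1, 1), yi) for yi in y], mask)
        stat = voxelwise_glm_ttest(maps, design)
        resid = y - design.X @ beta_ref
        sigma2 = resid @ resid / (8 - design.p)
        se = np.sqrt(sigma2 * np.linalg.inv(design.X.T @ design.X)[1, 1])
        np.testing.assert_allclose(stat.values[0, 0, 0], beta_ref[1] / se,
                                   atol=1e-10)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        phen = [
            PhenotypeRecord(f"s{i}", "AD" if i < 10 else "HC",
                            float(rng.normal(68, 6)), "M" if rng.random() < 0.5 else "F",
                            float(rng.normal(11, 3)), 22, 22)
            for i in range(22)
        ]
        design = build_design(phen)
        y = rng.standard_normal(22)
        fit = sm.OLS(y, design.X).fit()
        mask = np.ones((1, 1, 1), dtype=bool)
        stat = voxelwise_glm_ttest(
            _maps([np.full((1, 1, 1), yi) for yi in y], mask), design
        )
        np.testing.assert_allclose(stat.values[0, 0, 0], fit.tvalues[1],
                                   atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0], [2, 2, 2, 0, 0, 0]])
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(X=X, columns=["intercept", "group", "group2"])


class TestClusterExtract:
    def _stat(self, tvol, mask, df=30):
        from assomap.group_inference import StatMap

        return StatMap(values=tvol, df=df, contrast="group",
                       affine=np.diag([3.0, 3, 3, 1]), mask=mask)

    def test_single_voxel_cluster_coordinates(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        tvol = np.zeros((5, 5, 5))
        tvol[2, 3, 1] = 10.0
        table = cluster_extract(self._stat(tvol, mask))
        assert len(table.clusters) == 1
        c = table.clusters[0]
        assert c.extent == 1
        assert c.tail == "pos"
        np.testing.assert_allclose(c.peak_mm, (6.0, 9.0, 3.0))

    def test_face_neighbours_merge_at_all_connectivities(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        tvol = np.zeros((5, 5, 5))
        tvol[2, 2, 2] = tvol[2, 2, 3] = 10.0
        for conn in (6, 18, 26):
            table = cluster_extract(self._stat(tvol, mask), connectivity=conn)
            assert len(table.clusters) == 1

    def test_corner_neighbours_split_at_18_join_at_26(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        tvol = np.zeros((5, 5, 5))
        tvol[1, 1, 1] = tvol[2, 2, 2] = 10.0  # share only a corner
        assert len(cluster_extract(self._stat(tvol, mask),
                                   connectivity=18).clusters) == 2
        assert len(cluster_extract(self._stat(tvol, mask),
                                   connectivity=26).clusters) == 1

    def test_tails_labelled_separately(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        tvol = np.zeros((5, 5, 5))
        tvol[1, 1, 1] = 10.0
        tvol[1, 1, 2] = -10.0
        table = cluster_extract(self._stat(tvol, mask))
        assert sorted(c.tail for c in table.clusters) == ["neg", "pos"]

    def test_translation_moves_peaks_not_extents(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        tvol = np.zeros((5, 5, 5))
        tvol[2, 2, 2] = 8.0
        aff1 = np.diag([3.0, 3, 3, 1])
        aff2 = aff1.copy()
        aff2[:3, 3] = [10.0, -5.0, 2.0]
        from assomap.group_inference import StatMap

        t1 = cluster_extract(StatMap(tvol, 30, "g", aff1, mask))
        t2 = cluster_extract(StatMap(tvol, 30, "g", aff2, mask))
        assert t1.clusters[0].extent == t2.clusters[0].extent
        np.testing.assert_allclose(
            np.array(t2.clusters[0].peak_mm) - np.array(t1.clusters[0].peak_mm),
            [10.0, -5.0, 2.0],
        )


class TestPermutationCorrection:
    def test_strong_effect_hits_estimator_floor(self, rng):
        mask = np.ones((6, 6, 6), dtype=bool)
        groups = [1] * 10 + [0] * 10
        values = []
        for g in groups:
            v = rng.standard_normal((6, 6, 6))
            v[1:4, 1:4, 1:4] += 6.0 * g  # huge planted block
            values.append(v)
        stat, table = permutation_cluster_correction(
            _maps(values, mask), _group_design(groups), n_perm=100, seed=3
        )
        big = table.clusters[0]
        assert big.extent >= 27
        assert big.corrected_p == pytest.approx(1.0 / 101.0)

    def test_fixed_seed_reproducible(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        groups = [1] * 8 + [0] * 8
        values = [rng.standard_normal((5, 5, 5)) for _ in groups]
        maps = _maps(values, mask)
        d = _group_design(groups)
        _, t1 = permutation_cluster_correction(maps, d, n_perm=100, seed=9)
        _, t2 = permutation_cluster_correction(maps, d, n_perm=100, seed=9)
        np.testing.assert_array_equal(t1.null_max_extent, t2.null_max_extent)

    def test_too_few_permutations_warns(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        groups = [1] * 6 + [0] * 6
        maps = _maps([rng.standard_normal((4, 4, 4)) for _ in groups], mask)
        with pytest.warns(UserWarning, match="cannot resolve"):
            permutation_cluster_correction(maps, _group_design(groups),
                                           n_perm=100, cluster_p=0.005, seed=1)


class TestSummaryTtest:
    def test_education_row(self):
        t, df, p = summary_ttest(10.84, 3.11, 36, 11.62, 3.32, 42)
        assert df == 76
        assert round(p, 2) == 0.29

    def test_equal_means(self):
        t, df, p = summary_ttest(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_mmse_row_pooled_formula(self):
        # independent oracle: explicit pooled-variance arithmetic
        sp2 = (35 * 3.36**2 + 41 * 1.43**2) / 76
        t_ref = (21.3 - 28.24) / np.sqrt(sp2 * (1 / 36 + 1 / 42))
        t, df, p = summary_ttest(21.3, 3.36, 36, 28.24, 1.43, 42)
        assert df == 76
        assert t == pytest.approx(t_ref)
        assert t == pytest.approx(-12.2, abs=0.1)


class TestChiSquare:
    def test_balanced_table(self):
        chi2, p = chi_square_2x2(10, 10, 10, 10)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_gender_table_expected_counts(self):
        # hand-computed expected counts 17.08/18.92/19.92/22.08
        a, b, c, d = 21, 15, 16, 26
        n = a + b + c + d
        exp = np.array([
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ])
        np.testing.assert_allclose(exp, [17.077, 18.923, 19.923, 22.077],
                                   atol=1e-3)
        chi2_ref = (((np.array([a, b, c, d]) - exp) ** 2) / exp).sum()
        chi2, p = chi_square_2x2(a, b, c, d)
        assert chi2 == pytest.approx(chi2_ref)
        # cross-check against scipy without continuity correction
        chi2_sp, p_sp, _, _ = sp_stats.chi2_contingency(
            [[a, b], [c, d]], correction=False
        )
        assert chi2 == pytest.approx(chi2_sp)
        assert p == pytest.approx(p_sp)

    def test_doubling_cells_doubles_statistic(self):
        chi2, _ = chi_square_2x2(12, 8, 7, 13)
        chi2x2, _ = chi_square_2x2(24, 16, 14, 26)
        assert chi2x2 == pytest.approx(2 * chi2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)


def test_demographics_table_shape(demo_phenotypes):
    table = demographics_table(demo_phenotypes)
    assert list(table["variable"]) == ["age", "education", "mmse", "moca",
                                       "sex(M:F)"]
    assert (table["p"] <= 1.0).all() and (table["p"] >= 0.0).all()
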