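import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fcnet.cohort import CohortSpec, generate_cohort, records_to_frame
from fcnet.connectome import DensityGrid, binarize_at_density, compute_fc
from fcnet.inference import (
    build_design,
    chi_square_2x2,
    cohens_d,
    compare_global_aucs,
    demographics_table,
    fdr_bh,
    glm_group_test,
    mann_whitney,
    spearman_corr,
    two_sample_t_from_summary,
)
from fcnet.metrics import clustering_coefficient, metric_auc
from tests._oracles import bh_stepup, exact_mannwhitney_p, pooled_t


def design_of(groups, **covs):
    cols = {"intercept": np.ones(len(groups)), "group": np.asarray(groups, dtype=float)}
    cols.update({k: np.asarray(v, dtype=float) for k, v in covs.items()})
    return pd.DataFrame(cols)


class TestGLMGroupTest:
    def test_identical_groups_give_null_result(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        t, p = glm_group_test(y, design_of([1, 1, 1, 0, 0, 0]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_reduces_to_pooled_two_sample_t(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = 12, 9
        y = rng.standard_normal(n1 + n2)
        g = np.array([1] * n1 + [0] * n2)
        t, _ = glm_group_test(y, design_of(g))
        assert t == pytest.approx(pooled_t(y[:n1], y[n1:]), abs=1e-10)

    def test_many_random_datasets_match_textbook_t(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(1000):
            n1, n2 = int(rng.integers(3, 10)), int(rng.integers(3, 10))
            y = rng.standard_normal(n1 + n2)
            g = np.array([1] * n1 + [0] * n2)
            t, _ = glm_group_test(y, design_of(g))
            worst = max(worst, abs(t - pooled_t(y[:n1], y[n1:])))
        assert worst < 1e-10

    def test_duplicated_covariate_is_named(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        d = design_of(np.repeat([1, 0], 10), a=x, b=x)
        with pytest.raises(ValueError, match="rank deficient"):
            glm_group_test(rng.standard_normal(20), d)

    def test_covariate_adjustment_removes_confounded_effect(self):
        rng = np.random.default_rng(2)
        g = np.repeat([1.0, 0.0], 30)
        conf = g * 2 + rng.standard_normal(60) * 0.1
        y = 3 * conf + rng.standard_normal(60)  # group effect only via confound
        t_raw, p_raw = glm_group_test(y, design_of(g))
        t_adj, p_adj = glm_group_test(y, design_of(g, conf=conf))
        assert abs(t_adj) < abs(t_raw)


class TestEffectSizeAndFDR:
    def test_cohens_d_unit_case(self):
        y = np.concatenate([np.array([0.0, 1.0, 2.0]) + 1, [0.0, 1.0, 2.0]])
        g = np.array(["a"] * 3 + ["b"] * 3)
        assert cohens_d(y, g) == pytest.approx(1.0)

    def test_cohens_d_zero_for_equal_means(self):
        y = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        assert cohens_d(y, np.repeat(["a", "b"], 3)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_cohens_d_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        y1, y2 = rng.standard_normal(8) + 0.5, rng.standard_normal(11)
        sp = np.sqrt((7 * y1.var(ddof=1) + 10 * y2.var(ddof=1)) / 17)
        d = cohens_d(np.concatenate([y1, y2]), np.array(["p"] * 8 + ["c"] * 11))
        assert d == pytest.approx((y1.mean() - y2.mean()) / sp, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.ones(6), np.repeat(["a", "b"], 3))

    def test_bh_stepup_worked_example(self):
        # largest k with p_(k) <= k * 0.05 / 4 is k = 4 -> all rejected
        rej, adj = fdr_bh([0.001, 0.012, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_bh_edge_cases(self):
        rej, _ = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not rej.any()
        rej, _ = fdr_bh([0.04], q=0.05)
        assert rej.all()
        with pytest.raises(ValueError, match="empty"):
            fdr_bh([])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.integers(0, 100))
    def test_bh_matches_stepup_oracle_and_never_beats_raw(self, pvals, _seed):
        rej, _ = fdr_bh(pvals, q=0.05)
        assert list(rej) == bh_stepup(pvals, 0.05)
        assert rej.sum() <= np.sum(np.asarray(pvals) < 0.05) + np.sum(np.asarray(pvals) == 0.05)


class TestClassicalTests:
    def test_spearman_perfect_monotone(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, _ = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_spearman_with_ties_matches_rank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            sv = v[order]
            k = 0
            while k < len(v):
                m = k
                while m + 1 < len(v) and sv[m + 1] == sv[k]:
                    m += 1
                ranks[order[k : m + 1]] = (k + m) / 2 + 1
                k = m + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_corr(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_spearman_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr(np.ones(5), np.arange(5.0))

    def test_summary_t_published_gmv_row(self):
        t, p = two_sample_t_from_summary(628.22, 52.79, 127, 652.47, 52.03, 102)
        assert t == pytest.approx(-3.476, abs=0.005)
        assert p < 0.001

    def test_summary_t_equal_means_and_scaling(self):
        t, _ = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0
        t1, _ = two_sample_t_from_summary(1.0, 1.0, 10, 0.0, 1.0, 10)
        t2, _ = two_sample_t_from_summary(1.0, 2.0, 10, 0.0, 2.0, 10)
        assert t2 == pytest.approx(t1 / 2)

    def test_chi_square_published_sex_table(self):
        chi2, p = chi_square_2x2([[103, 24], [76, 26]])
        assert chi2 == pytest.approx(1.441, abs=5e-4)
        assert p == pytest.approx(0.230, abs=5e-3)

    def test_chi_square_proportional_rows_and_oracle(self):
        chi2, _ = chi_square_2x2([[20, 10], [40, 20]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        obs = np.array([[13.0, 7.0], [9.0, 21.0]])
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        chi2, _ = chi_square_2x2(obs)
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-12)

    def test_chi_square_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_mannwhitney_symmetric_null(self):
        rng = np.random.default_rng(0)
        zs = [mann_whitney(rng.standard_normal(30), rng.standard_normal(30))[1] for _ in range(50)]
        assert abs(np.mean(zs)) < 0.3

    def test_mannwhitney_full_separation(self):
        x = np.arange(10.0, 15.0)
        y = np.arange(0.0, 5.0)
        u, z, p = mann_whitney(x, y)
        assert u == 25.0  # n1 * n2
        u2, z2, _ = mann_whitney(y, x)
        assert u2 == 25.0 or u2 == 0.0  # scipy reports U of the first sample
        assert z == -z2

    @pytest.mark.parametrize("seed", range(3))
    def test_mannwhitney_small_sample_exact_p(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(5), rng.standard_normal(6) + 0.5
        _, _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-10)


class TestDesignAndTables:
    def test_design_columns_and_rank(self, small_phenotype):
        d = build_design(small_phenotype)
        assert list(d.columns)[:2] == ["intercept", "group"]
        assert d["group"].sum() == 16
        assert np.linalg.matrix_rank(d.to_numpy(float)) == d.shape[1]

    def test_missing_covariate_column_is_reported(self, small_phenotype):
        with pytest.raises(ValueError, match="nonexistent"):
            build_design(small_phenotype, covariates=("nonexistent",))

    def test_demographics_table_layout(self, small_phenotype):
        tab = demographics_table(small_phenotype)
        assert "sex (female/male)" in tab["variable"].tolist()
        assert {"variable", "patients", "controls", "statistic", "value", "p"} <= set(tab.columns)
        gmv_row = tab[tab["variable"] == "gmv"].iloc[0]
        assert "±" in gmv_row["patients"]

    def test_global_auc_comparison_runs(self, small_phenotype):
        rng = np.random.default_rng(0)
        auc = pd.DataFrame(
            {"subject_id": small_phenotype["subject_id"], "cp": rng.standard_normal(32)}
        )
        design = build_design(small_phenotype)
        out = compare_global_aucs(auc, small_phenotype, design)
        assert set(out.columns) == {"metric", "t", "p", "cohens_d", "direction"}
        assert len(out) == 1


class TestNullCalibration:
    def test_global_auc_test_type_I_error_under_null(self):
        """With no planted effect and covariates independent of group, the
        covariate-adjusted group test on a global metric's AUC rejects at
        about the nominal 5% rate (clustering-coefficient AUC; small grids
        and cohorts keep the simulation cheap)."""
        grid = DensityGrid(0.2, 0.4, 0.1)
        rejections = 0
        n_cohorts = 200
        for k in range(n_cohorts):
            spec = CohortSpec(n_group1=10, n_group2=10, n_regions=20,
                              n_timepoints=60, seed=300_000 + k)
            records, series = generate_cohort(spec)
            pheno = records_to_frame(records)
            aucs = []
            for ts in series:
                fc = compute_fc(ts)
                cps = [clustering_coefficient(binarize_at_density(fc, float(d)))[0]
                       for d in grid.values]
                aucs.append(metric_auc(grid.values, cps))
            design = build_design(pheno, covariates=("education_years", "gmv"),
                                  include_medication=False)
            _, p = glm_group_test(np.array(aucs), design)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_cohorts <= 0.09
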