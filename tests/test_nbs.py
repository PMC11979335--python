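import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fcnet._utils import triu_pairs
from fcnet.cohort import CohortSpec, generate_cohort, records_to_frame
from fcnet.connectome import compute_fc, stack_fc
from fcnet.inference import build_design
from fcnet.nbs import (
    NetworkBasedStatistic,
    edgewise_stats,
    permutation_test,
    suprathreshold_components,
)
from tests._oracles import pooled_t
from tests.conftest import PLANTED_EDGES, planted_effect


def simple_design(groups):
    return pd.DataFrame({"intercept": np.ones(len(groups)), "group": np.asarray(groups, float)})


def pairs_for(n):
    i, j = triu_pairs(n)
    return np.stack([i, j], axis=1)


class TestEdgewiseStats:
    def test_constant_edge_has_zero_statistic(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 5))
        y[:, 2] = 0.7
        g = np.repeat([1, 0], 10)
        stats = edgewise_stats(y, simple_design(g))
        assert stats[2] == 0.0

    def test_matches_pooled_t_per_edge(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((24, 10))
        g = np.repeat([1, 0], 12)
        stats = edgewise_stats(y, simple_design(g), contrast="patient_gt_control")
        for e in range(10):
            assert stats[e] == pytest.approx(pooled_t(y[:12, e], y[12:, e]), abs=1e-10)

    def test_row_coupled_permutation_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((16, 8))
        g = np.repeat([1, 0], 8)
        cov = rng.standard_normal(16)
        d = pd.DataFrame({"intercept": np.ones(16), "group": g.astype(float), "c": cov})
        perm = rng.permutation(16)
        s1 = edgewise_stats(y, d)
        s2 = edgewise_stats(y[perm], d.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_single_group_rejected(self):
        y = np.random.default_rng(3).standard_normal((10, 4))
        with pytest.raises(ValueError, match="2 subjects per group"):
            edgewise_stats(y, simple_design(np.ones(10)))


class TestComponents:
    def test_empty_when_nothing_exceeds_threshold(self):
        stats = np.array([1.0, 2.0, 3.0])
        assert suprathreshold_components(stats, pairs_for(3), 3.5) == []

    def test_hand_traced_union_find(self):
        # kept edges (1,2), (2,3), (5,6) -> components of extent 2 and 1
        pairs = np.array([[1, 2], [2, 3], [5, 6], [0, 4]])
        stats = np.array([4.0, 4.0, 4.0, 1.0])
        comps = suprathreshold_components(stats, pairs, 3.5)
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].nodes == (1, 2, 3)
        assert comps[1].nodes == (5, 6)

    def test_chain_component_shape(self):
        # 11-edge chain over 12 nodes: one component, tree shape
        pairs = np.array([[k, k + 1] for k in range(11)])
        comps = suprathreshold_components(np.full(11, 5.0), pairs, 3.5)
        assert len(comps) == 1
        assert comps[0].extent == 11
        assert len(comps[0].nodes) == 12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_component_labelling(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        pairs = pairs_for(n)
        stats = rng.standard_normal(len(pairs)) * 3
        t0 = 2.0
        comps = suprathreshold_components(stats, pairs, t0)
        g = nx.Graph()
        for (i, j), s in zip(pairs, stats):
            if s > t0:
                g.add_edge(int(i), int(j))
        expected = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        got_nodes = sorted((len(c.nodes) for c in comps), reverse=True)
        assert got_nodes == expected
        assert sum(c.extent for c in comps) == g.number_of_edges()

    def test_monotone_pruning_in_threshold(self):
        rng = np.random.default_rng(20)
        pairs = pairs_for(10)
        stats = rng.standard_normal(len(pairs)) * 3
        prev = None
        for t0 in (1.0, 2.0, 3.0):
            comps = suprathreshold_components(stats, pairs, t0)
            biggest = max((c.extent for c in comps), default=0)
            if prev is not None:
                assert biggest <= prev
            prev = biggest

    def test_node_count_bounded_by_extent(self):
        rng = np.random.default_rng(21)
        pairs = pairs_for(15)
        for _ in range(20):
            stats = rng.standard_normal(len(pairs)) * 2.5
            for c in suprathreshold_components(stats, pairs, 2.0):
                assert len(c.nodes) <= c.extent + 1


@pytest.fixture(scope="module")
def effect_cohort():
    spec = CohortSpec(n_group1=20, n_group2=20, n_regions=30, n_timepoints=150,
                      effect=planted_effect(0.4), seed=77)
    records, series = generate_cohort(spec)
    pheno = records_to_frame(records)
    fcs = [compute_fc(ts) for ts in series]
    stack, eidx = stack_fc(fcs)
    return pheno, stack, eidx[["i", "j"]].to_numpy()


class TestPermutationTest:
    def test_recovers_planted_subnetwork(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        design = build_design(pheno)
        res = NetworkBasedStatistic(stack, design, pairs).fit(t0=3.5, n_perm=500, seed=1)
        sig = res.significant_components(0.05)
        assert sig, "planted effect not detected"
        found = {e for c in sig for e in c.edges}
        sensitivity = len(found & set(PLANTED_EDGES)) / len(PLANTED_EDGES)
        assert sensitivity >= 0.8

    def test_boundary_p_value_convention(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        design = build_design(pheno)
        res = NetworkBasedStatistic(stack, design, pairs).fit(t0=3.5, n_perm=500, seed=1)
        top = res.components[0]
        if (res.null_max_extents >= top.extent).sum() == 0:
            assert top.fwer_p == pytest.approx(1 / 501)
        assert all(1 / 501 <= c.fwer_p <= 1.0 for c in res.components)

    def test_fwer_p_monotone_in_extent(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        res = NetworkBasedStatistic(stack, build_design(pheno), pairs).fit(
            t0=2.5, n_perm=300, seed=2
        )
        extents = [c.extent for c in res.components]
        ps = [c.fwer_p for c in res.components]
        for a, b in zip(sorted(zip(extents, ps), reverse=True), sorted(zip(extents, ps), reverse=True)[1:]):
            assert a[1] <= b[1] or a[0] == b[0]

    def test_relabeling_regions_preserves_inference(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        design = build_design(pheno)
        rng = np.random.default_rng(5)
        perm = rng.permutation(30)
        # relabel regions: edge (i,j) -> (perm[i], perm[j]); stack order unchanged
        new_pairs = np.sort(perm[pairs], axis=1)
        r1 = permutation_test(stack, design, pairs, t0=3.5, n_perm=300, seed=3)
        r2 = permutation_test(stack, design, new_pairs, t0=3.5, n_perm=300, seed=3)
        assert [c.extent for c in r1.components] == [c.extent for c in r2.components]
        assert [c.fwer_p for c in r1.components] == [c.fwer_p for c in r2.components]

    def test_deterministic_given_seed(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        design = build_design(pheno)
        r1 = permutation_test(stack, design, pairs, t0=3.5, n_perm=200, seed=9)
        r2 = permutation_test(stack, design, pairs, t0=3.5, n_perm=200, seed=9)
        np.testing.assert_array_equal(r1.null_max_extents, r2.null_max_extents)

    def test_label_scheme_and_intensity_statistic_run(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        design = build_design(pheno, covariates=(), include_medication=False)
        res = permutation_test(stack, design, pairs, t0=3.5, n_perm=100, seed=4,
                               scheme="labels", component_stat="intensity")
        assert res.components and res.components[0].fwer_p < 0.05

    def test_too_few_permutations_rejected(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(stack, build_design(pheno), pairs, n_perm=10)

    def test_summary_mentions_components(self, effect_cohort):
        pheno, stack, pairs = effect_cohort
        res = NetworkBasedStatistic(stack, build_design(pheno), pairs).fit(
            t0=3.5, n_perm=200, seed=1
        )
        text = res.summary()
        assert "Network-based statistic" in text and "FWER" in text
        table = res.component_table([f"ROI{k + 1:03d}" for k in range(30)])
        assert {"component", "extent", "fwer_p", "region_i", "region_j", "t"} <= set(table.columns)
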