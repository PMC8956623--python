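"""Permutation ANCOVA: partial-F identities, Freedman-Lane behavior,
BH-FDR correctness, and the group-comparison tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connstats.io import AnalysisConfig
from connstats.permstats import (compare_global, compare_nodal, fdr_adjust,
                                 freedman_lane_f, group_pairs, partial_f,
                                 permutation_ancova)

from conftest import make_cohort


def two_group_data(rng, n=12, shift=0.0):
    y = np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)])
    groups = np.array(["A"] * n + ["B"] * n)
    return y, groups


class TestPartialF:
    def test_identical_y_gives_zero(self):
        y = np.full(12, 3.7)
        groups = np.array(["A"] * 6 + ["B"] * 6)
        cov = np.arange(12, dtype=float)[:, None]
        f, _ = partial_f(y, groups, cov)
        assert f == 0.0

    def test_equals_t_squared_without_covariates(self, rng):
        y, groups = two_group_data(rng, shift=0.8)
        f, (df1, df2) = partial_f(y, groups, None)
        t = stats.ttest_ind(y[:12], y[12:]).statistic
        assert df1 == 1 and df2 == 22
        assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_covariate_absorbs_linear_signal(self, rng):
        age = np.linspace(20, 60, 20)
        y = 0.3 * age  # pure covariate effect
        groups = np.array(["A", "B"] * 10)  # balanced
        f, _ = partial_f(y, groups, age[:, None])
        assert f == 0.0

    def test_affine_invariance(self, rng):
        y, groups = two_group_data(rng, shift=1.0)
        cov = rng.normal(size=(24, 2))
        f1, _ = partial_f(y, groups, cov)
        f2, _ = partial_f(5.0 * y - 3.0, groups, 2.0 * cov + 7.0)
        assert f2 == pytest.approx(f1, rel=1e-10)

    def test_singular_design_rejected(self):
        groups = np.array(["A"] * 5 + ["B"] * 5)
        cov = (groups == "B").astype(float)[:, None]  # collinear with group
        with pytest.raises(ValueError, match="singular"):
            partial_f(np.arange(10, dtype=float), groups, cov)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2 subjects"):
            partial_f(np.arange(3.0), np.array(["A", "A", "B"]), None)


class TestPermutationAncova:
    def test_determinism(self, rng):
        y, groups = two_group_data(rng, shift=0.5)
        cov = rng.normal(size=(24, 2))
        a = permutation_ancova(y, groups, cov, 300, seed=42)
        b = permutation_ancova(y, groups, cov, 300, seed=42)
        assert a.p_perm == b.p_perm and a.statistic == b.statistic

    def test_huge_shift_reaches_floor(self, rng):
        y, groups = two_group_data(rng, shift=10.0)
        res = permutation_ancova(y, groups, None, 500, seed=1)
        assert res.p_perm == pytest.approx(1 / 501)

    def test_p_floor_invariant(self, rng):
        y, groups = two_group_data(rng)
        res = permutation_ancova(y, groups, None, 99, seed=0)
        assert 1 / 100 <= res.p_perm <= 1.0

    def test_freedman_lane_equals_label_permutation_without_covariates(self, rng):
        """With no covariates, permuting reduced-model residuals is
        numerically identical to permuting the outcome itself."""
        y, groups = two_group_data(rng, shift=0.6)
        n_perm = 50
        f_obs, f_perm, _ = freedman_lane_f(
            y, groups, None, n_perm, np.random.default_rng(7))
        idx = np.argsort(np.random.default_rng(7).random((n_perm, len(y))),
                         axis=1)
        for p in range(n_perm):
            f_direct, _ = partial_f(y[idx[p]], groups, None)
            assert f_perm[p, 0] == pytest.approx(f_direct, rel=1e-9)

    def test_type_one_error_calibration(self, rng):
        """Quick null calibration on gaussian outcomes with real covariate
        effects; the full cohort-level check lives in the acceptance suite."""
        n_rep, n_perm, alpha = 250, 200, 0.05
        rej = 0
        for _ in range(n_rep):
            groups = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
            cov = np.column_stack([rng.normal(40, 10, 30),
                                   rng.integers(0, 2, 30)])
            y = 0.05 * cov[:, 0] + 0.3 * cov[:, 1] + rng.normal(0, 1, 30)
            res = permutation_ancova(y, groups, cov, n_perm,
                                     rng=np.random.default_rng(rng.integers(2**31)))
            rej += res.p_perm <= alpha
        rate = rej / n_rep
        assert 0.02 <= rate <= 0.09

    def test_adjusted_means_recover_group_offsets(self, rng):
        groups = np.array(["A"] * 20 + ["B"] * 20)
        age = rng.normal(40, 10, 40)
        y = 2.0 + 0.1 * age + 1.5 * (groups == "B")
        res = permutation_ancova(y, groups, age[:, None], 100, seed=0)
        diff = res.group_adjusted_means["B"] - res.group_adjusted_means["A"]
        assert diff == pytest.approx(1.5, abs=1e-10)


class TestFdrAdjust:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.5] * 7), 0.5)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=30)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_reapplication_never_lowers_adjusted_values(self, rng):
        # BH is not a projection: reapplying can only move values up
        adj = fdr_adjust(np.sort(rng.uniform(size=10)))
        assert np.all(fdr_adjust(adj) >= adj - 1e-15)
        # exact fixed point when all inputs are equal
        np.testing.assert_allclose(fdr_adjust([0.2] * 5), 0.2)

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.90]
        adj = fdr_adjust(p)
        assert adj[1] <= adj[0] <= adj[2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    def test_bh_bounds_and_rank_monotonicity(self, pvals):
        adj = fdr_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def attenuated_cohort(rng, n_per_group=12, n_nodes=15, scale=0.80):
    """Disease groups globally attenuated relative to control."""
    base = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    base[iu] = rng.uniform(0.3, 0.6, len(iu[0]))
    base += base.T
    mats, groups, ages, sexes = [], [], [], []
    for g, s in (("MS", scale), ("NMOSD", scale), ("HC", 1.0)):
        for _ in range(n_per_group):
            noise = np.zeros_like(base)
            noise[iu] = rng.normal(0, 0.02, len(iu[0]))
            noise += noise.T
            mats.append(np.clip(base * s + noise, 0, None))
            groups.append(g)
            ages.append(rng.uniform(25, 55))
            sexes.append(rng.integers(0, 2))
    return make_cohort(mats, groups, ages, sexes)


class TestCompareGlobal:
    def test_attenuation_sign_pattern(self, rng):
        cohort = attenuated_cohort(rng)
        config = AnalysisConfig(n_permutations=400, seed=3)
        table = compare_global(cohort, config).set_index("measure")
        for m in ("total_strength", "global_efficiency"):
            assert table.loc[m, "p_fdr_MS_vs_HC"] < 0.05
            assert table.loc[m, "p_fdr_NMOSD_vs_HC"] < 0.05
            assert table.loc[m, "p_fdr_MS_vs_NMOSD"] > 0.05
            assert table.loc[m, "direction_MS_vs_HC"] == "MS < HC"
        cpl = table.loc["characteristic_path_length"]
        assert cpl["direction_MS_vs_HC"] == "MS > HC"

    def test_identical_networks_give_f_zero_p_one(self, rng):
        w = np.zeros((6, 6))
        iu = np.triu_indices(6, k=1)
        w[iu] = 0.4
        w += w.T
        cohort = make_cohort([w] * 12, ["MS"] * 4 + ["NMOSD"] * 4 + ["HC"] * 4,
                             ages=30 + np.arange(12),
                             sexes=[0, 1] * 6)
        config = AnalysisConfig(n_permutations=100, seed=0)
        table = compare_global(cohort, config)
        assert np.all(table["p_omnibus"] == 1.0)
        assert np.all(table.filter(like="p_fdr_") == 1.0)


class TestCompareNodal:
    def test_planted_clique_reduction_flags_exact_nodes(self):
        """Halving the edges inside a 5-node clique lowers strength at
        exactly those 5 nodes; FDR-corrected omnibus should flag them all
        and nothing else (seeded draw; under FDR a chance extra node is
        possible in a minority of draws)."""
        rng = np.random.default_rng(2025)
        n_nodes, planted = 14, [0, 1, 2, 3, 4]
        base = np.zeros((n_nodes, n_nodes))
        iu = np.triu_indices(n_nodes, k=1)
        base[iu] = rng.uniform(0.35, 0.55, len(iu[0]))
        base += base.T
        clique = np.zeros_like(base, dtype=bool)
        for i in planted:
            for j in planted:
                if i != j:
                    clique[i, j] = True
        mats, groups = [], []
        for g in ("MS", "NMOSD", "HC"):
            for _ in range(12):
                noise = np.zeros_like(base)
                noise[iu] = rng.normal(0, 0.01, len(iu[0]))
                noise += noise.T
                w = base + noise
                if g != "HC":
                    w = np.where(clique, w * 0.5, w)
                mats.append(np.clip(w, 0, None))
                groups.append(g)
        cohort = make_cohort(mats, groups,
                             ages=rng.uniform(25, 55, 36),
                             sexes=rng.integers(0, 2, 36))
        config = AnalysisConfig(n_permutations=300, seed=5)
        table = compare_nodal(cohort, config, measure_names=("strength",))
        flagged = sorted(
            int(n.split("_")[1]) for n in table[table["significant"]]["node"])
        assert flagged == planted

    def test_single_node_fdr_is_identity(self, rng):
        cohort = attenuated_cohort(rng, n_per_group=8, n_nodes=5)
        config = AnalysisConfig(n_permutations=200, seed=1)
        table = compare_nodal(cohort, config, measure_names=("strength",))
        one = table.iloc[[0]]
        assert one["p_omnibus_fdr"].iloc[0] >= one["p_omnibus"].iloc[0]


def test_group_pairs_order():
    cohort = attenuated_cohort(np.random.default_rng(0), n_per_group=3,
                               n_nodes=4)
    assert group_pairs(cohort) == [("MS", "HC"), ("NMOSD", "HC"),
                                   ("MS", "NMOSD")]
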