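"""MIEL pipeline: features, z-score, condensation, classification, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfscope.miel import (
    bootstrap_condensation,
    condense,
    discriminant_scatter,
    distance_analysis,
    extract_features,
    fit_classify,
    haralick_features,
    zscore,
    apply_zscore,
)
from tfscope.synthetic import (
    FeatureSimParams,
    simulate_feature_table,
    simulate_nuclei_images,
)


def _feat_cols(df):
    return [c for c in df.columns
            if c not in ("cell_id", "condition", "center_id", "pool_size")]


class TestFeatures:
    def test_row_conservation(self):
        crops, masks, labels = simulate_nuclei_images(
            ["a"], [3.0], n=5, shape=(48, 48), seed=50)
        table = extract_features(crops, masks, labels)
        assert len(table) == 5
        assert len(_feat_cols(table)) == 13 * 4 + 4

    def test_rotation_invariance_of_direction_averaged_features(self):
        crops, masks, _ = simulate_nuclei_images(["a"], [3.0], n=1,
                                                 shape=(49, 49), seed=51)
        rot = [np.rot90(crops[0])]
        rot_masks = [np.rot90(masks[0])]
        t1 = extract_features(crops, masks, ["a"])
        t2 = extract_features(rot, rot_masks, ["a"])
        for c in _feat_cols(t1):
            assert t1[c].iloc[0] == pytest.approx(t2[c].iloc[0], abs=1e-6), c

    def test_texture_scales_separate_conditions(self):
        crops, masks, labels = simulate_nuclei_images(
            ["fine", "coarse"], [2.0, 8.0], n=15, shape=(64, 64), seed=52)
        table = extract_features(crops, masks, labels)
        z, _ = zscore(table)
        means = z.groupby("condition")[_feat_cols(z)].mean()
        gap = (means.loc["fine"] - means.loc["coarse"]).abs()
        assert gap.max() > 1.0  # at least one feature shifts > 1 SD

    def test_constant_crop_yields_defined_values(self):
        img = np.ones((32, 32)) * 7.0
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        table = extract_features([img], [mask], ["a"])
        vals = table[_feat_cols(table)].to_numpy()
        assert np.all(np.isfinite(vals))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            extract_features([np.ones((8, 8))], [np.zeros((8, 8), bool)], ["a"])

    def test_degenerate_glcm_statistics(self):
        p = np.zeros((64, 64))
        p[0, 0] = 1.0
        f = haralick_features(p)
        names = ["asm", "contrast", "correlation", "variance", "idm"]
        assert f[0] == 1.0      # ASM of a point mass
        assert f[1] == 0.0      # contrast
        assert f[2] == 0.0      # correlation defined as 0 at zero variance
        assert np.all(np.isfinite(f))


class TestZscore:
    def test_columns_standardized(self, two_condition_table):
        table, _ = two_condition_table
        z, params = zscore(table)
        for c in _feat_cols(z):
            assert z[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[c].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert set(params) == set(_feat_cols(z))

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"cell_id": ["a", "b", "c"], "condition": "x",
                           "f_000": [1.0, 2.0, 3.0], "f_001": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _ = zscore(df)
        assert "f_001" not in z.columns

    def test_stored_parameters_reproduce_transform(self, two_condition_table):
        table, _ = two_condition_table
        z, params = zscore(table)
        z2 = apply_zscore(table, params)
        pd.testing.assert_frame_equal(z, z2)

    def test_all_constant_rejected(self):
        df = pd.DataFrame({"cell_id": ["a", "b"], "condition": "x",
                           "f_000": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                zscore(df)


class TestCondense:
    def test_floor_partition_and_remainder(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a"], n_cells_per_condition=10, n_features=3,
            effect_size=0.0, seed=53))
        res = condense(df, 3, seed=0)
        assert len(res.centers) == 3
        assert res.discarded["a"] == 1
        used = [cid for mem in res.members.values() for cid in mem]
        assert len(used) == len(set(used)) == 9  # disjoint pools

    def test_pool_size_one_returns_cells(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a"], n_cells_per_condition=5, n_features=3,
            effect_size=0.0, seed=54))
        res = condense(df, 1, seed=0)
        got = np.sort(res.centers[_feat_cols(res.centers)].to_numpy(), axis=0)
        want = np.sort(df[_feat_cols(df)].to_numpy(), axis=0)
        assert np.allclose(got, want)

    def test_center_equals_brute_force_member_mean(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a", "b"], n_cells_per_condition=20, n_features=4,
            effect_size=1.0, seed=55))
        res = condense(df, 5, seed=7)
        for _, row in res.centers.iterrows():
            mem = df[df["cell_id"].isin(res.members[row["center_id"]])]
            brute = mem[_feat_cols(df)].mean()
            for c in _feat_cols(df):
                assert row[c] == pytest.approx(brute[c], rel=1e-12)

    def test_insufficient_cells_rejected(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a"], n_cells_per_condition=4, n_features=2,
            effect_size=0.0, seed=56))
        with pytest.raises(ValueError, match="pool size"):
            condense(df, 5, seed=0)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_seeded_partition_reproducible(self, seed):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a", "b"], n_cells_per_condition=12, n_features=3,
            effect_size=0.5, seed=57))
        a = condense(df, 4, seed=seed)
        b = condense(df, 4, seed=seed)
        pd.testing.assert_frame_equal(a.centers, b.centers)


class TestFitClassify:
    def test_indistinguishable_duplicate_condition_near_chance(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a"], n_cells_per_condition=1200, n_features=10,
            effect_size=0.0, seed=58))
        half = len(df) // 2
        df.loc[: half - 1, "condition"] = "a1"
        df.loc[half:, "condition"] = "a2"
        z, _ = zscore(df)
        res = condense(z, 10, seed=1)
        _, rep = fit_classify(res.centers, seed=1, repeats=10)
        assert 0.2 < rep.accuracy < 0.8

    def test_strong_effect_high_accuracy_and_row_sums(self, two_condition_table):
        table, _ = two_condition_table
        z, _ = zscore(table)
        res = condense(z, 10, seed=2)
        _, rep = fit_classify(res.centers, seed=2, repeats=10)
        assert rep.accuracy >= 0.95
        sums = rep.confusion.sum(axis=1).to_numpy()
        assert np.allclose(sums, 100.0, atol=0.5)

    def test_too_few_test_centers_error_names_condition(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["tiny", "big"], n_cells_per_condition=25,
            n_features=5, effect_size=1.0, seed=59))
        res = condense(df, 5, seed=0)  # 5 centers per condition -> 1 test
        with pytest.raises(ValueError, match="tiny|big"):
            fit_classify(res.centers, repeats=1)

    def test_single_condition_rejected(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a"], n_cells_per_condition=50, n_features=5,
            effect_size=0.0, seed=60))
        res = condense(df, 5, seed=0)
        with pytest.raises(ValueError, match="2 conditions"):
            fit_classify(res.centers)


class TestDistances:
    def test_three_four_five(self):
        centers = pd.DataFrame({
            "center_id": ["p", "q"], "condition": ["a", "b"],
            "pool_size": 1, "f_000": [0.0, 3.0], "f_001": [0.0, 4.0]})
        pairwise, cond, disp = distance_analysis(centers)
        assert pairwise.loc["p", "q"] == 5.0
        assert cond.loc["a", "b"] == 5.0
        assert np.isnan(disp["a"])

    def test_matches_brute_force_double_loop(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a", "b", "c"], n_cells_per_condition=30,
            n_features=6, effect_size=1.0, seed=61))
        res = condense(df, 5, seed=3)  # 18 centers
        pairwise, cond, disp = distance_analysis(res.centers)
        x = res.centers[_feat_cols(res.centers)].to_numpy()
        n = len(x)
        for i in range(n):
            assert pairwise.iloc[i, i] == 0.0
            for j in range(n):
                brute = np.sqrt(((x[i] - x[j]) ** 2).sum())
                assert pairwise.iloc[i, j] == pytest.approx(brute, rel=1e-12)
                assert pairwise.iloc[i, j] == pairwise.iloc[j, i]
        # condition-level matrix by brute-force double loop
        conds = res.centers["condition"].to_numpy()
        for a in "abc":
            for b in "abc":
                if a == b:
                    ia = np.nonzero(conds == a)[0]
                    vals = [pairwise.iloc[i, j] for k, i in enumerate(ia)
                            for j in ia[k + 1:]]
                else:
                    vals = [pairwise.iloc[i, j]
                            for i in np.nonzero(conds == a)[0]
                            for j in np.nonzero(conds == b)[0]]
                assert cond.loc[a, b] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_permutation_invariance_of_condition_matrix(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a", "b"], n_cells_per_condition=20, n_features=4,
            effect_size=1.0, seed=62))
        res = condense(df, 4, seed=4)
        _, cond1, _ = distance_analysis(res.centers)
        shuffled = res.centers.sample(frac=1.0, random_state=0).reset_index(drop=True)
        _, cond2, _ = distance_analysis(shuffled)
        pd.testing.assert_frame_equal(cond1, cond2)


class TestDiscriminantScatter:
    def test_two_coordinates_per_point(self, two_condition_table):
        table, _ = two_condition_table
        z, _ = zscore(table)
        coords = discriminant_scatter(z)
        assert list(coords.columns[-2:]) == ["factor_1", "factor_2"]
        assert len(coords) == len(z)

    def test_separated_conditions_separate_on_factor_one(self, two_condition_table):
        # pooled centers, as plotted: pooling by n shrinks within-condition
        # spread by sqrt(n) while the between-condition gap is unchanged
        table, _ = two_condition_table
        z, _ = zscore(table)
        centers = condense(z, 10, seed=9).centers
        coords = discriminant_scatter(centers)
        g = coords.groupby("condition")["factor_1"]
        gap = abs(g.mean().diff().iloc[-1])
        within = g.std().mean()
        assert gap > 5 * within

    def test_identical_conditions_do_not_separate(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a", "b"], n_cells_per_condition=200, n_features=10,
            effect_size=0.0, seed=63))
        coords = discriminant_scatter(df)
        g = coords.groupby("condition")["factor_1"]
        gap = abs(g.mean().diff().iloc[-1])
        assert gap < 0.5 * g.std().mean()


@pytest.fixture(scope="module")
def separable_table():
    df, _ = simulate_feature_table(FeatureSimParams(
        conditions=["a", "b"], n_cells_per_condition=300, n_features=20,
        effect_size=2.0, seed=64))
    z, _ = zscore(df)
    return z


class TestBootstrap:
    def test_identical_conditions_yield_no_optimal_n(self):
        df, _ = simulate_feature_table(FeatureSimParams(
            conditions=["a", "b"], n_cells_per_condition=200, n_features=10,
            effect_size=0.0, seed=65))
        z, _ = zscore(df)
        rep = bootstrap_condensation(z, [5, 10], iterations=30, seed=5)
        assert rep.optimal_n is None

    def test_selection_rule_matches_independent_reimplementation(self, separable_table):
        rep = bootstrap_condensation(separable_table, [5, 10, 20],
                                     iterations=50, seed=6)
        # independent re-application of the 95/95 rule to the recorded draws
        best = None
        for n in sorted(rep.candidate_ns):
            ok = sum(1 for a in rep.accuracies[n] if a >= 0.95)
            if ok / rep.iterations >= 0.95:
                best = n
                break
        assert rep.optimal_n == best
        assert all(len(rep.accuracies[n]) == 50 for n in rep.candidate_ns)

    def test_infeasible_candidate_rejected(self, separable_table):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_condensation(separable_table, [500], iterations=5, seed=7)

    def test_deterministic_given_seed(self, separable_table):
        a = bootstrap_condensation(separable_table, [10], iterations=20, seed=8)
        b = bootstrap_condensation(separable_table, [10], iterations=20, seed=8)
        assert np.array_equal(a.accuracies[10], b.accuracies[10])
        assert a.optimal_n == b.optimal_n
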