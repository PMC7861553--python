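"""KS distances, PCA projection, neutral ellipse, and clone clustering."""

import numpy as np
import pandas as pd
import pytest

from dynevolve.phenotype_clusters import (
    CONDITIONS,
    cluster_characteristics,
    cluster_clones,
    cluster_clones_5d,
    cluster_usage,
    ks_distance_matrix,
    pca_project,
    remove_neutral_ellipse,
)


def brute_force_ks(a, b):
    """Independent oracle: sup-norm ECDF distance by direct enumeration."""
    grid = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in grid
    )


def profile_frame(groups):
    """Build a clone-profile table from {origin: {condition: values}}."""
    rows = []
    for origin, conds in groups.items():
        n = len(next(iter(conds.values())))
        for i in range(n):
            rows.append(
                {"origin": origin, **{c: conds[c][i] for c in conds}}
            )
    return pd.DataFrame(rows)


class TestKSDistance:
    def test_identical_distributions_have_zero_distance(self):
        vals = {c: [0.1, 0.2, 0.3] for c in CONDITIONS}
        mat = ks_distance_matrix(profile_frame({"a": vals, "b": vals}))
        assert mat.distances[0, 1] == 0.0

    def test_single_disjoint_condition_gives_one(self):
        base = {c: [0.1, 0.2, 0.3] for c in CONDITIONS}
        other = dict(base)
        other["Mix"] = [5.0, 6.0, 7.0]  # disjoint support in one condition
        mat = ks_distance_matrix(profile_frame({"a": base, "b": other}))
        assert mat.distances[0, 1] == pytest.approx(1.0)

    def test_toy_shifted_sample_matches_brute_force(self):
        """{1,2,3} vs {2,3,4} in one condition: component 1/3, total 1/3."""
        a = {c: [1.0, 2.0, 3.0] for c in CONDITIONS}
        b = dict(a)
        b["Fluconazole"] = [2.0, 3.0, 4.0]
        mat = ks_distance_matrix(profile_frame({"a": a, "b": b}))
        oracle = brute_force_ks(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert oracle == pytest.approx(1 / 3)
        assert mat.components["Fluconazole"][0, 1] == pytest.approx(oracle)
        assert mat.distances[0, 1] == pytest.approx(1 / 3)

    def test_components_match_brute_force_on_random_data(self, rng):
        groups = {
            g: {c: rng.normal(loc, 1, size=12) for c in CONDITIONS}
            for g, loc in (("a", 0.0), ("b", 0.7), ("c", -0.4))
        }
        mat = ks_distance_matrix(profile_frame(groups))
        for i, gi in enumerate(mat.experiments):
            for j, gj in enumerate(mat.experiments):
                if i < j:
                    for c in CONDITIONS:
                        assert mat.components[c][i, j] == pytest.approx(
                            brute_force_ks(groups[gi][c], groups[gj][c])
                        )
        # metric sanity: symmetric, nonnegative, bounded by sqrt(5)
        assert np.allclose(mat.distances, mat.distances.T)
        assert (mat.distances >= 0).all()
        assert mat.distances.max() <= np.sqrt(5) + 1e-12
        assert mat.cluster_labels is not None

    def test_underpowered_experiment_excluded(self):
        good = {c: [0.1, 0.2, 0.3] for c in CONDITIONS}
        bad = {c: [0.1] for c in CONDITIONS}
        with pytest.warns(UserWarning, match="excluded"):
            mat = ks_distance_matrix(profile_frame({"a": good, "b": bad, "c": good}))
        assert mat.experiments == ["a", "c"]


class TestPCA:
    def test_collinear_data_explained_by_first_component(self, rng):
        t = rng.normal(size=40)
        df = pd.DataFrame(
            {c: t * w for c, w in zip(CONDITIONS, [1, 2, -1, 0.5, 3])}
        )
        coords, evr, _ = pca_project(df)
        assert evr[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_spreads_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 5)), columns=list(CONDITIONS))
        _, evr, pca = pca_project(df, n_components=5)
        np.testing.assert_allclose(evr, 0.2, atol=0.03)

    def test_projection_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 5)) @ np.diag([3, 2, 1, 1, 1]),
                          columns=list(CONDITIONS))
        coords, _, _ = pca_project(df)
        again, _, _ = pca_project(
            coords.rename(columns={"PC1": CONDITIONS[0], "PC2": CONDITIONS[1]}),
            conditions=CONDITIONS[:2],
        )
        np.testing.assert_allclose(np.abs(again.to_numpy()), np.abs(coords.to_numpy()),
                                   atol=1e-8)

    def test_incomplete_profiles_dropped(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)), columns=list(CONDITIONS))
        df.iloc[0, 0] = np.nan
        coords, _, _ = pca_project(df)
        assert 0 not in coords.index

    def test_too_few_complete_profiles_rejected(self):
        df = pd.DataFrame(np.ones((2, 5)), columns=list(CONDITIONS))
        with pytest.raises(ValueError, match=">= 3"):
            pca_project(df)


class TestNeutralEllipse:
    @staticmethod
    def planted(rng, sep=3.0, n=200):
        neutral = rng.normal(0, 1, size=(n, 2))
        adaptive = rng.normal(0, 1, size=(n, 2)) + [2 * sep, 0]
        coords = pd.DataFrame(np.vstack([neutral, adaptive]), columns=["PC1", "PC2"])
        flags = np.array([True] * n + [False] * n)
        return coords, flags

    def test_centroid_removed_far_point_kept(self, rng):
        coords, flags = self.planted(rng)
        coords.iloc[0] = coords[flags.tolist()].mean()  # a neutral at the centroid
        coords.iloc[-1] = [30.0, 0.0]  # 10+ SD along PC1
        kept, inside, ellipse = remove_neutral_ellipse(coords, flags)
        assert inside[0]
        assert not inside[len(coords) - 1]

    def test_planted_gaussian_mixture_separation(self, rng):
        """Gaussian blobs 3 SD apart: the 2-SD ellipse removes the chi-square
        mass inside 2 sigma (1 - e^-2 ~ 86% in 2D) of planted neutrals and
        <= 10% of adaptives."""
        coords, flags = self.planted(rng, sep=3.0)
        _, inside, _ = remove_neutral_ellipse(coords, flags)
        assert 0.80 <= inside[flags].mean() <= 0.95
        assert inside[~flags].mean() <= 0.10

    def test_heterogeneous_precision_neutrals_mostly_removed(self, rng):
        """With realistic heterogeneous measurement precision (per-clone SE
        tracks read support, so most clones scatter far less than the pooled
        SD), the 2-SD ellipse removes >= 95% of planted neutrals."""
        n = 400
        scale = np.where(rng.random(n) < 0.95, 0.3, 2.0)
        neutral = rng.normal(0, 1, size=(n, 2)) * scale[:, None]
        adaptive = rng.normal(0, 0.5, size=(n // 2, 2)) + [6, 0]
        coords = pd.DataFrame(np.vstack([neutral, adaptive]), columns=["PC1", "PC2"])
        flags = np.array([True] * n + [False] * (n // 2))
        _, inside, _ = remove_neutral_ellipse(coords, flags)
        assert inside[flags].mean() >= 0.95
        assert inside[~flags].mean() <= 0.10

    def test_rotation_invariance(self, rng):
        """Rigidly rotating all coordinates preserves the neutral call
        (ellipse semi-axes follow the rotated spread only up to axis
        alignment, so compare on an isotropic cloud)."""
        n = 300
        neutral = rng.normal(0, 1, size=(n, 2))
        adaptive = rng.normal(0, 1, size=(n, 2)) * 1.0 + [7, 7]
        xy = np.vstack([neutral, adaptive])
        flags = np.array([True] * n + [False] * n)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = remove_neutral_ellipse(pd.DataFrame(xy, columns=["PC1", "PC2"]), flags)[1]
        b = remove_neutral_ellipse(pd.DataFrame(xy @ rot.T, columns=["PC1", "PC2"]), flags)[1]
        assert (a == b).mean() > 0.97

    def test_needs_enough_neutrals(self):
        coords = pd.DataFrame(np.ones((10, 2)), columns=["PC1", "PC2"])
        with pytest.raises(ValueError, match=">= 5"):
            remove_neutral_ellipse(coords, [True] * 3 + [False] * 7)


class TestClusterClones:
    def test_identical_points_one_cluster(self):
        coords = pd.DataFrame(np.zeros((5, 2)), columns=["PC1", "PC2"])
        labels, _ = cluster_clones(coords)
        assert labels.nunique() == 1

    def test_two_well_separated_blobs(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.5, (30, 2)), rng.normal(0, 0.5, (30, 2)) + [10, 0]]
        )
        coords = pd.DataFrame(pts, columns=["PC1", "PC2"])
        labels, sens = cluster_clones(coords, distance_threshold=2.5)
        assert labels.nunique() == 2
        assert labels.iloc[:30].nunique() == 1
        assert labels.iloc[30:].nunique() == 1
        # robustness: a finer threshold may split a blob but never merges
        # points across the planted partition
        labels15, _ = cluster_clones(coords, distance_threshold=1.5)
        left, right = set(labels15.iloc[:30]), set(labels15.iloc[30:])
        assert not (left & right)

    def test_threshold_beyond_diameter_gives_one_cluster(self, rng):
        coords = pd.DataFrame(rng.normal(size=(20, 2)), columns=["PC1", "PC2"])
        labels, _ = cluster_clones(coords, distance_threshold=1e3)
        assert labels.nunique() == 1

    def test_singletons_reassigned(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.3, (20, 2)), rng.normal(0, 0.3, (20, 2)) + [8, 0],
             [[4.0, 30.0]]]
        )
        labels, _ = cluster_clones(pd.DataFrame(pts, columns=["PC1", "PC2"]))
        counts = labels.value_counts()
        assert (counts >= 2).all()  # the lone point joined a real cluster

    def test_5d_mode_standardizes(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)) * [1, 10, 100, 1, 1],
                          columns=list(CONDITIONS))
        labels, _ = cluster_clones_5d(df, distance_threshold=5.0)
        assert labels.nunique() >= 1


class TestClusterCharacteristics:
    def test_whole_set_cluster_sits_at_median(self, rng):
        prof = pd.DataFrame(rng.normal(size=(101, 5)), columns=list(CONDITIONS))
        labels = pd.Series(np.ones(101, int), index=prof.index)
        chars = cluster_characteristics(labels, prof)
        np.testing.assert_allclose(chars.to_numpy(), 50.0, atol=1.0)

    def test_singleton_maximum_scores_100(self):
        prof = pd.DataFrame(
            {c: np.arange(10, dtype=float) for c in CONDITIONS}
        )
        labels = pd.Series([1] * 9 + [2], index=prof.index)
        chars = cluster_characteristics(labels, prof)
        assert chars.loc[2, "Mix"] == pytest.approx(100.0)

    def test_hand_computed_two_cluster_table(self):
        """10 clones, 2 clusters; oracle = explicit rank counting."""
        vals = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        prof = pd.DataFrame({c: vals for c in CONDITIONS})
        labels = pd.Series([1] * 5 + [2] * 5, index=prof.index)
        chars = cluster_characteristics(labels, prof)
        # cluster 1 median = 2 -> 3 of 10 values at or below -> 30%
        # cluster 2 median = 7 -> 8 of 10 values at or below -> 80%
        assert chars.loc[1, "Gly/Eth"] == pytest.approx(30.0)
        assert chars.loc[2, "Gly/Eth"] == pytest.approx(80.0)

    def test_usage_fractions(self):
        labels = pd.Series([1, 1, 2], index=[0, 1, 2])
        origins = pd.Series(["a", "a", "a"], index=[0, 1, 2])
        usage = cluster_usage(labels, origins)
        np.testing.assert_allclose(usage.loc["a"].to_numpy(), [2 / 3, 1 / 3])
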