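import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sleepspan.clustering import (
    FeatureMatrix,
    build_features,
    cluster,
    contrast_tests,
    elbow_curve,
    select_k,
    window_stability,
)
from sleepspan.stats import t_from_moments, two_sample_t
from sleepspan.synthetic_data import generate_cohort, planted_two_cluster_config


def _features_from_array(X):
    frame = pd.DataFrame(X, index=[f"p{i:02d}" for i in range(len(X))])
    frame.columns = [f"v{j}" for j in range(X.shape[1])]
    return FeatureMatrix(
        frame=frame,
        X=np.asarray(X, dtype=float),
        center=pd.Series(0.0, index=frame.columns),
        scale=pd.Series(1.0, index=frame.columns),
        excluded=[],
        weeks_back=1,
        window=(pd.Timestamp("2017-12-01"), pd.Timestamp("2017-12-28")),
    )


@pytest.fixture(scope="module")
def planted():
    cfg = planted_two_cluster_config(seed=1)
    panel, truth = generate_cohort(cfg, seed=1)
    return panel, truth


class TestBuildFeatures:
    def test_means_match_brute_force_window_average(self, small_panel):
        feats = build_features(small_panel, weeks_back=4, min_days=3)
        start, end = feats.window
        for pid in feats.frame.index:
            s = small_panel.get_series(pid, "tst_h")
            s = s[(s.index >= start) & (s.index <= end)]
            assert feats.frame.loc[pid, "tst_h"] == pytest.approx(s.mean(), rel=1e-12)

    def test_insufficient_days_excluded_with_reason(self, small_panel):
        from sleepspan.data_model import CohortPanel

        # keep only 2 nights for the first participant
        victim = small_panel.participants[0]
        nights = small_panel.nights
        mask = nights["participant_id"] != victim
        keep_first_two = nights[~mask].head(2)
        panel = CohortPanel(
            nights=pd.concat([nights[mask], keep_first_two]), days=small_panel.days
        )
        feats = build_features(panel, weeks_back=4, min_days=5)
        assert victim not in feats.frame.index
        assert any(pid == victim and "min_days" in reason
                   for pid, reason in feats.excluded)
        assert feats.frame.shape[0] == len(small_panel.participants) - 1

    def test_degenerate_columns_standardize_to_zero(self, planted):
        panel, _ = planted
        feats = build_features(panel, weeks_back=5, min_days=5)
        dead = (feats.scale == 0).to_numpy()
        assert dead.any()  # the identical variables
        assert np.all(feats.X[:, dead] == 0.0)

    def test_no_eligible_participants_raises(self, small_panel):
        with pytest.raises(ValueError):
            build_features(small_panel, weeks_back=1, min_days=100)


class TestElbow:
    @staticmethod
    def _three_clouds(seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([rng.normal(c, 0.3, size=(15, 2)) for c in centers])
        return X

    def test_three_separated_clouds_elbow_at_three(self):
        feats = _features_from_array(self._three_clouds())
        curve = elbow_curve(feats, range(1, 7), seed=0)
        # sharp drops up to K=3, essentially flat after
        assert curve.loc[2] < 0.5 * curve.loc[1]
        assert curve.loc[3] < 0.2 * curve.loc[2]
        assert abs(curve.loc[4] - curve.loc[3]) < 0.5 * (curve.loc[2] - curve.loc[3])
        assert select_k(curve) == 3

    def test_hand_curve_second_difference(self):
        curve = pd.Series([10.0, 4.0, 3.8, 3.7], index=[1, 2, 3, 4])
        assert select_k(curve) == 2

    def test_linear_curve_warns_and_returns_smallest(self):
        curve = pd.Series([4.0, 3.0, 2.0, 1.0], index=[1, 2, 3, 4])
        with pytest.warns(UserWarning):
            assert select_k(curve) == 1

    def test_duplicated_points_leave_curve_unchanged(self):
        X = self._three_clouds(3)
        c1 = elbow_curve(_features_from_array(X), range(1, 5), seed=0)
        c2 = elbow_curve(_features_from_array(np.vstack([X, X])), range(1, 5), seed=0)
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-8)

    def test_k_beyond_n_raises(self):
        feats = _features_from_array(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            elbow_curve(feats, range(1, 10))


class TestCluster:
    def test_two_points_get_their_own_centers(self):
        feats = _features_from_array(np.array([[0.0, 0.0], [5.0, 5.0]]))
        run = cluster(feats, 2, min_size=1, seed=0)
        got = sorted(run.centers.to_numpy().tolist())
        assert got == [[0.0, 0.0], [5.0, 5.0]]

    def test_min_size_larger_than_all_clusters_raises(self):
        feats = _features_from_array(np.array([[0.0], [0.1], [5.0], [5.1]]))
        with pytest.raises(ValueError):
            cluster(feats, 2, min_size=3, seed=0)

    def test_small_clusters_marked_unassigned(self):
        X = np.vstack([np.zeros((10, 1)), np.full((2, 1), 8.0)])
        run = cluster(_features_from_array(X), 2, min_size=5, seed=0)
        assert (run.assignments == -1).sum() == 2
        assert len(run.retained) == 1

    def test_same_seed_is_deterministic(self, planted):
        panel, _ = planted
        feats = build_features(panel, weeks_back=5, min_days=5)
        a = cluster(feats, 2, seed=3).assignments
        b = cluster(feats, 2, seed=3).assignments
        assert (a == b).all()

    def test_planted_clusters_recovered(self, planted):
        panel, truth = planted
        feats = build_features(panel, weeks_back=5, min_days=5)
        run = cluster(feats, 2, min_size=8, seed=0)
        ari = adjusted_rand_score(
            truth.cluster_labels[run.assignments.index], run.assignments
        )
        assert ari >= 0.9


class TestContrasts:
    def test_identical_groups_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0])
        assert two_sample_t(x, x) == (0.0, 1.0)

    def test_printed_moment_summary_is_significant(self):
        # awakening counts 2.03 (SD 0.93, n=25) vs 3.06 (SD 1.27, n=25)
        t, p = t_from_moments(2.03, 0.93, 25, 3.06, 1.27, 25)
        assert p < 0.05
        # cross-check the pooled-variance formula against raw-data scipy on
        # synthetic samples with exactly these moments
        rng = np.random.default_rng(0)

        def with_moments(m, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return m + sd * z

        t2, p2 = two_sample_t(with_moments(2.03, 0.93, 25), with_moments(3.06, 1.27, 25))
        assert t == pytest.approx(t2, rel=1e-9)
        assert p == pytest.approx(p2, rel=1e-9)

    def test_only_planted_variable_flagged(self, planted):
        panel, _ = planted
        feats = build_features(panel, weeks_back=5, min_days=5)
        run = cluster(feats, 2, min_size=8, seed=0)
        table = contrast_tests(run)
        sig = set(table.loc[table["significant"], "variable"])
        assert sig == {"n_awake"}

    def test_requires_two_retained_clusters(self):
        X = np.vstack([np.zeros((10, 1)), np.full((2, 1), 8.0)])
        run = cluster(_features_from_array(X), 2, min_size=5, seed=0)
        with pytest.raises(ValueError, match="2 retained"):
            contrast_tests(run)


class TestWindowStability:
    def test_agreement_rises_with_window_length(self):
        """Short windows give noisy partitions; agreement climbs toward 1 as
        more weeks enter the window, mirroring the >30-days-for-stable-
        clusters behaviour."""
        cfg = planted_two_cluster_config(n_days=49, seed=2)
        panel, _ = generate_cohort(cfg, seed=2)
        table, stable_from = window_stability(
            panel, [2, 3, 4, 5, 6], k=2, seed=0, ari_threshold=0.9
        )
        assert table["ari"].iloc[-1] == pytest.approx(1.0)
        assert table["ari"].iloc[-1] > table["ari"].iloc[0]
        assert stable_from is not None and 3 <= stable_from <= 5

    def test_needs_at_least_two_windows(self, small_panel):
        with pytest.raises(ValueError):
            window_stability(small_panel, [4], k=2)

    def test_random_labels_have_near_zero_ari(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 2000)
        b = rng.integers(0, 2, 2000)
        assert abs(adjusted_rand_score(a, b)) < 0.05
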