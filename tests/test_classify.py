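"""Threshold/ROC machinery, template matching, discriminant analysis."""

import numpy as np
import pytest

from leechdendro.classify import (
    covariance_features,
    detect_episodes,
    discriminant_classify,
    match_behavior_template,
    pca_reduce,
    roc_curve,
    sliding_template_match,
    threshold_classify,
)
from leechdendro.dendro import behavior_dendrogram


class TestThresholdAndRoc:
    def test_threshold_sides(self):
        scores = np.array([1.0, 2.0, 3.0])
        assert threshold_classify(scores, 0.5, "less").tolist() == [0, 0, 0]
        assert threshold_classify(scores, 2.0, "greater").tolist() == [0, 0, 1]

    def test_perfect_separator_reaches_corner(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        truth = scores > 0.5
        curve = roc_curve(scores, truth, thresholds=np.array([0.5]))
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 1.0
        assert curve.auc == pytest.approx(1.0)

    def test_threshold_below_everything_labels_all(self):
        scores = np.random.default_rng(0).normal(size=200)
        truth = np.random.default_rng(1).integers(0, 2, 200).astype(bool)
        curve = roc_curve(scores, truth, thresholds=np.array([-np.inf]))
        assert curve.fpr[0] == 1.0 and curve.tpr[0] == 1.0

    def test_uninformative_score_stays_near_diagonal(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=10_000)
        truth = rng.integers(0, 2, 10_000).astype(bool)
        curve = roc_curve(scores, truth)
        assert np.max(np.abs(curve.tpr - curve.fpr)) < 0.1

    def test_monotone_when_thresholds_sorted(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=500)
        truth = (scores + rng.normal(size=500)) > 0
        curve = roc_curve(scores, truth, thresholds=np.sort(scores))
        assert (np.diff(curve.tpr) <= 1e-12).all()
        assert (np.diff(curve.fpr) <= 1e-12).all()

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.arange(5.0), np.ones(5, bool))


class TestTemplateMatching:
    def test_template_against_own_data_scores_one(self, repertoire_session):
        s = repertoire_session
        template = behavior_dendrogram(s, "crawling")
        crawl = [iv for iv in s.schedule if iv.label == "crawling"]
        longest = max(crawl, key=lambda iv: iv.duration)
        centers, scores = sliding_template_match(
            s, template, k=2, window=longest.duration - 1.0,
            step=2.0, index_kind="nmi",
        )
        inside = (centers - (longest.duration - 1) / 2 >= longest.t_start) & (
            centers + (longest.duration - 1) / 2 <= longest.t_end
        )
        assert inside.any()
        assert scores[inside].max() == pytest.approx(1.0)

    def test_crawling_windows_outscore_stationary_windows(self, repertoire_session):
        s = repertoire_session
        template = behavior_dendrogram(s, "crawling")
        centers, scores = match_behavior_template(s, template, "crawling")

        def fully_in(label, c):
            return any(
                iv.label == label and iv.t_start <= c - 50 and c + 50 <= iv.t_end
                for iv in s.schedule
            )

        crawl = np.array([fully_in("crawling", c) for c in centers])
        stat = np.array([fully_in("stationary", c) for c in centers])
        assert scores[crawl].min() > scores[stat].max()

    def test_missing_template_units_reported(self, repertoire_session):
        import copy

        template = behavior_dendrogram(repertoire_session, "crawling")
        crippled = copy.copy(repertoire_session)
        crippled.spikes = {
            k: v for k, v in repertoire_session.spikes.items() if k != "3_DP_1L"
        }
        with pytest.raises(KeyError, match="3_DP_1L"):
            sliding_template_match(crippled, template, k=2)


class TestDetectEpisodes:
    def test_all_zero_series_no_episodes(self):
        centers = np.arange(0.0, 100.0, 2.0)
        assert detect_episodes(centers, np.zeros(centers.size)) == []

    def test_runs_above_threshold(self):
        centers = np.arange(0.0, 20.0, 2.0)
        scores = np.array([0, 0, 0.9, 0.9, 0.9, 0, 0, 0.9, 0, 0], float)
        eps = detect_episodes(centers, scores, 0.5, min_duration=4.0,
                              label="crawling")
        assert len(eps) == 1
        assert eps[0].t_start == pytest.approx(3.0)
        assert eps[0].t_end == pytest.approx(9.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        centers = np.arange(0.0, 400.0, 2.0)
        scores = np.clip(rng.normal(0.5, 0.2, centers.size), 0, 1)
        def labeled_time(th):
            return sum(iv.duration for iv in detect_episodes(centers, scores, th))
        ts = [labeled_time(th) for th in (0.3, 0.5, 0.7)]
        assert ts[0] >= ts[1] >= ts[2]

    def test_detected_crawling_overlaps_truth(self, repertoire_session):
        from leechdendro.containers import intervals_with_label

        s = repertoire_session
        template = behavior_dendrogram(s, "crawling")
        centers, scores = match_behavior_template(s, template, "crawling")
        detected = detect_episodes(centers, scores, 0.5, min_duration=20.0,
                                   label="crawling", erode=50.0, merge_gap=30.0)
        truth = intervals_with_label(s.schedule, "crawling")
        grid = np.arange(0.0, s.duration, 1.0)
        in_det = np.zeros(grid.size, bool)
        in_truth = np.zeros(grid.size, bool)
        for iv in detected:
            in_det |= (grid >= iv.t_start) & (grid < iv.t_end)
        for iv in truth:
            in_truth |= (grid >= iv.t_start) & (grid < iv.t_end)
        jaccard = (in_det & in_truth).sum() / (in_det | in_truth).sum()
        assert jaccard > 0.8


class TestDiscriminant:
    def test_feature_count_is_pairs(self):
        mats = np.zeros((5, 24, 24))
        assert covariance_features(mats).shape == (5, 276)

    def test_pca_identity_when_components_cover(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        Z, pca = pca_reduce(X, n_components=10)
        assert pca is None and Z is X  # applied only when needed
        with pytest.raises(ValueError):
            pca_reduce(X, n_components=11)

    def test_pca_projects_to_requested_dimension(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 30))
        Z, pca = pca_reduce(X, n_components=10)
        assert Z.shape == (50, 10)
        # full-rank reconstruction through all components is exact
        Zf, pf = pca_reduce(X, n_components=29)
        back = pf.inverse_transform(Zf)
        assert np.abs(back - X).max() < 0.5  # 29/30 components

    @pytest.mark.parametrize("kind", ["linear", "diaglinear", "quadratic",
                                      "diagquadratic"])
    def test_separable_clouds_classified_perfectly(self, kind):
        rng = np.random.default_rng(7)
        X0 = rng.normal(0.0, 0.5, size=(100, 4))
        X1 = rng.normal(5.0, 0.5, size=(100, 4))
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 100)
        pred = discriminant_classify(X, y, X, kind)
        assert (pred == y).all()

    def test_linear_beats_naive_bayes_on_correlated_features(self):
        rng = np.random.default_rng(8)
        # class difference lives along a direction masked by correlation
        cov = np.array([[1.0, 0.95], [0.95, 1.0]])
        L = np.linalg.cholesky(cov)
        X0 = rng.normal(size=(300, 2)) @ L.T
        X1 = rng.normal(size=(300, 2)) @ L.T + np.array([0.5, -0.5])
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 300)
        acc = {
            kind: (discriminant_classify(X, y, X, kind) == y).mean()
            for kind in ("linear", "diaglinear")
        }
        assert acc["linear"] >= acc["diaglinear"]

    def test_matches_sklearn_lda_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=120) > 0).astype(int)
        Xt = rng.normal(size=(60, 5))
        mine = discriminant_classify(X, y, Xt, "linear")
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(Xt)
        assert (mine == ref).mean() > 0.97

    def test_singular_covariance_advises_pca(self):
        X = np.zeros((10, 3))
        X[:5, 0] = 1.0
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="PCA"):
            discriminant_classify(X, y, X, "linear")
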