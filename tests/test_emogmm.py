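"""EM training, MAP adaptation, scoring and cross-validated classification."""

import numpy as np
import pytest

from emotruth import (
    EMOTIONS,
    ConcordanceMatrix,
    EmotionLabel,
    EmotionModelSet,
    GaussianMixture,
    classify,
    kfold_evaluate,
    map_adapt,
    score,
    train_model_set,
    train_ubm,
)

RNG = np.random.default_rng(0)


def gaussian_corpus(means, n_per_class=20, frames_per_utt=30, scale=0.3, seed=0):
    """Synthetic 2-D feature corpus embedded in the 60-dim feature space."""
    rng = np.random.default_rng(seed)
    corpus = {}
    for label, mu in zip(EMOTIONS, means):
        utts = []
        for _ in range(n_per_class):
            x = np.zeros((frames_per_utt, 60))
            x[:, :2] = mu + scale * rng.standard_normal((frames_per_utt, 2))
            x[:, 2:] = 0.1 * rng.standard_normal((frames_per_utt, 58))
            utts.append(x)
        corpus[label] = utts
    return corpus


class TestTrainUbm:
    def test_single_component_closed_form(self):
        x = RNG.standard_normal((500, 60)) * 1.7 + 0.4
        gmm = train_ubm(x, n_components=1, seed=0, max_iter=5)
        np.testing.assert_allclose(gmm.means[0], x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(gmm.covariances[0], x.var(axis=0), atol=1e-8)
        assert gmm.weights[0] == pytest.approx(1.0)

    def test_two_cluster_recovery(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((800, 60)) * 0.1 + 2.0
        b = rng.standard_normal((400, 60)) * 0.1 - 2.0
        gmm = train_ubm(np.vstack([a, b]), n_components=2, seed=1)
        order = np.argsort(gmm.means[:, 0])
        assert np.max(np.abs(gmm.means[order[0]] + 2.0)) < 0.05
        assert np.max(np.abs(gmm.means[order[1]] - 2.0)) < 0.05
        np.testing.assert_allclose(sorted(gmm.weights), [1 / 3, 2 / 3], atol=0.02)

    def test_loglik_monotone_nondecreasing(self):
        x = RNG.standard_normal((600, 60))
        x[:300] += 1.5
        _, history = train_ubm(x, n_components=4, seed=2, return_history=True)
        assert np.all(np.diff(history) >= -1e-6 * np.abs(history[:-1]))

    def test_too_few_frames_errors(self):
        with pytest.raises(ValueError):
            train_ubm(RNG.standard_normal((3, 60)), n_components=8)

    def test_matches_sklearn_loglik(self):
        """Independent cross-check: our EM reaches a comparable optimum."""
        from sklearn.mixture import GaussianMixture as SkGMM

        rng = np.random.default_rng(5)
        x = np.vstack(
            [rng.standard_normal((300, 4)) + 3, rng.standard_normal((300, 4)) - 3]
        )
        x = np.hstack([x, np.zeros((600, 56))]) + 0.01 * rng.standard_normal((600, 60))
        ours = train_ubm(x, n_components=2, seed=0)
        theirs = SkGMM(2, covariance_type="diag", random_state=0, reg_covar=1e-6).fit(x)
        ll_ours = ours.log_likelihood(x) / len(x)
        ll_theirs = theirs.score(x)
        assert ll_ours == pytest.approx(ll_theirs, rel=0.02)


@pytest.fixture(scope="module")
def ubm():
    x = np.random.default_rng(1).standard_normal((1000, 60))
    return train_ubm(x, n_components=4, seed=1)


class TestMapAdapt:
    def test_empty_data_is_identity(self, ubm):
        adapted = map_adapt(ubm, None)
        np.testing.assert_array_equal(adapted.means, ubm.means)
        np.testing.assert_array_equal(adapted.weights, ubm.weights)
        np.testing.assert_array_equal(adapted.covariances, ubm.covariances)

    def test_small_relevance_reaches_data_means(self, ubm):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5000, 60)) * 0.5 + 4.0
        adapted = map_adapt(ubm, x, relevance_factor=1e-6)
        resp = ubm.responsibilities(x)
        nk = resp.sum(axis=0)
        ex = (resp.T @ x) / nk[:, None]
        # components that actually saw data reach their posterior data means
        seen = nk > 1.0
        np.testing.assert_allclose(adapted.means[seen], ex[seen], atol=1e-4)

    def test_count_equal_relevance_is_midpoint(self):
        # single component: soft count equals frame count exactly
        ubm = GaussianMixture(np.array([1.0]), np.zeros((1, 60)), np.ones((1, 60)))
        x = np.ones((16, 60)) * 3.0
        adapted = map_adapt(ubm, x, relevance_factor=16.0)
        np.testing.assert_allclose(adapted.means[0], 1.5, atol=1e-12)

    def test_dimension_mismatch_errors(self, ubm):
        with pytest.raises(ValueError):
            map_adapt(ubm, np.ones((10, 3)))


class TestScoreAndClassify:
    def unit_model_set(self):
        gmm = GaussianMixture(np.array([1.0]), np.zeros((1, 60)), np.ones((1, 60)))
        return EmotionModelSet(gmm, {e: gmm for e in EMOTIONS})

    def test_single_frame_at_mean_closed_form(self):
        models = self.unit_model_set()
        s = score(models, np.zeros((1, 60)))
        np.testing.assert_allclose(s, -(60 / 2) * np.log(2 * np.pi), atol=1e-10)

    def test_brute_force_density_oracle(self):
        rng = np.random.default_rng(4)
        M, D, T = 3, 5, 4
        w = rng.dirichlet(np.ones(M))
        mu = rng.standard_normal((M, D))
        var = rng.uniform(0.5, 2.0, (M, D))
        gmm = GaussianMixture(w, mu, var)
        x = rng.standard_normal((T, D))
        expected = 0.0
        for t in range(T):
            dens = 0.0
            for k in range(M):
                norm = np.prod(1 / np.sqrt(2 * np.pi * var[k]))
                dens += w[k] * norm * np.exp(-0.5 * np.sum((x[t] - mu[k]) ** 2 / var[k]))
            expected += np.log(dens)
        assert gmm.log_likelihood(x) == pytest.approx(expected, rel=1e-8)

    def test_duplicating_frames_doubles_score(self):
        models = self.unit_model_set()
        x = np.random.default_rng(5).standard_normal((7, 60))
        s1 = score(models, x)
        s2 = score(models, np.vstack([x, x]))
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_equal_scores_give_uniform_posterior_neutral(self):
        models = self.unit_model_set()
        label, post = classify(models, np.random.default_rng(6).standard_normal((3, 60)))
        np.testing.assert_allclose(post, 0.2, atol=1e-12)
        assert label == EmotionLabel.NEUTRAL  # tie broken by canonical order

    def test_posteriors_normalized(self):
        corpus = gaussian_corpus(np.array([[i * 2.0, -i] for i in range(5)]), seed=7)
        models = train_model_set(corpus, n_components=4, seed=0)
        for utt in corpus[EmotionLabel.SAD][:3]:
            _, post = classify(models, utt)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_features_error(self):
        with pytest.raises(ValueError):
            score(self.unit_model_set(), np.empty((0, 60)))


class TestKfold:
    def test_perfect_separation_corpus(self):
        corpus = gaussian_corpus(
            np.array([[0, 0], [8, 0], [0, 8], [8, 8], [-8, 4]], float),
            n_per_class=10, seed=8,
        )
        cm = kfold_evaluate(corpus, k=5, n_components=4, seed=0, max_iter=10)
        assert cm.accuracy_overall == 1.0

    def test_identical_classes_are_chance(self):
        corpus = gaussian_corpus(np.zeros((5, 2)), n_per_class=20, seed=9)
        cm = kfold_evaluate(corpus, k=5, n_components=4, seed=0, max_iter=10)
        assert abs(cm.accuracy_overall - 0.2) < 0.1

    def test_confusion_concentrates_on_overlapping_pair(self):
        # Sad and Angry generated nearly on top of each other; others far apart
        means = np.array([[0, 0], [10, 0], [0, 10], [0.3, 10], [10, 10]], float)
        corpus = gaussian_corpus(means, n_per_class=10, scale=0.5, seed=10)
        cm = kfold_evaluate(corpus, k=5, n_components=4, seed=0, max_iter=10)
        off = cm.counts - np.diag(np.diag(cm.counts))
        sad, angry = int(EmotionLabel.SAD), int(EmotionLabel.ANGRY)
        pair_errors = off[sad, angry] + off[angry, sad]
        assert pair_errors >= 0.8 * off.sum()

    def test_class_smaller_than_k_errors(self):
        corpus = gaussian_corpus(np.zeros((5, 2)), n_per_class=3, seed=11)
        with pytest.raises(ValueError, match="smaller K"):
            kfold_evaluate(corpus, k=5, n_components=2)


class TestConcordance:
    def test_accuracy_identities(self):
        counts = np.array(
            [[8, 1, 0, 0, 1], [0, 7, 2, 0, 1], [1, 1, 6, 1, 1], [0, 0, 2, 8, 0], [1, 0, 0, 0, 9]]
        )
        cm = ConcordanceMatrix(counts)
        assert cm.accuracy_overall == pytest.approx(np.trace(counts) / counts.sum())
        np.testing.assert_allclose(
            cm.accuracy_per_class, np.diag(counts) / counts.sum(axis=1)
        )
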