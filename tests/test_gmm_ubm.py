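"""GMM-UBM back-end: EM, MAP adaptation, likelihood scoring, identification."""

import numpy as np
import pytest

from neurosid.gmm_ubm import (
    GMMModel,
    SpeakerModelSet,
    em_fit,
    identify,
    load_models,
    loglik,
    map_adapt,
    save_models,
    train_speaker_models,
)


@pytest.fixture
def toy_model(rng):
    means = rng.normal(size=(3, 2))
    variances = rng.uniform(0.5, 2.0, size=(3, 2))
    return GMMModel(np.array([0.5, 0.3, 0.2]), means, variances)


class TestLoglik:
    def test_standard_normal_closed_form(self):
        m = GMMModel(np.array([1.0]), np.zeros((1, 1)), np.ones((1, 1)))
        assert loglik(m, np.zeros((1, 1))) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_matches_brute_force_sum(self, toy_model, rng):
        # independent oracle: direct density sum without log-sum-exp
        data = rng.normal(size=(5, 2))
        expected = 0.0
        for x in data:
            dens = 0.0
            for w, mu, var in zip(toy_model.weights, toy_model.means,
                                  toy_model.variances):
                dens += w * np.prod(
                    np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
                )
            expected += np.log(dens)
        assert loglik(toy_model, data) == pytest.approx(expected, abs=1e-10)

    def test_additivity_over_frames(self, toy_model, rng):
        data = rng.normal(size=(4, 2))
        extra = np.vstack([data, data[-1:]])
        gain = loglik(toy_model, extra) - loglik(toy_model, data)
        assert gain == pytest.approx(loglik(toy_model, data[-1:]), abs=1e-10)

    def test_stable_far_from_means(self, toy_model):
        # log-sum-exp must not underflow to -inf for plausible outliers
        assert np.isfinite(loglik(toy_model, np.full((1, 2), 50.0)))


class TestEmFit:
    def test_single_gaussian_matches_moments(self, rng):
        data = rng.normal(loc=3.0, scale=2.0, size=(5000, 1))
        m = em_fit(data, n_components=1, seed=0)
        assert m.means[0, 0] == pytest.approx(data.mean(), abs=1e-6)
        assert m.variances[0, 0] == pytest.approx(data.var(), rel=1e-4)

    def test_two_cluster_recovery(self, rng):
        data = np.vstack([
            rng.normal(loc=-10.0, size=(1000, 2)),
            rng.normal(loc=+10.0, size=(1000, 2)),
        ])
        m = em_fit(data, n_components=2, seed=0)
        centers = np.sort(m.means[:, 0])
        assert centers[0] == pytest.approx(-10.0, abs=0.1)
        assert centers[1] == pytest.approx(+10.0, abs=0.1)
        np.testing.assert_allclose(m.weights, 0.5, atol=0.05)

    def test_loglik_monotone_nondecreasing(self, rng):
        data = rng.normal(size=(400, 3)) + rng.integers(0, 2, size=(400, 1)) * 4.0
        m = em_fit(data, n_components=4, seed=1)
        hist = np.array(m.meta["loglik_history"])
        assert np.all(np.diff(hist) >= -1e-8 * np.abs(hist[:-1]))

    def test_cross_check_against_sklearn(self, rng):
        # sklearn's GaussianMixture as an independent reference: final
        # likelihoods should land in the same place on easy data
        from sklearn.mixture import GaussianMixture

        data = np.vstack([
            rng.normal(loc=-5.0, size=(500, 2)),
            rng.normal(loc=+5.0, size=(500, 2)),
        ])
        ours = em_fit(data, n_components=2, seed=0)
        ref = GaussianMixture(2, covariance_type="diag", random_state=0,
                              reg_covar=1e-6).fit(data)
        assert loglik(ours, data) == pytest.approx(
            ref.score(data) * data.shape[0], rel=1e-3
        )

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.empty((0, 2)), n_components=2)

    def test_few_frames_warns(self, rng):
        with pytest.warns(UserWarning, match="frames"):
            em_fit(rng.normal(size=(30, 2)), n_components=8, seed=0)


class TestMapAdapt:
    def test_infinite_relevance_returns_ubm_means(self, toy_model, rng):
        adapted = map_adapt(toy_model, rng.normal(size=(50, 2)), relevance=np.inf)
        np.testing.assert_array_equal(adapted.means, toy_model.means)

    def test_weights_variances_untouched(self, toy_model, rng):
        adapted = map_adapt(toy_model, rng.normal(size=(50, 2)), relevance=8.0)
        np.testing.assert_array_equal(adapted.weights, toy_model.weights)
        np.testing.assert_array_equal(adapted.variances, toy_model.variances)

    def test_zero_relevance_gives_posterior_mean(self):
        # one far-away component takes all posterior mass
        m = GMMModel(np.array([0.5, 0.5]),
                     np.array([[0.0], [100.0]]),
                     np.ones((2, 1)))
        data = np.array([[1.0], [3.0]])
        adapted = map_adapt(m, data, relevance=0.0)
        assert adapted.means[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_relevance_equal_counts_gives_midpoint(self):
        m = GMMModel(np.array([1.0]), np.array([[0.0]]), np.ones((1, 1)))
        data = np.full((4, 1), 6.0)  # n_k = 4, x_bar = 6
        adapted = map_adapt(m, data, relevance=4.0)
        assert adapted.means[0, 0] == pytest.approx(3.0, abs=1e-12)


class TestIdentify:
    def _model_set(self, rng, n_speakers=5, m=8, d=4):
        by_speaker = {
            f"s{i}": rng.normal(loc=3.0 * i, size=(300, d))
            for i in range(n_speakers)
        }
        return train_speaker_models(by_speaker, n_components=m, seed=0), by_speaker

    def test_self_consistency(self, rng):
        models, by_speaker = self._model_set(rng)
        for sid, feats in by_speaker.items():
            test = feats[:500] + 0.1 * rng.standard_normal(feats[:500].shape)
            got, margin = identify(models, test)
            assert got == sid
            assert margin > 0

    def test_single_speaker_margin_infinite(self, rng):
        models = SpeakerModelSet(
            GMMModel(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2))),
            [("only", GMMModel(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2))))],
        )
        sid, margin = identify(models, rng.normal(size=(10, 2)))
        assert sid == "only"
        assert margin == np.inf

    def test_tie_breaks_to_first_with_warning(self, rng):
        g = GMMModel(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2)))
        models = SpeakerModelSet(g, [("a", g), ("b", g)])
        with pytest.warns(UserWarning, match="tie"):
            sid, margin = identify(models, rng.normal(size=(10, 2)))
        assert sid == "a"
        assert margin == pytest.approx(0.0)

    def test_invariant_to_frame_duplication(self, rng):
        # duplicating the test frames adds the same multiple to every
        # speaker's total loglik; decision and per-frame margin must hold
        models, by_speaker = self._model_set(rng, n_speakers=3)
        test = by_speaker["s1"][:200]
        base, margin1 = identify(models, test)
        again, margin2 = identify(models, np.vstack([test, test]))
        assert base == again == "s1"
        assert margin2 == pytest.approx(margin1, rel=1e-9)

    def test_empty_model_set_rejected(self, rng):
        with pytest.raises(ValueError):
            identify(SpeakerModelSet(None, []), rng.normal(size=(5, 2)))

    def test_persistence_round_trip(self, rng, tmp_path):
        models, by_speaker = self._model_set(rng, n_speakers=3)
        save_models(models, tmp_path / "models.json")
        back = load_models(tmp_path / "models.json")
        assert back.relevance == models.relevance
        for (sid_a, m_a), (sid_b, m_b) in zip(models.speakers, back.speakers):
            assert sid_a == sid_b
            np.testing.assert_array_equal(m_a.means, m_b.means)
        test = by_speaker["s2"][:100]
        assert identify(back, test)[0] == identify(models, test)[0]
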