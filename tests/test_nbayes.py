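import numpy as np
import pytest
from scipy.stats import norm

import fasd_eeg as fe
from fasd_eeg.core import ParameterError
from fasd_eeg.nbayes import NBModel, _log_scores


def brute_force_posterior(model: NBModel, x: np.ndarray) -> np.ndarray:
    """Direct Bayes rule with an explicit normalizer, in linear space."""
    joint = np.array(
        [
            model.priors[k]
            * np.prod(norm.pdf(x, model.means[k], np.sqrt(model.variances[k])))
            for k in range(len(model.classes))
        ]
    )
    return joint / joint.sum()


def random_model_and_data(seed, n=30, d=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d)) * rng.uniform(0.5, 2.0, d) + rng.normal(0, 2, d)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b"] += rng.normal(0, 1, d)
    return fe.fit(X, y), rng.standard_normal(d)


class TestFit:
    def test_balanced_priors(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.array(["control"] * 30 + ["fasd"] * 30)
        model = fe.fit(X, y)
        assert model.classes == ("control", "fasd")
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_moments_match_two_pass_computation(self, rng):
        X = rng.standard_normal((25, 6)) * 3 + 1
        y = np.array(["a"] * 11 + ["b"] * 14)
        model = fe.fit(X, y)
        for k, c in enumerate(model.classes):
            Xc = X[y == c]
            mu = np.array([sum(col) / len(col) for col in Xc.T])
            var = np.array(
                [sum((v - m) ** 2 for v in col) / len(col) for col, m in zip(Xc.T, mu)]
            )
            np.testing.assert_allclose(model.means[k], mu, rtol=1e-12)
            np.testing.assert_allclose(model.variances[k], var, rtol=1e-9)

    def test_constant_feature_gets_floor(self, rng):
        X = rng.standard_normal((20, 3))
        X[:10, 1] = 5.0  # constant within class "a"
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fe.fit(X, y)
        assert model.variances[0, 1] == model.variance_floor[1] > 0
        # scoring still finite
        assert np.isfinite(fe.log_posterior(model, X[0]).log_scores).all()

    def test_single_class_or_tiny_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ParameterError):
            fe.fit(X, np.array(["a"] * 10))
        with pytest.raises(ParameterError):
            fe.fit(X, np.array(["a"] * 9 + ["b"]))


class TestPosterior:
    def test_symmetric_midpoint_is_fifty_fifty(self):
        X = np.array([[-1.0], [1.0], [0.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fe.fit(X, y)  # class means 0 and 1, equal variances and priors
        post = fe.log_posterior(model, np.array([0.5]))
        np.testing.assert_allclose(post.probabilities, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_bayes_rule(self, seed):
        model, x = random_model_and_data(seed)
        post = fe.log_posterior(model, x)
        np.testing.assert_allclose(
            post.probabilities, brute_force_posterior(model, x), atol=1e-10
        )

    def test_normalization_and_no_underflow_at_900_features(self, rng):
        X = rng.standard_normal((40, 900))
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = fe.fit(X, y)
        post = fe.log_posterior(model, rng.standard_normal(900))
        assert np.isfinite(post.log_scores).all()
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_and_nonfinite_rejected(self, rng):
        model, _ = random_model_and_data(0)
        with pytest.raises(ParameterError):
            fe.log_posterior(model, np.zeros(99))
        with pytest.raises(ParameterError):
            fe.log_posterior(model, np.array([np.nan, 0.0, 0.0]))


class TestPredict:
    def test_tie_breaks_to_first_class(self):
        X = np.array([[-1.0], [1.0], [0.0], [2.0]])
        model = fe.fit(X, np.array(["a", "a", "b", "b"]))
        assert fe.predict(model, np.array([0.5])) == "a"

    def test_class_mean_maps_to_class(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
        y = np.array(["lo"] * 20 + ["hi"] * 20)
        model = fe.fit(X, y)
        assert fe.predict(model, model.means[1]) == "hi"

    def test_full_agreement_with_sklearn(self):
        from sklearn.naive_bayes import GaussianNB

        agree = total = 0
        for seed in range(120):
            rng = np.random.default_rng(seed)
            n, d = int(rng.integers(10, 50)), int(rng.integers(1, 6))
            X = rng.standard_normal((n, d)) * rng.uniform(0.5, 3, d)
            y = np.where(rng.random(n) < 0.5, "a", "b")
            if min((y == "a").sum(), (y == "b").sum()) < 2:
                continue
            Xt = rng.standard_normal((20, d)) * 2
            ours = fe.fit(X, y)
            sk = GaussianNB(var_smoothing=1e-12).fit(X, y)
            agree += int(np.sum(fe.predict(ours, Xt) == sk.predict(Xt)))
            total += 20
        assert total >= 100 * 20 * 0.8
        assert agree == total

    def test_affine_rescaling_invariance(self, rng):
        """Per-feature affine maps of train+test leave predictions unchanged."""
        X = rng.standard_normal((40, 5))
        y = np.where(rng.random(40) < 0.5, "a", "b")
        Xt = rng.standard_normal((30, 5))
        a = rng.uniform(0.1, 10, 5)
        b = rng.normal(0, 5, 5)
        p1 = fe.predict(fe.fit(X, y), Xt)
        p2 = fe.predict(fe.fit(X * a + b, y), Xt * a + b)
        assert (p1 == p2).all()

    def test_bayes_error_recovery_1d(self):
        rng = np.random.default_rng(99)
        Xtr = np.concatenate([rng.normal(0, 1, 2000), rng.normal(1, 1, 2000)])[:, None]
        ytr = np.array(["a"] * 2000 + ["b"] * 2000)
        Xte = np.concatenate([rng.normal(0, 1, 10000), rng.normal(1, 1, 10000)])[:, None]
        yte = np.array(["a"] * 10000 + ["b"] * 10000)
        acc = np.mean(fe.predict(fe.fit(Xtr, ytr), Xte) == yte)
        assert acc == pytest.approx(norm.cdf(0.5), abs=0.02)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        model, x = random_model_and_data(3)
        model.to_json(tmp_path / "model.json")
        back = NBModel.from_json(tmp_path / "model.json")
        assert back.classes == model.classes
        np.testing.assert_allclose(
            _log_scores(back, x), _log_scores(model, x), rtol=1e-12
        )
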