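"""CSP eigenproblem, feature extraction, and the CSP-SVM baseline."""

import numpy as np
import pytest

from baraug import (
    AVERAGED_TRACE_NORM,
    POOLED,
    CSPSVMBaseline,
    GeneratorParams,
    class_covariance,
    csp_features,
    fit_csp,
    make_subject,
    split_pool,
)


def _random_spd(rng, c=6):
    a = rng.standard_normal((c, c))
    return a @ a.T + 0.1 * np.eye(c)


def rayleigh(w, c1, c2):
    return float(w @ c1 @ w) / float(w @ c2 @ w)


class TestClassCovariance:
    def test_orthonormal_rows_give_identity_pooled(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((20, 4)))
        trial = q.T[None]  # 4 orthonormal rows of length 20
        cov = class_covariance(trial, mode=POOLED)
        np.testing.assert_allclose(cov.matrix, np.eye(4), atol=1e-12)

    def test_duplication_scaling(self):
        rng = np.random.default_rng(1)
        trials = rng.standard_normal((5, 4, 30))
        doubled = np.concatenate([trials, trials])
        pooled = class_covariance(trials, mode=POOLED).matrix
        pooled2 = class_covariance(doubled, mode=POOLED).matrix
        np.testing.assert_allclose(pooled2, 2 * pooled, rtol=1e-12)
        tn = class_covariance(trials, mode=AVERAGED_TRACE_NORM).matrix
        tn2 = class_covariance(doubled, mode=AVERAGED_TRACE_NORM).matrix
        np.testing.assert_allclose(tn2, tn, rtol=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((3, 5, 40))
        got = class_covariance(trials, mode=POOLED).matrix
        want = np.zeros((5, 5))
        for x in trials:
            for a in range(5):
                for b in range(5):
                    want[a, b] += np.dot(x[a], x[b])
        np.testing.assert_allclose(got, (want + want.T) / 2, rtol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            class_covariance(np.zeros((2, 3, 10)), mode=AVERAGED_TRACE_NORM)


class TestFitCSP:
    def test_diagonal_analytic_case(self):
        bank = fit_csp(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), k=1, reg=0.0)
        assert bank.eigenvalues[0] == pytest.approx(2.0)
        assert abs(bank.filters[0, 0]) > 100 * abs(bank.filters[1, 0])
        # swapped problem: class-2 filter along the other axis with eigenvalue 2
        assert bank.eigenvalues[1] == pytest.approx(2.0)
        assert abs(bank.filters[1, 1]) > 100 * abs(bank.filters[0, 1])

    def test_rayleigh_scale_invariance(self):
        rng = np.random.default_rng(3)
        c1, c2 = _random_spd(rng), _random_spd(rng)
        w = rng.standard_normal(6)
        assert rayleigh(3.0 * w, c1, c2) == pytest.approx(rayleigh(w, c1, c2), rel=1e-12)

    def test_constraint_satisfaction(self):
        rng = np.random.default_rng(4)
        c1, c2 = _random_spd(rng), _random_spd(rng)
        bank = fit_csp(c1, c2, k=3, reg=0.0)
        for f in range(3):
            w = bank.filters[:, f]
            assert w @ c2 @ w == pytest.approx(1.0, abs=1e-8)
        for f in range(3, 6):
            w = bank.filters[:, f]
            assert w @ c1 @ w == pytest.approx(1.0, abs=1e-8)

    def test_eigen_residual(self):
        rng = np.random.default_rng(5)
        c1, c2 = _random_spd(rng), _random_spd(rng)
        bank = fit_csp(c1, c2, k=3, reg=0.0)
        for f in range(3):
            w, lam = bank.filters[:, f], bank.eigenvalues[f]
            assert np.linalg.norm(c1 @ w - lam * (c2 @ w)) <= 1e-8 * np.linalg.norm(c1 @ w)

    def test_top_filter_beats_monte_carlo_search(self):
        """The generalized-eigen maximizer dominates 1e5 random directions."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            c1, c2 = _random_spd(rng), _random_spd(rng)
            bank = fit_csp(c1, c2, k=3, reg=0.0)
            best_eig = rayleigh(bank.filters[:, 0], c1, c2)
            dirs = rng.standard_normal((100_000, 6))
            quot = np.einsum("nc,cd,nd->n", dirs, c1, dirs) / np.einsum(
                "nc,cd,nd->n", dirs, c2, dirs
            )
            assert best_eig >= quot.max() - 1e-9
            assert best_eig == pytest.approx(bank.eigenvalues[0], rel=1e-10)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            fit_csp(_random_spd(rng, 4), _random_spd(rng, 4), k=3)

    def test_non_psd_rejected(self):
        bad = np.diag([1.0, -1.0])
        with pytest.raises(ValueError):
            fit_csp(bad, np.eye(2), k=1)


class TestFeatures:
    def _bank(self):
        rng = np.random.default_rng(8)
        return fit_csp(_random_spd(rng), _random_spd(rng), k=3)

    def test_normalization_sums_to_one(self):
        bank = self._bank()
        x = np.random.default_rng(9).standard_normal((6, 100))
        f = csp_features(x, bank)
        assert f.shape == (6,)
        assert np.exp(f).sum() == pytest.approx(1.0, abs=1e-10)

    def test_amplitude_invariance(self):
        bank = self._bank()
        x = np.random.default_rng(10).standard_normal((6, 100))
        np.testing.assert_allclose(csp_features(2.0 * x, bank), csp_features(x, bank), atol=1e-10)

    def test_pure_source_maximizes_own_feature(self):
        bank = self._bank()
        # project a rank-1 epoch onto the direction the first filter passes best
        w = bank.filters[:, 0]
        pattern = np.linalg.pinv(bank.filters.T)[:, 0]
        x = np.outer(pattern, np.sin(np.linspace(0, 20, 200)))
        x += 1e-6 * np.random.default_rng(11).standard_normal(x.shape)
        f = csp_features(x, bank)
        assert np.argmax(f) == 0

    def test_zero_variance_rejected(self):
        bank = self._bank()
        with pytest.raises(ValueError):
            csp_features(np.zeros((6, 50)), bank)


class TestBaseline:
    def test_separable_features_fit_perfectly(self):
        rng = np.random.default_rng(12)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        # two clearly separated variance profiles on 4 channels
        scale = np.where(labels[:, None] == 0, [4.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 4.0])
        trials = rng.standard_normal((n, 4, 100)) * scale[:, :, None]
        clf = CSPSVMBaseline(k=2).fit(trials, labels)
        assert clf.score(trials, labels) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        n = 200
        trials = rng.standard_normal((n, 4, 60))
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        half = n // 2
        clf = CSPSVMBaseline(k=2).fit(trials[:half], labels[:half])
        acc = clf.score(trials[half:], labels[half:])
        # 99% binomial CI around 0.5 for 100 held-out trials
        assert 0.37 <= acc <= 0.63

    def test_single_class_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            CSPSVMBaseline().fit(rng.standard_normal((10, 4, 50)), np.zeros(10))

    def test_warm_start_requires_previous_fit(self):
        rng = np.random.default_rng(15)
        clf = CSPSVMBaseline(k=2)
        with pytest.raises(ValueError):
            clf.fit(rng.standard_normal((8, 4, 50)), np.repeat([0, 1], 4), warm_start=True)

    def test_strong_erd_high_holdout_accuracy(self):
        es, _ = make_subject(GeneratorParams(erd_depth=0.6, n_trials_per_class=100, seed=42))
        sd = split_pool(es, n_pool=100, seed=0)
        clf = CSPSVMBaseline().fit(sd.pool.data, sd.pool.labels)
        assert clf.score(sd.test.data, sd.test.labels) > 0.9
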