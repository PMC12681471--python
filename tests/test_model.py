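"""Likelihood, thresholds, analytic score, and maximum-likelihood fitting."""

import numpy as np
import pytest
from scipy.special import ndtr

from hopit.designs import LatentDesign, ThresholdDesign
from hopit.model import (
    FittedHopit,
    HopitParams,
    category_probabilities,
    fit,
    latent_index,
    log_likelihood,
    score,
    thresholds,
)


def _designs(X, Z):
    latent = LatentDesign(
        matrix=np.asarray(X, dtype=float),
        column_names=tuple(f"x{i}" for i in range(np.asarray(X).shape[1])),
        provenance=tuple(("main", f"x{i}") for i in range(np.asarray(X).shape[1])),
    )
    threshold = ThresholdDesign(
        matrix=np.asarray(Z, dtype=float),
        column_names=tuple(f"z{i}" for i in range(np.asarray(Z).shape[1])),
        group_block=(),
    )
    return latent, threshold


def _params(beta, lam, q):
    return HopitParams(
        beta=np.asarray(beta, dtype=float),
        lam=np.asarray(lam, dtype=float),
        gamma=np.zeros((4, q)),
    )


class TestLatentIndex:
    def test_zero_beta_gives_zeros(self):
        latent, _ = _designs(np.eye(3), np.empty((3, 0)))
        p = _params(np.zeros(3), np.zeros(4), 0)
        np.testing.assert_array_equal(latent_index(p, latent), np.zeros(3))

    def test_dot_product_and_linearity(self):
        latent, _ = _designs([[1, 0, 1]], np.empty((1, 0)))
        p = _params([0.2, 0.5, 0.3], np.zeros(4), 0)
        assert latent_index(p, latent)[0] == pytest.approx(0.5)
        p2 = _params([0.4, 1.0, 0.6], np.zeros(4), 0)
        assert latent_index(p2, latent)[0] == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self):
        latent, _ = _designs(np.ones((2, 3)), np.empty((2, 0)))
        p = _params(np.zeros(2), np.zeros(4), 0)
        with pytest.raises(ValueError, match="column"):
            latent_index(p, latent)


class TestThresholds:
    def test_unit_increments_at_zero_parameters(self):
        _, threshold = _designs(np.empty((3, 0)), np.zeros((3, 2)))
        p = _params([], np.zeros(4), 2)
        tau = thresholds(p, threshold)
        np.testing.assert_allclose(tau, np.tile([0, 1, 2, 3], (3, 1)))

    def test_exponential_increment_values(self):
        # lambda = (0.2, -0.1, 0.3, 0): tau = (0.2, 0.2+e^-0.1, +e^0.3, +1)
        _, threshold = _designs(np.empty((1, 0)), np.empty((1, 0)))
        p = _params([], [0.2, -0.1, 0.3, 0.0], 0)
        tau = thresholds(p, threshold)[0]
        expected = np.array(
            [0.2, 0.2 + np.exp(-0.1), 0.2 + np.exp(-0.1) + np.exp(0.3),
             0.2 + np.exp(-0.1) + np.exp(0.3) + 1.0]
        )
        np.testing.assert_allclose(tau, expected, rtol=1e-12)
        np.testing.assert_allclose(
            tau, [0.2, 1.104837, 2.454696, 3.454696], atol=5e-7
        )

    def test_coherence_over_random_draws(self):
        # the construction keeps tau strictly increasing for any parameters
        rng = np.random.default_rng(42)
        for _ in range(1000):
            q = int(rng.integers(0, 4))
            Z = rng.integers(0, 2, size=(5, q)).astype(float)
            _, threshold = _designs(np.empty((5, 0)), Z)
            p = HopitParams(
                beta=np.empty(0),
                lam=rng.normal(0, 3, size=4),
                gamma=rng.normal(0, 3, size=(4, q)),
            )
            tau = thresholds(p, threshold)
            assert np.all(np.diff(tau, axis=1) > 0)
            assert np.isfinite(tau).all()

    def test_non_finite_parameter_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            HopitParams(beta=np.array([np.nan]), lam=np.zeros(4),
                        gamma=np.zeros((4, 0)))


class TestLogLikelihood:
    def test_closed_form_single_row_level1(self):
        latent, threshold = _designs(np.zeros((1, 1)), np.empty((1, 0)))
        p = _params([0.0], [0.0, 0.0, 0.0, 0.0], 0)  # tau = (0,1,2,3)
        ll = log_likelihood(p, latent, threshold, np.array([1]), np.ones(1))
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_closed_form_single_row_level5(self):
        latent, threshold = _designs(np.zeros((1, 1)), np.empty((1, 0)))
        p = _params([0.0], [0.0, 0.0, 0.0, 0.0], 0)
        ll = log_likelihood(p, latent, threshold, np.array([5]), np.ones(1))
        assert ll == pytest.approx(np.log(1 - ndtr(3.0)), rel=1e-10)
        assert ll == pytest.approx(-6.60773, abs=1e-5)

    def test_duplicated_row_equals_double_weight(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(6, 2)).astype(float)
        Z = rng.integers(0, 2, size=(6, 1)).astype(float)
        y = rng.integers(1, 6, size=6)
        latent, threshold = _designs(X, Z)
        p = HopitParams(beta=np.array([0.3, -0.2]), lam=np.zeros(4),
                        gamma=rng.normal(0, 0.2, (4, 1)))
        w = np.ones(6)
        w2 = w.copy()
        w2[2] = 2.0
        latent_dup, threshold_dup = _designs(
            np.vstack([X, X[2]]), np.vstack([Z, Z[2]])
        )
        ll_dup = log_likelihood(
            p, latent_dup, threshold_dup, np.append(y, y[2]), np.ones(7)
        )
        ll_w = log_likelihood(p, latent, threshold, y, w2)
        assert ll_dup == ll_w  # exact equality of the weighted sum

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(50, 3)).astype(float)
        Z = rng.integers(0, 2, size=(50, 2)).astype(float)
        latent, threshold = _designs(X, Z)
        p = HopitParams(
            beta=rng.normal(size=3), lam=rng.normal(size=4),
            gamma=rng.normal(scale=0.5, size=(4, 2)),
        )
        probs = category_probabilities(p, latent, threshold)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_parameters_stay_finite(self):
        latent, threshold = _designs(np.ones((2, 1)), np.empty((2, 0)))
        p = _params([50.0], [0.0, 0.0, 0.0, 0.0], 0)
        ll = log_likelihood(p, latent, threshold, np.array([1, 1]), np.ones(2))
        assert np.isfinite(ll)

    def test_invalid_inputs_rejected(self):
        latent, threshold = _designs(np.zeros((1, 1)), np.empty((1, 0)))
        p = _params([0.0], np.zeros(4), 0)
        with pytest.raises(ValueError, match="1..5"):
            log_likelihood(p, latent, threshold, np.array([6]), np.ones(1))
        with pytest.raises(ValueError, match="positive sum"):
            log_likelihood(p, latent, threshold, np.array([1]), np.zeros(1))


class TestScore:
    @staticmethod
    def _finite_diff(p, latent, threshold, y, w):
        theta = p.pack()
        pdim, qdim = latent.n_columns, threshold.n_columns
        fd = np.empty_like(theta)
        for i in range(theta.size):
            h = 1e-6 * (1 + abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd[i] = (
                log_likelihood(HopitParams.unpack(tp, pdim, qdim), latent,
                               threshold, y, w)
                - log_likelihood(HopitParams.unpack(tm, pdim, qdim), latent,
                                 threshold, y, w)
            ) / (2 * h)
        return fd

    def test_matches_finite_differences_at_random_points(self, compact_synth):
        s = compact_synth
        sub = slice(0, 200)
        latent = LatentDesign(
            matrix=s.latent.matrix[sub], column_names=s.latent.column_names,
            provenance=s.latent.provenance,
        )
        threshold = ThresholdDesign(
            matrix=s.threshold.matrix[sub],
            column_names=s.threshold.column_names,
            group_block=s.threshold.group_block,
        )
        y = s.table.outcome("Mobility")[sub]
        w = s.table.weights[sub]
        rng = np.random.default_rng(9)
        for _ in range(10):
            theta = rng.normal(0, 0.3, latent.n_columns + 4 + 4 * threshold.n_columns)
            p = HopitParams.unpack(theta, latent.n_columns, threshold.n_columns)
            g = score(p, latent, threshold, y, w)
            fd = self._finite_diff(p, latent, threshold, y, w)
            assert np.max(np.abs(g - fd) / (1 + np.abs(fd))) < 1e-6

    def test_zero_covariate_has_zero_gamma_gradient(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (30, 2)).astype(float)
        Z = np.zeros((30, 1))
        latent, threshold = _designs(X, Z)
        y = rng.integers(1, 6, 30)
        p = HopitParams(beta=np.array([0.2, 0.1]), lam=np.zeros(4),
                        gamma=np.full((4, 1), 0.3))
        g = score(p, latent, threshold, y, np.ones(30))
        gamma_block = g[2 + 4:]
        np.testing.assert_array_equal(gamma_block, np.zeros(4))

    def test_gradient_small_at_mle(self, compact_fit):
        assert compact_fit.gradient_norm < 1e-4 * (1 + abs(compact_fit.loglik))


class TestFit:
    def test_refit_is_deterministic(self, compact_synth):
        s = compact_synth
        y = s.table.outcome("Mobility")
        f1 = fit(s.latent, s.threshold, y, s.table.weights, fit_null=False)
        f2 = fit(s.latent, s.threshold, y, s.table.weights, fit_null=False)
        np.testing.assert_array_equal(f1.params.pack(), f2.params.pack())

    def test_nested_null_has_lower_loglik(self, compact_fit):
        assert compact_fit.loglik >= compact_fit.loglik_null

    def test_vcov_symmetric_psd(self, compact_fit):
        v = compact_fit.vcov
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        eig = np.linalg.eigvalsh(v)
        assert eig.min() >= -1e-10 * max(1.0, eig.max())

    def test_weight_rescaling_leaves_mle_unchanged(self):
        # balanced two-group design: every parameter is well identified,
        # so the maximizer is unique and scale-free
        import dataclasses

        from hopit.simulate import SyntheticConfig, generate

        cfg = dataclasses.replace(
            SyntheticConfig(n=1500, seed=13).compact(),
            group_shares={"group_white": 0.5, "group_asian": 0.5},
            group_shifts={"group_asian": (0.2, 0.1, 0.0, 0.0)},
        )
        s = generate(cfg)
        y = s.table.outcome("Mobility")
        w = s.table.weights
        f1 = fit(s.latent, s.threshold, y, w, fit_null=False)
        f2 = fit(s.latent, s.threshold, y, w * 7.5, fit_null=False)
        assert np.max(np.abs(f1.params.pack() - f2.params.pack())) < 1e-8

    def test_missing_level_warns(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (200, 1)).astype(float)
        latent, threshold = _designs(X, np.empty((200, 0)))
        y = rng.choice([1, 2, 3, 4], size=200)  # level 5 absent
        with pytest.warns(RuntimeWarning, match="unobserved"):
            fit(latent, threshold, y, np.ones(200), fit_null=False)

    def test_roundtrip_through_json(self, compact_fit, tmp_path):
        path = tmp_path / "fit.json"
        compact_fit.to_json(path)
        back = FittedHopit.from_json(path)
        np.testing.assert_array_equal(
            back.params.pack(), compact_fit.params.pack()
        )
        np.testing.assert_allclose(back.vcov, compact_fit.vcov)
        assert back.dimension == compact_fit.dimension
        assert back.group_block == compact_fit.group_block
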