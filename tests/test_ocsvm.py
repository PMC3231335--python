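"""One-class SVM: kernel closed forms, dual feasibility, QP oracle, endmember."""

import numpy as np
import pytest
from scipy.optimize import minimize

from bloomsat import (
    OCSVMModel,
    SceneParams,
    classify_pixels,
    derive_endmember,
    fit_ocsvm,
    generate_scene,
    rbf_kernel,
    select_training_pixels,
)
from bloomsat.raster import GeoTransform, SpectralImage
from bloomsat.ocsvm import PurePixelMask

# numerical zero for decision values: margin support vectors sit at f = 0
# up to solver tolerance
DECISION_EPS = 1e-8


def dense_qp_oracle(X, nu, gamma):
    """Solve the one-class dual directly on the full kernel matrix.

    Independent of the libsvm path: general-purpose SLSQP on
    min 1/2 a^T K a subject to 0 <= a <= 1/(nu l), sum a = 1.
    Returns (alphas, bias, decision values on X).
    """
    l = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * d2)
    C = 1.0 / (nu * l)
    res = minimize(
        lambda a: 0.5 * a @ K @ a,
        np.full(l, 1.0 / l),
        jac=lambda a: K @ a,
        bounds=[(0.0, C)] * l,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(l)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 2000},
    )
    assert res.success
    a = res.x
    free = (a > 1e-7) & (a < C - 1e-7)
    bias = float(np.mean((K @ a)[free]))
    return a, bias, K @ a - bias


class TestKernel:
    def test_zero_distance_is_one(self, rng):
        x = rng.normal(size=6)
        assert rbf_kernel(x, x, gamma=3.7) == 1.0

    def test_closed_form(self):
        assert rbf_kernel((0, 0), (1, 0), 1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=(2, 4))
            g = float(rng.uniform(0.1, 5))
            k = rbf_kernel(x, y, g)
            assert k == rbf_kernel(y, x, g)
            assert 0 < k <= 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel((1, 2), (1, 2, 3), 1.0)


class TestFit:
    def test_degenerate_cluster_is_inlier(self):
        X = np.tile([0.3, 0.4, 0.5, 0.6], (10, 1))
        model = fit_ocsvm(X, nu=0.1, gamma=1.0)
        assert model.decision_function(X[:1])[0] >= -DECISION_EPS

    def test_dual_feasibility(self, rng):
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(40, 4))
            model = fit_ocsvm(X, nu=0.2, gamma=0.8)
            l = model.n_training
            assert model.alphas.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(model.alphas >= -1e-6)
            assert np.all(model.alphas <= 1.0 / (0.2 * l) + 1e-6)

    def test_infeasible_nu_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError, match="infeasible nu"):
            fit_ocsvm(X, nu=0.1, gamma=1.0)  # nu*l = 0.5 < 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_ocsvm(np.ones((1, 4)), nu=1.0, gamma=1.0)

    def test_nu_bounds_training_outlier_fraction(self):
        # over seeded datasets: outliers <= nu + 0.05, SV fraction >= nu - 0.05
        nu = 0.15
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(150, 4))
            model = fit_ocsvm(X, nu=nu, gamma=0.5)
            d = model.decision_function(X)
            assert np.mean(d < -DECISION_EPS) <= nu + 0.05
            assert len(model.alphas) / len(X) >= nu - 0.05

    def test_matches_dense_qp_oracle(self):
        for seed, nu, gamma in [(0, 0.25, 0.5), (1, 0.25, 0.5), (2, 0.4, 1.5)]:
            X = np.random.default_rng(seed).normal(size=(20, 2))
            model = fit_ocsvm(X, nu=nu, gamma=gamma)
            a_or, b_or, dec_or = dense_qp_oracle(X, nu, gamma)
            full = np.zeros(len(X))
            for sv, al in zip(model.support_vectors, model.alphas):
                idx = np.flatnonzero((X == sv).all(axis=1))[0]
                full[idx] = al
            assert np.abs(full - a_or).max() < 1e-4
            assert abs(model.bias - b_or) < 1e-4
            assert np.abs(model.decision_function(X) - dec_or).max() < 1e-4

    def test_decision_invariant_to_training_order(self, rng):
        X = rng.normal(size=(60, 4))
        probe = rng.normal(size=(20, 4))
        m1 = fit_ocsvm(X, nu=0.2, gamma=0.7)
        m2 = fit_ocsvm(X[::-1], nu=0.2, gamma=0.7)
        np.testing.assert_allclose(
            m1.decision_function(probe), m2.decision_function(probe), atol=1e-6
        )

    def test_serialization_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(30, 4))
        model = fit_ocsvm(X, nu=0.3, gamma=0.9)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = OCSVMModel.load(path)
        probe = rng.normal(size=(10, 4))
        np.testing.assert_allclose(
            model.decision_function(probe), loaded.decision_function(probe), rtol=1e-12
        )


class TestClassifyAndEndmember:
    def test_training_identical_image_all_true(self):
        spec = np.array([0.2, 0.5, 0.6, 0.4])
        X = np.tile(spec, (10, 1)) + np.random.default_rng(0).normal(0, 1e-3, (10, 4))
        model = fit_ocsvm(X, nu=0.1, gamma=1.0)
        values = np.tile(spec[:, None, None], (1, 4, 4))
        image = SpectralImage(values=values, transform=GeoTransform(0, 0, 2.4))
        mask = classify_pixels(model, image)
        assert mask.values.all()

    def test_far_pixel_rejected(self, rng):
        X = rng.normal(0, 0.05, size=(30, 4)) + 0.5
        model = fit_ocsvm(X, nu=0.1, gamma=1.0)
        far = np.full((1, 4), 1e3)
        assert model.decision_function(far)[0] < 0

    def test_band_count_mismatch_rejected(self, rng, small_scene):
        _, image, _ = small_scene
        model = fit_ocsvm(rng.normal(size=(20, 3)), nu=0.2, gamma=1.0)
        with pytest.raises(ValueError):
            classify_pixels(model, image)

    def test_endmember_is_masked_mean(self):
        values = np.zeros((2, 1, 2))
        values[:, 0, 0] = [0.2, 0.4]
        values[:, 0, 1] = [0.4, 0.6]
        image = SpectralImage(
            values=values, transform=GeoTransform(0, 0, 2.4), band_names=("a", "b")
        )
        mask = PurePixelMask(np.ones((1, 2), bool), image.transform)
        np.testing.assert_allclose(derive_endmember(image, mask), [0.3, 0.5])
        single = PurePixelMask(np.array([[True, False]]), image.transform)
        np.testing.assert_allclose(derive_endmember(image, single), [0.2, 0.4])

    def test_empty_mask_is_error(self, small_scene):
        _, image, _ = small_scene
        mask = PurePixelMask(np.zeros(image.shape, bool), image.transform)
        with pytest.raises(ValueError, match="empty mask"):
            derive_endmember(image, mask)

    def test_noiseless_endmember_recovery(self, library):
        params = SceneParams(
            width=64, height=64, n_crowns=5, noise_sd=0.0,
            flower_fraction_range=(1.0, 1.0), seed=17,
        )
        image, truth = generate_scene(params)
        pure = truth.fraction_map >= 1.0 - 1e-12
        assert pure.any()
        mask = PurePixelMask(pure, image.transform)
        em = derive_endmember(image, mask)
        np.testing.assert_allclose(em, library.spectrum("flower"), atol=1e-9)

    def test_training_selection_targets_flower_pixels(self, small_scene):
        _, image, truth = small_scene
        spectra, (rows, cols) = select_training_pixels(image, quantile=0.001)
        # the brightest green+red pixels should all sit on planted crowns
        assert (truth.fraction_map[rows, cols] > 0.5).mean() > 0.9
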