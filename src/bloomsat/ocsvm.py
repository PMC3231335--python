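"""One-class SVM pure-pixel extraction and endmember derivation.

A one-class SVM with an RBF kernel is trained on candidate flowering-crown
pixels and applied to the whole scene; pixels on the positive side of the
decision boundary form a binary "pure pixel" mask, and the target endmember
spectrum is the per-band mean of the masked pixels.

The dual problem solved is

    min_alpha  1/2 sum_ij alpha_i alpha_j K(x_i, x_j)
    s.t.       0 <= alpha_i <= 1/(nu*l),   sum_i alpha_i = 1

with K the RBF kernel exp(-gamma * ||x - y||^2), and decision function
f(x) = sum_i alpha_i K(x_i, x) - b; f(x) < 0 labels x an anomaly. ``nu``
upper-bounds the training outlier fraction and lower-bounds the support
vector fraction. The heavy lifting is delegated to libsvm via
scikit-learn; coefficients are rescaled to the normalization above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.svm import OneClassSVM

from .raster import GeoTransform, SpectralImage, write_geotiff, read_geotiff

__all__ = [
    "rbf_kernel",
    "fit_ocsvm",
    "classify_pixels",
    "derive_endmember",
    "select_training_pixels",
    "OCSVMModel",
    "PurePixelMask",
]

#: Bands whose summed reflectance ranks pixels by flower-likeness. A yellow
#: floral display is the brightest green+red feature in the scene.
FLOWER_DOMINANT_BANDS = ("green", "red")


def rbf_kernel(x, y, gamma: float) -> float:
    """Gaussian RBF kernel exp(-gamma * ||x - y||^2), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("kernel inputs must be finite")
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-gamma * d2))


def _rbf_matrix(X, Y, gamma):
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0))


@dataclass
class OCSVMModel:
    """Trained one-class boundary in kernel-expansion form."""

    support_vectors: np.ndarray  # (n_sv, n_bands)
    alphas: np.ndarray  # (n_sv,), 0 < alpha_i <= 1/(nu*l), sum = 1
    bias: float
    nu: float
    gamma: float
    n_training: int

    def decision_function(self, X) -> np.ndarray:
        """f(x) = sum_i alpha_i K(x_i, x) - b for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature length {X.shape[1]} != training length "
                f"{self.support_vectors.shape[1]}"
            )
        K = _rbf_matrix(X, self.support_vectors, self.gamma)
        return K @ self.alphas - self.bias

    def save(self, path) -> None:
        payload = {
            "format": "bloomsat-ocsvm-v1",
            "nu": self.nu,
            "gamma": self.gamma,
            "bias": self.bias,
            "n_training": self.n_training,
            "alphas": self.alphas.tolist(),
            "support_vectors": self.support_vectors.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "OCSVMModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "bloomsat-ocsvm-v1":
            raise ValueError(f"{path}: not a bloomsat OCSVM model file")
        return cls(
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            alphas=np.asarray(payload["alphas"], dtype=float),
            bias=float(payload["bias"]),
            nu=float(payload["nu"]),
            gamma=float(payload["gamma"]),
            n_training=int(payload["n_training"]),
        )


def fit_ocsvm(training, nu: float, gamma: float, tol: float = 1e-9) -> OCSVMModel:
    """Fit the one-class SVM dual on training spectra (rows).

    Raises on an infeasible box constraint (nu * l < 1, i.e. the upper bound
    1/(nu*l) > 1 cannot accommodate sum(alpha) = 1 ... more precisely fewer
    than one support vector would be allowed).
    """
    X = np.atleast_2d(np.asarray(training, dtype=float))
    l = X.shape[0]
    if l < 2:
        raise ValueError("need at least 2 training spectra")
    if not 0 < nu <= 1:
        raise ValueError("nu must lie in (0, 1]")
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    if nu * l < 1:
        raise ValueError(
            f"infeasible nu: nu*l = {nu * l:.3f} < 1 (box constraint cannot hold)"
        )
    clf = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma, tol=tol)
    clf.fit(X)
    if clf.fit_status_ != 0:
        raise RuntimeError("one-class SVM solver did not converge")
    raw = clf.dual_coef_[0].astype(float)
    scale = raw.sum()  # libsvm normalizes sum(alpha) to nu*l
    if scale <= 0:
        raise RuntimeError("degenerate dual solution")
    alphas = raw / scale
    bias = float(-clf.intercept_[0] / scale)
    return OCSVMModel(
        support_vectors=clf.support_vectors_.astype(float),
        alphas=alphas,
        bias=bias,
        nu=nu,
        gamma=gamma,
        n_training=l,
    )


@dataclass
class PurePixelMask:
    """Binary raster flagging flower-pure pixels, aligned to its source image."""

    values: np.ndarray  # (rows, cols) bool
    transform: GeoTransform

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.values))

    def save(self, path) -> None:
        write_geotiff(path, self.values.astype(np.uint8), self.transform)

    @classmethod
    def load(cls, path) -> "PurePixelMask":
        values, transform, _ = read_geotiff(path)
        return cls(values=values[0] > 0, transform=transform)


def classify_pixels(model: OCSVMModel, image: SpectralImage) -> PurePixelMask:
    """Binary map of pixels on the non-negative side of the decision boundary."""
    if image.n_bands != model.support_vectors.shape[1]:
        raise ValueError("image band count does not match the trained model")
    scores = model.decision_function(image.pixels())
    mask = (scores >= 0).reshape(image.shape)
    return PurePixelMask(values=mask, transform=image.transform)


def derive_endmember(image: SpectralImage, mask: PurePixelMask) -> np.ndarray:
    """Target endmember: per-band mean reflectance of the masked pixels."""
    if mask.values.shape != image.shape:
        raise ValueError("mask does not align with image")
    if mask.n_true == 0:
        raise ValueError("empty mask: no pixels to average")
    return image.values[:, mask.values].mean(axis=1)


def select_training_pixels(
    image: SpectralImage,
    quantile: float = 0.001,
    bands: tuple[str, ...] = FLOWER_DOMINANT_BANDS,
    min_pixels: int = 2,
):
    """Top-``quantile`` pixels by flower-likeness (summed reflectance in ``bands``).

    Replaces the manual picking of candidate bright flowering pixels with a
    reproducible rule. Returns ``(spectra, (rows, cols))`` sorted brightest
    first; at least ``min_pixels`` (and never fewer than 2) are returned so
    a downstream one-class fit stays feasible on small scenes.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    idx = [image.band_names.index(b) for b in bands]
    score = image.values[idx].sum(axis=0).ravel()
    n = max(2, min_pixels, int(round(quantile * score.size)))
    n = min(n, score.size)
    order = np.argsort(score)[::-1][:n]
    rows, cols = np.unravel_index(order, image.shape)
    return image.pixels()[order], (rows, cols)
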