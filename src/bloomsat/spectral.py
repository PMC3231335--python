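"""Spectral angle mapping, linear spectral unmixing and the region rule.

The spectral angle between a target spectrum t and a pixel spectrum r is

    theta = arccos( (t . r) / (|t| |r|) )

— a shape-only similarity, invariant to positive scaling of either vector
(illumination changes). Linear unmixing models each pixel as

    r_b = sum_i F_i R_ib + E_b

and solves for the fractional abundances F by least squares, here under a
sum-to-one constraint with non-negativity on by default so the F_i read as
physical proportions. Pixels are then classified jointly on (F, theta):

* PURE_A       — F above the purity threshold (default 0.80): pixels
                 dominated by the flowering crown;
* MIXED_B      — intermediate F (default 0.25–0.80) *and* small angle
                 (default < 0.05 rad): crown-edge mixtures whose spectral
                 shape still matches the target;
* BACKGROUND   — everything else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .raster import GeoTransform, SpectralImage, write_geotiff
from .scene import EndmemberLibrary

__all__ = [
    "RegionLabel",
    "Thresholds",
    "AbundanceResult",
    "AbundanceAngleMaps",
    "spectral_angle",
    "spectral_angle_map",
    "unmix",
    "unmix_image",
    "classify_region",
    "map_scene",
]

# weight of the sum-to-one row in the augmented least-squares system;
# drives |sum(F) - 1| below ~1e-10 before the final exact renormalization
_SUM_TO_ONE_WEIGHT = 1e5


class RegionLabel(enum.IntEnum):
    BACKGROUND = 0
    PURE_A = 1
    MIXED_B = 2


@dataclass(frozen=True)
class Thresholds:
    """Joint abundance/angle decision thresholds (angle in radians)."""

    fraction_pure: float = 0.80
    fraction_mixed_low: float = 0.25
    angle_max: float = 0.05
    angle_applies_to_pure: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fraction_mixed_low < self.fraction_pure <= 1:
            raise ValueError("need 0 < fraction_mixed_low < fraction_pure <= 1")
        if not self.angle_max > 0:
            raise ValueError("angle_max must be > 0")


def spectral_angle(target, pixel) -> float:
    """Angle in radians between two spectra; raises on zero-norm input."""
    t = np.asarray(target, dtype=float)
    r = np.asarray(pixel, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {r.shape}")
    nt = np.linalg.norm(t)
    nr = np.linalg.norm(r)
    if nt == 0 or nr == 0:
        raise ValueError("spectral angle undefined for zero-norm spectra")
    cosang = np.clip(np.dot(t, r) / (nt * nr), -1.0, 1.0)
    return float(np.arccos(cosang))


def spectral_angle_map(image: SpectralImage, target) -> np.ndarray:
    """Per-pixel angle raster vs. ``target``; zero-norm pixels get pi (max dissimilarity)."""
    t = np.asarray(target, dtype=float)
    nt = np.linalg.norm(t)
    if nt == 0:
        raise ValueError("target spectrum must be nonzero")
    pix = image.pixels()
    norms = np.linalg.norm(pix, axis=1)
    safe = norms > 0
    cosang = np.full(pix.shape[0], -1.0)
    cosang[safe] = np.clip((pix[safe] @ t) / (norms[safe] * nt), -1.0, 1.0)
    return np.arccos(cosang).reshape(image.shape)


@dataclass
class AbundanceResult:
    """Unmixing output for one pixel: fractions per endmember, per-band residual, rmse."""

    fractions: np.ndarray
    residual: np.ndarray
    rmse: float


def _check_mixing_matrix(E: np.ndarray, sum_to_one: bool = True) -> None:
    # with the sum-to-one constraint the effective system is [E; 1^T]
    A = np.vstack([E, np.ones(E.shape[1])]) if sum_to_one else E
    if np.linalg.matrix_rank(A) < E.shape[1]:
        raise ValueError("endmember matrix is rank-deficient")


def _solve_fractions(E, r, sum_to_one, nonneg):
    if nonneg:
        if sum_to_one:
            A = np.vstack([E, _SUM_TO_ONE_WEIGHT * np.ones(E.shape[1])])
            b = np.concatenate([r, [_SUM_TO_ONE_WEIGHT]])
            F, _ = nnls(A, b)
            s = F.sum()
            if s > 0:
                F = F / s  # pin sum-to-one exactly
        else:
            F, _ = nnls(E, r)
    else:
        if sum_to_one:
            # eliminate the equality: F = e_n + N z, columns of N span {1^T z = 0}
            n = E.shape[1]
            F0 = np.full(n, 1.0 / n)
            N = np.vstack([np.eye(n - 1), -np.ones(n - 1)])
            z, *_ = np.linalg.lstsq(E @ N, r - E @ F0, rcond=None)
            F = F0 + N @ z
        else:
            F, *_ = np.linalg.lstsq(E, r, rcond=None)
    return F


def unmix(
    pixel,
    endmembers,
    sum_to_one: bool = True,
    nonneg: bool = True,
) -> AbundanceResult:
    """Least-squares fractional abundances of ``pixel`` in the endmember basis.

    ``endmembers`` is an :class:`EndmemberLibrary` or a (n_bands, n_endmembers)
    matrix. Requires a full-column-rank mixing matrix and, with sum-to-one,
    n_endmembers <= n_bands + 1.
    """
    E = endmembers.matrix if isinstance(endmembers, EndmemberLibrary) else np.asarray(
        endmembers, dtype=float
    )
    r = np.asarray(pixel, dtype=float)
    if r.shape != (E.shape[0],):
        raise ValueError("pixel length must equal the endmember band count")
    if sum_to_one and E.shape[1] > E.shape[0] + 1:
        raise ValueError("need n_endmembers <= n_bands + 1 with sum-to-one")
    _check_mixing_matrix(E, sum_to_one)
    F = _solve_fractions(E, r, sum_to_one, nonneg)
    residual = E @ F - r
    rmse = float(np.sqrt(np.mean(residual**2)))
    return AbundanceResult(fractions=F, residual=residual, rmse=rmse)


def unmix_image(
    image: SpectralImage,
    endmembers: EndmemberLibrary,
    sum_to_one: bool = True,
    nonneg: bool = True,
):
    """Per-pixel abundances for a whole image.

    Returns ``(fractions, rmse)`` with fractions shaped
    (n_endmembers, rows, cols).
    """
    E = endmembers.matrix
    _check_mixing_matrix(E, sum_to_one)
    pix = image.pixels()
    n_px = pix.shape[0]
    F = np.empty((n_px, E.shape[1]))
    rmse = np.empty(n_px)
    for i in range(n_px):
        Fi = _solve_fractions(E, pix[i], sum_to_one, nonneg)
        F[i] = Fi
        rmse[i] = np.sqrt(np.mean((E @ Fi - pix[i]) ** 2))
    h, w = image.shape
    return F.T.reshape(E.shape[1], h, w), rmse.reshape(h, w)


def classify_region(fraction: float, theta: float, thresholds: Thresholds) -> RegionLabel:
    """Joint abundance/angle rule for one pixel.

    PURE_A iff F > fraction_pure (optionally also requiring the angle cut);
    MIXED_B iff fraction_mixed_low < F <= fraction_pure and theta < angle_max;
    BACKGROUND otherwise. The F = fraction_pure boundary belongs to MIXED_B.
    """
    if not (np.isfinite(fraction) and np.isfinite(theta)):
        raise ValueError("fraction and theta must be finite")
    if fraction > thresholds.fraction_pure:
        if not thresholds.angle_applies_to_pure or theta < thresholds.angle_max:
            return RegionLabel.PURE_A
        return RegionLabel.BACKGROUND
    if thresholds.fraction_mixed_low < fraction and theta < thresholds.angle_max:
        return RegionLabel.MIXED_B
    return RegionLabel.BACKGROUND


def _classify_region_arrays(F, theta, thresholds: Thresholds):
    pure = F > thresholds.fraction_pure
    if thresholds.angle_applies_to_pure:
        pure &= theta < thresholds.angle_max
    mixed = (
        (F > thresholds.fraction_mixed_low)
        & (F <= thresholds.fraction_pure)
        & (theta < thresholds.angle_max)
    )
    labels = np.full(F.shape, RegionLabel.BACKGROUND, dtype=np.uint8)
    labels[mixed] = RegionLabel.MIXED_B
    labels[pure] = RegionLabel.PURE_A
    return labels


@dataclass
class AbundanceAngleMaps:
    """Flower fraction F, spectral angle theta and region labels for one scene."""

    fraction: np.ndarray  # (rows, cols) float
    angle: np.ndarray  # (rows, cols) float, radians
    labels: np.ndarray  # (rows, cols) uint8 of RegionLabel
    transform: GeoTransform
    thresholds: Thresholds

    def save(self, fraction_path, angle_path, labels_path) -> None:
        write_geotiff(fraction_path, self.fraction.astype(np.float32), self.transform)
        write_geotiff(angle_path, self.angle.astype(np.float32), self.transform)
        write_geotiff(labels_path, self.labels, self.transform)


def map_scene(
    image: SpectralImage,
    target,
    endmembers: EndmemberLibrary,
    thresholds: Thresholds | None = None,
) -> AbundanceAngleMaps:
    """Joint SAM + LSU analysis of a scene against a target endmember.

    The library's "flower" spectrum is replaced by ``target`` (the
    data-derived endmember) before unmixing; F is the target's abundance
    plane. Zero-reflectance pixels (possible after clipping) are assigned
    angle pi, fraction 0 and the BACKGROUND label.
    """
    if thresholds is None:
        thresholds = Thresholds()
    target = np.asarray(target, dtype=float)
    if target.shape != (image.n_bands,):
        raise ValueError("target length must match image band count")
    lib = endmembers.with_spectrum("flower", target)
    theta = spectral_angle_map(image, target)
    fractions, _ = unmix_image(image, lib)
    F = fractions[lib.names.index("flower")]
    zero = np.linalg.norm(image.values, axis=0) == 0
    F = np.where(zero, 0.0, F)
    labels = _classify_region_arrays(F, theta, thresholds)
    labels[zero] = RegionLabel.BACKGROUND
    return AbundanceAngleMaps(
        fraction=F,
        angle=theta,
        labels=labels,
        transform=image.transform,
        thresholds=thresholds,
    )
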