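"""Synthetic Quickbird-like scene generator with known flowering-crown truth.

Emulates 4-band (blue/green/red/NIR) reflectance imagery at ~2.4 m ground
sample distance over a forested landscape in which a subset of canopy trees
carries a synchronized mass-flowering display. Each flowering crown is a
compact blob (2–4 pixel diameter) whose pixel spectra are linear mixtures of
a bright "flower" endmember and the local background endmember, with the
flower abundance tapering linearly from a peak at the crown centroid to zero
at the crown radius. The background is a blocky mosaic of land-cover classes
(vegetation, soil, water, man-made) so that downstream one-class training
has realistic clutter to reject.

Every generated scene returns a :class:`SceneTruth` listing the planted
crowns, which downstream stages are scored against.
"""

from __future__ import annotations

import math
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .raster import DEFAULT_BAND_NAMES, GeoTransform, SpectralImage

__all__ = [
    "EndmemberLibrary",
    "SceneParams",
    "SceneTruth",
    "default_library",
    "generate_scene",
    "generate_scene_pair",
]


@dataclass(frozen=True)
class EndmemberLibrary:
    """Per-class reference reflectance spectra, fixed band order.

    Must contain a "flower" class; every spectrum lies in [0, 1] per band and
    is nonzero. Rows of ``spectra`` align with ``names``.
    """

    names: tuple[str, ...]
    spectra: np.ndarray
    band_names: tuple[str, ...] = DEFAULT_BAND_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        object.__setattr__(self, "spectra", spectra)
        if len(self.names) != spectra.shape[0]:
            raise ValueError("one spectrum per class name required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if "flower" not in self.names:
            raise ValueError('library must include a "flower" class')
        if spectra.shape[1] != len(self.band_names):
            raise ValueError("spectra band count must match band_names")
        if np.any(spectra < 0) or np.any(spectra > 1):
            raise ValueError("reflectances must lie in [0, 1]")
        if np.any(np.linalg.norm(spectra, axis=1) == 0):
            raise ValueError("endmember spectra must be nonzero")

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """(n_bands, n_classes) mixing matrix — endmembers as columns."""
        return self.spectra.T.copy()

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[self.names.index(name)].copy()

    def background_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != "flower")

    def with_spectrum(self, name: str, spectrum) -> "EndmemberLibrary":
        """Library with one class's spectrum replaced (e.g. by a data-derived endmember)."""
        spectra = self.spectra.copy()
        spectra[self.names.index(name)] = np.asarray(spectrum, dtype=float)
        return EndmemberLibrary(self.names, spectra, self.band_names)


def default_library() -> EndmemberLibrary:
    """Default 4-band endmember set.

    The flower spectrum peaks in the green/red bands (a yellow floral display
    over a still-vegetated crown keeps NIR high); vegetation shows the usual
    chlorophyll signature (green bump, red absorption, strong NIR); soil a
    gentle brightening toward NIR; water dark everywhere; man-made surfaces a
    flat, moderately dark gray.
    """
    return EndmemberLibrary(
        names=("flower", "vegetation", "soil", "water", "man_made"),
        spectra=np.array(
            [
                [0.12, 0.45, 0.50, 0.55],  # flower
                [0.04, 0.08, 0.05, 0.45],  # vegetation
                [0.12, 0.15, 0.18, 0.25],  # soil
                [0.06, 0.05, 0.04, 0.02],  # water
                [0.15, 0.16, 0.17, 0.18],  # man_made
            ]
        ),
    )


#: Landscape composition used when a library provides these classes: mostly
#: closed-canopy forest with minor open water, bare soil and built patches.
DEFAULT_BACKGROUND_WEIGHTS = {
    "vegetation": 0.85,
    "water": 0.06,
    "soil": 0.06,
    "man_made": 0.03,
}


@dataclass(frozen=True)
class SceneParams:
    """Geometry, crown statistics and noise level of a synthetic scene.

    Units: meters for sizes/radii, reflectance units for ``noise_sd``.
    ``crown_radius_range`` defaults to 2–4 pixel crown *diameters* at the
    2.4 m Quickbird pixel. ``min_separation`` keeps planted crowns apart so
    that distinct trees never abut (no overlapping mixtures).
    """

    width: int = 256
    height: int = 256
    pixel_size: float = 2.4
    n_crowns: int = 50
    crown_radius_range: tuple[float, float] = (2.4, 4.8)
    flower_fraction_range: tuple[float, float] = (0.9, 1.0)
    noise_sd: float = 0.01
    background_patch_size: int = 8
    min_separation: float = 12.0
    origin_x: float = 625000.0
    origin_y: float = 1012000.0
    seed: int = 0
    max_placement_tries: int = 10000

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must be at least 1x1 pixels")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        lo, hi = self.crown_radius_range
        if lo > hi or lo < self.pixel_size:
            raise ValueError(
                "crown radii must be >= one pixel and ordered low <= high"
            )
        flo, fhi = self.flower_fraction_range
        if not (0 < flo <= fhi <= 1):
            raise ValueError("flower_fraction_range must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_patch_size < 1:
            raise ValueError("background_patch_size must be >= 1")

    @property
    def transform(self) -> GeoTransform:
        return GeoTransform(self.origin_x, self.origin_y, self.pixel_size)


@dataclass
class SceneTruth:
    """Ground truth for a generated scene (or scene pair).

    ``crowns`` columns: id, x, y (pixel-center map coordinates of the crown
    centroid), radius_m, peak_fraction, in_date1, in_date2. The per-pixel
    planted flower-fraction maps and the background class map are kept for
    oracle-style checks; they are not part of the tabular export.
    """

    crowns: pd.DataFrame
    fraction_map_date1: np.ndarray
    fraction_map_date2: np.ndarray
    background_class_map: np.ndarray
    clip_fraction: float = 0.0

    @property
    def fraction_map(self) -> np.ndarray:
        """Single-date alias (dates are identical for one-date scenes)."""
        return self.fraction_map_date1

    def to_csv(self, path) -> None:
        self.crowns.to_csv(path, index=False)

    def to_geojson(self, path) -> None:
        features = []
        for rec in self.crowns.itertuples(index=False):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [rec.x, rec.y]},
                    "properties": {
                        "id": int(rec.id),
                        "radius_m": float(rec.radius_m),
                        "peak_fraction": float(rec.peak_fraction),
                        "in_date1": bool(rec.in_date1),
                        "in_date2": bool(rec.in_date2),
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _background_mosaic(params: SceneParams, library: EndmemberLibrary, rng) -> np.ndarray:
    """(rows, cols) int map into library rows, blocky random mosaic of background classes."""
    bg_names = library.background_names()
    if not bg_names:
        raise ValueError("library needs at least one background class")
    weights = np.array(
        [DEFAULT_BACKGROUND_WEIGHTS.get(n, np.nan) for n in bg_names], dtype=float
    )
    if np.any(np.isnan(weights)) or weights.sum() == 0:
        weights = np.ones(len(bg_names))
    weights = weights / weights.sum()
    ps = params.background_patch_size
    ny = math.ceil(params.height / ps)
    nx = math.ceil(params.width / ps)
    patch_classes = rng.choice(len(bg_names), size=(ny, nx), p=weights)
    full = np.repeat(np.repeat(patch_classes, ps, axis=0), ps, axis=1)
    full = full[: params.height, : params.width]
    bg_rows = np.array([library.names.index(n) for n in bg_names])
    return bg_rows[full]


def _place_crowns(params: SceneParams, rng) -> pd.DataFrame:
    """Rejection-sample non-overlapping crown centers snapped to pixel centers."""
    transform = params.transform
    placed_rc: list[tuple[int, int]] = []
    radii: list[float] = []
    tries = 0
    while len(placed_rc) < params.n_crowns:
        if tries >= params.max_placement_tries:
            raise RuntimeError(
                f"could not place {params.n_crowns} crowns with "
                f"min_separation={params.min_separation} m within "
                f"{params.max_placement_tries} tries"
            )
        tries += 1
        radius = rng.uniform(*params.crown_radius_range)
        # keep the full taper footprint inside the raster
        margin = int(math.ceil(radius / params.pixel_size))
        if params.height - 1 - margin < margin or params.width - 1 - margin < margin:
            raise RuntimeError("crown radius too large for scene extent")
        row = int(rng.integers(margin, params.height - margin))
        col = int(rng.integers(margin, params.width - margin))
        ok = True
        for (r0, c0), rad0 in zip(placed_rc, radii):
            d = params.pixel_size * math.hypot(row - r0, col - c0)
            if d <= max(params.min_separation, radius + rad0):
                ok = False
                break
        if ok:
            placed_rc.append((row, col))
            radii.append(radius)
    rows = np.array([rc[0] for rc in placed_rc], dtype=int)
    cols = np.array([rc[1] for rc in placed_rc], dtype=int)
    xs, ys = transform.rowcol_to_xy(rows, cols)
    peaks = rng.uniform(*params.flower_fraction_range, size=params.n_crowns)
    return pd.DataFrame(
        {
            "id": np.arange(params.n_crowns, dtype=int),
            "row": rows,
            "col": cols,
            "x": xs,
            "y": ys,
            "radius_m": np.asarray(radii),
            "peak_fraction": peaks,
        }
    )


def _fraction_map(params: SceneParams, crowns: pd.DataFrame, present) -> np.ndarray:
    """Planted flower-fraction raster: linear taper, peak at centroid, 0 at radius."""
    frac = np.zeros((params.height, params.width), dtype=float)
    for rec, keep in zip(crowns.itertuples(index=False), present):
        if not keep:
            continue
        r_px = rec.radius_m / params.pixel_size
        span = int(math.ceil(r_px))
        r0, r1 = rec.row - span, rec.row + span
        c0, c1 = rec.col - span, rec.col + span
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        d = np.hypot(rr - rec.row, cc - rec.col)
        taper = rec.peak_fraction * np.clip(1.0 - d / r_px, 0.0, None)
        frac[r0 : r1 + 1, c0 : c1 + 1] = np.maximum(
            frac[r0 : r1 + 1, c0 : c1 + 1], taper
        )
    return frac


def _render(params, library, class_map, frac, noise_rng):
    flower = library.spectrum("flower")
    bg_spectra = library.spectra[class_map]  # (H, W, B)
    cube = frac[..., None] * flower + (1.0 - frac[..., None]) * bg_spectra
    if params.noise_sd > 0:
        cube = cube + noise_rng.normal(0.0, params.noise_sd, size=cube.shape)
    clipped = np.count_nonzero((cube < 0) | (cube > 1))
    cube = np.clip(cube, 0.0, 1.0)
    values = np.moveaxis(cube, -1, 0)
    image = SpectralImage(
        values=values, transform=params.transform, band_names=library.band_names
    )
    return image, clipped / cube.size


def generate_scene(params: SceneParams, library: EndmemberLibrary | None = None):
    """Generate one date's scene.

    Returns ``(SpectralImage, SceneTruth)``. Each pixel is a sum-to-one
    linear mixture of the flower endmember (planted fraction) and one
    background endmember, plus additive i.i.d. Gaussian noise per band,
    clipped to [0, 1].
    """
    if library is None:
        library = default_library()
    if len(library.names) < 2:
        raise ValueError("library needs at least 2 classes")
    rng = np.random.default_rng(params.seed)
    class_map = _background_mosaic(params, library, rng)
    crowns = _place_crowns(params, rng)
    present = np.ones(len(crowns), dtype=bool)
    frac = _fraction_map(params, crowns, present)
    image, clip_fraction = _render(params, library, class_map, frac, rng)
    table = crowns.drop(columns=["row", "col"]).assign(in_date1=True, in_date2=True)
    truth = SceneTruth(
        crowns=table,
        fraction_map_date1=frac,
        fraction_map_date2=frac,
        background_class_map=class_map,
        clip_fraction=clip_fraction,
    )
    return image, truth


def generate_scene_pair(
    params: SceneParams,
    library: EndmemberLibrary | None = None,
    shared_fraction: float = 0.5,
):
    """Generate a two-date pair sharing a configurable fraction of crowns.

    ``round(shared_fraction * n_crowns)`` crowns flower on both dates; the
    remainder is split as evenly as possible between date-1-only trees
    (fallen, died, or skipped the second event) and date-2-only trees (new
    recruits). The background mosaic is identical across dates; the additive
    noise is drawn independently per date.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if library is None:
        library = default_library()
    rng = np.random.default_rng(params.seed)
    class_map = _background_mosaic(params, library, rng)
    crowns = _place_crowns(params, rng)
    n = len(crowns)
    n_shared = int(round(shared_fraction * n))
    rest = n - n_shared
    n_only1 = (rest + 1) // 2
    order = rng.permutation(n)
    in1 = np.zeros(n, dtype=bool)
    in2 = np.zeros(n, dtype=bool)
    in1[order[:n_shared]] = in2[order[:n_shared]] = True
    in1[order[n_shared : n_shared + n_only1]] = True
    in2[order[n_shared + n_only1 :]] = True
    frac1 = _fraction_map(params, crowns, in1)
    frac2 = _fraction_map(params, crowns, in2)
    noise1 = np.random.default_rng([params.seed, 1])
    noise2 = np.random.default_rng([params.seed, 2])
    image1, clip1 = _render(params, library, class_map, frac1, noise1)
    image2, clip2 = _render(params, library, class_map, frac2, noise2)
    table = crowns.drop(columns=["row", "col"]).assign(in_date1=in1, in_date2=in2)
    truth = SceneTruth(
        crowns=table,
        fraction_map_date1=frac1,
        fraction_map_date2=frac2,
        background_class_map=class_map,
        clip_fraction=max(clip1, clip2),
    )
    return image1, image2, truth
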