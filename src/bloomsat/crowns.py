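"""From region-labeled rasters to a consolidated set of crown centroids.

Stages: (1) ISODATA-style unsupervised clustering of the scene's pixel
spectra into spectral classes; (2) selection of the classes dominated by
flower-region pixels; (3) 8-connected component labeling of the selected
pixels and conversion of each component to a centroid point in map
coordinates; (4) buffer-merge consolidation — any centroids within the merge
radius of one another (transitively) are treated as a single crown, since
adjacent crown fragments of one tree otherwise yield duplicate centroids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GeoTransform, SpectralImage
from .spectral import AbundanceAngleMaps, RegionLabel

__all__ = [
    "CrownCentroid",
    "CrownSet",
    "isodata_cluster",
    "select_flower_classes",
    "extract_centroids",
    "buffer_merge",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def isodata_cluster(
    image: SpectralImage,
    n_classes: int = 25,
    max_iter: int = 100,
    seed: int = 0,
    tol: float = 1e-4,
) -> np.ndarray:
    """Cluster pixel spectra into up to ``n_classes`` spectral classes.

    Iterative self-organizing (k-means-style) assignment/update loop. Class
    seeds are the pixels whose projections onto the first principal axis sit
    at evenly spaced quantiles (endpoints included, so extreme spectra such
    as bright flowering crowns seed their own class). Classes that empty out
    during iteration are dropped with a warning, so the final number of
    classes may be smaller than requested. Deterministic for fixed inputs;
    ``seed`` is accepted for interface stability but the initialization is
    fully data-driven.

    Returns a (rows, cols) int label raster with labels in [0, n_final).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    X = image.pixels()
    n_px = X.shape[0]
    if n_px == 0:
        raise ValueError("empty image")
    if n_classes == 1:
        return np.zeros(image.shape, dtype=int)

    centered = X - X.mean(axis=0)
    # first principal axis via SVD of the (tiny) band covariance
    _, _, vt = np.linalg.svd(centered.T @ centered)
    proj = centered @ vt[0]
    qs = np.quantile(proj, np.linspace(0.0, 1.0, n_classes))
    seed_idx = np.abs(proj[:, None] - qs[None, :]).argmin(axis=0)
    centers = X[seed_idx].astype(float)
    # collapse duplicate seeds (possible on images with few distinct spectra)
    centers = np.unique(centers, axis=0)

    labels = np.zeros(n_px, dtype=int)
    for _ in range(max_iter):
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ centers.T
            + np.sum(centers**2, axis=1)[None, :]
        )
        new_labels = d2.argmin(axis=1)
        counts = np.bincount(new_labels, minlength=centers.shape[0])
        if np.any(counts == 0):
            keep = counts > 0
            warnings.warn(
                f"dropping {np.count_nonzero(~keep)} empty ISODATA class(es)",
                stacklevel=2,
            )
            remap = -np.ones(centers.shape[0], dtype=int)
            remap[keep] = np.arange(keep.sum())
            centers = centers[keep]
            new_labels = remap[new_labels]
        changed = np.mean(new_labels != labels)
        labels = new_labels
        centers = np.stack(
            [X[labels == k].mean(axis=0) for k in range(centers.shape[0])]
        )
        if changed < tol:
            break
    return labels.reshape(image.shape)


def select_flower_classes(labels: np.ndarray, maps: AbundanceAngleMaps) -> np.ndarray:
    """Union of spectral classes whose pixel majority lies in Region A or B.

    Returns a boolean raster; empty (all False) when no class qualifies,
    which is a valid zero-crown outcome.
    """
    if labels.shape != maps.labels.shape:
        raise ValueError("label raster does not align with the region maps")
    flowerish = (maps.labels == RegionLabel.PURE_A) | (
        maps.labels == RegionLabel.MIXED_B
    )
    out = np.zeros(labels.shape, dtype=bool)
    for k in np.unique(labels):
        members = labels == k
        if flowerish[members].mean() > 0.5:
            out |= members
    return out


@dataclass
class CrownCentroid:
    """One detected crown (or raw pre-merge component) in map coordinates."""

    id: int
    x: float
    y: float
    n_pixels: int = 1
    mean_fraction: float = float("nan")


def extract_centroids(
    flower: np.ndarray,
    transform: GeoTransform,
    fraction: np.ndarray | None = None,
) -> list[CrownCentroid]:
    """One centroid per 8-connected component of the binary flower raster.

    The centroid is the unweighted mean of member pixel-center map
    coordinates; ``fraction`` (the flower abundance raster), when given,
    supplies each component's mean flower fraction.
    """
    flower = np.asarray(flower).astype(bool)
    comp, n_comp = ndimage.label(flower, structure=_EIGHT_CONNECTED)
    out: list[CrownCentroid] = []
    for cid in range(1, n_comp + 1):
        rows, cols = np.nonzero(comp == cid)
        xs, ys = transform.rowcol_to_xy(rows, cols)
        mf = float(np.mean(fraction[rows, cols])) if fraction is not None else float("nan")
        out.append(
            CrownCentroid(
                id=cid - 1,
                x=float(xs.mean()),
                y=float(ys.mean()),
                n_pixels=len(rows),
                mean_fraction=mf,
            )
        )
    return out


@dataclass
class CrownSet:
    """Merged crown centroids for one acquisition date."""

    date: str
    crowns: list[CrownCentroid]
    merge_log: list[dict] = field(default_factory=list)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.crowns)

    def positions(self) -> np.ndarray:
        return np.array([[c.x, c.y] for c in self.crowns]).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.crowns],
                "x": [c.x for c in self.crowns],
                "y": [c.y for c in self.crowns],
                "n_pixels": [c.n_pixels for c in self.crowns],
                "mean_fraction": [c.mean_fraction for c in self.crowns],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, date: str = "", crs: str | None = None) -> "CrownSet":
        df = pd.read_csv(path)
        crowns = [
            CrownCentroid(
                id=int(r.id),
                x=float(r.x),
                y=float(r.y),
                n_pixels=int(r.n_pixels),
                mean_fraction=float(r.mean_fraction),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(date=date, crowns=crowns, crs=crs)

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [c.x, c.y]},
                "properties": {
                    "id": c.id,
                    "n_pixels": c.n_pixels,
                    "mean_fraction": c.mean_fraction,
                },
            }
            for c in self.crowns
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _merge_pass(centroids: list[CrownCentroid], radius: float):
    pos = np.array([[c.x, c.y] for c in centroids])
    uf = _UnionFind(len(centroids))
    for i in range(len(centroids)):
        d = np.hypot(pos[i + 1 :, 0] - pos[i, 0], pos[i + 1 :, 1] - pos[i, 1])
        for j in np.nonzero(d <= radius)[0]:
            uf.union(i, i + 1 + int(j))
    groups: dict[int, list[int]] = {}
    for i in range(len(centroids)):
        groups.setdefault(uf.find(i), []).append(i)
    merged: list[CrownCentroid] = []
    log: list[dict] = []
    for new_id, root in enumerate(sorted(groups)):
        members = groups[root]
        w = np.array([max(centroids[i].n_pixels, 1) for i in members], dtype=float)
        w = w / w.sum()
        x = float(np.sum(w * pos[members, 0]))
        y = float(np.sum(w * pos[members, 1]))
        n_pixels = int(sum(centroids[i].n_pixels for i in members))
        fracs = np.array([centroids[i].mean_fraction for i in members])
        npx = np.array([max(centroids[i].n_pixels, 1) for i in members], dtype=float)
        with np.errstate(invalid="ignore"):
            mf = float(np.nansum(fracs * npx) / npx[~np.isnan(fracs)].sum()) if np.any(
                ~np.isnan(fracs)
            ) else float("nan")
        merged.append(CrownCentroid(id=new_id, x=x, y=y, n_pixels=n_pixels, mean_fraction=mf))
        if len(members) > 1:
            log.append({"crown": new_id, "merged_from": [centroids[i].id for i in members]})
    return merged, log


def buffer_merge(
    centroids: list[CrownCentroid],
    radius: float = 5.0,
    date: str = "",
    crs: str | None = None,
) -> CrownSet:
    """Consolidate centroids within ``radius`` meters of each other into single crowns.

    Grouping is the transitive closure of the pairwise "within radius"
    relation (union-find); each group collapses to its pixel-count-weighted
    mean position. The pass repeats until no two crowns remain within the
    radius, so the post-merge minimum spacing exceeds ``radius`` even when
    repositioning draws previously distant groups together. An audit log
    records every grouping for later review.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    current = list(centroids)
    log: list[dict] = []
    while True:
        merged, pass_log = _merge_pass(current, radius) if current else ([], [])
        log.extend(pass_log)
        if len(merged) == len(current):
            current = merged
            break
        current = merged
    return CrownSet(date=date, crowns=current, merge_log=log, crs=crs)
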