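"""Bi-temporal crown matching and aerial-photo comparison statistics.

Crown centroid sets from two acquisition dates are matched one-to-one by a
greedy nearest-pair rule under a distance tolerance. Matched crowns are
"common" trees (assumed to be the same individuals flowering on both
dates); date-1-only crowns are "lost" (fallen, died, or skipped the second
flowering event); date-2-only crowns are "new" (recruits that reached
reproductive size). A packaged 18-site comparison table against
high-resolution aerial photography supports a simple percentage match-rate
statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .crowns import CrownSet

__all__ = [
    "ChangeReport",
    "match_crowns",
    "match_rate",
    "load_aerial_comparison",
]

#: Columns of the aerial-photo comparison table. ``count_date1``/``count_date2``
#: are satellite detections for the two image dates; ``count_reference`` the
#: crowns interpreted on the reference aerial photos; ``matched_*_ref`` the
#: satellite crowns re-found on the photos. ``nonflowering_*_ref`` counts trees
#: that flowered on the satellite date but not on the reference date (kept for
#: completeness, excluded from match rates).
TABLE_COLUMNS = (
    "site_id",
    "count_date1",
    "count_date2",
    "count_reference",
    "matched_1_ref",
    "nonflowering_1_ref",
    "matched_2_ref",
    "nonflowering_2_ref",
)


@dataclass
class ChangeReport:
    """Partition of two dates' crowns into common / lost / new."""

    n_date1: int
    n_date2: int
    common: list[tuple[int, int]]
    lost: list[int]
    new: list[int]
    tolerance: float

    def __post_init__(self) -> None:
        if self.n_date1 != len(self.common) + len(self.lost):
            raise ValueError("date-1 counts do not reconcile")
        if self.n_date2 != len(self.common) + len(self.new):
            raise ValueError("date-2 counts do not reconcile")
        a_ids = [p[0] for p in self.common]
        b_ids = [p[1] for p in self.common]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("matching must be one-to-one")

    @property
    def n_common(self) -> int:
        return len(self.common)

    def summary(self) -> dict:
        return {
            "n_date1": self.n_date1,
            "n_date2": self.n_date2,
            "n_common": self.n_common,
            "n_lost": len(self.lost),
            "n_new": len(self.new),
            "tolerance_m": self.tolerance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    **self.summary(),
                    "common_pairs": [list(p) for p in self.common],
                    "lost_ids": list(self.lost),
                    "new_ids": list(self.new),
                },
                fh,
                indent=2,
            )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.common, columns=["id_date1", "id_date2"]).to_csv(
            path, index=False
        )


def match_crowns(a: CrownSet, b: CrownSet, tolerance: float = 5.0) -> ChangeReport:
    """Greedy one-to-one nearest-pair matching under a distance tolerance.

    Repeatedly pairs the globally closest unmatched cross-set pair whose
    distance is <= ``tolerance``; remaining crowns become lost (date 1) or
    new (date 2). Deterministic: exact distance ties break on (id_a, id_b)
    order.
    """
    if a.crs is not None and b.crs is not None and a.crs != b.crs:
        raise ValueError(f"coordinate systems differ: {a.crs!r} vs {b.crs!r}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pa, pb = a.positions(), b.positions()
    candidates = []
    for i, ca in enumerate(a.crowns):
        if len(b.crowns) == 0:
            break
        d = np.hypot(pb[:, 0] - pa[i, 0], pb[:, 1] - pa[i, 1])
        for j in np.nonzero(d <= tolerance)[0]:
            candidates.append((float(d[j]), ca.id, b.crowns[int(j)].id, i, int(j)))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    common: list[tuple[int, int]] = []
    for _, ida, idb, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        common.append((ida, idb))
    lost = [c.id for k, c in enumerate(a.crowns) if k not in used_a]
    new = [c.id for k, c in enumerate(b.crowns) if k not in used_b]
    return ChangeReport(
        n_date1=len(a.crowns),
        n_date2=len(b.crowns),
        common=common,
        lost=lost,
        new=new,
        tolerance=tolerance,
    )


def load_aerial_comparison() -> pd.DataFrame:
    """Packaged 18-site satellite-vs-aerial-photo comparison table."""
    with resources.files("bloomsat.data").joinpath("aerial_photo_comparison.csv").open() as fh:
        df = pd.read_csv(fh)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"comparison table missing columns: {sorted(missing)}")
    return df


def match_rate(table: pd.DataFrame, date: int = 1) -> int:
    """Percent of satellite-detected crowns re-found on the reference photos.

    ``100 * sum(matched) / sum(detected)`` over all sites for the chosen
    date (1 or 2), rounded half-up to the nearest integer percent.
    """
    if date not in (1, 2):
        raise ValueError("date must be 1 or 2")
    detected = int(table[f"count_date{date}"].sum())
    matched = int(table[f"matched_{date}_ref"].sum())
    if detected == 0:
        raise ValueError("zero detections: match rate undefined")
    if matched > detected:
        raise ValueError("matched count exceeds detections")
    return int(math.floor(100.0 * matched / detected + 0.5))
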