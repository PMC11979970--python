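"""Per-epoch occurrence classification and wall-type diversity counting.

A genus occupies every bin its [fad, lad] range intersects (ranges are
interval-valued, so intersection is on bin indices, not ages).  Within an
occupied bin it is exactly one of: singleton (fad = lad = bin), originator
(fad = bin < lad), extinct-in-bin (fad < bin = lad) or boundary crosser
(fad < bin < lad).  Proportional diversity (count / epoch total) is the
preservation-bias-robust quantity used for all cross-era comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .taxa_io import Dataset, WALL_TYPES

__all__ = [
    "OccurrenceCategory",
    "DiversityTable",
    "classify_in_bin",
    "diversity_table",
    "proportions",
    "percent_change",
    "format_percent",
    "remove_singletons",
]


class OccurrenceCategory(str, Enum):
    SINGLETON = "singleton"
    BOUNDARY_CROSSER = "boundary_crosser"
    ORIGINATOR = "originator"
    EXTINCT_IN_BIN = "extinct_in_bin"


CATEGORIES = tuple(c.value for c in OccurrenceCategory)


def classify_in_bin(fad: int, lad: int, bin_idx: int, n_bins: int | None = None) -> OccurrenceCategory | None:
    """Occurrence category of a (fad, lad) range in one bin, or None if absent."""
    for v, label in ((fad, "fad"), (lad, "lad"), (bin_idx, "bin")):
        if v < 0 or (n_bins is not None and v >= n_bins):
            raise IndexError(f"{label} index {v} out of range")
    if fad > lad:
        raise ValueError(f"range reversed: fad {fad} > lad {lad}")
    if not (fad <= bin_idx <= lad):
        return None
    if fad == lad:
        return OccurrenceCategory.SINGLETON
    if bin_idx == fad:
        return OccurrenceCategory.ORIGINATOR
    if bin_idx == lad:
        return OccurrenceCategory.EXTINCT_IN_BIN
    return OccurrenceCategory.BOUNDARY_CROSSER


@dataclass
class DiversityTable:
    """Wide per-epoch table plus a tidy exporter.

    ``frame`` has one row per epoch: ``total``, per-wall-type counts
    (``n_<wall>``), per-wall-type proportions (``p_<wall>``, NaN where the
    epoch total is zero) and per-wall-type category counts
    (``<wall>_<category>``).
    """

    frame: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        """Long format: epoch, era, midpoint_ma, wall_type, count, proportion,
        singletons, boundary_crossers, originators, extinctions."""
        rows = []
        for _, r in self.frame.iterrows():
            for wall in WALL_TYPES:
                rows.append(
                    {
                        "epoch": r["epoch"],
                        "era": r["era"],
                        "midpoint_ma": r["midpoint_ma"],
                        "wall_type": wall,
                        "count": r[f"n_{wall}"],
                        "proportion": r[f"p_{wall}"],
                        "singletons": r[f"{wall}_singleton"],
                        "boundary_crossers": r[f"{wall}_boundary_crosser"],
                        "originators": r[f"{wall}_originator"],
                        "extinctions": r[f"{wall}_extinct_in_bin"],
                    }
                )
        return pd.DataFrame(rows)


def _range_counts(fad: np.ndarray, lad: np.ndarray, n_bins: int) -> np.ndarray:
    """Count, per bin, the ranges that intersect it (difference-array trick)."""
    diff = np.zeros(n_bins + 1, dtype=np.int64)
    np.add.at(diff, fad, 1)
    np.add.at(diff, lad + 1, -1)
    return np.cumsum(diff)[:n_bins]


def diversity_table(ds: Dataset) -> DiversityTable:
    """Per-epoch genus counts by wall type and occurrence category."""
    bad = [r.genus for r in ds.records if r.wall_type not in WALL_TYPES]
    if bad:
        raise ValueError(
            f"diversity_table needs analysable wall types only; run filter_benthic "
            f"first (offending: {bad[:5]}...)"
        )
    ts = ds.timescale
    n_bins = len(ts)
    fad, lad, _, wall = ds.arrays()

    data: dict[str, np.ndarray] = {}
    total = np.zeros(n_bins, dtype=np.int64)
    for w in WALL_TYPES:
        m = wall == w
        f, l = fad[m], lad[m]
        n_w = _range_counts(f, l, n_bins) if m.any() else np.zeros(n_bins, dtype=np.int64)
        data[f"n_{w}"] = n_w
        total += n_w
        single = f == l
        data[f"{w}_singleton"] = np.bincount(f[single], minlength=n_bins)
        data[f"{w}_originator"] = np.bincount(f[~single], minlength=n_bins)
        data[f"{w}_extinct_in_bin"] = np.bincount(l[~single], minlength=n_bins)
        data[f"{w}_boundary_crosser"] = (
            n_w
            - data[f"{w}_singleton"]
            - data[f"{w}_originator"]
            - data[f"{w}_extinct_in_bin"]
        )

    frame = pd.DataFrame(
        {
            "epoch": ts.names,
            "era": [iv.era for iv in ts.intervals],
            "midpoint_ma": [iv.midpoint_ma for iv in ts.intervals],
            "total": total,
        }
    )
    for k, v in data.items():
        frame[k] = v
    with np.errstate(invalid="ignore", divide="ignore"):
        for w in WALL_TYPES:
            frame[f"p_{w}"] = np.where(total > 0, data[f"n_{w}"] / np.where(total > 0, total, 1), np.nan)
    return DiversityTable(frame=frame)


def proportions(dt: DiversityTable) -> pd.DataFrame:
    """Per-epoch wall-type fractions; zero-total epochs flagged undefined."""
    f = dt.frame
    out = f[["epoch", "era", "midpoint_ma", "total"]].copy()
    for w in WALL_TYPES:
        out[f"p_{w}"] = f[f"p_{w}"]
    out["undefined"] = f["total"] == 0
    return out


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100*(after-before)/before; before must be > 0."""
    if before <= 0:
        raise ValueError(f"percent_change undefined for before={before}")
    return 100.0 * (after - before) / before


def format_percent(value: float) -> int:
    """Round to integer percent, halves away from zero (62/17 -> 265%)."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


def remove_singletons(ds: Dataset, bin_idx: int) -> Dataset:
    """Drop genera confined to ``bin_idx`` (fad = lad = bin); log the removals.

    Used for the pull-of-the-recent sensitivity check on the terminal bin:
    singletons are invisible to boundary-crosser rates but inflate raw
    diversity.
    """
    if not (0 <= bin_idx < len(ds.timescale)):
        raise IndexError(f"bin index {bin_idx} outside timescale")
    keep = [i for i, r in enumerate(ds.records) if not (r.fad_interval == r.lad_interval == bin_idx)]
    removed = len(ds) - len(keep)
    out = ds.subset(
        keep,
        note=f"remove_singletons: dropped {removed} singleton(s) from "
        f"{ds.timescale[bin_idx].name}",
    )
    out.exclusions.extend(
        (r.genus, f"singleton in {ds.timescale[bin_idx].name}")
        for r in ds.records
        if r.fad_interval == r.lad_interval == bin_idx
    )
    return out
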