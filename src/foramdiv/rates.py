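"""Boundary-crosser counting and Foote per-capita origination/extinction rates.

For each bin, with Nbt the taxa crossing both its boundaries, Nt the taxa
crossing its top (younger) boundary and Nb the taxa crossing its bottom
(older) boundary, the per-capita rates are

    p_hat = -ln(Nbt / Nt) / dt      (origination)
    q_hat = -ln(Nbt / Nb) / dt      (extinction)

with dt the bin duration in Myr.  Singletons never cross a boundary and so
never enter the counts.  Where Nbt = 0 the estimators are undefined and the
bin is flagged invalid rather than set to zero or infinity.

Extant genera are, by default, treated as crossing the top of the terminal
(Holocene) bin — they have not gone extinct — so the terminal extinction rate
reflects only true extinctions.  The terminal bin is still flagged
edge-affected for q_hat, as is the first bin for p_hat (nothing can cross
into the oldest bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taxa_io import Dataset, WALL_TYPES
from .timescale import TimeScale

__all__ = ["CrossingCounts", "RateSeries", "crossing_counts", "foote_rates"]

GROUPS = WALL_TYPES + ("all",)


@dataclass(frozen=True)
class CrossingCounts:
    """Per-epoch boundary-crosser counts for one taxon group."""

    group: str
    nbt: np.ndarray  # cross bottom and top
    nb: np.ndarray  # cross bottom (Nbt + die in bin)
    nt: np.ndarray  # cross top (Nbt + originate in bin and survive)
    n_singletons: np.ndarray  # diagnostic: confined to the bin, cross nothing

    def __post_init__(self) -> None:
        for name in ("nbt", "nb", "nt", "n_singletons"):
            arr = getattr(self, name)
            if (arr < 0).any():
                raise ValueError(f"{name} has negative counts")
        if (self.nbt > self.nb).any() or (self.nbt > self.nt).any():
            raise ValueError("Nbt must not exceed Nb or Nt")


@dataclass(frozen=True)
class RateSeries:
    """Per-epoch Foote rates (per Myr) with validity and edge flags."""

    group: str
    epochs: list[str]
    midpoint_ma: np.ndarray
    duration_myr: np.ndarray
    nbt: np.ndarray
    nb: np.ndarray
    nt: np.ndarray
    p_hat: np.ndarray  # NaN where invalid
    q_hat: np.ndarray
    valid_p: np.ndarray
    valid_q: np.ndarray
    edge_p: np.ndarray  # first bin: no older boundary to cross
    edge_q: np.ndarray  # terminal bin: extinction censored by the present

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "midpoint_ma": self.midpoint_ma,
                "group": self.group,
                "Nbt": self.nbt,
                "Nb": self.nb,
                "Nt": self.nt,
                "p_hat_per_myr": self.p_hat,
                "q_hat_per_myr": self.q_hat,
                "valid_p": self.valid_p,
                "valid_q": self.valid_q,
                "edge_p": self.edge_p,
                "edge_q": self.edge_q,
            }
        )


def crossing_arrays(
    fad: np.ndarray,
    lad: np.ndarray,
    extant: np.ndarray,
    n_bins: int,
    extant_top_crossing: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(Nbt, Nb, Nt, singletons) per bin from fad/lad index arrays.

    Implemented with difference arrays: a genus with effective range
    [L, R_eff) of boundary crossings contributes to Nb on bins L < b <= R_eff,
    to Nt on bins L <= b < R_eff and to Nbt on L < b < R_eff, where
    R_eff = lad (+1 when the genus is extant and extant survivorship counts
    as crossing the terminal top boundary).
    """
    fad = np.asarray(fad, dtype=np.int64)
    lad = np.asarray(lad, dtype=np.int64)
    r_eff = lad + (np.asarray(extant, dtype=np.int64) if extant_top_crossing else 0)

    size = n_bins + 2
    d_nb = np.zeros(size, dtype=np.int64)
    d_nt = np.zeros(size, dtype=np.int64)
    d_nbt = np.zeros(size, dtype=np.int64)

    # Nb: bins fad < b <= r_eff
    np.add.at(d_nb, fad + 1, 1)
    np.add.at(d_nb, r_eff + 1, -1)
    # Nt: bins fad <= b < r_eff
    np.add.at(d_nt, fad, 1)
    np.add.at(d_nt, r_eff, -1)
    # Nbt: bins fad < b < r_eff
    np.add.at(d_nbt, fad + 1, 1)
    np.add.at(d_nbt, np.maximum(r_eff, fad + 1), -1)

    nb = np.cumsum(d_nb)[:n_bins]
    nt = np.cumsum(d_nt)[:n_bins]
    nbt = np.cumsum(d_nbt)[:n_bins]

    single = fad == r_eff  # crosses nothing at all
    singles = np.bincount(fad[single], minlength=n_bins)[:n_bins]
    return nbt, nb, nt, singles


def crossing_counts(
    ds: Dataset,
    group: str = "all",
    ts: TimeScale | None = None,
    extant_top_crossing: bool = True,
) -> CrossingCounts:
    """Boundary-crosser counts for a wall-type group (or ``all``)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    ts = ts or ds.timescale
    if ts is not ds.timescale and len(ts) != len(ds.timescale):
        raise ValueError("timescale does not match the dataset's")
    fad, lad, extant, wall = ds.arrays()
    if group != "all":
        m = wall == group
        fad, lad, extant = fad[m], lad[m], extant[m]
    nbt, nb, nt, singles = crossing_arrays(
        fad, lad, extant, len(ts), extant_top_crossing=extant_top_crossing
    )
    return CrossingCounts(group=group, nbt=nbt, nb=nb, nt=nt, n_singletons=singles)


def foote_rates(cc: CrossingCounts, ts: TimeScale) -> RateSeries:
    """Per-capita rates from crossing counts; degenerate bins are flagged,
    never raised."""
    n_bins = len(ts)
    if len(cc.nbt) != n_bins:
        raise ValueError("crossing counts do not match the timescale")
    dt = np.array([iv.duration_myr for iv in ts.intervals])

    valid_p = (cc.nbt > 0) & (cc.nt > 0)
    valid_q = (cc.nbt > 0) & (cc.nb > 0)

    p_hat = np.full(n_bins, np.nan)
    q_hat = np.full(n_bins, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat[valid_p] = -np.log(cc.nbt[valid_p] / cc.nt[valid_p]) / dt[valid_p]
        q_hat[valid_q] = -np.log(cc.nbt[valid_q] / cc.nb[valid_q]) / dt[valid_q]

    edge_p = np.zeros(n_bins, dtype=bool)
    edge_q = np.zeros(n_bins, dtype=bool)
    edge_p[0] = True
    edge_q[-1] = True

    return RateSeries(
        group=cc.group,
        epochs=ts.names,
        midpoint_ma=np.array([iv.midpoint_ma for iv in ts.intervals]),
        duration_myr=dt,
        nbt=cc.nbt.copy(),
        nb=cc.nb.copy(),
        nt=cc.nt.copy(),
        p_hat=p_hat,
        q_hat=q_hat,
        valid_p=valid_p,
        valid_q=valid_q,
        edge_p=edge_p,
        edge_q=edge_q,
    )
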