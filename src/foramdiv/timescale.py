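"""Epoch-level geological timescale with name-alias resolution.

The Phanerozoic analysis bins everything at epoch (series) resolution, so the
timescale is the temporal skeleton of all counting: interval durations feed
the per-capita rate denominators and interval midpoints are the plotting /
regression ages.  The embedded table follows the ICS chronostratigraphic
chart in the 2013 version (Cohen et al.), with the Permian–Triassic boundary
at 251.902 Ma, and treats the four Cambrian series and the Quaternary's
Pleistocene/Holocene as separate epoch-level bins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "GeoInterval",
    "TimeScale",
    "TimescaleError",
    "IntervalLookupError",
    "load_timescale",
    "resolve_interval",
    "uniform_timescale",
    "TIMESCALE_VERSION",
]

TIMESCALE_VERSION = "ICS-2013 epochs (P-Tr at 251.902 Ma)"

ERAS = ("Palaeozoic", "Mesozoic", "Cenozoic")

#: Era boundary ages in Ma (older edge of Mesozoic, older edge of Cenozoic).
PALAEOZOIC_MESOZOIC_MA = 251.902
MESOZOIC_CENOZOIC_MA = 66.0


class TimescaleError(ValueError):
    """The timescale table violates an invariant (corrupt or inconsistent)."""


class IntervalLookupError(KeyError):
    """An interval name could not be resolved against the timescale."""


@dataclass(frozen=True)
class GeoInterval:
    """One epoch-level bin: ``base_ma`` (older edge) to ``top_ma`` (younger)."""

    name: str
    era: str
    period: str
    base_ma: float
    top_ma: float

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise TimescaleError(f"{self.name}: era {self.era!r} not one of {ERAS}")
        if not (self.base_ma > self.top_ma >= 0.0):
            raise TimescaleError(
                f"{self.name}: need base_ma > top_ma >= 0, got "
                f"({self.base_ma}, {self.top_ma})"
            )

    @property
    def duration_myr(self) -> float:
        return self.base_ma - self.top_ma

    @property
    def midpoint_ma(self) -> float:
        return (self.base_ma + self.top_ma) / 2.0

    def contains_age(self, age_ma: float) -> bool:
        """True if ``age_ma`` falls in [base_ma, top_ma); age 0 belongs to the
        youngest bin, which callers handle by checking ``top_ma == 0``."""
        if self.top_ma == 0.0:
            return self.base_ma >= age_ma >= 0.0
        return self.base_ma >= age_ma > self.top_ma


def _normalize(name: str) -> str:
    """Case/whitespace-insensitive key; 'Lower'->'Early', 'Upper'->'Late'."""
    key = re.sub(r"\s+", " ", name.strip().lower())
    key = re.sub(r"\blower\b", "early", key)
    key = re.sub(r"\bupper\b", "late", key)
    return key


@dataclass(frozen=True)
class TimeScale:
    """Ordered, contiguous epoch bins (oldest first) plus an alias map."""

    intervals: tuple[GeoInterval, ...]
    alias_map: dict[str, int] = field(default_factory=dict)
    version: str = TIMESCALE_VERSION

    def __post_init__(self) -> None:
        if not self.intervals:
            raise TimescaleError("empty timescale")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.top_ma != b.base_ma:
                raise TimescaleError(
                    f"gap/overlap between {a.name} (top {a.top_ma}) and "
                    f"{b.name} (base {b.base_ma})"
                )
            if b.base_ma >= a.base_ma:
                raise TimescaleError("base_ma must strictly decrease")
        # full lookup: canonical names + aliases, all normalized
        lookup: dict[str, int] = {}
        for i, iv in enumerate(self.intervals):
            lookup[_normalize(iv.name)] = i
        for alias, idx in self.alias_map.items():
            lookup.setdefault(_normalize(alias), idx)
        object.__setattr__(self, "_lookup", lookup)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, idx: int) -> GeoInterval:
        return self.intervals[idx]

    @property
    def span_myr(self) -> float:
        return self.intervals[0].base_ma - self.intervals[-1].top_ma

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def index_of_age(self, age_ma: float, boundary: str = "younger") -> int:
        """Index of the bin containing an age.

        An age exactly on a bin boundary is ambiguous; ``boundary='younger'``
        assigns it to the younger bin (the bin it opens — the convention for
        origination times, intervals read as [base_ma, top_ma)), while
        ``boundary='older'`` assigns it to the older bin (the bin it closes —
        used for extinction times such as boundary-timed kill pulses).
        """
        if boundary not in ("younger", "older"):
            raise ValueError("boundary must be 'younger' or 'older'")
        if not (self.intervals[0].base_ma >= age_ma >= self.intervals[-1].top_ma):
            raise TimescaleError(f"age {age_ma} Ma outside timescale span")
        for i, iv in enumerate(self.intervals):
            if boundary == "younger":
                hit = iv.contains_age(age_ma)
            else:
                hit = (iv.base_ma > age_ma >= iv.top_ma) or (i == 0 and age_ma == iv.base_ma)
            if hit:
                return i
        raise TimescaleError(f"age {age_ma} Ma not contained in any bin")

    def era_of(self, idx: int) -> str:
        return self.intervals[idx].era

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.names,
                "era": [iv.era for iv in self.intervals],
                "period": [iv.period for iv in self.intervals],
                "base_ma": [iv.base_ma for iv in self.intervals],
                "top_ma": [iv.top_ma for iv in self.intervals],
                "duration_myr": [iv.duration_myr for iv in self.intervals],
                "midpoint_ma": [iv.midpoint_ma for iv in self.intervals],
            }
        )


def resolve_interval(name: str, ts: TimeScale) -> int:
    """Resolve a free-text interval label to an epoch index.

    Stage names map to their containing epoch through the alias table;
    'Lower'/'Early' and 'Upper'/'Late' are synonyms; matching is
    case-insensitive.  Unknown names raise rather than being skipped.
    """
    if not isinstance(name, str) or not name.strip():
        raise IntervalLookupError(f"empty interval name: {name!r}")
    key = _normalize(name)
    lookup: dict[str, int] = getattr(ts, "_lookup")
    if key not in lookup:
        raise IntervalLookupError(f"unrecognized interval name: {name!r}")
    return lookup[key]


def load_timescale() -> TimeScale:
    """Load the embedded Phanerozoic epoch table (541 Ma to present)."""
    pkg = resources.files(__package__)
    try:
        epochs = pd.read_csv(pkg / "data" / "ics2013_epochs.csv")
        aliases = pd.read_csv(pkg / "data" / "interval_aliases.csv")
    except Exception as exc:  # pragma: no cover - corrupt install
        raise TimescaleError(f"embedded timescale tables unreadable: {exc}") from exc

    required = {"name", "era", "period", "base_ma", "top_ma"}
    if not required.issubset(epochs.columns):
        raise TimescaleError(f"timescale table missing columns {required - set(epochs.columns)}")

    intervals = tuple(
        GeoInterval(
            name=row["name"],
            era=row["era"],
            period=row["period"],
            base_ma=float(row["base_ma"]),
            top_ma=float(row["top_ma"]),
        )
        for row in epochs.to_dict("records")
    )
    name_to_idx = {iv.name: i for i, iv in enumerate(intervals)}
    alias_map: dict[str, int] = {}
    for row in aliases.to_dict("records"):
        canonical = row["canonical_name"]
        if canonical not in name_to_idx:
            raise TimescaleError(f"alias {row['alias']!r} points at unknown epoch {canonical!r}")
        alias_map[row["alias"]] = name_to_idx[canonical]

    ts = TimeScale(intervals=intervals, alias_map=alias_map)
    if ts.intervals[0].base_ma != 541.0 or ts.intervals[-1].top_ma != 0.0:
        raise TimescaleError("embedded timescale does not span 541-0 Ma")
    return ts


def uniform_timescale(
    n_bins: int, bin_myr: float = 10.0, base_ma: float | None = None, prefix: str = "E"
) -> TimeScale:
    """Build a synthetic timescale of ``n_bins`` equal bins ending at 0 Ma.

    Used by the simulator and tests; bin names are E1 (oldest) .. En.
    Eras are assigned from the real era boundary ages so era-split code
    works on synthetic scales too.
    """
    if n_bins < 1 or bin_myr <= 0:
        raise TimescaleError("need n_bins >= 1 and bin_myr > 0")
    if base_ma is None:
        base_ma = n_bins * bin_myr
    if abs(base_ma - n_bins * bin_myr) > 1e-9:
        raise TimescaleError("base_ma inconsistent with n_bins * bin_myr")

    def era_for(mid: float) -> str:
        if mid > PALAEOZOIC_MESOZOIC_MA:
            return "Palaeozoic"
        if mid > MESOZOIC_CENOZOIC_MA:
            return "Mesozoic"
        return "Cenozoic"

    intervals = []
    for i in range(n_bins):
        base = base_ma - i * bin_myr
        top = base - bin_myr
        if i == n_bins - 1:
            top = 0.0
        intervals.append(
            GeoInterval(
                name=f"{prefix}{i + 1}",
                era=era_for((base + top) / 2),
                period="synthetic",
                base_ma=base,
                top_ma=top,
            )
        )
    return TimeScale(intervals=tuple(intervals), version="synthetic-uniform")
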