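"""Genus-range table I/O, validation and wall-type normalization.

The analysis dataset is a genus-level range chart compiled from Loeblich &
Tappan's *Foraminiferal Genera and their Classification* (1987): one row per
genus with habit (benthic/planktic), the verbatim wall-type description, and
the origination/extinction intervals at epoch resolution.  The free-text wall
descriptions are collapsed onto three analysis categories:

* calcareous — CaCO3 precipitated by the test (incl. porcelaneous, aragonite)
* agglutinated — grains aggregated from the sediment, whatever their
  composition (so "calcareous and agglutinated" is agglutinated)
* organic — organic-walled tests

with three special rules: fusulinids with unknown/microgranular walls count
as calcareous; *Saudia* and *Sornayina* (unknown walls) are agglutinated per
WoRMS; the single opaline genus *Milammellus* is excluded from analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .timescale import TimeScale, resolve_interval

__all__ = [
    "GenusRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "WallTypeError",
    "WALL_TYPES",
    "simplify_wall_type",
    "read_genus_table",
    "write_genus_table",
    "write_exclusion_log",
    "filter_benthic",
]

WALL_TYPES = ("calcareous", "agglutinated", "organic")

HABITS = ("benthic", "planktic")

#: canonical CSV column order (writer output / reader default)
CANONICAL_COLUMNS = (
    "genus",
    "order",
    "suborder",
    "superfamily",
    "family",
    "subfamily",
    "habit",
    "wall_type_original",
    "fad_interval",
    "lad_interval",
)

HIGHER_TAXON_FIELDS = ("order", "suborder", "superfamily", "family", "subfamily")


class SchemaError(ValueError):
    """Input table is missing required columns."""


class ValidationError(ValueError):
    """A row violates a dataset invariant (reversed range, duplicate genus...)."""


class WallTypeError(ValueError):
    """A wall description is outside the known vocabulary and special cases."""


def _norm_text(s: str) -> str:
    """Normalize free text: lowercase, strip, drop commas, collapse spaces."""
    s = s.replace(",", " ").replace("&", "and")
    return re.sub(r"\s+", " ", s.strip().lower())


#: Loeblich & Tappan description -> analysis category (normalized keys)
_WALL_MAP = {
    "agglutinated": "agglutinated",
    "calcareous and agglutinated": "agglutinated",
    "calcareous porcelaneous and agglutinated": "agglutinated",
    "porcelaneous and agglutinated": "agglutinated",
    "aragonite": "calcareous",
    "aragonitic": "calcareous",
    "calcareous": "calcareous",
    "porcelaneous": "calcareous",
    "calcareous and porcelaneous": "calcareous",
    "organic": "organic",
}

#: descriptions that defer to the genus/higher-taxon special rules
_UNKNOWN_WALLS = {"unknown", "microgranular", "unknown/microgranular", ""}

_AGGLUTINATED_UNKNOWN_GENERA = {"saudia", "sornayina"}
_EXCLUDED_GENERA = {"milammellus"}  # opaline, the only one in the compilation

#: substring that flags a fusulinid higher taxon (Fusulinida, Fusulinina,
#: Fusulinacea, Fusulinidae ... all share the stem)
_FUSULINID_STEM = "fusulin"


def _is_fusulinid(
    higher_taxa: Mapping[str, str] | None,
    genus: str,
    fusulinid_genera: Iterable[str] = (),
) -> bool:
    if genus and _norm_text(genus) in {_norm_text(g) for g in fusulinid_genera}:
        return True
    if higher_taxa:
        for value in higher_taxa.values():
            if value and _FUSULINID_STEM in value.lower():
                return True
    return False


def simplify_wall_type(
    original: str,
    genus: str = "",
    higher_taxa: Mapping[str, str] | None = None,
    fusulinid_genera: Iterable[str] = (),
) -> str:
    """Collapse a verbatim wall description onto an analysis category.

    Returns one of ``calcareous``, ``agglutinated``, ``organic`` or
    ``excluded`` (the opaline case).  Unknown descriptions fall back to the
    special-case genus rules; anything still unresolved raises
    :class:`WallTypeError` so the vocabulary must be extended explicitly
    rather than rows being dropped in silence.
    """
    g = _norm_text(genus) if genus else ""
    if g in _EXCLUDED_GENERA:
        return "excluded"
    if g in _AGGLUTINATED_UNKNOWN_GENERA:
        return "agglutinated"

    key = _norm_text(original or "")
    if key in _WALL_MAP:
        return _WALL_MAP[key]
    if _is_fusulinid(higher_taxa, genus, fusulinid_genera):
        return "calcareous"
    if key in _UNKNOWN_WALLS:
        raise WallTypeError(
            f"genus {genus!r}: wall type {original!r} is unknown and the genus "
            "matches no special-case rule (fusulinid / Saudia / Sornayina / "
            "Milammellus)"
        )
    raise WallTypeError(
        f"wall description {original!r} not in the simplification vocabulary; "
        "extend the mapping explicitly if this description is legitimate"
    )


@dataclass(frozen=True)
class GenusRecord:
    """One genus: habit, wall types, and its range in epoch indices."""

    genus: str
    habit: str
    wall_type_original: str
    wall_type: str
    fad_interval: int
    lad_interval: int
    extant: bool = False
    higher_taxa: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habit not in HABITS:
            raise ValidationError(f"{self.genus}: habit {self.habit!r} not in {HABITS}")
        if self.wall_type not in WALL_TYPES + ("excluded",):
            raise ValidationError(f"{self.genus}: wall_type {self.wall_type!r} invalid")
        if self.fad_interval > self.lad_interval:
            raise ValidationError(
                f"{self.genus}: range reversed (fad index {self.fad_interval} "
                f"younger than lad index {self.lad_interval})"
            )


@dataclass
class Dataset:
    """A validated collection of genus records bound to a timescale."""

    records: list[GenusRecord]
    timescale: TimeScale
    provenance: list[str] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (genus, reason)

    def __post_init__(self) -> None:
        n = len(self.timescale)
        seen: set[str] = set()
        dupes: list[str] = []
        for r in self.records:
            if not (0 <= r.fad_interval < n and 0 <= r.lad_interval < n):
                raise ValidationError(f"{r.genus}: interval index outside timescale")
            if r.extant and r.lad_interval != n - 1:
                raise ValidationError(f"{r.genus}: extant but lad is not the terminal bin")
            key = r.genus.strip().lower()
            if key in seen:
                dupes.append(r.genus)
            seen.add(key)
        if dupes:
            raise ValidationError(f"duplicate genus names: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.records)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def arrays(self):
        """(fad, lad, extant, wall) as plain lists/arrays for the kernels."""
        import numpy as np

        fad = np.fromiter((r.fad_interval for r in self.records), dtype=np.int64, count=len(self))
        lad = np.fromiter((r.lad_interval for r in self.records), dtype=np.int64, count=len(self))
        extant = np.fromiter((r.extant for r in self.records), dtype=bool, count=len(self))
        wall = np.array([r.wall_type for r in self.records], dtype=object)
        return fad, lad, extant, wall

    def subset(self, indices: Sequence[int], note: str | None = None) -> "Dataset":
        ds = Dataset(
            records=[self.records[i] for i in indices],
            timescale=self.timescale,
            provenance=list(self.provenance),
            exclusions=list(self.exclusions),
        )
        if note:
            ds.log(note)
        return ds

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {c: r.higher_taxa.get(c, "") for c in HIGHER_TAXON_FIELDS}
            row.update(
                genus=r.genus,
                habit=r.habit,
                wall_type_original=r.wall_type_original,
                wall_type=r.wall_type,
                fad_interval=self.timescale[r.fad_interval].name,
                lad_interval=self.timescale[r.lad_interval].name,
                extant=r.extant,
            )
            rows.append(row)
        cols = list(CANONICAL_COLUMNS) + ["wall_type", "extant"]
        return pd.DataFrame(rows, columns=cols)


DEFAULT_COLUMN_MAP = {
    "genus": "genus",
    "habit": "habit",
    "wall_type_original": "wall_type_original",
    "fad_interval": "fad_interval",
    "lad_interval": "lad_interval",
}


def read_genus_table(
    path: str | Path,
    ts: TimeScale,
    column_map: Mapping[str, str] | None = None,
    fusulinid_genera: Iterable[str] = (),
) -> Dataset:
    """Read a genus-range CSV into a validated :class:`Dataset`.

    ``column_map`` maps the canonical field names (keys of
    ``DEFAULT_COLUMN_MAP``) to the file's actual headers, so arbitrary source
    layouts can be adapted without editing the file.  Wall descriptions are
    simplified on read; interval names are resolved against ``ts``.  Rows are
    never silently dropped — any problem raises with the row number.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[GenusRecord] = []
    last_idx = len(ts) - 1
    for i, row in enumerate(df.to_dict("records")):
        rowno = i + 2  # header is line 1
        genus = str(row[cmap["genus"]]).strip()
        if not genus:
            raise ValidationError(f"{path} row {rowno}: empty genus name")
        habit = str(row[cmap["habit"]]).strip().lower()
        original = str(row[cmap["wall_type_original"]]).strip()
        higher = {c: str(row.get(c, "")).strip() for c in HIGHER_TAXON_FIELDS if c in df.columns}
        try:
            fad = resolve_interval(str(row[cmap["fad_interval"]]), ts)
            lad = resolve_interval(str(row[cmap["lad_interval"]]), ts)
        except KeyError as exc:
            raise ValidationError(f"{path} row {rowno} ({genus}): {exc.args[0]}") from exc
        if fad > lad:
            raise ValidationError(
                f"{path} row {rowno} ({genus}): range reversed "
                f"(fad {ts[fad].name!r} younger than lad {ts[lad].name!r})"
            )
        wall = simplify_wall_type(original, genus, higher, fusulinid_genera)
        records.append(
            GenusRecord(
                genus=genus,
                habit=habit,
                wall_type_original=original,
                wall_type=wall,
                fad_interval=fad,
                lad_interval=lad,
                extant=(lad == last_idx),
                higher_taxa=higher,
            )
        )

    ds = Dataset(records=records, timescale=ts)
    ds.log(f"read {len(records)} genus records from {path}")
    return ds


def write_genus_table(ds: Dataset, path: str | Path) -> None:
    """Write the canonical genus CSV (round-trips through read_genus_table)."""
    ds.to_frame().to_csv(path, index=False)


def write_exclusion_log(ds: Dataset, path: str | Path) -> None:
    pd.DataFrame(ds.exclusions, columns=["genus", "reason"]).to_csv(path, index=False)


def filter_benthic(ds: Dataset) -> Dataset:
    """Restrict to benthic genera with an analysable wall type.

    Planktic genera and excluded (opaline) genera are removed and logged with
    reasons; counts are conserved: ``len(input) == len(output) + new
    exclusions``.
    """
    keep: list[GenusRecord] = []
    excl: list[tuple[str, str]] = []
    for r in ds.records:
        if r.habit != "benthic":
            excl.append((r.genus, f"habit={r.habit}"))
        elif r.wall_type == "excluded":
            excl.append((r.genus, "wall type excluded (opaline)"))
        else:
            keep.append(r)
    out = Dataset(
        records=keep,
        timescale=ds.timescale,
        provenance=list(ds.provenance),
        exclusions=list(ds.exclusions) + excl,
    )
    n_planktic = sum(1 for _, reason in excl if reason.startswith("habit"))
    n_wall = len(excl) - n_planktic
    out.log(
        f"filter_benthic: kept {len(keep)} of {len(ds)} "
        f"(removed {n_planktic} non-benthic, {n_wall} excluded wall types)"
    )
    if not keep:
        import warnings

        warnings.warn("filter_benthic produced an empty dataset", stacklevel=2)
    return out
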