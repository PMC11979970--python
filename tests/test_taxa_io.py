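"""Genus-table reading, wall-type simplification and the benthic filter."""

import pandas as pd
import pytest

from foramdiv.taxa_io import (
    Dataset,
    SchemaError,
    ValidationError,
    WallTypeError,
    filter_benthic,
    read_genus_table,
    simplify_wall_type,
    write_genus_table,
)

TOY_CSV = """genus,habit,wall_type_original,fad_interval,lad_interval
Silurella,benthic,calcareous,Llandovery,Late Devonian
Cretaplankt,planktic,calcareous,Early Cretaceous,Late Cretaceous
Aggfossil,benthic,agglutinated,Furongian,Holocene
"""


@pytest.fixture()
def toy_path(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text(TOY_CSV)
    return p


# --- wall-type simplification: the full source vocabulary --------------------

@pytest.mark.parametrize(
    "original, expected",
    [
        ("agglutinated", "agglutinated"),
        ("calcareous and agglutinated", "agglutinated"),
        ("calcareous, porcelaneous and agglutinated", "agglutinated"),
        ("porcelaneous and agglutinated", "agglutinated"),
        ("aragonite", "calcareous"),
        ("calcareous", "calcareous"),
        ("porcelaneous", "calcareous"),
        ("calcareous and porcelaneous", "calcareous"),
        ("organic", "organic"),
    ],
)
def test_simplification_vocabulary_is_total(original, expected):
    assert simplify_wall_type(original) == expected
    # case/whitespace/comma-insensitive
    assert simplify_wall_type(original.upper().replace(", ", " , ")) == expected


@pytest.mark.parametrize("genus", ["Saudia", "Sornayina", "saudia"])
def test_unknown_wall_special_genera_are_agglutinated(genus):
    assert simplify_wall_type("unknown", genus=genus) == "agglutinated"


def test_opaline_milammellus_is_excluded():
    assert simplify_wall_type("unknown", genus="Milammellus") == "excluded"


def test_fusulinids_with_unknown_walls_are_calcareous():
    assert simplify_wall_type("unknown", genus="Triticites", higher_taxa={"order": "Fusulinida"}) == "calcareous"
    assert simplify_wall_type("microgranular", genus="X", higher_taxa={"suborder": "Fusulinina"}) == "calcareous"
    assert simplify_wall_type("unknown", genus="Triticites", fusulinid_genera=["Triticites"]) == "calcareous"


def test_unknown_description_without_special_case_raises():
    with pytest.raises(WallTypeError):
        simplify_wall_type("unknown", genus="Mysterius")
    with pytest.raises(WallTypeError):
        simplify_wall_type("chitinous-frilled", genus="Mysterius")


# --- reading -----------------------------------------------------------------

def test_read_toy_table(toy_path, ts):
    ds = read_genus_table(toy_path, ts)
    assert len(ds) == 3
    assert sum(r.habit == "benthic" for r in ds.records) == 2
    agg = next(r for r in ds.records if r.genus == "Aggfossil")
    assert agg.extant  # lad resolves to Holocene
    sil = next(r for r in ds.records if r.genus == "Silurella")
    assert not sil.extant
    assert ts[sil.fad_interval].name == "Llandovery"


def test_reversed_range_rejected(tmp_path, ts):
    p = tmp_path / "bad.csv"
    p.write_text(
        "genus,habit,wall_type_original,fad_interval,lad_interval\n"
        "Backwards,benthic,calcareous,Holocene,Lopingian\n"
    )
    with pytest.raises(ValidationError, match="reversed"):
        read_genus_table(p, ts)


def test_missing_column_is_schema_error(tmp_path, ts):
    p = tmp_path / "bad.csv"
    p.write_text("genus,habit,fad_interval,lad_interval\nA,benthic,Eocene,Eocene\n")
    with pytest.raises(SchemaError, match="wall_type_original"):
        read_genus_table(p, ts)


def test_unresolvable_interval_names_row(tmp_path, ts):
    p = tmp_path / "bad.csv"
    p.write_text(
        "genus,habit,wall_type_original,fad_interval,lad_interval\n"
        "A,benthic,calcareous,Eocene,Eocene\n"
        "B,benthic,calcareous,Nonsuchian,Eocene\n"
    )
    with pytest.raises(ValidationError, match=r"row 3.*Nonsuchian"):
        read_genus_table(p, ts)


def test_duplicate_genus_rejected(tmp_path, ts):
    p = tmp_path / "dup.csv"
    p.write_text(
        "genus,habit,wall_type_original,fad_interval,lad_interval\n"
        "A,benthic,calcareous,Eocene,Eocene\n"
        "a,benthic,organic,Eocene,Miocene\n"
    )
    with pytest.raises(ValidationError, match="duplicate"):
        read_genus_table(p, ts)


def test_column_mapping_adapts_foreign_headers(tmp_path, ts):
    p = tmp_path / "foreign.csv"
    p.write_text("Genus name,mode,wall,first,last\nA,benthic,calcareous,Eocene,Miocene\n")
    ds = read_genus_table(
        p,
        ts,
        column_map={
            "genus": "Genus name",
            "habit": "mode",
            "wall_type_original": "wall",
            "fad_interval": "first",
            "lad_interval": "last",
        },
    )
    assert len(ds) == 1 and ds.records[0].wall_type == "calcareous"


def test_round_trip_identical(toy_path, ts, tmp_path):
    ds = read_genus_table(toy_path, ts)
    out = tmp_path / "canonical.csv"
    write_genus_table(ds, out)
    ds2 = read_genus_table(out, ts)
    assert [
        (r.genus, r.habit, r.wall_type, r.fad_interval, r.lad_interval, r.extant)
        for r in ds.records
    ] == [
        (r.genus, r.habit, r.wall_type, r.fad_interval, r.lad_interval, r.extant)
        for r in ds2.records
    ]


# --- benthic filter ----------------------------------------------------------

def test_filter_benthic_counts_conserved(toy_path, ts):
    ds = read_genus_table(toy_path, ts)
    out = filter_benthic(ds)
    assert len(out) == 2
    assert len(ds) == len(out) + len(out.exclusions) - len(ds.exclusions)
    assert ("Cretaplankt", "habit=planktic") in out.exclusions


def test_filter_benthic_drops_and_logs_opaline(tmp_path, ts):
    p = tmp_path / "op.csv"
    p.write_text(
        "genus,habit,wall_type_original,fad_interval,lad_interval\n"
        "Milammellus,benthic,unknown,Miocene,Miocene\n"
        "Keeper,benthic,calcareous,Miocene,Miocene\n"
    )
    ds = read_genus_table(p, ts)
    out = filter_benthic(ds)
    assert [r.genus for r in out.records] == ["Keeper"]
    assert any(g == "Milammellus" and "opaline" in reason for g, reason in out.exclusions)


def test_filter_benthic_empty_result_warns(tmp_path, ts):
    p = tmp_path / "pk.csv"
    p.write_text(
        "genus,habit,wall_type_original,fad_interval,lad_interval\n"
        "P1,planktic,calcareous,Eocene,Eocene\n"
    )
    ds = read_genus_table(p, ts)
    with pytest.warns(UserWarning, match="empty"):
        out = filter_benthic(ds)
    assert len(out) == 0
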