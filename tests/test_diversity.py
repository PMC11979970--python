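"""Occurrence categories, per-epoch counting, proportions and singleton removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_diversity, make_random_dataset
from foramdiv.diversity import (
    OccurrenceCategory,
    classify_in_bin,
    diversity_table,
    format_percent,
    percent_change,
    proportions,
    remove_singletons,
)
from foramdiv.rates import crossing_counts
from foramdiv.taxa_io import WALL_TYPES


@pytest.mark.parametrize(
    "fad, lad, bin_idx, expected",
    [
        (1, 1, 1, OccurrenceCategory.SINGLETON),
        (0, 2, 1, OccurrenceCategory.BOUNDARY_CROSSER),
        (1, 2, 1, OccurrenceCategory.ORIGINATOR),
        (0, 1, 1, OccurrenceCategory.EXTINCT_IN_BIN),
        (0, 2, 3, None),
        (1, 2, 0, None),
    ],
)
def test_classify_in_bin(fad, lad, bin_idx, expected):
    assert classify_in_bin(fad, lad, bin_idx) == expected


def test_classify_rejects_bad_indices():
    with pytest.raises(ValueError):
        classify_in_bin(3, 1, 2)
    with pytest.raises(IndexError):
        classify_in_bin(-1, 1, 0)
    with pytest.raises(IndexError):
        classify_in_bin(0, 1, 5, n_bins=4)


@given(fad=st.integers(0, 9), lad=st.integers(0, 9), b=st.integers(0, 9))
@settings(max_examples=300, deadline=None)
def test_category_partition_property(fad, lad, b):
    """Inside the range exactly one category applies; outside, none."""
    fad, lad = min(fad, lad), max(fad, lad)
    cat = classify_in_bin(fad, lad, b)
    if fad <= b <= lad:
        assert isinstance(cat, OccurrenceCategory)
    else:
        assert cat is None


def test_fixture_bin_e2_one_genus_per_category(fixture_ds):
    dt = diversity_table(fixture_ds)
    row = dt.frame.iloc[1]  # E2
    assert row["total"] == 4
    for cat in ("singleton", "boundary_crosser", "originator", "extinct_in_bin"):
        assert sum(row[f"{w}_{cat}"] for w in WALL_TYPES) == 1
    assert row["p_calcareous"] == pytest.approx(0.5)
    assert row["p_agglutinated"] == pytest.approx(0.5)
    assert row["p_organic"] == pytest.approx(0.0)


def test_full_range_crosser_counts_everywhere(fixture_ds):
    ds = fixture_ds.subset([0])  # genus A spans E1-E3
    dt = diversity_table(ds)
    assert dt.frame["total"].tolist() == [1, 1, 1, 0]


def test_counts_sum_and_proportions_sum(fixture_ds):
    dt = diversity_table(fixture_ds)
    f = dt.frame
    assert (f[[f"n_{w}" for w in WALL_TYPES]].sum(axis=1) == f["total"]).all()
    occupied = f["total"] > 0
    psum = f.loc[occupied, [f"p_{w}" for w in WALL_TYPES]].sum(axis=1)
    assert np.allclose(psum, 1.0, atol=1e-12)
    # zero-total epochs flagged undefined, not NaN-propagated to 0
    props = proportions(dt)
    assert bool(props.loc[3, "undefined"]) is True
    assert np.isnan(props.loc[3, "p_calcareous"])


def test_diversity_matches_brute_force_on_random_datasets():
    rng = np.random.default_rng(20260919)
    for _ in range(150):
        ds = make_random_dataset(rng)
        dt = diversity_table(ds)
        oracle = brute_force_diversity(ds)
        for b in range(len(ds.timescale)):
            row = dt.frame.iloc[b]
            for w in WALL_TYPES:
                cell = oracle[(b, w)]
                assert row[f"n_{w}"] == cell["count"]
                for cat in ("singleton", "originator", "extinct_in_bin", "boundary_crosser"):
                    assert row[f"{w}_{cat}"] == cell[cat], (b, w, cat)


@pytest.mark.parametrize(
    "before, after, formatted",
    [
        (17, 62, 265),
        (441, 264, -40),
        (428, 869, 103),
        (10, 10, 0),
        (38, 88, 132),  # 131.6% rounds to 132 under half-away-from-zero
    ],
)
def test_percent_change_formatting(before, after, formatted):
    assert format_percent(percent_change(before, after)) == formatted


def test_percent_change_requires_positive_base():
    with pytest.raises(ValueError):
        percent_change(0, 5)


def test_modern_wall_type_proportions_format():
    """Counts 246/571/51 give the printed 28% / 66% / 6% split."""
    counts = {"agglutinated": 246, "calcareous": 571, "organic": 51}
    total = sum(counts.values())
    pct = {w: format_percent(100.0 * c / total) for w, c in counts.items()}
    assert pct == {"agglutinated": 28, "calcareous": 66, "organic": 6}


def test_remove_singletons_fixture(fixture_ds):
    out = remove_singletons(fixture_ds, 1)  # D is confined to E2
    assert [r.genus for r in out.records] == ["A", "B", "C"]
    assert any(g == "D" for g, _ in out.exclusions)
    # no-op on a bin without singletons
    same = remove_singletons(fixture_ds, 0)
    assert len(same) == len(fixture_ds)


def test_remove_singletons_never_touches_boundary_crossers():
    """Single-bin genera cross no boundaries, so dropping them leaves all
    crossing counts intact.  The one exception is deliberate: an *extant*
    terminal-bin genus counts as crossing the terminal top under the
    survivorship adjustment, so only terminal Nt may change there."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        ds = make_random_dataset(rng)
        b = int(rng.integers(0, len(ds.timescale)))
        before = crossing_counts(ds, extant_top_crossing=False)
        after = crossing_counts(remove_singletons(ds, b), extant_top_crossing=False)
        assert (before.nbt == after.nbt).all()
        assert (before.nb == after.nb).all()
        assert (before.nt == after.nt).all()
        adj_before = crossing_counts(ds)
        adj_after = crossing_counts(remove_singletons(ds, b))
        assert (adj_before.nbt == adj_after.nbt).all()
        assert (adj_before.nb == adj_after.nb).all()
        assert (adj_before.nt[:-1] == adj_after.nt[:-1]).all()


def test_remove_singletons_matches_generator_count():
    """Terminal-bin singleton removal drops exactly the fad=lad=terminal genera."""
    rng = np.random.default_rng(11)
    ds = make_random_dataset(rng, max_genera=100)
    last = len(ds.timescale) - 1
    n_single = sum(1 for r in ds.records if r.fad_interval == r.lad_interval == last)
    out = remove_singletons(ds, last)
    assert len(out) == len(ds) - n_single


def test_diversity_rejects_excluded_wall_types(fixture_ds):
    from foramdiv.taxa_io import Dataset, GenusRecord

    bad = Dataset(
        records=fixture_ds.records
        + [
            GenusRecord(
                genus="Op",
                habit="benthic",
                wall_type_original="unknown",
                wall_type="excluded",
                fad_interval=0,
                lad_interval=0,
            )
        ],
        timescale=fixture_ds.timescale,
    )
    with pytest.raises(ValueError, match="filter_benthic"):
        diversity_table(bad)
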