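"""Birth-death generator: truth containment, reproducibility, pulses, fixture."""

import numpy as np
import pytest

from foramdiv.diversity import diversity_table
from foramdiv.rates import crossing_counts, foote_rates
from foramdiv.synthdata import (
    PopulationExplosionError,
    Pulse,
    SimConfig,
    simulate_genera,
    worked_fixture,
)
from foramdiv.taxa_io import read_genus_table, write_genus_table
from foramdiv.timescale import uniform_timescale

RATES_ALL = ("calcareous", "agglutinated", "organic")


def _cfg(**kw):
    base = dict(
        seed=1,
        t_start=100.0,
        t_end=0.0,
        n_initial=100,
        founder_mix={"calcareous": 0.5, "agglutinated": 0.5},
        p_true={w: 0.03 for w in RATES_ALL},
        q_true={w: 0.03 for w in RATES_ALL},
    )
    base.update(kw)
    return SimConfig(**base)


def test_immortal_lineages_when_q_zero():
    cfg = _cfg(q_true={w: 0.0 for w in RATES_ALL}, pulses=())
    tsx = uniform_timescale(10, 10.0)
    sim = simulate_genera(cfg, tsx)
    assert all(r.extant for r in sim.dataset.records)
    assert sim.truth["t_ext_ma"].isna().all()
    rs = foote_rates(crossing_counts(sim.dataset), tsx)
    ok = rs.valid_q
    assert np.all(rs.q_hat[ok] == 0.0)


def test_truth_containment():
    """Every true origination/extinction time lies inside its assigned bin."""
    cfg = _cfg(seed=3, pulses=(Pulse(time_ma=50.0, kill_fraction={"calcareous": 0.5}),))
    tsx = uniform_timescale(10, 10.0)
    sim = simulate_genera(cfg, tsx)
    truth = sim.truth.set_index("genus")
    for r in sim.dataset.records:
        t_orig = truth.loc[r.genus, "t_orig_ma"]
        fad_iv = tsx[r.fad_interval]
        assert fad_iv.base_ma >= t_orig >= fad_iv.top_ma
        if not r.extant:
            t_ext = truth.loc[r.genus, "t_ext_ma"]
            lad_iv = tsx[r.lad_interval]
            assert lad_iv.base_ma >= t_ext >= lad_iv.top_ma
            assert t_orig >= t_ext


def test_same_config_reproduces_identically():
    tsx = uniform_timescale(10, 10.0)
    a = simulate_genera(_cfg(seed=11), tsx)
    b = simulate_genera(_cfg(seed=11), tsx)
    assert a.truth.equals(b.truth)
    assert [(r.genus, r.fad_interval, r.lad_interval) for r in a.dataset.records] == [
        (r.genus, r.fad_interval, r.lad_interval) for r in b.dataset.records
    ]
    c = simulate_genera(_cfg(seed=12), tsx)
    assert not a.truth.equals(c.truth)


def test_pulse_creates_selective_extinction_spike():
    cfg = _cfg(
        seed=21,
        n_initial=400,
        q_true={w: 0.02 for w in RATES_ALL},
        pulses=(Pulse(time_ma=50.0, kill_fraction={"calcareous": 0.9}),),
    )
    tsx = uniform_timescale(10, 10.0)
    sim = simulate_genera(cfg, tsx)
    pulse_bin = tsx.index_of_age(50.0, boundary="older")
    q_cal = foote_rates(crossing_counts(sim.dataset, group="calcareous"), tsx).q_hat
    q_agg = foote_rates(crossing_counts(sim.dataset, group="agglutinated"), tsx).q_hat
    assert q_cal[pulse_bin] > q_agg[pulse_bin]
    # a 90% cull implies q*dt >= -ln(0.1) in that bin for the hit group
    assert q_cal[pulse_bin] > 0.15


def test_explosion_guard():
    cfg = _cfg(
        seed=2,
        n_initial=200,
        p_true={w: 0.2 for w in RATES_ALL},
        q_true={w: 0.0 for w in RATES_ALL},
        max_genera=1000,
    )
    with pytest.raises(PopulationExplosionError):
        simulate_genera(cfg, uniform_timescale(10, 10.0))


def test_extant_survivors_inflate_terminal_bin():
    """Pull of the recent: survivors marked extant raise terminal diversity
    relative to the same ranges censored at their last true occupancy."""
    cfg = _cfg(seed=31, n_initial=300)
    tsx = uniform_timescale(10, 10.0)
    sim = simulate_genera(cfg, tsx)
    dt = diversity_table(sim.dataset)
    n_extant = sum(r.extant for r in sim.dataset.records)
    assert n_extant > 0
    assert dt.frame["total"].iloc[-1] >= n_extant


def test_worked_fixture_shape_and_round_trip(tmp_path):
    ds = worked_fixture()
    assert len(ds) == 4 and len(ds.timescale) == 4
    cc = crossing_counts(ds)
    assert (cc.nbt[1], cc.nb[1], cc.nt[1]) == (1, 2, 2)
    dt = diversity_table(ds)
    assert dt.frame.loc[1, "total"] == 4
    path = tmp_path / "fixture.csv"
    write_genus_table(ds, path)
    ds2 = read_genus_table(path, ds.timescale)
    assert [(r.genus, r.wall_type, r.fad_interval, r.lad_interval) for r in ds.records] == [
        (r.genus, r.wall_type, r.fad_interval, r.lad_interval) for r in ds2.records
    ]


def test_config_from_yaml(tmp_path):
    p = tmp_path / "sim.yaml"
    p.write_text(
        "seed: 7\n"
        "t_start: 100.0\n"
        "t_end: 0.0\n"
        "n_initial: 50\n"
        "founder_mix: {calcareous: 0.5, agglutinated: 0.5}\n"
        "p_true: {calcareous: 0.03, agglutinated: 0.03, organic: 0.03}\n"
        "q_true: {calcareous: 0.02, agglutinated: 0.02, organic: 0.02}\n"
        "pulses:\n"
        "  - time_ma: 50.0\n"
        "    kill_fraction: {calcareous: 0.8}\n"
    )
    cfg = SimConfig.from_yaml(p)
    assert cfg.seed == 7 and cfg.n_initial == 50
    assert cfg.pulses[0].time_ma == 50.0
    assert cfg.pulses[0].kill_fraction == {"calcareous": 0.8}


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(seed=0, t_start=0.0, t_end=10.0)
    with pytest.raises(ValueError):
        SimConfig(seed=0, n_initial=0)
    with pytest.raises(ValueError):
        Pulse(time_ma=10.0, kill_fraction={"calcareous": 1.5})
    with pytest.raises(ValueError):
        Pulse(time_ma=10.0, kill_fraction={"opaline": 0.5})
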