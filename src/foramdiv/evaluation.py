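"""Simulation-based self-checks of the estimators and models.

Each function runs a small Monte-Carlo study against datasets from
:mod:`foramdiv.synthdata` with known truth and returns summary numbers:

* recovery of the per-capita rates by the boundary-crosser estimators under a
  constant-rate birth-death process;
* coverage of the bootstrap null envelope when wall types really are
  exchangeable, and detection of a planted selective kill pulse;
* size and power behaviour of the Gamma-GLM trend fit (false-positive rate on
  flat rates, recovery of a known link-scale slope).

The study conditions (founder counts, spans, rates, replicate counts) are
fixed reference configurations, not tuning knobs; all randomness derives from
the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .nullmodel import bootstrap_envelope, compare_to_envelope
from .rates import crossing_counts, foote_rates
from .synthdata import Pulse, SimConfig, simulate_genera
from .taxa_io import WALL_TYPES
from .timescale import load_timescale, uniform_timescale
from .trends import fit_gamma_sqrt_glm

__all__ = [
    "estimator_recovery",
    "envelope_coverage",
    "planted_pulse_detection",
    "glm_null_slope_rate",
    "glm_slope_recovery_rate",
]

_SEED_CAP = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=n)


def estimator_recovery(
    seed: int,
    n_seeds: int = 100,
    rate: float = 0.05,
    n_initial: int = 500,
    span_myr: float = 100.0,
    bin_myr: float = 10.0,
) -> dict:
    """Relative error of mean p_hat / q_hat under a constant-rate process.

    Reference configuration: p = q = ``rate`` per lineage-Myr, ``n_initial``
    founders over ``span_myr`` discretized into ``bin_myr`` bins, pooled over
    ``n_seeds`` independent simulations (valid bins only).
    """
    ts = uniform_timescale(int(round(span_myr / bin_myr)), bin_myr)
    p_vals, q_vals = [], []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(
            seed=int(s),
            t_start=span_myr,
            t_end=0.0,
            n_initial=n_initial,
            founder_mix={"calcareous": 0.5, "agglutinated": 0.5},
            p_true={w: rate for w in WALL_TYPES},
            q_true={w: rate for w in WALL_TYPES},
        )
        rs = foote_rates(crossing_counts(simulate_genera(cfg, ts).dataset), ts)
        p_vals.extend(rs.p_hat[rs.valid_p])
        q_vals.extend(rs.q_hat[rs.valid_q])
    mean_p, mean_q = float(np.mean(p_vals)), float(np.mean(q_vals))
    return {
        "true_rate": rate,
        "mean_p_hat": mean_p,
        "mean_q_hat": mean_q,
        "rel_err_p": abs(mean_p - rate) / rate,
        "rel_err_q": abs(mean_q - rate) / rate,
        "n_seeds": n_seeds,
        "n_bins_pooled_p": len(p_vals),
        "n_bins_pooled_q": len(q_vals),
    }


def _exchangeable_config(s: int, n_initial: int = 200, span: float = 120.0) -> SimConfig:
    return SimConfig(
        seed=int(s),
        t_start=span,
        t_end=0.0,
        n_initial=n_initial,
        founder_mix={"calcareous": 0.5, "agglutinated": 0.5},
        p_true={w: 0.05 for w in WALL_TYPES},
        q_true={w: 0.05 for w in WALL_TYPES},
    )


def envelope_coverage(
    seed: int,
    n_sims: int = 200,
    n_reps: int = 500,
    ci: float = 0.95,
) -> dict:
    """Envelope coverage of observed calcareous rates under exchangeability.

    Both wall types share one birth-death process, so the calcareous group is
    statistically a random subset of its own size and its rates should fall
    inside the central ``ci`` envelope in about ``ci`` of epochs.
    """
    ts = uniform_timescale(12, 10.0)
    within = defined = 0
    seeds = _child_seeds(seed, 2 * n_sims).reshape(n_sims, 2)
    for sim_seed, env_seed in seeds:
        ds = simulate_genera(_exchangeable_config(sim_seed), ts).dataset
        wall = ds.arrays()[3]
        n_cal = int((wall == "calcareous").sum())
        if n_cal == 0:
            continue
        env = bootstrap_envelope(ds, group_size=n_cal, n_reps=n_reps, ci=ci, seed=int(env_seed))
        rs = foote_rates(crossing_counts(ds, group="calcareous"), ts)
        flags = compare_to_envelope(rs, env)
        for col in ("p_flag", "q_flag"):
            vals = flags[col][flags[col] != "undefined"]
            defined += len(vals)
            within += int((vals == "within").sum())
    return {
        "coverage_pct": 100.0 * within / defined,
        "nominal_pct": 100.0 * ci,
        "n_sims": n_sims,
        "n_epochs_pooled": defined,
    }


def planted_pulse_detection(
    seed: int, kill_fraction: float = 0.9, n_reps: int = 500
) -> dict:
    """Detection of a selective calcareous kill pulse by the null envelope."""
    ts = uniform_timescale(12, 10.0)
    sim_seed, env_seed = _child_seeds(seed, 2)
    cfg = SimConfig(
        seed=int(sim_seed),
        t_start=120.0,
        t_end=0.0,
        n_initial=300,
        founder_mix={"calcareous": 0.5, "agglutinated": 0.5},
        p_true={w: 0.05 for w in WALL_TYPES},
        q_true={w: 0.03 for w in WALL_TYPES},
        pulses=(Pulse(time_ma=60.0, kill_fraction={"calcareous": kill_fraction}),),
    )
    ds = simulate_genera(cfg, ts).dataset
    pulse_bin = ts.index_of_age(60.0, boundary="older")
    wall = ds.arrays()[3]
    n_cal = int((wall == "calcareous").sum())
    env = bootstrap_envelope(ds, group_size=n_cal, n_reps=n_reps, seed=int(env_seed))
    rs = foote_rates(crossing_counts(ds, group="calcareous"), ts)
    flags = compare_to_envelope(rs, env)
    return {
        "pulse_bin": ts[pulse_bin].name,
        "q_flag": flags.loc[pulse_bin, "q_flag"],
        "flagged_above": bool(flags.loc[pulse_bin, "q_flag"] == "above"),
        "observed_q": float(rs.q_hat[pulse_bin]),
        "envelope_upper_q": float(env.q_upper[pulse_bin]),
    }


def _phanerozoic_midpoints() -> np.ndarray:
    ts = load_timescale()
    return np.array([iv.midpoint_ma for iv in ts.intervals])


def glm_null_slope_rate(
    seed: int, n_sims: int = 200, rate: float = 0.05, shape: float = 50.0
) -> dict:
    """Fraction of flat-rate simulations where the slope is (correctly) not
    significant at 0.05."""
    ages = _phanerozoic_midpoints()
    rng = np.random.default_rng(seed)
    not_significant = 0
    for _ in range(n_sims):
        y = rng.gamma(shape, rate / shape, size=ages.size)
        fit = fit_gamma_sqrt_glm(ages, y)
        not_significant += int(fit.p_slope > 0.05)
    return {"pct_p_above_05": 100.0 * not_significant / n_sims, "n_sims": n_sims}


def glm_slope_recovery_rate(
    seed: int,
    n_sims: int = 200,
    intercept: float = 0.30,
    slope: float = -0.0005,
    shape: float = 50.0,
) -> dict:
    """Fraction of simulations recovering a known link-scale slope within
    two standard errors."""
    ages = _phanerozoic_midpoints()
    rng = np.random.default_rng(seed)
    covered = 0
    slopes = []
    for _ in range(n_sims):
        mu = (intercept + slope * ages) ** 2
        y = rng.gamma(shape, mu / shape)
        fit = fit_gamma_sqrt_glm(ages, y)
        covered += int(abs(fit.slope - slope) <= 2.0 * fit.se_slope)
        slopes.append(fit.slope)
    return {
        "pct_within_2se": 100.0 * covered / n_sims,
        "mean_slope": float(np.mean(slopes)),
        "true_slope": slope,
        "n_sims": n_sims,
    }
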