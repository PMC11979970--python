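"""Shared fixtures and independent brute-force oracles.

The oracles intentionally reimplement the counting logic as slow, readable
double loops over (genus, bin) pairs so the vectorized kernels can be checked
against an implementation with no shared code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from foramdiv import load_timescale, worked_fixture
from foramdiv.diversity import classify_in_bin
from foramdiv.taxa_io import Dataset, GenusRecord, WALL_TYPES
from foramdiv.timescale import uniform_timescale


@pytest.fixture(scope="session")
def ts():
    return load_timescale()


@pytest.fixture()
def fixture_ds():
    return worked_fixture()


def make_random_dataset(rng: np.random.Generator, max_genera: int = 50, max_bins: int = 10) -> Dataset:
    """A random small dataset on a uniform toy timescale (for oracle checks)."""
    n_bins = int(rng.integers(2, max_bins + 1))
    n = int(rng.integers(1, max_genera + 1))
    tsx = uniform_timescale(n_bins, 10.0)
    records = []
    for i in range(n):
        fad = int(rng.integers(0, n_bins))
        lad = int(rng.integers(fad, n_bins))
        wall = WALL_TYPES[int(rng.integers(0, 3))]
        extant = bool(lad == n_bins - 1 and rng.random() < 0.5)
        records.append(
            GenusRecord(
                genus=f"R{i}",
                habit="benthic",
                wall_type_original=wall,
                wall_type=wall,
                fad_interval=fad,
                lad_interval=lad,
                extant=extant,
            )
        )
    return Dataset(records=records, timescale=tsx)


def brute_force_diversity(ds: Dataset):
    """Per (bin, wall) counts by category via an explicit double loop."""
    n_bins = len(ds.timescale)
    out = {
        (b, w): {"count": 0, "singleton": 0, "originator": 0, "extinct_in_bin": 0, "boundary_crosser": 0}
        for b in range(n_bins)
        for w in WALL_TYPES
    }
    for r in ds.records:
        for b in range(n_bins):
            cat = classify_in_bin(r.fad_interval, r.lad_interval, b, n_bins)
            if cat is not None:
                cell = out[(b, r.wall_type)]
                cell["count"] += 1
                cell[cat.value] += 1
    return out


def brute_force_crossings(ds: Dataset, group: str = "all", extant_top_crossing: bool = True):
    """Per-bin (Nbt, Nb, Nt) via explicit boundary membership tests."""
    n_bins = len(ds.timescale)
    nbt = np.zeros(n_bins, dtype=int)
    nb = np.zeros(n_bins, dtype=int)
    nt = np.zeros(n_bins, dtype=int)
    for r in ds.records:
        if group != "all" and r.wall_type != group:
            continue
        lad_eff = r.lad_interval + (1 if (extant_top_crossing and r.extant) else 0)
        for b in range(n_bins):
            crosses_bottom = r.fad_interval < b <= lad_eff
            crosses_top = r.fad_interval <= b < lad_eff
            nb[b] += crosses_bottom
            nt[b] += crosses_top
            nbt[b] += crosses_bottom and crosses_top
    return nbt, nb, nt


def gamma_sqrt_irls(ages, y, maxiter=200, tol=1e-12):
    """Reference Gamma-family IRLS with sqrt link, written from the textbook
    update: w = 4/mu per unit weight (V(mu)=mu^2, g'(mu)=1/(2*sqrt(mu))),
    working response z = eta + (y - mu) * g'(mu).

    Returns (beta, cov) with cov scaled by the Pearson dispersion on n-2 df.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(ages), ages])
    beta = np.linalg.lstsq(X, np.sqrt(y), rcond=None)[0]  # init on link scale
    for _ in range(maxiter):
        eta = X @ beta
        mu = eta**2
        gprime = 1.0 / (2.0 * np.sqrt(mu))
        w = 1.0 / (mu**2 * gprime**2)  # = 4/mu
        z = eta + (y - mu) * gprime
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = eta**2
    w = 4.0 / mu
    pearson = np.sum((y - mu) ** 2 / mu**2)
    phi = pearson / (len(y) - 2)
    cov = np.linalg.inv(X.T @ (X * w[:, None])) * phi
    return beta, cov
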