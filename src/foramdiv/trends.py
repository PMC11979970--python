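"""Era-split Gamma-GLM trend fits of per-capita rates against time.

Each response (a wall type's origination or extinction rate series) is
regressed on epoch midpoint age (Ma) with a generalized linear model using a
square-root link and Gamma variance:  sqrt(mu) = b0 + b1 * age,
Var(y) ~ mu^2.  Fitting is by iteratively reweighted least squares with the
dispersion estimated from the Pearson chi-square (quasi-Gamma), and slope
inference is a Wald test on that dispersion.  Bins with invalid or
non-positive rates are excluded (a Gamma response must be positive) and the
exclusion count is carried on the fit.  The data are split into the
Palaeozoic and the Mesozoic+Cenozoic at 251.9 Ma so the two fits have
comparable numbers of points; age increases into the past, so a negative
slope means rates declining toward the present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rates import RateSeries
from .timescale import TimeScale

__all__ = [
    "GlmFit",
    "InsufficientDataError",
    "fit_rate_trend",
    "fit_gamma_sqrt_glm",
    "predict_band",
    "ERA_FILTERS",
]

ERA_FILTERS = ("Palaeozoic", "Mesozoic+Cenozoic", "all")

SIGNIFICANCE_LEVEL = 0.05


class InsufficientDataError(ValueError):
    """Fewer than three usable (valid, positive) rates in the era."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class GlmFit:
    """One fitted trend: sqrt(mu) = intercept + slope * age_ma."""

    era_label: str
    response_label: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_slope: float
    dispersion: float  # Pearson estimate
    n_points: int
    excluded_points: int
    cov_params: np.ndarray  # 2x2, link scale
    age_range: tuple[float, float]
    significant: bool

    def summary_row(self) -> dict:
        return {
            "era": self.era_label,
            "response": self.response_label,
            "intercept": self.intercept,
            "slope": self.slope,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "p_slope": self.p_slope,
            "dispersion": self.dispersion,
            "n_points": self.n_points,
            "excluded_points": self.excluded_points,
            "significant": self.significant,
        }


def fit_gamma_sqrt_glm(
    ages: np.ndarray, rates: np.ndarray, era_label: str = "all", response_label: str = ""
) -> GlmFit:
    """Fit the Gamma GLM with sqrt link to positive rates at the given ages."""
    ages = np.asarray(ages, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if ages.shape != rates.shape:
        raise ValueError("ages and rates must have equal length")
    if (rates <= 0).any() or np.isnan(rates).any():
        raise ValueError("rates must be strictly positive and finite")
    if len(rates) < 3:
        raise InsufficientDataError(
            f"{era_label}/{response_label}: need >= 3 positive rates, have {len(rates)}"
        )

    X = sm.add_constant(ages)
    # sqrt is a non-canonical link for Gamma; it is well defined for strictly
    # positive rates, so bypass statsmodels' conservative link whitelist
    family = sm.families.Gamma(link=sm.families.links.Power(power=0.5), check_link=False)
    try:
        import warnings

        with warnings.catch_warnings():
            from statsmodels.tools.sm_exceptions import DomainWarning

            warnings.simplefilter("ignore", DomainWarning)
            model = sm.GLM(rates, X, family=family)
            res = model.fit(scale="X2", maxiter=200, tol=1e-10)
    except Exception as exc:
        raise ConvergenceError(f"{era_label}/{response_label}: IRLS failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError(
            f"{era_label}/{response_label}: IRLS did not converge "
            f"(deviance trace: {getattr(res, 'fit_history', {}).get('deviance', 'n/a')})"
        )

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    return GlmFit(
        era_label=era_label,
        response_label=response_label,
        intercept=params[0],
        slope=params[1],
        se_intercept=bse[0],
        se_slope=bse[1],
        p_slope=pvals[1],
        dispersion=float(res.scale),
        n_points=len(rates),
        excluded_points=0,
        cov_params=np.asarray(res.cov_params(), dtype=float),
        age_range=(float(ages.min()), float(ages.max())),
        significant=bool(pvals[1] < SIGNIFICANCE_LEVEL),
    )


def fit_rate_trend(
    rs: RateSeries,
    ts: TimeScale,
    era: str = "all",
    rate_kind: str = "p",
) -> GlmFit:
    """Era-filtered trend fit for one rate kind of one group.

    ``era`` is ``Palaeozoic``, ``Mesozoic+Cenozoic`` or ``all``; the boundary
    epoch belongs to whichever era the timescale assigns it.  Invalid and
    non-positive rates are excluded and counted on the returned fit.
    """
    if era not in ERA_FILTERS:
        raise ValueError(f"era must be one of {ERA_FILTERS}")
    if rate_kind not in ("p", "q"):
        raise ValueError("rate_kind must be 'p' or 'q'")
    if rs.epochs != ts.names:
        raise ValueError("rate series and timescale do not match")

    eras = np.array([iv.era for iv in ts.intervals])
    if era == "Palaeozoic":
        in_era = eras == "Palaeozoic"
    elif era == "Mesozoic+Cenozoic":
        in_era = (eras == "Mesozoic") | (eras == "Cenozoic")
    else:
        in_era = np.ones(len(eras), dtype=bool)

    values = rs.p_hat if rate_kind == "p" else rs.q_hat
    valid = rs.valid_p if rate_kind == "p" else rs.valid_q
    usable = in_era & valid & (np.nan_to_num(values) > 0)
    excluded = int(in_era.sum() - usable.sum())

    label = f"{rs.group} {'origination' if rate_kind == 'p' else 'extinction'}"
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"{era}/{label}: need >= 3 positive valid rates, have {int(usable.sum())}"
        )
    fit = fit_gamma_sqrt_glm(
        rs.midpoint_ma[usable], values[usable], era_label=era, response_label=label
    )
    return GlmFit(**{**fit.__dict__, "excluded_points": excluded})


def predict_band(fit: GlmFit, ages: np.ndarray) -> pd.DataFrame:
    """Response-scale fitted mean with a pointwise +/-1 SE band.

    The linear predictor eta = b0 + b1*age has SE from the coefficient
    covariance; the mean is eta^2 and its SE is delta-method propagated
    (2*|eta|*se_eta).  Ages outside the fitted range are flagged as
    extrapolation, not refused.
    """
    ages = np.asarray(ages, dtype=float)
    X = np.column_stack([np.ones_like(ages), ages])
    eta = X @ np.array([fit.intercept, fit.slope])
    var_eta = np.einsum("ij,jk,ik->i", X, fit.cov_params, X)
    se_eta = np.sqrt(np.maximum(var_eta, 0.0))
    mean = eta**2
    se_mean = 2.0 * np.abs(eta) * se_eta
    lo, hi = fit.age_range
    return pd.DataFrame(
        {
            "age_ma": ages,
            "mean": mean,
            "se_lower": mean - se_mean,
            "se_upper": mean + se_mean,
            "extrapolated": (ages < lo) | (ages > hi),
        }
    )
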