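"""Calibration of demographic transition (CDT): rate calibration.

Turns the mutation-scaled transition-time posterior of the two-epoch model
into a stochastic molecular-rate distribution: calendar dates are drawn from
the discretized warming rate of a temperature proxy (the expansion trigger),
every (transition time, date) pair yields a rate TT/date, and the pooled
rate sample is summarized by maximum-likelihood log-normal and Gaussian fits
compared by AIC.

Units: rates are carried internally in substitutions/site/year; the
distribution fit is performed in substitutions/site/My so that a LogMean of
about -3.9 corresponds to about 2%/My, and headline values are reported in
%/My (1 %/My = 1e-8 substitutions/site/year).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .synthetic_data import TemperatureRecord

__all__ = [
    "CalibrationDates",
    "RateSamples",
    "RateDistributionFit",
    "warming_rate_weights",
    "sample_calibration_dates",
    "cross_rate_samples",
    "fit_rate_distribution",
    "convert_rate_units",
]

#: multiplier taking each unit to substitutions/site/year
_UNIT_TO_PER_YEAR = {
    "subst/site/year": 1.0,
    "subst/site/My": 1e-6,
    "%/My": 1e-8,
}

PER_MY = 1e6  # years per My; fits are done on the subst/site/My scale


@dataclass
class CalibrationDates:
    """Calendar dates (years BP) drawn from the warming-rate weights."""

    dates: np.ndarray
    weights_source: str
    seed: int

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        if self.dates.size < 1:
            raise ValueError("at least one calibration date required")
        if np.any(self.dates <= 0):
            raise ValueError("calibration dates must be positive (years BP)")


@dataclass
class RateSamples:
    """Evolutionary-rate draws in substitutions/site/year.

    ``rates`` holds the materialized sample for subsample mode (and for full
    mode at desk scale); for very large full cross products only the factors
    are kept and moments/quantiles are computed exactly from them, honouring
    the memory contract of never materializing the full product.
    """

    rates: np.ndarray | None
    tt_samples: np.ndarray
    dates: np.ndarray
    mode: str  # "full" or "subsample"

    @property
    def n(self) -> int:
        if self.rates is not None:
            return int(self.rates.size)
        return int(self.tt_samples.size) * int(self.dates.size)

    # -- exact cross-product summaries (no materialization) --------------------

    def _count_le(self, x: float) -> int:
        tt_sorted = np.sort(self.tt_samples)
        return int(np.searchsorted(tt_sorted, x * self.dates, side="right").sum())

    def quantile(self, q: float) -> float:
        if self.rates is not None:
            return float(np.quantile(self.rates, q))
        target = q * self.n
        lo = float(self.tt_samples.min() / self.dates.max())
        hi = float(self.tt_samples.max() / self.dates.min())
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if self._count_le(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi / lo < 1 + 1e-12:
                break
        return hi

    def median(self) -> float:
        return self.quantile(0.5)

    def log_moments(self) -> tuple[float, float]:
        """Mean and variance of ln(rate); exact for the full cross product
        because ln(TT/date) = ln TT - ln date and the factors are independent."""
        if self.rates is not None:
            lx = np.log(self.rates)
            return float(lx.mean()), float(lx.var())
        lt, ld = np.log(self.tt_samples), np.log(self.dates)
        return float(lt.mean() - ld.mean()), float(lt.var() + ld.var())

    def moments(self) -> tuple[float, float]:
        """Mean and variance of the rate on the natural scale."""
        if self.rates is not None:
            return float(self.rates.mean()), float(self.rates.var())
        t, inv_d = self.tt_samples, 1.0 / self.dates
        mean = float(t.mean() * inv_d.mean())
        second = float((t**2).mean() * (inv_d**2).mean())
        return mean, second - mean**2


@dataclass
class RateDistributionFit:
    lognormal: dict  # LogMean, LogSD, loglik, aic (subst/site/My scale)
    gaussian: dict  # mean, sd, loglik, aic
    selected: str
    median_rate_pct_per_my: float
    n: int
    units: str = "subst/site/My"

    def rate_quantile(self, q: float) -> float:
        """Quantile of the selected fitted density, in subst/site/year."""
        from scipy.stats import lognorm, norm

        if self.selected == "lognormal":
            val = lognorm.ppf(q, s=self.lognormal["LogSD"], scale=math.exp(self.lognormal["LogMean"]))
        else:
            val = norm.ppf(q, loc=self.gaussian["mean"], scale=self.gaussian["sd"])
        return float(val) / PER_MY

    def to_json(self, path, seed: int | None = None) -> None:
        payload = {
            "lognormal": self.lognormal,
            "gaussian": self.gaussian,
            "selected": self.selected,
            "median_rate_pct_per_my": self.median_rate_pct_per_my,
            "n": self.n,
            "units": self.units,
            "seed": seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def warming_rate_weights(
    record: TemperatureRecord,
    window: tuple[float, float] = (0.0, 25_000.0),
    grid_step: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-age sampling weights proportional to the warming rate.

    The record is linearly interpolated onto a regular age grid over
    ``window``; the weight at each grid age is the rate of temperature
    increase toward the present (centered difference), floored at zero
    (cooling intervals cannot trigger an expansion) and normalized to sum 1.
    Returns (grid_ages, weights).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = window
    if lo < record.ages.min() - 1e-9 or hi > record.ages.max() + 1e-9:
        raise ValueError("record does not span the requested window")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    temp = np.interp(grid, record.ages, record.temperatures)
    # warming toward the present = temperature decreasing with age
    rate = -np.gradient(temp, grid)
    w = np.maximum(rate, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no warming intervals in window: no admissible expansion dates")
    return grid, w / total


def sample_calibration_dates(
    ages: np.ndarray, weights: np.ndarray, k: int = 10_000, seed: int = 0
) -> CalibrationDates:
    """Draw k calendar dates (with replacement) proportional to the weights."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ages.shape != weights.shape:
        raise ValueError("ages and weights must align")
    rng = np.random.default_rng(seed)
    picks = rng.choice(ages.size, size=k, p=weights / weights.sum())
    dates = ages[picks]
    dates = np.where(dates <= 0, np.min(ages[ages > 0], initial=1.0), dates)
    return CalibrationDates(dates, weights_source="warming-rate weights", seed=seed)


def cross_rate_samples(
    tt_posterior: np.ndarray,
    dates: CalibrationDates | np.ndarray,
    mode: str = "full",
    subsample_size: int = 1_000_000,
    seed: int = 0,
    materialize_limit: int = 20_000_000,
) -> RateSamples:
    """Rates TT/date for all (or a seeded subsample of) posterior/date pairs.

    ``full`` forms the complete cross product (kept virtual above
    ``materialize_limit`` pairs); ``subsample`` draws pairs independently.
    TT is in substitutions/site, dates in years, so rates come out in
    substitutions/site/year.
    """
    tt = np.asarray(tt_posterior, dtype=float)
    d = dates.dates if isinstance(dates, CalibrationDates) else np.asarray(dates, float)
    if tt.size == 0 or d.size == 0:
        raise ValueError("empty transition-time or date sample")
    if np.any(tt <= 0) or np.any(d <= 0):
        raise ValueError("transition times and dates must be positive")
    if mode == "full":
        if tt.size * d.size <= materialize_limit:
            rates = np.outer(tt, 1.0 / d).ravel()
        else:
            rates = None
        return RateSamples(rates, tt, d, "full")
    if mode == "subsample":
        rng = np.random.default_rng(seed)
        i = rng.integers(tt.size, size=subsample_size)
        j = rng.integers(d.size, size=subsample_size)
        return RateSamples(tt[i] / d[j], tt, d, "subsample")
    raise ValueError(f"unknown mode {mode!r}")


def fit_rate_distribution(rates: RateSamples) -> RateDistributionFit:
    """ML log-normal and Gaussian fits of the rate density, selected by AIC.

    Closed-form MLEs on the substitutions/site/My scale; AIC = 2k - 2 lnL
    with k = 2 for both families.  Degenerate (zero-variance) samples are
    rejected.
    """
    if rates.n < 100:
        raise ValueError("need at least 100 rate samples")
    lmu, lvar = rates.log_moments()
    mu, var = rates.moments()
    # rescale to subst/site/My
    lmu += math.log(PER_MY)
    mu *= PER_MY
    var *= PER_MY**2
    n = rates.n
    if lvar <= 0 or var <= 0:
        raise ValueError("degenerate rate sample: zero variance")
    lsd, sd = math.sqrt(lvar), math.sqrt(var)
    # lognormal lnL at the MLE: sum ln x = n * (E ln x)
    sum_log_x = n * lmu
    ll_ln = -sum_log_x - n * math.log(lsd) - n / 2.0 * math.log(2 * math.pi) - n / 2.0
    ll_g = -n / 2.0 * math.log(2 * math.pi * var) - n / 2.0
    aic_ln, aic_g = 4.0 - 2.0 * ll_ln, 4.0 - 2.0 * ll_g
    selected = "lognormal" if aic_ln <= aic_g else "gaussian"
    return RateDistributionFit(
        lognormal={"LogMean": lmu, "LogSD": lsd, "loglik": ll_ln, "aic": aic_ln},
        gaussian={"mean": mu, "sd": sd, "loglik": ll_g, "aic": aic_g},
        selected=selected,
        median_rate_pct_per_my=rates.median() * 1e8,
        n=n,
    )


def convert_rate_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact linear conversion between substitution-rate units."""
    try:
        per_year = value * _UNIT_TO_PER_YEAR[from_unit]
        return per_year / _UNIT_TO_PER_YEAR[to_unit]
    except KeyError as e:
        raise ValueError(f"unknown rate unit {e.args[0]!r}; known: {sorted(_UNIT_TO_PER_YEAR)}")
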