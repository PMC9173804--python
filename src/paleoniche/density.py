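"""Suitability-to-density relation and metapopulation size.

Camp population densities tend to sit under a wedge: suitability limits the
*maximum* density a cell supports, so besides an ordinary least-squares fit
the module provides linear quantile regressions toward the upper percentiles
of the density distribution, with the R1 goodness-of-fit measure (one minus
the ratio of minimised check-loss to the intercept-only check-loss).

Metapopulation size converts summed per-cell potential population sizes
(PPS) into a territory-corrected census:

    size = GPPS * GCS / ASA

where GPPS is the sum of PPS over cells, GCS the grid-cell area (123 km^2 by
default) and ASA the average subsistence area (1,079 km^2 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

log = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (50, 55, 60, 65, 70, 75, 80, 90, 95, 99)
DEFAULT_GCS_KM2 = 123.0
DEFAULT_ASA_KM2 = 1079.0


@dataclass
class QuantileFit:
    percentile: float
    slope: float
    intercept: float
    r1: float


@dataclass
class DensityModel:
    slope: float
    intercept: float
    t_stat: float
    p_value: float
    quantile_fits: list[QuantileFit] = field(default_factory=list)
    fence: float | None = None


@dataclass
class MetapopEstimate:
    gpps: float
    gcs: float
    asa: float

    @property
    def size(self) -> float:
        return self.gpps * self.gcs / self.asa


def tukey_filter(sizes) -> tuple[np.ndarray, float]:
    """Drop values strictly above the Tukey upper fence Q3 + 1.5*(Q3-Q1).

    Quartiles use linear interpolation.  Only the upper fence is applied
    (small camps are not outliers).  Fewer than 4 values: nothing removed.
    """
    x = np.asarray(sizes, dtype=float)
    if x.size < 4:
        warnings.warn("tukey_filter: fewer than 4 values; no filtering applied")
        return x, np.inf
    q1, q3 = np.percentile(x, [25, 75])  # type-7 linear interpolation
    fence = q3 + 1.5 * (q3 - q1)
    return x[x <= fence], float(fence)


def fit_density_ols(suitability, density) -> DensityModel:
    """OLS of density on suitability with the standard t-test on the slope."""
    s = np.asarray(suitability, dtype=float)
    d = np.asarray(density, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 cells")
    if np.std(s) == 0:
        raise ValueError("zero variance in suitability")
    res = sm.OLS(d, sm.add_constant(s)).fit()
    return DensityModel(slope=float(res.params[1]), intercept=float(res.params[0]),
                        t_stat=float(res.tvalues[1]), p_value=float(res.pvalues[1]))


def _check_loss(u: np.ndarray, q: float) -> float:
    return float(np.sum(u * (q - (u < 0))))


def fit_density_quantiles(suitability, density,
                          percentiles=DEFAULT_PERCENTILES) -> list[QuantileFit]:
    """Linear quantile regression per percentile with the R1 local fit measure.

    R1(q) = 1 - Vfit/Vnull, where V is the minimised asymmetric absolute
    residual sum and Vnull comes from the intercept-only (unconditional
    quantile) fit.
    """
    s = np.asarray(suitability, dtype=float)
    d = np.asarray(density, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 cells")
    X = sm.add_constant(s)
    fits = []
    for p in percentiles:
        if not (0 < p < 100):
            raise ValueError(f"percentile {p} outside (0,100)")
        q = p / 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = QuantReg(d, X).fit(q=q)
        vfit = _check_loss(d - res.fittedvalues, q)
        vnull = _check_loss(d - np.quantile(d, q), q)
        r1 = 1.0 if vnull <= 0 else float(np.clip(1.0 - vfit / vnull, 0.0, 1.0))
        fits.append(QuantileFit(percentile=float(p), slope=float(res.params[1]),
                                intercept=float(res.params[0]), r1=r1))
    return fits


def potential_population(suitability, slope: float, mean_observed_pop: float,
                         mean_observed_suit: float | None = None,
                         intercept: float | None = None,
                         anchor: str = "centered") -> np.ndarray:
    """Per-cell potential population size, clipped at zero.

    ``centered`` (default): PPS_c = max(0, Pbar + b*(s_c - sbar)), anchored so
    cells at the mean observed suitability carry the mean observed population.
    ``intercept``: PPS_c = max(0, a + b*s_c) using the fitted intercept.
    """
    s = np.asarray(suitability, dtype=float)
    if anchor == "centered":
        if mean_observed_suit is None:
            raise ValueError("centered anchoring needs mean observed suitability")
        log.info("PPS anchoring: centered form Pbar + b*(s - sbar) "
                 "(Pbar=%.3f, sbar=%.3f, b=%.3f)", mean_observed_pop,
                 mean_observed_suit, slope)
        pps = mean_observed_pop + slope * (s - mean_observed_suit)
    elif anchor == "intercept":
        if intercept is None:
            raise ValueError("intercept anchoring needs the fitted intercept")
        pps = intercept + slope * s
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return np.maximum(pps, 0.0)


def metapopulation_size(suitability, slope: float, mean_observed_pop: float,
                        mean_observed_suit: float | None = None,
                        intercept: float | None = None,
                        gcs: float = DEFAULT_GCS_KM2, asa: float = DEFAULT_ASA_KM2,
                        anchor: str = "centered") -> MetapopEstimate:
    """Territory-corrected metapopulation size = GPPS * GCS / ASA."""
    if gcs <= 0 or asa <= 0:
        raise ValueError("GCS and ASA must be positive")
    pps = potential_population(suitability, slope, mean_observed_pop,
                               mean_observed_suit, intercept, anchor)
    return MetapopEstimate(gpps=float(pps.sum()), gcs=gcs, asa=asa)
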