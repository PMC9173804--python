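"""Project a fitted niche model across paleoclimate time slices.

Projection clamps every predictor into its training range before feature
evaluation, so suitability in novel climates extrapolates flat from the
training extremes rather than running off the fitted response curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, LayerStack, PresenceGrid
from .niche import NicheModel

log = logging.getLogger(__name__)


@dataclass
class SuitabilityMap:
    """Continuous model output on [0,1] for one time slice."""

    grid: GridSpec
    age: int
    values: np.ndarray  # (n_rows, n_cols); NaN on water

    def __post_init__(self):
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability raster does not match grid dims")
        v = self.values[self.grid.land_mask]
        if np.any((v < -1e-9) | (v > 1 + 1e-9)):
            raise ValueError("suitability outside [0,1]")


@dataclass
class RangeSeries:
    """Predicted presence-cell counts (PP_T) per time slice."""

    ages: list[int]
    presence_counts: list[int]

    @property
    def mean_pp(self) -> float:
        return float(np.mean(self.presence_counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_bp": self.ages, "pp": self.presence_counts})


def project(model: NicheModel, env_slice: dict[str, np.ndarray], grid: GridSpec,
            age: int = 0, clamp: bool = True) -> SuitabilityMap:
    """Score one slice; predictors are clipped into the model's clamp ranges."""
    missing = [n for n in model.predictor_names if n not in env_slice]
    if missing:
        raise KeyError(f"slice lacks predictor layer(s): {missing}")
    land = grid.land_mask
    X = pd.DataFrame({n: np.asarray(env_slice[n])[land]
                      for n in model.predictor_names})
    vals = np.full(grid.shape, np.nan)
    vals[land] = model.predict(X, clamp=clamp)
    return SuitabilityMap(grid=grid, age=age, values=vals)


def binarize(s: SuitabilityMap, tau: float) -> PresenceGrid:
    """Presence wherever suitability >= tau (land cells only)."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau outside [0,1]")
    pres = np.zeros(s.grid.shape, dtype=bool)
    land = s.grid.land_mask
    pres[land] = s.values[land] >= tau
    return PresenceGrid(grid=s.grid, presence=pres)


def range_series(model: NicheModel, stack: LayerStack, tau: float | None = None,
                 clamp: bool = True) -> RangeSeries:
    """PP_T for every slice of the stack (slices missing a layer are skipped)."""
    if not stack.ages:
        raise ValueError("empty layer stack")
    if tau is None:
        tau = model.threshold
    ages, counts = [], []
    for age in stack.ages:
        sl = stack.slice(age)
        if any(n not in sl for n in model.predictor_names):
            log.warning("slice %d missing layers; skipped", age)
            continue
        s = project(model, sl, stack.grid, age=age, clamp=clamp)
        ages.append(age)
        counts.append(binarize(s, tau).n_presence)
    return RangeSeries(ages=ages, presence_counts=counts)
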