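"""Radiocarbon-site curation and the date-permutation validation test.

The projected suitability maps are validated against the archaeological
record: curated hunter-gatherer 14C dates are matched to the time slice
nearest their age, and the count of sites falling on predicted-presence
cells (O) is compared with the count expected if sites were scattered at
random over the map,

    E_T = N_T * PP_T / TC    (summed over slices T),

via a goodness-of-fit chi-square and a permutation test that reshuffles the
multiset of 14C dates over sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grid import LayerStack
from .niche import NicheModel
from .projection import binarize, project

log = logging.getLogger(__name__)

FARMING_INDICATORS = {"pearl_millet", "oil_palm", "iron_metallurgy", "pit_features"}
FARMING_CHRONOCULTURES = {"Neolithic", "EarlyIronAge", "RecentIronAge"}


@dataclass
class ArchaeoSite:
    """One published 14C date from an archaeological site."""

    id: str
    lon: float
    lat: float
    age_bp: float
    age_error: float
    material: str = "other"  # charcoal | carbonate | other
    lab_code: str | None = None
    stratigraphy_ok: bool = True
    farming_indicators: frozenset = frozenset()
    chronoculture: str = "other"
    has_lithics: bool = False
    pottery: bool = False
    disputed: bool = False

    def __post_init__(self):
        if self.age_bp < 0 or self.age_error < 0:
            raise ValueError(f"site {self.id}: negative age or error")
        self.farming_indicators = frozenset(self.farming_indicators)
        bad = self.farming_indicators - FARMING_INDICATORS
        if bad:
            raise ValueError(f"site {self.id}: unknown farming indicator {bad}")


@dataclass
class ValidationResult:
    observed: int
    expected: float
    chi_square: float
    df: int
    perm_counts: np.ndarray
    p_value: float
    seed: int

    @property
    def perm_mean(self) -> float:
        return float(np.mean(self.perm_counts))

    @property
    def perm_sd(self) -> float:
        return float(np.std(self.perm_counts, ddof=1))

    @property
    def n_perm(self) -> int:
        return len(self.perm_counts)


def filter_dates(raw: list[ArchaeoSite], lithics_only: bool = False,
                 exclude_disputed: bool = False,
                 exclude_pottery: bool = False) -> list[ArchaeoSite]:
    """Curate 14C dates down to reliable hunter-gatherer records.

    Removes carbonate-based dates (reservoir effects), errors above 1,000
    years, dubious stratigraphy and missing lab codes; then removes any
    record with farming indicators (pearl millet, oil palm, iron metallurgy,
    pit features) or a farming chronoculture.  Optional stricter subsets
    restrict to sites with lithics, drop disputed dates, or drop
    pottery-bearing sites.
    """
    out = []
    for s in raw:
        if s.material == "carbonate":
            continue
        if s.age_error > 1000.0:
            continue
        if not s.stratigraphy_ok:
            continue
        if s.lab_code is None or str(s.lab_code).strip() == "":
            continue
        if s.farming_indicators:
            continue
        if s.chronoculture in FARMING_CHRONOCULTURES:
            continue
        if lithics_only and not s.has_lithics:
            continue
        if exclude_disputed and s.disputed:
            continue
        if exclude_pottery and s.pottery:
            continue
        out.append(s)
    log.info("filter_dates: %d of %d records retained", len(out), len(raw))
    return out


def dedupe(sites: list[ArchaeoSite], stack: LayerStack,
           dedupe_deg: float = 0.5) -> list[ArchaeoSite]:
    """Keep one date per 0.5-degree cell per time slice.

    The representative is the record with the smallest age error (ties by
    earliest id).
    """
    groups: dict[tuple, ArchaeoSite] = {}
    for s in sites:
        ci = int(np.floor(s.lon / dedupe_deg))
        cj = int(np.floor(s.lat / dedupe_deg))
        key = (ci, cj, stack.nearest_age(s.age_bp))
        cur = groups.get(key)
        if cur is None or (s.age_error, s.id) < (cur.age_error, cur.id):
            groups[key] = s
    kept = sorted(groups.values(), key=lambda s: s.id)
    log.info("dedupe: %d of %d dates retained", len(kept), len(sites))
    return kept


def expected_sites(n_t: int, pp_t: int, tc: int) -> float:
    """E_T = N_T * PP_T / TC: sites expected on presence cells by chance."""
    if tc < 1:
        raise ValueError("TC must be at least 1")
    if not (0 <= pp_t <= tc):
        raise ValueError("PP_T outside [0, TC]")
    return n_t * pp_t / tc


def _presence_by_slice(model: NicheModel, stack: LayerStack, tau: float):
    pres = {}
    for age in stack.ages:
        s = project(model, stack.slice(age), stack.grid, age=age)
        pres[age] = binarize(s, tau).presence
    return pres


def _site_slice_indicator(sites, model, stack, tau):
    """Boolean matrix: site i is on a presence cell at slice j; plus the
    per-site slice index of its own date.  Sites outside the stack's age
    range are excluded (logged)."""
    ages = list(stack.ages)
    amin, amax = min(ages), max(ages)
    step = {a: (1000.0 if a <= 21000 else 2000.0) for a in ages}
    keep = []
    for s in sites:
        if amin - step[amin] / 2 <= s.age_bp <= amax + step[amax] / 2:
            keep.append(s)
        else:
            log.warning("site %s age %.0f outside stack range; excluded", s.id, s.age_bp)
    pres = _presence_by_slice(model, stack, tau)
    ind = np.zeros((len(keep), len(ages)), dtype=bool)
    own = np.zeros(len(keep), dtype=int)
    for i, s in enumerate(keep):
        r, c = stack.grid.cell_of(s.lon, s.lat)
        for j, a in enumerate(ages):
            ind[i, j] = pres[a][r, c]
        own[i] = ages.index(stack.nearest_age(s.age_bp))
    return keep, ind, own


def observed_count(sites, model: NicheModel, stack: LayerStack, tau: float) -> int:
    """O: sites whose cell is a predicted presence at their own time slice."""
    _, ind, own = _site_slice_indicator(sites, model, stack, tau)
    return int(ind[np.arange(len(own)), own].sum())


def chi_square_gof(observed: int, expected: float, n_sites: int) -> tuple[float, int]:
    """Goodness-of-fit chi-square on {in-presence, not-in-presence}.

    chi2 = (O-E)^2/E + ((n-O)-(n-E))^2/(n-E), df = 1.
    """
    if not (0 < expected < n_sites):
        raise ValueError("expected count must lie strictly between 0 and n_sites")
    o2 = n_sites - observed
    e2 = n_sites - expected
    chi2 = (observed - expected) ** 2 / expected + (o2 - e2) ** 2 / e2
    return float(chi2), 1


def permute_dates(sites, model: NicheModel, stack: LayerStack, tau: float,
                  n_perm: int = 1000, seed: int = 0) -> ValidationResult:
    """Permutation test of the date-suitability association.

    Each permutation reassigns the multiset of 14C dates across sites
    (without replacement) and recounts sites on presence cells at their
    assigned slice.  p = (1 + #{perm >= O_obs}) / (n_perm + 1).
    """
    kept, ind, own = _site_slice_indicator(sites, model, stack, tau)
    n = len(kept)
    if len(set(s.age_bp for s in kept)) < 2:
        raise ValueError("need at least two distinct dates to permute")
    o_obs = int(ind[np.arange(n), own].sum())
    rng = np.random.default_rng(seed)
    rows = np.arange(n)
    perm_counts = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        perm_counts[k] = ind[rows, own[rng.permutation(n)]].sum()
    p = (1 + int(np.sum(perm_counts >= o_obs))) / (n_perm + 1)

    # chance expectation from per-slice presence fractions
    tc = stack.grid.total_cells
    ages = list(stack.ages)
    n_t = np.bincount(own, minlength=len(ages))
    pres = _presence_by_slice(model, stack, tau)
    e = sum(expected_sites(int(n_t[j]), int(pres[a].sum()), tc)
            for j, a in enumerate(ages))
    if 0 < e < n:
        chi2, df = chi_square_gof(o_obs, e, n)
    else:
        chi2, df = float("nan"), 1
    return ValidationResult(observed=o_obs, expected=float(e), chi_square=chi2,
                            df=df, perm_counts=perm_counts, p_value=float(p),
                            seed=seed)


def performance_vs_age(sites, model: NicheModel, stack: LayerStack,
                       tau: float) -> float:
    """Point-biserial correlation of the in-presence indicator with age.

    Returns NaN (flagged) when the indicator has zero variance.
    """
    kept, ind, own = _site_slice_indicator(sites, model, stack, tau)
    if len(kept) < 3:
        raise ValueError("need at least 3 sites")
    hit = ind[np.arange(len(own)), own].astype(float)
    ages = np.array([s.age_bp for s in kept], dtype=float)
    if np.std(hit) == 0 or np.std(ages) == 0:
        warnings.warn("performance_vs_age: indicator (or ages) constant; r undefined")
        return float("nan")
    return float(stats.pointbiserialr(hit, ages).correlation)


def confounder_check(env_layers: dict[str, np.ndarray], soil_layer: np.ndarray,
                     land_mask: np.ndarray, r_cut: float = 0.7):
    """Screen a soil layer against model predictors for collinearity.

    Pass iff every |Pearson r| over land cells is below ``r_cut``.
    Returns (max |r|, passed, per-layer r dict).
    """
    soil = np.asarray(soil_layer, dtype=float)[land_mask]
    rs = {}
    if np.std(soil) == 0:
        warnings.warn("confounder_check: soil layer constant; skipped")
        return 0.0, True, rs
    for name, layer in env_layers.items():
        v = np.asarray(layer, dtype=float)[land_mask]
        if np.std(v) == 0:
            warnings.warn(f"confounder_check: layer {name!r} constant; skipped")
            continue
        rs[name] = float(np.corrcoef(soil, v)[0, 1])
    max_r = max((abs(r) for r in rs.values()), default=0.0)
    return max_r, bool(max_r < r_cut), rs
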