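"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the structure of the real inputs — spatially
autocorrelated environmental fields drifting over time slices, camp
presences drawn from a known logistic suitability, a wedge-shaped
(upper-bounded, heteroscedastic) density-suitability relation, dated sites
enriched on suitable cells, island-model genotypes at a preset F_ST and IBD
segment lists with preset cross-population sharing rates — so recovery and
calibration tests have exact targets.  Every generator is a pure function
of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .archaeo import ArchaeoSite
from .grid import CampRecord, GridSpec, LayerStack
from .ibd import IBDSegment
from .projection import SuitabilityMap


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic generators."""

    seed: int = 0
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 0.1
    lon_min: float = 10.0
    lat_max: float = 0.0
    n_slices: int = 10
    corr_length_cells: float = 6.0  # e-folding distance of field autocorrelation
    drift: float = 0.15             # per-slice mean shift of each field
    rotation: float = 0.35          # per-slice pattern drift (radians): the
                                    # field rotates between two independent
                                    # realizations, so *which* cells are
                                    # favorable changes through time
    beta0: float = -0.5             # logistic suitability intercept
    beta: tuple[float, ...] = (2.0, -1.5)  # one coefficient per layer
    density_intercept: float = 5.0  # wedge: sizes ~ U(0, a + b_true*s)
    b_true: float = 43.4
    p_suit: float = 0.8             # site-placement enrichment on suitable cells
    fst: float = 0.10               # island-model differentiation
    ibd_rates: dict = field(default_factory=lambda: {"1-5": 0.4, "5-10": 0.3, ">10": 0.2})


def _grf(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Unit-variance Gaussian random field: smoothed white noise.

    A Gaussian kernel of width sigma gives correlation exp(-d^2/(4 sigma^2));
    the e-folding correlation length is therefore 2*sigma.
    """
    sigma = corr_length / 2.0
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def make_grid(cfg: SimConfig, water_fraction: float = 0.0,
              rng: np.random.Generator | None = None) -> GridSpec:
    mask = np.ones((cfg.n_rows, cfg.n_cols), dtype=bool)
    if water_fraction > 0:
        rng = rng or np.random.default_rng(cfg.seed + 7)
        n_water = int(water_fraction * mask.size)
        idx = rng.choice(mask.size, size=n_water, replace=False)
        mask.flat[idx] = False
    return GridSpec(lon_min=cfg.lon_min, lon_max=cfg.lon_min + cfg.n_cols * cfg.cell_size,
                    lat_min=cfg.lat_max - cfg.n_rows * cfg.cell_size,
                    lat_max=cfg.lat_max, cell_size=cfg.cell_size, land_mask=mask)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_landscape_stack(cfg: SimConfig, grid: GridSpec | None = None
                        ) -> tuple[LayerStack, dict[int, SuitabilityMap]]:
    """Drifting correlated fields plus the true logistic suitability per slice.

    Layer k at slice t combines a mean shift ``drift * t`` (a monotone
    climate trend) with a rotation ``cos(rotation*t)*A + sin(rotation*t)*B``
    between two independent field realizations, so both the overall level
    and the spatial pattern of favorable cells change through time.  True
    suitability is sigmoid(beta0 + sum_k beta_k * layer_k).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = grid or make_grid(cfg)
    ages = [1000 * t for t in range(cfg.n_slices)]
    base = [(_grf(rng, grid.shape, cfg.corr_length_cells),
             _grf(rng, grid.shape, cfg.corr_length_cells)) for _ in cfg.beta]
    layers, truth = {}, {}
    for t, age in enumerate(ages):
        c, s = np.cos(cfg.rotation * t), np.sin(cfg.rotation * t)
        sl = {f"env{k}": c * base[k][0] + s * base[k][1] + cfg.drift * t
              for k in range(len(cfg.beta))}
        layers[age] = sl
        eta = cfg.beta0 + sum(b * sl[f"env{k}"] for k, b in enumerate(cfg.beta))
        vals = np.where(grid.land_mask, _sigmoid(eta), np.nan)
        truth[age] = SuitabilityMap(grid=grid, age=age, values=vals)
    stack = LayerStack(grid=grid, ages=ages, layers=layers)
    return stack, truth


def gen_camps(true_suit: SuitabilityMap, n_camps: int, b_true: float,
              seed: int = 0, density_intercept: float = 5.0) -> list[CampRecord]:
    """Camps on cells sampled proportionally to true suitability, with sizes
    drawn Uniform(0, a + b_true * s) so the upper-quantile slope is b_true."""
    if n_camps < 1:
        raise ValueError("need at least one camp")
    rng = np.random.default_rng(seed)
    grid = true_suit.grid
    land = np.argwhere(grid.land_mask)
    w = true_suit.values[land[:, 0], land[:, 1]]
    w = w / w.sum()
    idx = rng.choice(len(land), size=n_camps, replace=True, p=w)
    lon_c, lat_c = grid.cell_centers()
    camps = []
    for k, ci in enumerate(idx):
        i, j = land[ci]
        s = true_suit.values[i, j]
        size = rng.uniform(0.0, density_intercept + b_true * s)
        camps.append(CampRecord(id=f"camp{k}", lon=float(lon_c[i, j]),
                                lat=float(lat_c[i, j]), population_size=float(size)))
    return camps


def gen_archaeo_sites(stack: LayerStack, truth: dict[int, SuitabilityMap],
                      p_suit: float, n_sites: int, mode: str = "signal",
                      seed: int = 0, suit_threshold: float = 0.5) -> list[ArchaeoSite]:
    """Dated sites enriched on suitable cells (``signal``) or placed uniformly
    over land regardless of suitability (``null``); dates uniform over slices."""
    if mode not in ("signal", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    lon_c, lat_c = grid.cell_centers()
    land = np.argwhere(grid.land_mask)
    sites = []
    for k in range(n_sites):
        age = int(rng.choice(stack.ages))
        if mode == "signal" and rng.random() < p_suit:
            sv = truth[age].values[land[:, 0], land[:, 1]]
            good = land[sv >= suit_threshold]
            pool = good if len(good) else land
        else:
            pool = land
        i, j = pool[rng.integers(len(pool))]
        sites.append(ArchaeoSite(
            id=f"site{k}", lon=float(lon_c[i, j]), lat=float(lat_c[i, j]),
            age_bp=float(age), age_error=float(rng.integers(20, 300)),
            material="charcoal", lab_code=f"LAB-{k}", chronoculture="LSA",
            has_lithics=True))
    return sites


def gen_dem(grid: GridSpec, relief_amplitude: float = 0.0,
            river_col: int | None = None, river_width: int = 1,
            corr_length_cells: float = 6.0, seed: int = 0
            ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random relief (m) plus an optional vertical river barrier."""
    rng = np.random.default_rng(seed)
    if relief_amplitude > 0:
        dem = relief_amplitude * _grf(rng, grid.shape, corr_length_cells)
    else:
        dem = np.zeros(grid.shape)
    water = ~grid.land_mask.copy()
    if river_col is not None:
        water[:, river_col:river_col + river_width] = True
    return dem, water


def gen_genotypes(n_per_pop: int, n_sites: int, fst: float, n_pops: int = 2,
                  seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Balding-Nichols island-model genotypes at differentiation F.

    Ancestral frequencies ~ U(0.1, 0.9); each population's frequency ~
    Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes ~ Binomial(2, p_i).
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_sites)
    geno = []
    labels = []
    for k in range(n_pops):
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_k = rng.beta(a, b)
        else:
            p_k = p_anc
        geno.append(rng.binomial(2, p_k, size=(n_per_pop, n_sites)))
        labels += [f"pop{k}"] * n_per_pop
    return np.vstack(geno).astype(np.int8), labels


_CLASS_BOUNDS = {"1-5": (1.0, 5.0), "5-10": (5.0, 10.0), ">10": (10.0, 25.0)}


def gen_ibd_segments(pop_sizes: dict[str, int], rates: dict[str, float],
                     min_blocks: dict[str, int] | None = None,
                     seed: int = 0) -> tuple[list[IBDSegment], dict[str, str]]:
    """IBD lists with preset cross-population sharing rates per length class.

    Each cross-population dyad is connected in a class with the configured
    probability; its block count is then Poisson-distributed above the
    class's minimum-block threshold when connected (and below it, mostly
    zero, when not), so the recovered sharing probability targets the rate.
    """
    from .ibd import DEFAULT_MIN_BLOCKS

    mb = dict(DEFAULT_MIN_BLOCKS)
    if min_blocks:
        mb.update(min_blocks)
    rng = np.random.default_rng(seed)
    inds = {p: [f"{p}_i{k}" for k in range(n)] for p, n in pop_sizes.items()}
    labels = {i: p for p, ii in inds.items() for i in ii}
    segs = []
    pops = sorted(pop_sizes)
    for ai in range(len(pops)):
        for bi in range(ai + 1, len(pops)):
            for a in inds[pops[ai]]:
                for b in inds[pops[bi]]:
                    for cls, rate in rates.items():
                        lo, hi = _CLASS_BOUNDS[cls]
                        if rng.random() < rate:
                            n_blocks = mb[cls] + rng.poisson(1.0)
                        else:
                            n_blocks = min(int(rng.poisson(0.3)), mb[cls] - 1)
                        for k in range(n_blocks):
                            ln = rng.uniform(lo, hi)
                            start = rng.uniform(0.0, 150.0)
                            segs.append(IBDSegment(
                                ind_a=a, ind_b=b, chrom=f"chr{rng.integers(1, 23)}",
                                start_cm=start, end_cm=start + ln))
    return segs, labels
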