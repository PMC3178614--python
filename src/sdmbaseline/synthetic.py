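"""Synthetic landscapes, virtual species, occurrence records, and surveys.

The generator supplies every input the pipeline consumes, with known
ground truth: smooth continuous environmental gradients plus contiguous
categorical region layers; virtual species with logistic-linear niches
s(x) = sigmoid(alpha + sum_l beta_l env_l(x) + categorical bonus);
presence records sampled proportionally to suitability, with reported
georeferencing error radii drawn from a small/large mixture and
collection years spanning the 1950 cutoff (so every quality filter is
exercised); and multinomial-style survey abundances at chosen sites.

Defaults describe a desk-scale study region: a 60x60 grid of 30
arc-second cells, three continuous gradients and two categorical region
layers, eight species with ~120 records each, 70% of records with sub-km
georeferencing error, one quarter collected before 1950, and 90%
vouchered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .assemblage import AssemblageMatrix
from .layers import ARCSEC30, GridSpec, Layer, LayerStack, RegionMask
from .occurrence import OccurrenceSet

__all__ = [
    "SimulationConfig",
    "VirtualSpecies",
    "generate_layers",
    "generate_species",
    "ghost_species",
    "sample_occurrences",
    "sample_survey",
    "watershed_mask",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study region and its sampling processes."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = ARCSEC30
    origin_lon: float = -99.0
    origin_lat: float = 31.0
    n_continuous: int = 3
    n_categorical: int = 2
    n_categories: int = 4
    n_species: int = 8
    records_per_species: int = 120
    frac_large_error: float = 0.3     # records with >1 km reported radius
    frac_pre_cutoff_years: float = 0.25
    year_cutoff: int = 1950
    year_range: tuple[int, int] = (1930, 2005)
    voucher_prob: float = 0.9
    detectability: float = 1.0
    smooth_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_continuous", "n_species",
                     "records_per_species", "n_categories"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.detectability <= 1:
            raise ValueError("detectability must be in (0, 1]")
        if not 0 <= self.frac_large_error <= 1:
            raise ValueError("frac_large_error must be in [0, 1]")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size,
                        self.origin_lon, self.origin_lat)

    def as_dict(self) -> dict:
        return asdict(self)


def generate_layers(cfg: SimulationConfig) -> LayerStack:
    """Deterministic (seeded) synthetic layer stack with full validity.

    Continuous layers are a low-order polynomial trend plus
    Gaussian-smoothed noise, standardized; categorical layers are
    contiguous regions built as nearest-center partitions of random
    seed points.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    rows, cols = np.mgrid[0:cfg.n_rows, 0:cfg.n_cols]
    u = rows / max(cfg.n_rows - 1, 1)
    v = cols / max(cfg.n_cols - 1, 1)
    layers: list[Layer] = []
    for i in range(cfg.n_continuous):
        coef = rng.normal(size=5)
        trend = (coef[0] * u + coef[1] * v + coef[2] * u * v
                 + coef[3] * u ** 2 + coef[4] * v ** 2)
        noise = gaussian_filter(rng.normal(size=grid.shape), cfg.smooth_sigma)
        vals = trend + noise * 1.5
        vals = (vals - vals.mean()) / vals.std()
        layers.append(Layer(f"env{i}", "continuous", vals))
    for i in range(cfg.n_categorical):
        centers = rng.uniform(size=(cfg.n_categories, 2)) * \
            np.array([cfg.n_rows, cfg.n_cols])
        d2 = ((rows[..., None] - centers[:, 0]) ** 2
              + (cols[..., None] - centers[:, 1]) ** 2)
        codes = np.argmin(d2, axis=-1).astype(float)
        layers.append(Layer(f"region{i}", "categorical", codes,
                            categories=tuple(range(cfg.n_categories))))
    return LayerStack(grid, layers, set_id="synthetic")


@dataclass
class VirtualSpecies:
    """A species with a known logistic-linear niche."""

    species_id: str
    intercept: float
    slopes: dict[str, float]                       # continuous layer -> coefficient
    cat_prefs: dict[str, dict[int, float]] = field(default_factory=dict)
    native: bool = True
    detectability: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.detectability <= 1:
            raise ValueError("detectability must be in (0, 1]")
        vals = [self.intercept, *self.slopes.values()]
        for prefs in self.cat_prefs.values():
            vals.extend(prefs.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("niche coefficients must be finite")

    def true_suitability(self, stack: LayerStack) -> np.ndarray:
        """s(x) on the grid (NaN outside the valid extent)."""
        eta = np.full(stack.grid.shape, self.intercept, dtype=float)
        for name, beta in self.slopes.items():
            eta = eta + beta * stack[name].values
        for name, prefs in self.cat_prefs.items():
            codes = stack[name].values
            bonus = np.zeros_like(codes)
            for code, b in prefs.items():
                bonus = np.where(codes == code, b, bonus)
            eta = eta + bonus
        s = expit(eta)
        return np.where(stack.validity_mask, s, np.nan)


def generate_species(cfg: SimulationConfig, stack: LayerStack) -> list[VirtualSpecies]:
    """Draw ``cfg.n_species`` virtual species with random niches.

    Slopes are drawn from N(0, 3^2) on the standardized gradients and
    intercepts from N(-4, 2^2), producing a mix of restricted-range
    specialists (the regime where regional presence-only modelling
    performs well) and broader generalists whose models tend to fail the
    acceptance rule; one species in four is flagged non-native.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cont = [l.name for l in stack.layers if l.kind == "continuous"]
    cats = [l.name for l in stack.layers if l.kind == "categorical"]
    species = []
    for i in range(cfg.n_species):
        slopes = {name: float(rng.normal(scale=3.0)) for name in cont}
        cat_prefs = {}
        for name in cats:
            codes = stack[name].categories or ()
            fav = int(rng.integers(len(codes)))
            cat_prefs[name] = {codes[fav]: float(rng.uniform(0.5, 1.5))}
        sp = VirtualSpecies(
            species_id=f"species_{i:02d}",
            intercept=float(rng.normal(loc=-4.0, scale=2.0)),
            slopes=slopes,
            cat_prefs=cat_prefs,
            native=(i % 4 != 3),
            detectability=cfg.detectability,
        )
        species.append(sp)
    return species


def ghost_species(
    stack: LayerStack,
    focal: RegionMask,
    species_id: str = "species_ghost",
    sharpness: float = 6.0,
    peak_eta: float = 3.0,
) -> VirtualSpecies:
    """A habitat specialist whose niche covers the focal region.

    The niche points along the environmental direction that separates the
    focal region from the rest of the landscape: slopes are proportional
    to the focal-vs-landscape mean difference of each continuous layer
    (scaled to length ``sharpness``), with a bonus for the focal region's
    dominant category, and the intercept is set so the linear predictor at
    the focal mean environment equals ``peak_eta`` (suitability ~0.92).
    Used to stage the headline scenario: high true suitability inside the
    watershed while occurrence sampling there is withheld.
    """
    cont = [l for l in stack.layers if l.kind == "continuous"]
    if not cont:
        raise ValueError("ghost species needs at least one continuous layer")
    inside = focal.values & stack.validity_mask
    if not inside.any():
        raise ValueError("focal mask overlaps no valid cells")
    direction = {}
    for lyr in cont:
        d = float(np.nanmean(lyr.values[inside]) - np.nanmean(lyr.values[stack.validity_mask]))
        direction[lyr.name] = d
    norm = np.sqrt(sum(d * d for d in direction.values()))
    if norm == 0:
        # focal region is environmentally average; fall back to the first axis
        direction = {cont[0].name: 1.0}
        norm = 1.0
    slopes = {k: sharpness * d / norm for k, d in direction.items()}
    cat_prefs: dict[str, dict[int, float]] = {}
    for lyr in stack.layers:
        if lyr.kind == "categorical":
            codes = lyr.values[inside]
            dominant = int(np.bincount(codes[np.isfinite(codes)].astype(int)).argmax())
            cat_prefs[lyr.name] = {dominant: 1.0}
    eta_focal = sum(slopes[k] * float(np.nanmean(stack[k].values[inside]))
                    for k in slopes) + 1.0  # focal cells carry the category bonus
    return VirtualSpecies(species_id=species_id, intercept=peak_eta - eta_focal,
                          slopes=slopes, cat_prefs=cat_prefs, native=True)


def _default_error_model(rng: np.random.Generator, n: int,
                         frac_large: float) -> np.ndarray:
    """Reported georeference radii (m): lognormal below 1 km with
    probability 1 - frac_large, uniform 1-3 km otherwise."""
    large = rng.uniform(size=n) < frac_large
    small = np.minimum(rng.lognormal(mean=5.5, sigma=0.6, size=n), 1000.0)
    big = rng.uniform(1000.0 + 1e-6, 3000.0, size=n)
    return np.where(large, big, small)


def _default_year_model(rng: np.random.Generator, n: int, cfg: SimulationConfig
                        ) -> np.ndarray:
    pre = rng.uniform(size=n) < cfg.frac_pre_cutoff_years
    lo, hi = cfg.year_range
    early = rng.integers(lo, cfg.year_cutoff, size=n)
    late = rng.integers(cfg.year_cutoff, hi + 1, size=n)
    return np.where(pre, early, late)


def sample_occurrences(
    sp: VirtualSpecies,
    stack: LayerStack,
    n: int,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    exclude_mask: RegionMask | None = None,
) -> OccurrenceSet:
    """Sample ``n`` presence records for a virtual species.

    Cells are drawn (with replacement) with probability proportional to
    s(x) * detectability over valid cells; each record's point is jittered
    uniformly within its cell.  Reported uncertainty radii, collection
    years, and voucher flags follow the config's error/year/voucher
    models.  ``exclude_mask`` zeroes sampling probability inside a region
    (used to withhold a species' records from a focal watershed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed + 1000 if seed is None else seed)
    grid = stack.grid
    s = sp.true_suitability(stack)
    w = np.where(np.isfinite(s), s * sp.detectability, 0.0).ravel()
    if exclude_mask is not None:
        w = np.where(exclude_mask.values.ravel(), 0.0, w)
    if w.sum() <= 0:
        raise ValueError("species has zero sampling weight everywhere")
    cells = rng.choice(grid.n_cells, size=n, p=w / w.sum())
    row, col = grid.rowcol_from_id(cells)
    lon = grid.origin_lon + (col + rng.uniform(size=n)) * grid.cell_size
    lat = grid.origin_lat - (row + rng.uniform(size=n)) * grid.cell_size
    records = pd.DataFrame({
        "species_id": sp.species_id,
        "lon": lon,
        "lat": lat,
        "uncertainty_m": _default_error_model(rng, n, cfg.frac_large_error),
        "year": pd.array(_default_year_model(rng, n, cfg), dtype="Int64"),
        "vouchered": rng.uniform(size=n) < cfg.voucher_prob,
        "source_id": [f"sim:{sp.species_id}:{i}" for i in range(n)],
    })
    log = [{"op": "simulate", "species": sp.species_id, "n": n,
            "seed": int(cfg.seed if seed is None else seed)}]
    return OccurrenceSet(records, log)


def sample_survey(
    community: Sequence[VirtualSpecies],
    stack: LayerStack,
    sites: Sequence[tuple[int, int]],
    effort: float = 50.0,
    seed: int = 0,
    label: str = "survey",
    exclude_species: Sequence[str] = (),
) -> tuple[AssemblageMatrix, pd.DataFrame]:
    """Poisson survey counts at ``sites`` (grid (row, col) pairs).

    Expected count of species k at site i is effort * s_k(site_i) *
    detectability_k; species in ``exclude_species`` are never detected
    (simulating local loss).  Returns the sampled matrix and the expected
    (ground-truth) composition.
    """
    rng = np.random.default_rng(seed)
    site_ids = [f"site_{r}_{c}" for r, c in sites]
    expected = {}
    for sp in community:
        s = sp.true_suitability(stack)
        mu = np.array([s[r, c] for r, c in sites]) * sp.detectability * effort
        mu = np.where(np.isfinite(mu), mu, 0.0)
        if sp.species_id in exclude_species:
            mu = np.zeros_like(mu)
        expected[sp.species_id] = mu
    exp_df = pd.DataFrame(expected, index=site_ids)
    counts = pd.DataFrame(rng.poisson(exp_df.to_numpy()),
                          index=site_ids, columns=exp_df.columns)
    return AssemblageMatrix(counts, label=label), exp_df


def watershed_mask(grid: GridSpec, row_frac: tuple[float, float] = (0.78, 0.98),
                   col_frac: tuple[float, float] = (0.78, 0.98),
                   name: str = "watershed") -> RegionMask:
    """A rectangular focal-watershed mask in a corner of the grid.

    The corner placement makes the watershed environmentally distinctive
    (the smooth gradients are most extreme there), the way a small
    spring-fed watershed differs from the surrounding region.
    """
    vals = np.zeros(grid.shape, dtype=bool)
    r0, r1 = (int(f * grid.n_rows) for f in row_frac)
    c0, c1 = (int(f * grid.n_cols) for f in col_frac)
    vals[r0:r1, c0:c1] = True
    return RegionMask(grid, vals, name=name)
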