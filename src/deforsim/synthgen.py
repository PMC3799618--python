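"""Fully synthetic landscapes with known ground truth.

Generates everything the inference and simulation machinery consumes — an
initial land-cover state with a deforestation frontier, road/river/
settlement distance layers, terrain, a dry-season field derived from twelve
monthly precipitation surfaces, soil classes, protected-area blocks,
state-level (Voronoi) zonation and municipality-level economic values — and
draws ground-truth one-year transitions from the hazard model itself, so
parameter- and selection-recovery experiments know the answer.

Two named coefficient presets, ``pre_ppcdam`` and ``post_ppcdam``, carry the
published posterior-mean coefficient sets of the two Amazon calibration
regimes (the high- and low-pressure deforestation eras around the 2004
federal action plan) so scenario contrasts can be exercised qualitatively.
The landscapes themselves make no claim of reproducing real geography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .covariates import (NEIGHBOURHOOD, CovariateStack, distance_to_features,
                         dry_season_length, encode_categorical)
from .landscape import (DEFORESTED, EXCLUDED, FOREST, GridMeta,
                        LandscapeState, Layer, TransitionObservation,
                        derive_transition)
from .model import ModelSpec, ParameterPosterior, ParameterSet
from .simulator import step_year

__all__ = [
    "SyntheticScenario",
    "PRESETS",
    "preset_posterior",
    "preset_parameters",
    "make_landscape",
    "simulate_truth_transition",
]

# Published posterior summaries (mean, lower, upper) of the final models for
# the two calibration regimes; sd backed out of the 95% interval width.
_PRESET_TABLES: dict[str, list[tuple[str, float, float, float]]] = {
    "pre_ppcdam": [
        ("intercept", -3.70, -4.88, -2.57),
        (NEIGHBOURHOOD, 2.10, 1.70, 2.57),
        ("roads", -0.00011, -0.00013, -0.00009),
        ("prot_state", -0.18, -0.73, 0.09),
        ("prot_federal", -0.40, -0.84, -0.19),
        ("prot_indigenous", -0.52, -0.75, -0.41),
    ],
    "post_ppcdam": [
        ("intercept", -4.96, -5.92, -3.28),
        (NEIGHBOURHOOD, 2.32, 1.61, 3.07),
        ("roads", -0.00006, -0.00009, -0.00003),
        ("gdp", 0.45, 0.08, 0.76),
        ("prot_state", -0.18, -0.97, 0.52),
        ("prot_federal", -0.71, -1.25, -0.19),
        ("prot_indigenous", -0.42, -0.75, -0.13),
    ],
}

PRESETS = tuple(_PRESET_TABLES)


def preset_posterior(name: str) -> ParameterPosterior:
    """Posterior summaries of a named coefficient preset."""
    try:
        rows = _PRESET_TABLES[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}") from None
    names = tuple(r[0] for r in rows)
    mean = np.array([r[1] for r in rows])
    lower = np.array([r[2] for r in rows])
    upper = np.array([r[3] for r in rows])
    return ParameterPosterior(names=names, mean=mean,
                              sd=(upper - lower) / 3.92,
                              lower=lower, upper=upper)


def preset_parameters(name: str) -> tuple[ModelSpec, ParameterSet]:
    """Model spec and true (posterior-mean) coefficients of a preset."""
    post = preset_posterior(name)
    spec = ModelSpec(id=name, variables=post.names[1:])
    return spec, ParameterSet(post.mean.copy())


@dataclass
class SyntheticScenario:
    """Recipe for one reproducible synthetic landscape."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 5.0  # km
    seed: int = 0
    #: None -> dense frontier network with ~40 km spacing (one crossing road
    #: per 8 rows+cols), the regime the preset coefficients describe.
    n_roads: int | None = None
    n_rivers: int = 2
    n_settlements: int = 8
    n_protected_blocks: int = 3
    protected_block_frac: float = 0.15  # block side as fraction of grid side
    n_states: int = 4
    n_municipalities: int = 25
    frontier_rows: int = 3
    #: None -> scattered clearings near roads on ~0.5% of cells, so the
    #: starting landscape has the road-hugging prior deforestation the
    #: calibration regimes assume.
    n_frontier_seeds: int | None = None
    excluded_block: bool = True  # carve a small EXCLUDED (water) rectangle


class GenerationError(RuntimeError):
    """Scenario cannot be realised (e.g. infeasible block packing)."""


def _line_mask(shape: tuple[int, int], r0: float, c0: float,
               r1: float, c1: float) -> np.ndarray:
    """Rasterize a straight segment onto the lattice (dense sampling)."""
    mask = np.zeros(shape, dtype=bool)
    n = 4 * max(shape)
    rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, shape[1] - 1)
    mask[rr, cc] = True
    return mask


def _random_crossing_lines(shape: tuple[int, int], count: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Union of ``count`` straight polylines crossing the whole grid."""
    mask = np.zeros(shape, dtype=bool)
    nr, nc = shape
    for _ in range(count):
        if rng.random() < 0.5:  # top edge to bottom edge
            mask |= _line_mask(shape, 0, rng.uniform(0, nc - 1),
                               nr - 1, rng.uniform(0, nc - 1))
        else:  # left edge to right edge
            mask |= _line_mask(shape, rng.uniform(0, nr - 1), 0,
                               rng.uniform(0, nr - 1), nc - 1)
    return mask


def _voronoi_codes(shape: tuple[int, int], n_zones: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Nearest-seed (Voronoi) zonation of the lattice, codes 0..n-1."""
    nr, nc = shape
    seeds_r = rng.uniform(0, nr - 1, n_zones)
    seeds_c = rng.uniform(0, nc - 1, n_zones)
    rr, cc = np.mgrid[0:nr, 0:nc]
    d2 = ((rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2)
    return np.argmin(d2, axis=-1).astype(np.int64)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float = 6.0) -> np.ndarray:
    """Smooth standardized random surface (terrain-like)."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (field - field.mean()) / (field.std() + 1e-12)


def make_landscape(scenario: SyntheticScenario,
                   ) -> tuple[LandscapeState, CovariateStack]:
    """Generate the initial state and full covariate stack of a scenario.

    Deterministic given ``scenario.seed``. Raises on grids smaller than
    20x20 and propagates the empty-mask error if a scenario declares no
    road cells.
    """
    if scenario.n_rows < 20 or scenario.n_cols < 20:
        raise GenerationError("synthetic grids must be at least 20x20")
    rng = np.random.default_rng(scenario.seed)
    shape = (scenario.n_rows, scenario.n_cols)
    meta = GridMeta(n_rows=scenario.n_rows, n_cols=scenario.n_cols,
                    cell_size=scenario.cell_size)
    stack = CovariateStack(meta=meta)

    # --- accessibility: roads, rivers, settlements -> distance layers (m)
    n_roads = scenario.n_roads
    if n_roads is None:
        n_roads = max(3, (scenario.n_rows + scenario.n_cols) // 8)
    road_mask = _random_crossing_lines(shape, n_roads, rng)
    stack.add(distance_to_features(road_mask, meta, name="roads"))
    river_mask = _random_crossing_lines(shape, scenario.n_rivers, rng)
    if river_mask.any():
        stack.add(distance_to_features(river_mask, meta, name="rivers"))
    if scenario.n_settlements:
        settle = np.zeros(shape, dtype=bool)
        settle[rng.integers(0, shape[0], scenario.n_settlements),
               rng.integers(0, shape[1], scenario.n_settlements)] = True
        stack.add(distance_to_features(settle, meta, name="settlements"))

    # --- terrain (km) and soil class (ordinal 1..3)
    terrain = 0.6 + 0.4 * _smooth_field(shape, rng)
    stack.add(Layer(meta=meta, values=np.clip(terrain, 0.0, None),
                    name="topography", units="km"))
    soil_field = _smooth_field(shape, rng, sigma=8.0)
    soil = np.digitize(soil_field, [-0.5, 0.5]) + 1
    stack.add(Layer(meta=meta, values=soil.astype(np.int64),
                    name="soil_fertility", units="class"))

    # --- dry season: 12 monthly precipitation surfaces -> month count
    monthly = []
    gradient = np.linspace(0.0, 1.0, shape[1])[None, :] * np.ones(shape)
    for month in range(12):
        seasonal = 180.0 - 130.0 * np.cos(2 * np.pi * (month - 1) / 12.0)
        precip = seasonal - 120.0 * gradient + 15.0 * rng.standard_normal(shape)
        monthly.append(Layer(meta=meta, values=np.clip(precip, 0.0, None),
                             name=f"precip_{month + 1:02d}", units="mm"))
    stack.add(dry_season_length(monthly))

    # --- protected-area blocks (codes 0 none, 1 state, 2 federal, 3 indigenous)
    prot = np.zeros(shape, dtype=np.int64)
    side = max(3, int(scenario.protected_block_frac * min(shape)))
    if side * side * scenario.n_protected_blocks > 0.5 * meta.n_cells:
        raise GenerationError("protected blocks would cover most of the grid")
    for b in range(scenario.n_protected_blocks):
        for _ in range(200):
            r = rng.integers(0, shape[0] - side)
            c = rng.integers(0, shape[1] - side)
            if not prot[r:r + side, c:c + side].any():
                prot[r:r + side, c:c + side] = 1 + (b % 3)
                break
        else:
            raise GenerationError("could not pack protected blocks")
    prot_layer = Layer(meta=meta, values=prot, name="protected_class")
    codes = {0: "none", 1: "state", 2: "federal", 3: "indigenous"}
    for name, layer in encode_categorical(prot_layer, reference_code=0,
                                          codes=codes,
                                          prefix="prot_").items():
        stack.add(layer, name)

    # --- state zonation dummies (reference = largest zone)
    if scenario.n_states > 1:
        zones = _voronoi_codes(shape, scenario.n_states, rng)
        ref = int(np.bincount(zones.ravel()).argmax())
        zone_layer = Layer(meta=meta, values=zones, name="state_code")
        zcodes = {c: str(c) for c in range(scenario.n_states)}
        for name, layer in encode_categorical(zone_layer, reference_code=ref,
                                              codes=zcodes,
                                              prefix="state_").items():
            stack.add(layer, name)

    # --- municipality economics (log-normal, broadcast per Voronoi zone)
    muni = _voronoi_codes(shape, scenario.n_municipalities, rng)
    for name in ("gdp", "gdp_agro", "cattle", "temp_agriculture",
                 "perm_agriculture"):
        per_muni = rng.lognormal(mean=0.0, sigma=0.5,
                                 size=scenario.n_municipalities)
        stack.add(Layer(meta=meta, values=per_muni[muni], name=name,
                        units="index"))

    # --- initial land cover: frontier strip + seeds near roads; water block
    state = np.full(shape, FOREST, dtype=np.int8)
    if scenario.frontier_rows:
        state[-scenario.frontier_rows:, :] = DEFORESTED
    n_seeds = scenario.n_frontier_seeds
    if n_seeds is None:
        n_seeds = meta.n_cells // 200
    if n_seeds:
        road_dist = stack.static_layers["roads"].values
        near_road = np.flatnonzero((road_dist <= 2 * meta.cell_size * 1000.0)
                                   .ravel())
        picks = rng.choice(near_road, size=min(n_seeds, near_road.size),
                           replace=False)
        state.ravel()[picks] = DEFORESTED
    if scenario.excluded_block:
        h, w = max(2, shape[0] // 12), max(2, shape[1] // 12)
        r0, c0 = shape[0] // 6, (2 * shape[1]) // 3
        state[r0:r0 + h, c0:c0 + w] = EXCLUDED

    return LandscapeState(meta=meta, state=state, year=0), stack


def simulate_truth_transition(landscape: LandscapeState,
                              stack: CovariateStack, spec: ModelSpec,
                              true_params: ParameterSet,
                              seed: int = 0) -> TransitionObservation:
    """One ground-truth annual transition drawn from the hazard model."""
    rng = np.random.default_rng(seed)
    after = step_year(landscape, stack, spec, true_params, rng)
    return derive_transition(landscape, after)
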