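"""Covariate engineering on the lattice.

Static covariates (computed once): Euclidean distance to roads, rivers and
settlements in metres; topography in km; dry-season length in months (count
of months with precipitation strictly below 100 mm); soil-fertility class;
protected-area class and state/province dummies; municipality-level economic
values broadcast to member cells.

The model's single dynamic covariate is the neighbourhood deforested
fraction: the proportion of DEFORESTED cells among a focal cell's valid
neighbours (inside the grid, not EXCLUDED) within a Chebyshev radius,
focal cell excluded. It is recomputed from the current landscape every
simulated year and is what makes deforestation contagious.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .landscape import (DEFORESTED, EXCLUDED, AlignmentError, GridMeta,
                        LandscapeState, Layer)
from .model import INTERCEPT, ModelSpec, ModelSpecError

__all__ = [
    "NEIGHBOURHOOD",
    "CovariateStack",
    "Design",
    "distance_to_features",
    "neighbourhood_fraction",
    "dry_season_length",
    "encode_categorical",
    "assemble_design",
]

#: Reserved variable name of the dynamic neighbourhood-fraction covariate.
NEIGHBOURHOOD = "neighbourhood"

#: Dry-season rule: months with precipitation strictly below this (mm).
DRY_MONTH_MM = 100.0


@dataclass
class CovariateStack:
    """Named static layers plus the recipe for the dynamic covariate.

    The dynamic covariate is never stored: :func:`assemble_design`
    recomputes it from whatever LandscapeState it is handed, using
    ``neighbourhood_radius`` (Chebyshev/Moore radius in cells, default 1).
    """

    meta: GridMeta
    static_layers: dict[str, Layer] = field(default_factory=dict)
    neighbourhood_radius: int = 1

    def __post_init__(self) -> None:
        if self.neighbourhood_radius < 1:
            raise ValueError("neighbourhood radius must be >= 1")
        for name, layer in self.static_layers.items():
            if layer.meta != self.meta:
                raise AlignmentError(f"layer {name!r} is on a different grid")

    def add(self, layer: Layer, name: str | None = None) -> None:
        name = name or layer.name
        if layer.meta != self.meta:
            raise AlignmentError(f"layer {name!r} is on a different grid")
        self.static_layers[name] = layer

    def names(self) -> list[str]:
        return list(self.static_layers)

    def __contains__(self, name: str) -> bool:
        return name == NEIGHBOURHOOD or name in self.static_layers

    def resolve(self, name: str, state: LandscapeState) -> np.ndarray:
        """Values of covariate ``name``; the dynamic one comes from state."""
        if name == NEIGHBOURHOOD:
            return neighbourhood_fraction(state, self.neighbourhood_radius).values
        try:
            return self.static_layers[name].values
        except KeyError:
            raise ModelSpecError(f"unknown covariate {name!r}") from None


def distance_to_features(feature_mask: Layer | np.ndarray,
                         meta: GridMeta | None = None,
                         name: str = "distance") -> Layer:
    """Euclidean distance (metres) from each cell centre to the nearest
    feature-cell centre; exactly zero on feature cells.

    Exact (not chamfer) distances via the sampled Euclidean distance
    transform, with the grid's cell size converted km -> m.
    """
    if isinstance(feature_mask, Layer):
        meta = feature_mask.meta
        mask = feature_mask.values.astype(bool)
    else:
        if meta is None:
            raise ValueError("meta required when passing a bare array")
        mask = np.asarray(feature_mask).astype(bool)
    if not mask.any():
        raise ValueError("feature mask is empty: distance undefined")
    step_m = meta.cell_size * 1000.0
    dist = ndimage.distance_transform_edt(~mask, sampling=(step_m, step_m))
    return Layer(meta=meta, values=np.asarray(dist, dtype=np.float64),
                 name=name, units="m")


def neighbourhood_fraction(state: LandscapeState, radius: int = 1) -> Layer:
    """Proportion of DEFORESTED cells among each cell's valid neighbours.

    Valid neighbours are the cells within Chebyshev distance ``radius``
    that lie inside the grid and are not EXCLUDED; the focal cell is not
    its own neighbour. Cells with no valid neighbour get 0.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    kernel = np.ones((size, size), dtype=np.float64)
    deforested = (state.state == DEFORESTED).astype(np.float64)
    valid = (state.state != EXCLUDED).astype(np.float64)
    # Window sums include the focal cell; subtract it afterwards.
    def_count = ndimage.convolve(deforested, kernel, mode="constant", cval=0.0)
    val_count = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    def_count -= deforested
    val_count -= valid
    frac = np.divide(def_count, val_count,
                     out=np.zeros_like(def_count), where=val_count > 0.5)
    # Convolution is float-exact for small integer counts, but guard anyway.
    return Layer(meta=state.meta, values=np.clip(frac, 0.0, 1.0),
                 name=NEIGHBOURHOOD, units="fraction")


def dry_season_length(monthly_precip: list[Layer]) -> Layer:
    """Months per year with precipitation strictly below 100 mm, per cell."""
    if len(monthly_precip) != 12:
        raise ValueError(f"need exactly 12 monthly layers, got {len(monthly_precip)}")
    meta = monthly_precip[0].meta
    for lyr in monthly_precip[1:]:
        if lyr.meta != meta:
            raise AlignmentError("monthly precipitation layers are misaligned")
    stack = np.stack([lyr.values for lyr in monthly_precip])
    months = np.sum(stack < DRY_MONTH_MM, axis=0).astype(np.int64)
    return Layer(meta=meta, values=months, name="dry_season_length",
                 units="months")


def encode_categorical(zone_layer: Layer, reference_code: int,
                       codes: dict[int, str] | None = None,
                       prefix: str = "") -> dict[str, Layer]:
    """Dummy-code a categorical layer against a reference level.

    Returns one 0/1 indicator layer per non-reference code; on any cell at
    most one indicator is 1 (all zero on reference cells). ``codes`` maps
    integer codes to names; by default every code present in the layer is
    enumerated and named by its integer value.
    """
    values = zone_layer.values.astype(np.int64)
    present = set(int(c) for c in np.unique(values))
    if codes is None:
        codes = {c: str(c) for c in sorted(present)}
    unknown = present - set(codes)
    if unknown:
        raise ValueError(f"codes {sorted(unknown)} not in declared enumeration")
    if reference_code not in codes:
        raise ValueError(f"reference code {reference_code} not declared")
    out: dict[str, Layer] = {}
    for code, label in codes.items():
        if code == reference_code:
            continue
        name = f"{prefix}{label}"
        out[name] = Layer(meta=zone_layer.meta,
                          values=(values == code).astype(np.int64),
                          name=name)
    return out


@dataclass
class Design:
    """Design matrix over the FOREST cells of one landscape state.

    ``X`` is (n_forest_cells, n_params) with the intercept first; ``rows``
    maps each row back to its flat cell index in the grid.
    """

    X: np.ndarray
    rows: np.ndarray
    columns: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def assemble_design(stack: CovariateStack, state: LandscapeState,
                    spec: ModelSpec) -> Design:
    """Build the model design matrix over the FOREST cells of ``state``.

    Columns follow ``spec.columns`` (intercept first); the dynamic
    neighbourhood covariate, if listed, is recomputed from ``state`` at
    call time. EXCLUDED and DEFORESTED cells contribute no rows.
    """
    if stack.meta != state.meta:
        raise AlignmentError("stack and state are on different grids")
    fmask = state.forest_mask()
    rows = np.flatnonzero(fmask.ravel())
    X = np.empty((rows.size, spec.n_params), dtype=np.float64)
    X[:, 0] = 1.0
    for j, name in enumerate(spec.variables, start=1):
        X[:, j] = stack.resolve(name, state)[fmask]
    return Design(X=X, rows=rows, columns=spec.columns)
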