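"""Lattice data model and raster I/O.

The simulator works on a planar square lattice of cells (default 5 km on a
side). Every raster layer in an analysis — land-cover state, covariates,
simulation outputs — shares a single :class:`GridMeta`, and all file exchange
goes through the Esri ASCII grid dialect (.asc), the one plain-text raster
format the toolchain reads and writes.

Land cover is categorical per cell: ``FOREST`` cells are at risk of
deforestation, ``DEFORESTED`` cells have already been cleared, and
``EXCLUDED`` lumps together everything outside the modelled population
(non-forest at start, water, out-of-region). Deforestation is absorbing:
no cell ever reverts to forest in any state the simulator produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FOREST",
    "DEFORESTED",
    "EXCLUDED",
    "NEVER",
    "GridMeta",
    "Layer",
    "LandscapeState",
    "TransitionObservation",
    "GridFormatError",
    "AlignmentError",
    "StateConsistencyError",
    "read_ascii_grid",
    "write_ascii_grid",
    "derive_transition",
]

# Cell state codes (int8). EXCLUDED covers non-forest-at-start, water and
# out-of-region cells alike; the model does not distinguish them.
FOREST: int = 0
DEFORESTED: int = 1
EXCLUDED: int = 2

#: Sentinel used in deforestation-year maps for "not deforested".
NEVER: int = -1


class GridFormatError(ValueError):
    """Malformed Esri ASCII grid (bad header key or ragged row)."""


class AlignmentError(ValueError):
    """Two layers that must share a GridMeta do not."""


class StateConsistencyError(ValueError):
    """A land-cover transition violates the no-reversion rule."""


@dataclass(frozen=True)
class GridMeta:
    """Geometry shared by every layer of one analysis.

    ``cell_size`` is in kilometres (the study lattice is 5x5 km);
    ``origin_x``/``origin_y`` are the lower-left corner in arbitrary planar
    map units. Row 0 of every array is the top (northernmost) row, matching
    the Esri ASCII file order.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 5.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def _require_same_meta(a: GridMeta, b: GridMeta) -> None:
    if a != b:
        raise AlignmentError(f"grid metadata mismatch: {a} vs {b}")


@dataclass
class Layer:
    """A single named raster layer on a :class:`GridMeta` lattice.

    ``values`` has shape ``(n_rows, n_cols)``; categorical layers hold
    integer codes, continuous layers floats. Cells equal to
    ``meta.nodata_value`` (or NaN) are treated as nodata.
    """

    meta: GridMeta
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.meta.shape:
            raise AlignmentError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.meta.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        mask = self.values == self.meta.nodata_value
        if np.issubdtype(self.values.dtype, np.floating):
            mask = mask | np.isnan(self.values)
        return mask


@dataclass
class LandscapeState:
    """Per-cell land-cover state at one calendar year."""

    meta: GridMeta
    state: np.ndarray
    year: int

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.shape != self.meta.shape:
            raise AlignmentError(
                f"state shape {self.state.shape} != grid shape {self.meta.shape}"
            )
        valid = np.isin(self.state, (FOREST, DEFORESTED, EXCLUDED))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(f"unknown state code at cell {tuple(bad)}")

    def forest_mask(self) -> np.ndarray:
        return self.state == FOREST

    def n_forest(self) -> int:
        return int(np.count_nonzero(self.state == FOREST))

    def copy(self, year: int | None = None) -> "LandscapeState":
        return LandscapeState(self.meta, self.state.copy(),
                              self.year if year is None else year)


@dataclass
class TransitionObservation:
    """One-year observed transition: the Bernoulli outcomes the model fits.

    ``z`` is an int8 grid: 1 where a cell forest in ``before`` was cleared
    by ``after``, 0 where it stayed forest, and ``NEVER`` (−1) on cells that
    were not forest in ``before`` and therefore carry no outcome.
    """

    before: LandscapeState
    after: LandscapeState
    z: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def outcome_mask(self) -> np.ndarray:
        """Cells carrying an outcome (forest at the start of the interval)."""
        return self.before.state == FOREST

    @property
    def z_values(self) -> np.ndarray:
        """Flat 0/1 outcomes over the cells of :meth:`outcome_mask`."""
        return self.z[self.outcome_mask].astype(np.float64)


def derive_transition(before: LandscapeState,
                      after: LandscapeState) -> TransitionObservation:
    """Derive per-cell binary outcomes from two consecutive annual states.

    Raises :class:`StateConsistencyError` if any cell reverts
    (DEFORESTED or EXCLUDED back to FOREST), and :class:`AlignmentError`
    on a grid or year mismatch.
    """
    _require_same_meta(before.meta, after.meta)
    if after.year != before.year + 1:
        raise AlignmentError(
            f"after.year {after.year} must be before.year+1 ({before.year + 1})"
        )
    reverted = (before.state != FOREST) & (after.state == FOREST)
    if reverted.any():
        idx = tuple(np.argwhere(reverted)[0])
        raise StateConsistencyError(f"cell {idx} reverts to forest")

    z = np.full(before.meta.shape, NEVER, dtype=np.int8)
    fmask = before.state == FOREST
    z[fmask] = (after.state[fmask] == DEFORESTED).astype(np.int8)
    return TransitionObservation(before=before, after=after, z=z)


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, name: str = "") -> Layer:
    """Read an Esri ASCII grid into a :class:`Layer`.

    Header keys ``ncols nrows xllcorner yllcorner cellsize`` are required,
    ``NODATA_value`` optional (default −9999). The body is row-major with
    the top (north) row first, matching the internal array orientation.
    Bodies containing only integer literals come back as an integer array,
    so categorical layers round-trip with their codes intact.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and not _is_number(parts[0]):
            key = parts[0].lower()
            if not _is_number(parts[1]):
                raise GridFormatError(
                    f"{path}: header key {parts[0]!r} has non-numeric value")
            header[key] = float(parts[1])
            i += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"{path}: missing header key {key!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    meta = GridMeta(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata_value=nodata,
    )

    body_lines = [ln for ln in lines[i:] if ln.strip()]
    if len(body_lines) != n_rows:
        raise GridFormatError(
            f"{path}: expected {n_rows} data rows, found {len(body_lines)}")
    tokens: list[list[str]] = []
    for r, ln in enumerate(body_lines):
        row = ln.split()
        if len(row) != n_cols:
            raise GridFormatError(
                f"{path}: row {r} has {len(row)} values, expected {n_cols}")
        tokens.append(row)

    flat = [t for row in tokens for t in row]
    integral = all(_is_int_literal(t) for t in flat)
    dtype = np.int64 if integral else np.float64
    values = np.array(flat, dtype=dtype).reshape(n_rows, n_cols)
    return Layer(meta=meta, values=values, name=name or path.stem)


def write_ascii_grid(layer: Layer, path: str | Path) -> None:
    """Write a :class:`Layer` as an Esri ASCII grid (re-readable verbatim).

    Reals are printed with 10 significant digits; integer layers as plain
    integers; the nodata sentinel is written verbatim.
    """
    path = Path(path)
    meta = layer.meta
    is_int = np.issubdtype(layer.values.dtype, np.integer)
    nodata = meta.nodata_value
    nodata_txt = f"{int(nodata)}" if float(nodata).is_integer() else f"{nodata:.10g}"
    with path.open("w") as fh:
        fh.write(f"ncols {meta.n_cols}\n")
        fh.write(f"nrows {meta.n_rows}\n")
        fh.write(f"xllcorner {meta.origin_x:.10g}\n")
        fh.write(f"yllcorner {meta.origin_y:.10g}\n")
        fh.write(f"cellsize {meta.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata_txt}\n")
        for row in layer.values:
            if is_int:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def state_to_layer(state: LandscapeState, name: str = "state") -> Layer:
    return Layer(meta=state.meta, values=state.state.astype(np.int64), name=name)


def layer_to_state(layer: Layer, year: int) -> LandscapeState:
    return LandscapeState(meta=layer.meta,
                          state=layer.values.astype(np.int8), year=year)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _is_int_literal(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True
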