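"""Covariate layers: distances, neighbourhood fraction, encodings, design."""

import numpy as np
import pytest

from deforsim import (DEFORESTED, EXCLUDED, FOREST, CovariateStack, GridMeta,
                      LandscapeState, Layer, ModelSpec, assemble_design,
                      distance_to_features, dry_season_length,
                      encode_categorical, neighbourhood_fraction)
from deforsim.model import ModelSpecError

from conftest import random_state


def brute_distance(mask: np.ndarray, cell_m: float) -> np.ndarray:
    feats = np.argwhere(mask)
    out = np.empty(mask.shape)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            d2 = ((feats[:, 0] - r) ** 2 + (feats[:, 1] - c) ** 2).min()
            out[r, c] = cell_m * np.sqrt(d2)
    return out


def brute_neighbourhood(state: np.ndarray, radius: int) -> np.ndarray:
    nr, nc = state.shape
    out = np.zeros(state.shape)
    for r in range(nr):
        for c in range(nc):
            n_def = n_valid = 0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nr and 0 <= cc < nc):
                        continue
                    if state[rr, cc] == EXCLUDED:
                        continue
                    n_valid += 1
                    if state[rr, cc] == DEFORESTED:
                        n_def += 1
            out[r, c] = n_def / n_valid if n_valid else 0.0
    return out


class TestDistance:
    def test_zero_on_features_and_one_step(self):
        meta = GridMeta(n_rows=5, n_cols=5, cell_size=5.0)
        mask = np.zeros(meta.shape, dtype=bool)
        mask[2, 2] = True
        dist = distance_to_features(mask, meta).values
        assert dist[2, 2] == 0.0
        assert dist[2, 3] == pytest.approx(5000.0)
        assert dist[3, 3] == pytest.approx(5000.0 * np.sqrt(2))

    def test_matches_brute_force_scan(self, rng):
        meta = GridMeta(n_rows=10, n_cols=10, cell_size=5.0)
        mask = rng.random(meta.shape) < 0.1
        mask[0, 0] = True  # ensure non-empty
        dist = distance_to_features(mask, meta).values
        np.testing.assert_allclose(dist, brute_distance(mask, 5000.0),
                                   rtol=1e-12)

    def test_lipschitz_bound_between_neighbours(self, rng):
        meta = GridMeta(n_rows=30, n_cols=30, cell_size=5.0)
        mask = rng.random(meta.shape) < 0.03
        mask[5, 5] = True
        dist = distance_to_features(mask, meta).values
        step = 5000.0 * np.sqrt(2) + 1e-6
        assert np.all(np.abs(np.diff(dist, axis=0)) <= step)
        assert np.all(np.abs(np.diff(dist, axis=1)) <= step)

    def test_empty_mask_is_an_error(self):
        meta = GridMeta(n_rows=4, n_cols=4)
        with pytest.raises(ValueError, match="empty"):
            distance_to_features(np.zeros(meta.shape, dtype=bool), meta)


class TestNeighbourhoodFraction:
    def test_interior_cell_two_of_eight(self):
        meta = GridMeta(n_rows=3, n_cols=3)
        arr = np.full(meta.shape, FOREST)
        arr[0, 0] = arr[0, 1] = DEFORESTED
        state = LandscapeState(meta, arr, year=0)
        frac = neighbourhood_fraction(state, radius=1).values
        assert frac[1, 1] == pytest.approx(2 / 8)

    def test_corner_cell_normalizes_by_three(self):
        meta = GridMeta(n_rows=3, n_cols=3)
        arr = np.full(meta.shape, DEFORESTED)
        arr[0, 0] = FOREST
        state = LandscapeState(meta, arr, year=0)
        frac = neighbourhood_fraction(state, radius=1).values
        assert frac[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_double_loop_oracle(self, rng, radius):
        meta = GridMeta(n_rows=30, n_cols=30)
        state = random_state(meta, rng)
        frac = neighbourhood_fraction(state, radius=radius).values
        np.testing.assert_allclose(frac,
                                   brute_neighbourhood(state.state, radius),
                                   atol=1e-12)
        assert frac.min() >= 0.0 and frac.max() <= 1.0

    def test_contagion_monotone_in_neighbour_clearing(self, rng):
        meta = GridMeta(n_rows=20, n_cols=20)
        state = random_state(meta, rng, p_def=0.3)
        before = neighbourhood_fraction(state, radius=1).values
        forest = np.argwhere(state.state == FOREST)
        extra = tuple(forest[len(forest) // 2])
        bumped = state.copy()
        bumped.state[extra] = DEFORESTED
        after = neighbourhood_fraction(bumped, radius=1).values
        other = np.ones(meta.shape, dtype=bool)
        other[extra] = False
        assert np.all(after[other] >= before[other] - 1e-12)


class TestDrySeason:
    def _monthly(self, values_mm):
        meta = GridMeta(n_rows=1, n_cols=1)
        return [Layer(meta=meta, values=np.array([[v]], dtype=float))
                for v in values_mm]

    def test_counts_only_strictly_dry_months(self):
        assert dry_season_length(self._monthly([150.0] * 12)).values[0, 0] == 0
        layers = self._monthly([50.0] * 4 + [120.0] * 8)
        assert dry_season_length(layers).values[0, 0] == 4
        # exactly 100 mm is not dry (strict <)
        layers = self._monthly([100.0] * 12)
        assert dry_season_length(layers).values[0, 0] == 0

    def test_requires_twelve_months(self):
        with pytest.raises(ValueError, match="12"):
            dry_season_length(self._monthly([50.0] * 11))


class TestEncodeCategorical:
    def test_protection_classes_give_three_indicators(self, rng):
        meta = GridMeta(n_rows=10, n_cols=10)
        values = rng.integers(0, 4, size=meta.shape)
        layer = Layer(meta=meta, values=values, name="prot")
        codes = {0: "none", 1: "state", 2: "federal", 3: "indigenous"}
        ind = encode_categorical(layer, reference_code=0, codes=codes,
                                 prefix="prot_")
        assert set(ind) == {"prot_state", "prot_federal", "prot_indigenous"}
        total = sum(l.values for l in ind.values())
        assert np.array_equal(total == 0, values == 0)
        assert total.max() <= 1

    def test_all_reference_layer_encodes_to_zeros(self):
        meta = GridMeta(n_rows=4, n_cols=4)
        layer = Layer(meta=meta, values=np.zeros(meta.shape, dtype=int))
        ind = encode_categorical(layer, reference_code=0,
                                 codes={0: "none", 1: "state"})
        assert all(l.values.sum() == 0 for l in ind.values())

    def test_nine_zone_dummies_sum_at_most_one(self, rng):
        meta = GridMeta(n_rows=20, n_cols=20)
        values = rng.integers(0, 9, size=meta.shape)
        ref = int(np.bincount(values.ravel()).argmax())
        ind = encode_categorical(Layer(meta=meta, values=values), ref)
        assert len(ind) == 8
        total = sum(l.values for l in ind.values())
        assert total.max() <= 1

    def test_undeclared_code_rejected(self):
        meta = GridMeta(n_rows=2, n_cols=2)
        layer = Layer(meta=meta, values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="not in declared"):
            encode_categorical(layer, reference_code=0, codes={0: "a", 1: "b"})


class TestAssembleDesign:
    def _toy(self):
        meta = GridMeta(n_rows=3, n_cols=3, cell_size=5.0)
        arr = np.full(meta.shape, FOREST)
        arr[0, 0] = DEFORESTED
        arr[2, 2] = EXCLUDED
        state = LandscapeState(meta, arr, year=0)
        stack = CovariateStack(meta=meta)
        roads = np.arange(9, dtype=float).reshape(3, 3) * 1000.0
        stack.add(Layer(meta=meta, values=roads, name="roads", units="m"))
        return state, stack

    def test_intercept_only_is_all_ones(self):
        state, stack = self._toy()
        design = assemble_design(stack, state, ModelSpec(id="m0"))
        assert design.X.shape == (7, 1)
        assert np.all(design.X == 1.0)

    def test_rows_match_hand_assembly(self):
        state, stack = self._toy()
        spec = ModelSpec(id="m", variables=("roads", "neighbourhood"))
        design = assemble_design(stack, state, spec)
        # forest cells in row-major order, skipping (0,0) and (2,2)
        expected_roads = [1000.0 * k for k in (1, 2, 3, 4, 5, 6, 7)]
        np.testing.assert_allclose(design.X[:, 1], expected_roads)
        # cell (0,1): neighbours (0,0)=DEF among 4 valid ((0,0),(0,2),(1,0),
        # (1,1),(1,2)) -> 5 valid, 1 deforested
        np.testing.assert_allclose(design.X[0, 2], 1 / 5)
        assert np.all(design.X[:, 0] == 1.0)

    def test_row_count_equals_forest_count(self, scene40):
        state, stack = scene40
        spec = ModelSpec(id="m", variables=("roads", "neighbourhood"))
        design = assemble_design(stack, state, spec)
        assert design.n_rows == state.n_forest()

    def test_unknown_variable_rejected(self):
        state, stack = self._toy()
        with pytest.raises(ModelSpecError, match="nope"):
            assemble_design(stack, state, ModelSpec(id="m", variables=("nope",)))
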