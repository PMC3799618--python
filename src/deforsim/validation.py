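"""Comparing simulated and observed change maps.

Three families of agreement statistics, computed annually (predicted vs
observed clearing within one year) or cumulatively (all clearing up to each
horizon year):

* ROC-AUC of a clearing-probability surface against the observed binary
  outcomes over evaluable cells (forest at the start of the period) — the
  rank/Mann–Whitney formulation, ties counting one half.
* Pixel-wise fractions: perfect match |pred ∩ obs| / |obs|, omission
  |obs \\ pred| / |obs| (so perfect_match + omission = 1), and commission
  |pred \\ obs| / |pred|.
* Distance-band agreement: the fraction of observed-cleared cells lying
  within {0, 5, 10, 25, 50} km of any predicted-cleared cell (0 km means
  exact-cell agreement).

Per-iteration metrics are summarised as mean and range across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .landscape import (DEFORESTED, FOREST, NEVER, AlignmentError,
                        LandscapeState, Layer)
from .simulator import SimulationEnsemble

__all__ = [
    "DISTANCE_BANDS_KM",
    "UndefinedMetricError",
    "PixelMetrics",
    "roc_auc",
    "pixel_metrics",
    "distance_band_agreement",
    "cumulative_series",
    "annual_series",
]

#: Default distance thresholds (km) for band agreement.
DISTANCE_BANDS_KM: tuple[float, ...] = (0.0, 5.0, 10.0, 25.0, 50.0)


class UndefinedMetricError(ValueError):
    """Metric undefined (single-class observations or empty prediction)."""


def _as_values(layer: Layer | np.ndarray) -> np.ndarray:
    return layer.values if isinstance(layer, Layer) else np.asarray(layer)


def roc_auc(prob: Layer | np.ndarray, observed: Layer | np.ndarray,
            valid: np.ndarray | None = None) -> float:
    """Rank-based AUC of a probability surface against binary outcomes.

    ``valid`` restricts the population to evaluable cells (forest at the
    start of the period); ties in ``prob`` contribute one half, so any
    strictly monotone transform of the surface leaves the AUC unchanged.
    """
    p = _as_values(prob).ravel()
    obs = _as_values(observed).astype(bool).ravel()
    if valid is not None:
        keep = np.asarray(valid).astype(bool).ravel()
        p, obs = p[keep], obs[keep]
    if obs.all() or not obs.any():
        raise UndefinedMetricError(
            "AUC undefined: only one outcome class among evaluable cells")
    return float(roc_auc_score(obs.astype(int), p))


@dataclass(frozen=True)
class PixelMetrics:
    """Pixel-wise agreement fractions; NaN marks an empty denominator."""

    perfect_match: float
    omission: float
    commission: float


def pixel_metrics(predicted: Layer | np.ndarray,
                  observed: Layer | np.ndarray,
                  valid: np.ndarray | None = None) -> PixelMetrics:
    """Pixel-by-pixel precision of a binary prediction.

    perfect_match and omission share the observed-event denominator (they
    sum to 1 whenever any event was observed); commission is over
    predicted events.
    """
    if (isinstance(predicted, Layer) and isinstance(observed, Layer)
            and predicted.meta != observed.meta):
        raise AlignmentError("predicted and observed are on different grids")
    pred = _as_values(predicted).astype(bool)
    obs = _as_values(observed).astype(bool)
    if pred.shape != obs.shape:
        raise AlignmentError("predicted and observed shapes differ")
    if valid is not None:
        keep = np.asarray(valid).astype(bool)
        pred = pred & keep
        obs = obs & keep
    n_obs = int(obs.sum())
    n_pred = int(pred.sum())
    hit = int((pred & obs).sum())
    pm = hit / n_obs if n_obs else float("nan")
    om = (n_obs - hit) / n_obs if n_obs else float("nan")
    co = (n_pred - hit) / n_pred if n_pred else float("nan")
    return PixelMetrics(perfect_match=pm, omission=om, commission=co)


def distance_band_agreement(observed: Layer | np.ndarray,
                            predicted: Layer | np.ndarray,
                            cell_size_km: float | None = None,
                            thresholds: Sequence[float] = DISTANCE_BANDS_KM,
                            ) -> dict[float, float]:
    """Fraction of observed-cleared cells within d km of predicted clearing.

    Distances are centre-to-centre Euclidean; d = 0 therefore means the
    exact cell was predicted. Raises if the predicted set is empty.
    """
    if isinstance(observed, Layer) and cell_size_km is None:
        cell_size_km = observed.meta.cell_size
    if cell_size_km is None:
        raise ValueError("cell_size_km required with bare arrays")
    obs = _as_values(observed).astype(bool)
    pred = _as_values(predicted).astype(bool)
    if not pred.any():
        raise UndefinedMetricError("no predicted clearing: bands undefined")
    dist = ndimage.distance_transform_edt(
        ~pred, sampling=(cell_size_km, cell_size_km))
    obs_dist = dist[obs]
    out: dict[float, float] = {}
    for d in thresholds:
        if obs_dist.size == 0:
            out[float(d)] = float("nan")
        else:
            out[float(d)] = float(np.mean(obs_dist <= d + 1e-9))
    return out


def _observed_annual(observed_states: Sequence[LandscapeState],
                     years: Sequence[int]) -> dict[int, np.ndarray]:
    """Observed clearing mask per year from consecutive annual states."""
    by_year = {s.year: s for s in observed_states}
    out = {}
    for year in years:
        if year not in by_year or year - 1 not in by_year:
            raise ValueError(f"missing observed state for year {year}")
        before, after = by_year[year - 1], by_year[year]
        out[year] = (before.state == FOREST) & (after.state == DEFORESTED)
    return out


def annual_series(ensemble: SimulationEnsemble,
                  observed_states: Sequence[LandscapeState],
                  years: Sequence[int] | None = None,
                  thresholds: Sequence[float] = DISTANCE_BANDS_KM,
                  ) -> pd.DataFrame:
    """Annual validation: each simulated year against the observed year."""
    return _series(ensemble, observed_states, years, thresholds,
                   cumulative=False)


def cumulative_series(ensemble: SimulationEnsemble,
                      observed_states: Sequence[LandscapeState],
                      years: Sequence[int] | None = None,
                      thresholds: Sequence[float] = DISTANCE_BANDS_KM,
                      ) -> pd.DataFrame:
    """Cumulative validation: clearing unions up to each horizon year."""
    return _series(ensemble, observed_states, years, thresholds,
                   cumulative=True)


def _series(ensemble: SimulationEnsemble,
            observed_states: Sequence[LandscapeState],
            years: Sequence[int] | None,
            thresholds: Sequence[float],
            cumulative: bool) -> pd.DataFrame:
    """Per-iteration metrics for each year, then mean/min/max across
    iterations. AUC uses each iteration's annual probability surface when
    the ensemble recorded them, otherwise the ensemble probability map."""
    if years is None:
        years = [s.year for s in observed_states
                 if s.year in set(ensemble.years)]
    years = sorted(years)
    if not years:
        raise ValueError("no overlapping years to validate")
    obs_annual = _observed_annual(observed_states, years)
    by_year = {s.year: s for s in observed_states}
    meta = ensemble.initial.meta
    n_iter = ensemble.n_iterations
    ym = ensemble.year_maps
    cleared = ym != NEVER
    year_index = {y: t for t, y in enumerate(ensemble.years)}

    records = []
    obs_cum = np.zeros(meta.shape, dtype=bool)
    for year in years:
        obs_mask = obs_annual[year]
        obs_cum = obs_cum | obs_mask
        obs_eval = obs_cum if cumulative else obs_mask
        # evaluable population: forest at the start of the period
        start_year = years[0] - 1 if cumulative else year - 1
        valid = by_year[start_year].state == FOREST

        if cumulative:
            pred_masks = cleared & (ym <= year)
        else:
            pred_masks = ym == year
        ens_prob = pred_masks.sum(axis=0) / n_iter

        for i in range(n_iter):
            pm = pixel_metrics(pred_masks[i], obs_eval, valid=valid)
            try:
                bands = distance_band_agreement(
                    obs_eval & valid, pred_masks[i] & valid,
                    cell_size_km=meta.cell_size, thresholds=thresholds)
            except UndefinedMetricError:
                bands = {float(d): float("nan") for d in thresholds}
            if ensemble.prob_stacks is not None and not cumulative:
                surface = ensemble.prob_stacks[i][year_index[year]]
            else:
                surface = ens_prob
            try:
                auc = roc_auc(surface, obs_eval, valid=valid)
            except UndefinedMetricError:
                auc = float("nan")
            rec = {
                "year": year,
                "mode": "cumulative" if cumulative else "annual",
                "iteration": i,
                "auc": auc,
                "perfect_match": pm.perfect_match,
                "omission": pm.omission,
                "commission": pm.commission,
            }
            for d, v in bands.items():
                rec[f"within_{d:g}km"] = v
            records.append(rec)
    per_iter = pd.DataFrame.from_records(records)
    return per_iter


def summarize_report(per_iter: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of each metric across iterations, per year and mode."""
    metrics = [c for c in per_iter.columns
               if c not in ("year", "mode", "iteration")]
    grouped = per_iter.groupby(["year", "mode"])[metrics]
    out = grouped.agg(["mean", "min", "max"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
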