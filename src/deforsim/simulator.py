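"""Stochastic annual forward simulation with parameter uncertainty.

Each ensemble iteration draws one coefficient vector from independent
Gaussians (posterior mean and sd per coefficient) and then advances the
landscape year by year: the dynamic neighbourhood covariate is recomputed
from the start-of-year state, every forest cell gets its clearing
probability from the logistic hazard, and independent uniform draws decide
which cells clear — a synchronous update, so within a year cells do not see
each other's clearing. Deforestation is absorbing.

Because events feed back into next year's neighbourhood fractions, clearing
is contagious and spreads as a front; the regional annual rate is emergent,
simply the realised fraction of start-of-year forest cells cleared.

Ensembles (default 100 iterations) summarise to per-year cumulative clearing
probability maps, a median clearing-year map, an inter-quartile-range map
(timing uncertainty, in years), and per-year rate box statistics. Quantiles
over iteration years use midpoint interpolation (integer years; four
iterations clearing a cell in 2005/2007/2009/2011 give median 2008 and
IQR 2010 − 2006 = 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack, assemble_design
from .landscape import DEFORESTED, NEVER, LandscapeState, Layer
from .model import (ModelSpec, ParameterPosterior, ParameterSet,
                    defor_probability)

__all__ = [
    "SimulationConfig",
    "IterationResult",
    "SimulationEnsemble",
    "SummaryMaps",
    "draw_parameters",
    "step_year",
    "run_iteration",
    "run_ensemble",
    "summarize",
]


@dataclass
class SimulationConfig:
    """Knobs of one forward-simulation experiment."""

    start_year: int
    end_year: int = 2050
    n_iterations: int = 100
    neighbourhood_radius: int = 1
    seed: int = 0
    #: Draw one parameter vector per iteration (default) or hold the
    #: posterior means fixed throughout.
    draw_parameters_per_iteration: bool = True
    #: Redraw the parameter vector every simulated year instead of once per
    #: iteration.
    redraw_each_year: bool = False
    #: Keep each iteration's annual probability surfaces (memory-heavy;
    #: needed for per-iteration ROC validation).
    record_probabilities: bool = False

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def years(self) -> list[int]:
        """Calendar years at which new state is produced (start+1 .. end)."""
        return list(range(self.start_year + 1, self.end_year + 1))


def draw_parameters(posterior: ParameterPosterior,
                    rng: np.random.Generator) -> ParameterSet:
    """One independent Gaussian draw per coefficient (mean, sd)."""
    return ParameterSet(rng.normal(posterior.mean, posterior.sd))


def step_year(state: LandscapeState, stack: CovariateStack, spec: ModelSpec,
              params: ParameterSet, rng: np.random.Generator,
              return_probabilities: bool = False):
    """Advance the landscape by one year (synchronous Bernoulli update).

    All clearing probabilities are computed from the start-of-year state
    (the dynamic neighbourhood layer recomputed once), then each forest
    cell clears independently with its own probability. Returns the new
    state (year + 1), optionally with the flat probability vector and the
    forest-row indices it applies to.
    """
    design = assemble_design(stack, state, spec)
    p = np.asarray(defor_probability(design.X @ params.values))
    u = rng.random(p.size)
    cleared_rows = design.rows[u < p]
    new = state.copy(year=state.year + 1)
    new.state.ravel()[cleared_rows] = DEFORESTED
    if return_probabilities:
        return new, p, design.rows
    return new


@dataclass
class IterationResult:
    """One stochastic future: per-cell clearing year and annual rates."""

    year_map: np.ndarray  # int16 grid; NEVER where not cleared in-run
    rates: np.ndarray  # fraction of start-of-year forest cleared, per year
    years: list[int]
    prob_stack: np.ndarray | None = field(default=None, repr=False)


def run_iteration(initial: LandscapeState, stack: CovariateStack,
                  spec: ModelSpec, posterior: ParameterPosterior,
                  config: SimulationConfig,
                  rng: np.random.Generator) -> IterationResult:
    """Run one iteration from start_year to end_year.

    The parameter vector is drawn once and held fixed across the
    iteration's years (redrawn annually if ``config.redraw_each_year``).
    Records the first — necessarily only — clearing year of each cell and
    the emergent annual rate series.
    """
    if stack.neighbourhood_radius != config.neighbourhood_radius:
        stack = CovariateStack(meta=stack.meta,
                               static_layers=stack.static_layers,
                               neighbourhood_radius=config.neighbourhood_radius)
    if config.draw_parameters_per_iteration:
        params = draw_parameters(posterior, rng)
    else:
        params = posterior.mean_parameters()
    year_map = np.full(initial.meta.shape, NEVER, dtype=np.int16)
    years = config.years
    rates = np.zeros(len(years))
    probs = (np.zeros((len(years),) + initial.meta.shape, dtype=np.float32)
             if config.record_probabilities else None)

    state = initial
    for t, year in enumerate(years):
        if config.redraw_each_year and config.draw_parameters_per_iteration:
            params = draw_parameters(posterior, rng)
        n_forest = state.n_forest()
        out = step_year(state, stack, spec, params, rng,
                        return_probabilities=config.record_probabilities)
        if config.record_probabilities:
            new, p, rows = out
            probs[t].ravel()[rows] = p
        else:
            new = out
        cleared = (state.state != new.state)
        year_map[cleared] = year
        rates[t] = cleared.sum() / n_forest if n_forest else 0.0
        state = new
    return IterationResult(year_map=year_map, rates=rates, years=years,
                           prob_stack=probs)


@dataclass
class SimulationEnsemble:
    """Stacked iteration results (N iterations of the same experiment)."""

    year_maps: np.ndarray  # (N, rows, cols) int16, NEVER where never cleared
    rates: np.ndarray  # (N, n_years)
    years: list[int]
    initial: LandscapeState
    prob_stacks: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_iterations(self) -> int:
        return self.year_maps.shape[0]


def run_ensemble(initial: LandscapeState, stack: CovariateStack,
                 spec: ModelSpec, posterior: ParameterPosterior,
                 config: SimulationConfig) -> SimulationEnsemble:
    """Independent iterations with seeds derived from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_iterations)
    year_maps = np.empty((config.n_iterations,) + initial.meta.shape,
                         dtype=np.int16)
    rates = np.empty((config.n_iterations, len(config.years)))
    prob_stacks = [] if config.record_probabilities else None
    for i, child in enumerate(children):
        res = run_iteration(initial, stack, spec, posterior, config,
                            np.random.default_rng(child))
        year_maps[i] = res.year_map
        rates[i] = res.rates
        if prob_stacks is not None:
            prob_stacks.append(res.prob_stack)
    return SimulationEnsemble(year_maps=year_maps, rates=rates,
                              years=config.years, initial=initial,
                              prob_stacks=prob_stacks)


@dataclass
class SummaryMaps:
    """Ensemble summaries: probability, timing, and timing uncertainty."""

    cumulative_probability: dict[int, Layer]  # year -> P(cleared by year)
    median_year: Layer  # NaN where cleared in <= 50% of iterations
    iqr_years: Layer  # NaN likewise
    rate_stats: pd.DataFrame  # per year: median, q25, q75, min, max


def summarize(ensemble: SimulationEnsemble) -> SummaryMaps:
    """Reduce an ensemble to its probability/timing/uncertainty summaries.

    Cumulative probability in year y = fraction of iterations in which the
    cell is cleared by y (monotone non-decreasing in y per cell). Median
    clearing year and IQR are midpoint quantiles over the iterations in
    which the cell cleared, reported only for cells cleared in more than
    half the iterations (NaN elsewhere).
    """
    meta = ensemble.initial.meta
    ym = ensemble.year_maps
    n = ensemble.n_iterations
    cleared = ym != NEVER

    cum = {}
    for year in ensemble.years:
        frac = np.count_nonzero(cleared & (ym <= year), axis=0) / n
        cum[year] = Layer(meta=meta, values=frac,
                          name=f"cumulative_probability_{year}",
                          units="probability")

    n_cleared = cleared.sum(axis=0)
    median = np.full(meta.shape, np.nan)
    iqr = np.full(meta.shape, np.nan)
    majority = n_cleared > n / 2
    rr, cc = np.nonzero(majority)
    for r, c in zip(rr, cc):
        yrs = ym[:, r, c][cleared[:, r, c]].astype(np.float64)
        q25, q50, q75 = np.percentile(yrs, [25, 50, 75], method="midpoint")
        median[r, c] = q50
        iqr[r, c] = q75 - q25

    q25, q50, q75 = np.percentile(ensemble.rates, [25, 50, 75],
                                  axis=0, method="midpoint")
    rate_stats = pd.DataFrame({
        "year": ensemble.years,
        "median": q50,
        "q25": q25,
        "q75": q75,
        "min": ensemble.rates.min(axis=0),
        "max": ensemble.rates.max(axis=0),
    })
    return SummaryMaps(
        cumulative_probability=cum,
        median_year=Layer(meta=meta, values=median, name="median_year",
                          units="year"),
        iqr_years=Layer(meta=meta, values=iqr, name="iqr_years",
                        units="years"),
        rate_stats=rate_stats,
    )
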