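"""Posterior estimation and model selection.

Coefficients are estimated by component-wise Metropolis–Hastings under
broad flat priors (uniform on [-50, 50] per coefficient), with per-component
proposal widths adapted during burn-in only and frozen afterwards. Retained
samples summarise to a per-coefficient mean, sd and 2.5/97.5 percentile
credible interval.

Model selection is forward stepwise under 50/50 cross-validation: one fixed
random split of the forest cells into train and test halves is reused for
every candidate model so test likelihoods are comparable. Step 0 fits the
intercept-only model; each later step tries every remaining single-variable
addition, fitted on the train half and scored by the Bernoulli likelihood of
the held-out half, and keeps the addition with the highest test likelihood
until the candidate pool is exhausted (14 candidates => 106 fitted models).
The chosen model is the global test-likelihood maximum, demoted down the
ranking past any model containing a coefficient whose 95% credible interval
spans zero.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .covariates import CovariateStack, assemble_design
from .landscape import LandscapeState, TransitionObservation
from .model import (INTERCEPT, ModelSpec, ModelSpecError, ParameterPosterior,
                    ParameterSet, log_likelihood)

__all__ = [
    "DegenerateDataError",
    "PRIOR_BOUND",
    "mcmc_fit",
    "split_locations",
    "forward_stepwise",
    "prune_nonsignificant",
    "StepwiseRow",
    "StepwiseTable",
    "SelectionResult",
]

#: Half-width of the flat prior box on every coefficient.
PRIOR_BOUND = 50.0

#: Default chain lengths (sweeps over all components).
DEFAULT_BURN = 10_000
DEFAULT_SAMPLES = 10_000


class DegenerateDataError(ValueError):
    """Outcomes are all 0 or all 1; the intercept is unbounded."""


@njit(cache=True, fastmath=True)
def _bernoulli_ll(k, z):
    """Stable sum of z*k - log(1 + e^k) over cells."""
    total = 0.0
    for i in range(k.size):
        ki = k[i]
        total += z[i] * ki
        if ki > 0.0:
            total -= ki + np.log1p(np.exp(-ki))
        else:
            total -= np.log1p(np.exp(ki))
    return total


@njit(cache=True)
def _mh_chain(X, z, n_burn, n_samples, seed, bound, init_widths):
    """Component-wise adaptive Metropolis–Hastings for the logistic hazard.

    One sweep proposes each coefficient in turn; the linear predictor is
    updated incrementally so a proposal costs O(n). Widths adapt
    multiplicatively during burn-in (grow on accept, shrink on reject,
    equilibrating near ~1/3 acceptance) and are frozen afterwards.
    """
    np.random.seed(seed)
    n, p = X.shape
    theta = np.zeros(p)
    widths = init_widths.copy()
    k = np.zeros(n)  # linear predictor at theta = 0
    ll = _bernoulli_ll(k, z)
    samples = np.empty((n_samples, p))
    total = n_burn + n_samples
    for it in range(total):
        adapting = it < n_burn
        for j in range(p):
            delta = widths[j] * np.random.normal()
            prop = theta[j] + delta
            if prop < -bound or prop > bound:
                accepted = False
            else:
                k_new = k + delta * X[:, j]
                ll_new = _bernoulli_ll(k_new, z)
                if ll_new >= ll or np.random.random() < np.exp(ll_new - ll):
                    theta[j] = prop
                    k = k_new
                    ll = ll_new
                    accepted = True
                else:
                    accepted = False
            if adapting:
                if accepted:
                    widths[j] *= 1.05
                else:
                    widths[j] *= 0.976
                if widths[j] < 1e-12:
                    widths[j] = 1e-12
                elif widths[j] > bound:
                    widths[j] = bound
        if it >= n_burn:
            samples[it - n_burn] = theta
    return samples


def _initial_widths(X: np.ndarray) -> np.ndarray:
    """Start proposal widths at ~1/scale of each column so adaptation has
    little work to do even for covariates in metres (coefficients ~1e-4)."""
    scale = np.maximum(np.abs(X).mean(axis=0), 1e-12)
    return np.minimum(1.0 / scale, PRIOR_BOUND)


def mcmc_fit(spec: ModelSpec, design: np.ndarray, z: np.ndarray,
             n_burn: int = DEFAULT_BURN, n_samples: int = DEFAULT_SAMPLES,
             seed: int = 0, keep_samples: bool = True) -> ParameterPosterior:
    """Fit one model by MCMC and summarise its posterior.

    ``design`` must have ``spec.n_params`` columns (intercept first) and
    align row-wise with the 0/1 outcomes ``z``. Deterministic given
    ``seed``. Raises :class:`DegenerateDataError` unless both outcome
    classes are present.
    """
    X = np.ascontiguousarray(np.asarray(design, dtype=np.float64))
    zz = np.ascontiguousarray(np.asarray(z, dtype=np.float64).ravel())
    if X.ndim != 2 or X.shape[1] != spec.n_params:
        raise ModelSpecError(
            f"design has {X.shape[-1]} columns, spec {spec.id!r} expects "
            f"{spec.n_params}")
    if X.shape[0] != zz.size:
        raise ModelSpecError("design rows and outcomes are misaligned")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ones = zz.sum()
    if ones == 0 or ones == zz.size:
        raise DegenerateDataError(
            "outcomes are single-class; the model is not identifiable")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")

    samples = _mh_chain(X, zz, int(n_burn), int(n_samples),
                        int(seed) & 0x7FFFFFFF, PRIOR_BOUND,
                        _initial_widths(X))
    lower, upper = np.percentile(samples, [2.5, 97.5], axis=0)
    return ParameterPosterior(
        names=spec.columns,
        mean=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=1),
        lower=lower,
        upper=upper,
        samples=samples if keep_samples else None,
    )


def split_locations(n_cells: int, fraction: float = 0.5,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/test split of cell row indices."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    n_train = int(round(fraction * n_cells))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class StepwiseRow:
    """One fitted model in the stepwise enumeration."""

    model_id: str
    variables: tuple[str, ...]
    train_ll: float
    test_ll: float
    significant: tuple[bool, ...]  # per non-intercept coefficient
    posterior: ParameterPosterior = field(repr=False, default=None)  # type: ignore[assignment]
    selected: bool = False

    @property
    def all_significant(self) -> bool:
        return all(self.significant)


@dataclass
class StepwiseTable:
    """Every model fitted during forward stepwise selection."""

    rows: list[StepwiseRow]
    train_index: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    test_index: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_models(self) -> int:
        return len(self.rows)

    @property
    def best(self) -> StepwiseRow:
        return max(self.rows, key=lambda r: r.test_ll)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model_id": [r.model_id for r in self.rows],
            "variables": ["+".join(r.variables) for r in self.rows],
            "n_params": [1 + len(r.variables) for r in self.rows],
            "train_ll": [r.train_ll for r in self.rows],
            "test_ll": [r.test_ll for r in self.rows],
            "all_significant": [r.all_significant for r in self.rows],
            "selected": [r.selected for r in self.rows],
        })


def forward_stepwise(candidates: list[str], stack: CovariateStack,
                     transition: TransitionObservation, seed: int = 0,
                     n_burn: int = 2000, n_samples: int = 2000,
                     fraction: float = 0.5) -> StepwiseTable:
    """Forward stepwise enumeration under fixed 50/50 cross-validation.

    Fits ``1 + m + (m-1) + ... + 1`` models for ``m`` candidates (106 for
    m = 14). All fits share one random split and derive their chain seeds
    deterministically from ``seed``.
    """
    if not candidates:
        raise ValueError("need at least one candidate variable")
    for name in candidates:
        if name not in stack:
            raise ModelSpecError(f"candidate {name!r} not in covariate stack")

    state = transition.before
    full_spec = ModelSpec(id="pool", variables=tuple(candidates))
    design = assemble_design(stack, state, full_spec)
    z = transition.z_values
    col_of = {name: j for j, name in enumerate(design.columns)}

    train, test = split_locations(design.n_rows, fraction=fraction,
                                  seed=int(seed))

    rows: list[StepwiseRow] = []

    def fit(variables: tuple[str, ...]) -> StepwiseRow:
        spec = ModelSpec(id="+".join((INTERCEPT,) + variables),
                         variables=variables)
        cols = [0] + [col_of[v] for v in variables]
        X = design.X[:, cols]
        # chain seed depends on (seed, variable set), not enumeration order,
        # so the table is invariant to candidate ordering
        key = f"{seed}:{'+'.join(sorted(variables))}".encode()
        fit_seed = int(zlib.crc32(key)) & 0x7FFFFFFF
        post = mcmc_fit(spec, X[train], z[train], n_burn=n_burn,
                        n_samples=n_samples, seed=fit_seed,
                        keep_samples=False)
        params = post.mean_parameters()
        row = StepwiseRow(
            model_id=spec.id,
            variables=variables,
            train_ll=log_likelihood(params, X[train], z[train]),
            test_ll=log_likelihood(params, X[test], z[test]),
            significant=tuple(bool(s) for s in post.significant()[1:]),
            posterior=post,
        )
        rows.append(row)
        return row

    fit(())  # step 0: intercept only
    included: tuple[str, ...] = ()
    remaining = list(candidates)
    while remaining:
        step_rows = [fit(included + (name,)) for name in remaining]
        best = max(step_rows, key=lambda r: r.test_ll)
        included = best.variables
        remaining.remove(best.variables[-1])

    table = StepwiseTable(rows=rows, train_index=train, test_index=test)
    table.best.selected = True
    return table


@dataclass
class SelectionResult:
    """Outcome of significance pruning over a stepwise table."""

    spec: ModelSpec
    row: StepwiseRow | None
    fallback_warning: bool = False


def prune_nonsignificant(table: StepwiseTable) -> SelectionResult:
    """Select the best cross-validated model with all coefficients significant.

    Walks the test-likelihood ranking downwards until every non-intercept
    coefficient's 95% credible interval excludes zero; if no such model
    exists (or nothing beats intercept-only), returns intercept-only with a
    warning flag.
    """
    if not table.rows:
        raise ValueError("empty stepwise table")
    intercept_row = next(r for r in table.rows if not r.variables)
    ranked = sorted(table.rows, key=lambda r: r.test_ll, reverse=True)
    for row in ranked:
        if not row.variables:
            break  # reached intercept-only: nothing better is significant
        if row.all_significant and row.test_ll >= intercept_row.test_ll:
            return SelectionResult(
                spec=ModelSpec(id=row.model_id, variables=row.variables),
                row=row)
    return SelectionResult(spec=ModelSpec(id=INTERCEPT, variables=()),
                           row=intercept_row, fallback_warning=True)
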