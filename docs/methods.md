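# Methods

## Model

The unit of analysis is a cell of a planar square lattice (default 5 km
side; distances are computed in map units from the cell size, with no
geodesy). Land cover is categorical — FOREST, DEFORESTED, EXCLUDED — and
clearing is absorbing: no state produced by the simulator ever reverts a
cell to forest, so the forest count is non-increasing along any simulated
trajectory. EXCLUDED covers non-forest-at-start, water and out-of-region
cells uniformly; the model never distinguishes them.

A forest cell's annual clearing probability is the standard logistic
`P = 1/(1+e^{−k})` of a linear predictor `k = θ·c` with the intercept always
first. The likelihood of a one-year transition is the independent-Bernoulli
(logistic-regression) log-likelihood over cells that were forest at the
start of the interval; probabilities are clipped to `[1e−12, 1−1e−12]`
before the logs so extreme parameter draws cannot produce −∞.

Assumptions worth keeping in mind: outcomes are conditionally independent
given the covariates (no spatial random effects); all covariates except the
neighbourhood fraction are frozen over the simulation horizon (roads and the
economy do not grow); and the link is exactly the standard logistic — the
alternative of a scaled sigmoid is excluded by the requirement that P spans
(0,1) monotonically in k.

## Covariates

* Distances (roads, rivers, settlements) are exact Euclidean
  centre-to-centre distances in **metres**, via the sampled distance
  transform. Topography is in **km**. The unit split matters because the
  published coefficient magnitudes differ by four orders of magnitude
  between road distance and altitude; units are recorded on each layer.
* Dry-season length is the count of months with precipitation **strictly**
  below 100 mm, computed from twelve aligned monthly layers.
* Categorical layers (protected-area class, state) are dummy-coded against
  a reference level (unprotected; the largest state).
* The single dynamic covariate is the deforested fraction among a cell's
  valid neighbours within Chebyshev radius 1 (the Moore 8-neighbourhood),
  focal cell excluded, edge and EXCLUDED-adjacent cells normalised by their
  actual valid-neighbour count, cells with no valid neighbour scoring 0.
  The radius is configurable; 1 is the default because it is the smallest
  window consistent with a neighbourhood *proportion* and produces the
  front-like spread the contagion mechanism is meant to capture.
* No automatic standardisation: the published coefficient sets are on raw
  scales, so design columns are raw by default. Economic covariates are
  accepted as per-cell layers (municipality values broadcast to member
  cells); whether they enter as levels or annual changes is the caller's
  modelling decision, not hard-coded.

## Estimation

Posteriors come from component-wise Metropolis–Hastings with flat priors on
[−50, 50] per coefficient. The chain starts at θ = 0 (inside the prior,
finite likelihood), and each component's Gaussian proposal width adapts
multiplicatively during burn-in only (×1.05 on accept, ×0.976 on reject,
equilibrating near one-third acceptance), starting at the reciprocal of the
column's mean absolute value so metre-scale covariates begin near the right
scale. Widths freeze after burn-in, so the retained chain is a valid
Metropolis sample. Default chain lengths are 10 000 burn-in + 10 000
retained sweeps; the test suite and the acceptance script use shorter chains
(300–3 000 sweeps) matched to their smaller designs. The linear predictor is
updated incrementally (a proposal costs O(n)), with the sweep kernel
compiled by numba. Summaries are the retained samples' mean, sd and
2.5/97.5 percentiles; "significant" means the 95% interval excludes zero.
Single-class outcomes raise a degenerate-data error rather than returning a
prior-shaped posterior.

## Selection

Forward stepwise under 50/50 cross-validation: one random split of forest
cells is drawn once and reused for every model so held-out likelihoods are
comparable. Step 0 is intercept-only; each step fits every remaining
single-variable addition on the train half (by MCMC) and scores the
held-out half at the posterior mean; the best addition is kept; the process
runs to exhaustion (m candidates ⇒ 1 + m(m+1)/2 models; 14 ⇒ 106). Each
model's chain seed is derived from its *variable set*, not its enumeration
position, which makes the whole table invariant to candidate ordering.
The selected model is the global test-likelihood maximum, demoted down the
ranking past any model containing a non-significant coefficient; if nothing
clean beats intercept-only, intercept-only is returned with a warning flag.
Information-criterion selection is deliberately not offered.

## Simulation

Each ensemble iteration draws one coefficient vector from independent
Gaussians (posterior mean, sd) and holds it fixed across its years —
parameter uncertainty varies *between* iterations, process noise within
them. (A flag enables per-year redraws; another disables drawing entirely.)
Posterior correlations are ignored by construction of the draw. Years
advance synchronously: all probabilities are computed from the start-of-year
state with the neighbourhood layer recomputed once, then independent uniform
draws clear cells. Per-iteration records are the (unique) clearing year per
cell and the emergent annual rate — cleared cells over start-of-year forest
cells.

Summaries over N iterations (default 100): cumulative probability per year
(fraction of iterations in which the cell is cleared by then — monotone in
year by construction); the median clearing year and inter-quartile range
over the iterations in which the cell cleared, reported only where the cell
cleared in more than half of the iterations; and per-year rate box
statistics. Quantiles over iteration years use **midpoint interpolation**:
clearing years {2005, 2007, 2009, 2011} give median 2008 and IQR
2010 − 2006 = 4. Midpoint is the package's fixed rule because it treats the
even-count integer-year case symmetrically; medians can therefore fall on
half-years. The timing map uses the median (the mean is available).

## Validation

Evaluable cells are those forest at the start of the compared period —
clearing probability is only defined for forest. Pixel-wise denominators
are chosen so that perfect match and omission share the observed-event
denominator (they sum to 1 whenever anything was observed) and commission
is over predicted events. Distance-band agreement is the fraction of
observed-cleared cells within d km (centre-to-centre) of any
predicted-cleared cell, d ∈ {0, 5, 10, 25, 50}; d = 0 coincides with
perfect match. AUC is the rank (Mann–Whitney) formulation with ties at one
half, so it is invariant to monotone transforms of the probability surface.
Annual metrics compare year-on-year clearing; cumulative metrics compare
unions of clearing up to each horizon. Metrics are computed per iteration
and summarised as mean and range. Per-iteration AUC uses that iteration's
own annual probability surface when the ensemble recorded surfaces
(`record_probabilities`, off by default — the surfaces are memory-heavy at
scale); otherwise the ensemble probability map is used.

## Synthetic landscapes

The generator emulates the calibration inputs of an active deforestation
frontier: straight roads crossing the grid with ~40 km spacing by default
(one road per 8 rows+cols — dense enough that mean road distance is ~10 km,
the regime in which the preset coefficients produce an emergent first-year
rate near 1%/yr, the observed magnitude of the high-pressure era); rivers
and settlements as sparser features; smooth Gaussian-field terrain; an
east–west precipitation gradient driving a 0–6-month dry season; three
non-overlapping protected blocks cycling through the state/federal/
indigenous classes; Voronoi state and municipality zonations with
log-normal economic indices; a deforested frontier strip plus scattered
clearings on ~0.5% of cells near roads (so the contagion covariate is
identified from the first year); and a small EXCLUDED water block.

What it does *not* emulate: realistic road-network topology, spatially
autocorrelated residual risk, polygon-to-raster artefacts, economic trends,
or the continental heterogeneity of a real basin. Passing tests therefore
demonstrate the correctness of the machinery and the recoverability of
known parameters under the model's own assumptions — not predictive skill
on real maps. In particular, discrimination (AUC) on synthetic landscapes
is intrinsically moderate because the generator's hazard field is far more
homogeneous than a real basin's.

## Numerical and design choices

* Esri ASCII grids are the interchange format (row 0 = north); reals are
  written with 10 significant digits, integer-bodied files round-trip as
  integer arrays so categorical codes survive I/O.
* All randomness flows from numpy `SeedSequence`s: ensemble iterations use
  spawned children of the master seed; CLI stages derive per-stage seeds;
  stepwise chains hash their variable set. Identical seeds give identical
  outputs bit for bit.
* Problem sizes in the tests and the acceptance script (lattices of 40–200
  cells a side, ensembles of 20–100, chains of 300–3 000 sweeps) are chosen
  as the smallest sizes at which the statistical assertions have comfortable
  Monte-Carlo margins.
* Degenerate inputs: empty feature masks (distance undefined), single-class
  outcomes, single-class AUC populations and empty prediction sets raise
  typed errors or return flagged NaNs rather than silent numbers.

## Known limitations

Static roads make long-horizon rates conservative: as road-adjacent forest
depletes, the simulated rate declines even when contagion sustains it
locally. Posterior correlations are discarded by the independent-Gaussian
draw (vectors drawn jointly from stored chains would preserve them). The
MCMC sampler is a single adaptive chain without formal convergence
diagnostics; the chains are persisted so users can run their own. Timing
summaries on cells cleared in barely more than half the iterations are
noisy by construction.
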