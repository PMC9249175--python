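# Methods

## The model

Cells are point agents at continuous positions on a periodic rectangle
(defaults: 180 × 512 pixels at 2.97 µm/pixel, i.e. 534.6 × 1520.6 µm — the
cropped field of view of a scratch-assay image; the 512-pixel axis is the
axis crossing the wound).  Periodic boundaries reflect that the field of
view is a window into a much larger monolayer.

Each cell `n` carries three event channels in continuous time:

* **movement**, rate `M_n = max(0, m − γ_m C_n)`,
* **proliferation**, rate `P_n = max(0, p − γ_p C_n)`,
* **death**, constant rate `d`,

where `C_n = Σ_{j≠n} w(‖x_n − x_j‖)` is a local crowding sum with Gaussian
kernel `w(r) = exp(−r²/2σ²)`, truncated to exactly zero at `r ≥ 3σ`.  The
interaction scale is tied to the cell diameter, `σ = φ/2`; `φ` defaults to
24 µm and can be estimated from data (below).  Negative `γ_m` means
crowding *increases* motility; positive `γ_m` models contact inhibition.

Movement and daughter-placement directions follow a von Mises distribution
whose mean is the direction of the bias vector `B_n = −∇B(x_n)` — the
negative gradient of the crowding potential `B(x) = Σ_j γ_b w(‖x − x_j‖)` —
and whose concentration is `‖B_n‖` (taken literally, in the units γ_b/σ²
carries).  An isolated cell therefore moves isotropically; a crowded cell
is pushed down the density gradient.  Both a move and a daughter placement
displace by exactly one cell diameter `φ`.  There is no hard-core volume
exclusion: coincident cells are legal.

The process is simulated exactly with the Gillespie algorithm: waiting
times are exponential in the total rate `R = ΣM + ΣP + N·d`, events are
chosen proportionally to individual rates, and all affected rates are
recomputed after every event.  `R = 0` is absorbing: the state is
propagated unchanged to the end time.

### Engines

`simulate(..., engine="fast")` is a numba-compiled event loop with

* a uniform grid (cell size ≥ 3σ) holding compact per-cell index arrays,
  with precomputed periodic 3×3 neighbourhoods, so rate updates touch only
  the cells within range of the event;
* block partial sums of the rate arrays for proportional event selection;
* a Best–Fisher von Mises sampler that returns the unit step vector
  directly (mathematically the same distribution as numpy's `vonmises`;
  verified against it statistically in the tests).

Neighbour crowding sums are updated incrementally (±w).  This matches full
recomputation only to floating-point rounding (≈1 ulp per event); the
accumulated drift is shed by periodic refreshes of the selection sums, and
the moved cell's own sum is always rebuilt from scratch.  We accept this
rounding-level deviation from exact bookkeeping because bitwise-exact
resummation after every event would cost an order of magnitude more.

`engine="reference"` is a plain-Python Gillespie loop that recomputes every
rate from scratch after each event through the public per-cell operations.
It is the independent oracle: the tests compare the two engines
statistically, and the compiled engine against birth–death closed forms
(`E[N(t)] = N₀ e^{(p−d)t}` when all γ's vanish).

Trajectories are bitwise reproducible given (seed, initial state,
parameters).  The two engines consume randomness differently, so they agree
in distribution, not per-seed.

## Summary statistics and distance

A snapshot is reduced to:

1. the cell count `N(24)`;
2. the pair correlation `P(j)` on annuli `(j−1)Δr < r < jΔr`, `Δr = 5 µm`,
   up to 100 µm (20 bins), at minimum-image distances, normalised by the
   expected ordered-pair count under complete spatial randomness,
   `N(N−1)·π((jΔr)² − ((j−1)Δr)²)/(LH)`, so CSR ⇒ `P ≡ 1`.  A printed
   variant of the prefactor that mixes the bin index with a length is
   available behind `normalisation="printed"` for comparison only — it is
   dimensionally inconsistent and does not have the CSR-normalisation
   property that defines the statistic, which is why the annulus-area form
   is the default;
3. the 64-bin density profile across the wound axis (half-open bins
   `[jΔy, (j+1)Δy)`, `Δy = 1520.64/64 = 23.76 µm` ≈ one cell diameter),
   which conserves `N` exactly.

The discrepancy between simulated and observed snapshots is the sum of
squared relative differences of the three blocks (count, pair correlation,
density profile), each normalised by the observed block's squared
magnitude.  It is non-negative and zero iff the summaries are equal;
validation rejects observed summaries that would zero a denominator.

## Minibatch ABC-SMC

Observations in a scratch screen differ strongly in initial wound position,
width and cell density, so a proposal can only be scored against an
observation by simulating *from that observation's own initial condition*.
Scoring one proposal against the whole dataset therefore costs `N_obs`
simulations.  The minibatch sampler replaces the full-data mean distance by
the mean over a random batch: for each proposal, `N_bs` observation indices
are drawn uniformly **with replacement**; one IBM realisation is simulated
per draw; the proposal's score is the mean of the per-observation
distances.  The expected score equals the full-data mean distance, and
simulation effort drops by `N_obs/N_bs`.  `n_batch = N_obs` with
`replace=False` recovers classical ABC-SMC exactly (tested).

Per generation, `N_gen` proposals are scored and the `N_acc` with smallest
score accepted — rank-based acceptance, so the tolerance sequence is
implicit and adaptive; ties break by proposal order, which keeps runs
deterministic under a seed.  Generation 1 proposes from the prior and
weights uniformly.  Later generations draw a parent by weight, perturb it
with a multivariate normal kernel whose covariance is **2× the weighted
empirical covariance** of the previous generation (the standard "optimal"
normal kernel choice), re-proposing until the result lands inside the prior
support, and weight accepted particles by `π(θ)/q̂(θ)` with
`q̂(θ) = Σ_j ŵ_j N(θ; θ_j, Σ)`.  The truncation of the kernel to the prior
box is not folded into `q̂`: it cancels to first order after weight
normalisation, and leaving it out keeps `q̂` strictly positive and cheap.

Priors are independent uniforms: `m ∈ (0, 10) h⁻¹`, `p, d ∈ (0, 0.05) h⁻¹`,
`γ_m ∈ (−2.5, 2.5) h⁻¹`, `γ_p ∈ (0, 0.05) h⁻¹`, `γ_b ∈ (0, 50) µm`.  The
sampled space is 6-D (p and d separately); only `p − d` is identifiable
from two snapshots, so reporting collapses to the 5-vector
`(m, p − d, γ_m, γ_p, γ_b)`.

Full-scale defaults are `N_gen = 2·10⁴`, `N_acc = 500` (2.5 % acceptance),
`N_bs = 10`, `T = 4`.  An optional stopping rule ends the run early when
the estimated KL divergence between successive generations falls below a
tolerance.  The KL estimate is the average over the six 1-D marginals of
weighted Gaussian-KDE estimates on a shared grid — chosen for robustness
with a few hundred weighted particles in 6-D, where joint KDE estimates
are unreliable; it is validated against the Gaussian closed form
(KL ≈ 0.5 for unit-variance normals one σ apart) at ±0.1.

The chance that a generation never touches a given observation is
`(1 − 1/N_obs)^{N_gen·N_bs} ≤ exp(−N_gen·N_bs/N_obs)`
(`coverage_bound`, exact and bound, also in log space since the values
underflow at realistic settings).

## Synthetic data

`generate_initial_condition` places a Poisson-distributed number of cells
uniformly outside a horizontal wound band (position and width drawn per
observation); `generate_regime_dataset` forward-simulates each initial
condition to 24 h under one of two built-in regimes:

| regime | m (h⁻¹) | p−d (h⁻¹) | γ_m (h⁻¹) | γ_p (h⁻¹) | γ_b (µm) |
|--------|---------|-----------|-----------|-----------|----------|
| I      | 1.5     | 0.010     | −1.0      | 0.01      | 20       |
| II     | 0.5     | 0.025     | +1.5      | 0.01      | 20       |

The p−d split is fixed at `d = 0.005 h⁻¹`.  Wound widths are drawn from
430–740 µm and centres from the middle 30 % of the field, spanning wound
fractions comparable to the range seen in control wells; the default
monolayer density (6.5·10⁻⁴ µm⁻²) gives initial populations of roughly
270–380 cells, which keeps a full inference run at desk scale.  Wound
areas are measured from the 64-bin density profile: bins below 50 % of the
median occupied-bin count are wound; the longest contiguous run (with
wrap) defines the band.  The threshold is exposed as a parameter.

What the generator does *not* emulate: imaging noise, detection errors,
stitching artefacts, dead/extruded cells, or cell-size variability between
wells.  Passing recovery tests therefore demonstrate that the sampler
inverts the model under ideal observation of cell centres — not robustness
to the imperfections of a real imaging pipeline.

### Cell diameter

`voronoi_areas` tessellates the periodic plane (3×3 tiling, central copy
kept; areas sum to the domain area) and `estimate_cell_diameter` returns
the equivalent-circle diameter of the **median** polygon area,
`φ = 2√(median A/π)`.  The median is used because wound-adjacent cells own
arbitrarily large polygons; the exact estimator used upstream of the model
is not fully specified, so this rule is a documented convention (validated
on a hexagonal packing: recovers the lattice spacing within 10 %).

## Screen analytics

Per condition, the particle population is summarised by its weighted
posterior mean in the 5-D space.  Across conditions, K-means (Lloyd, 10
restarts, seeded) clusters the posterior means after z-scoring — the
coordinates span three orders of magnitude, so unscaled clustering would be
dominated by `m` and `γ_b`; raw-coordinate clustering remains available via
`standardise=False`.  The number of clusters is the elbow of the
WCSS-versus-k curve, concretised as the k with the largest discrete second
difference (ties toward smaller k; needs k_max ≥ 3).

Fold changes: the density-independent expectation is `C = e^{24(p−d)}`.
The density-corrected estimate replaces the unobservable crowding sum by a
kernel integral at the mean of the initial and final free-area densities
`ρ_t = c_t/(F − w_t)`:

    C = exp(24·(p − d − γ_p·πσ²·(ρ₀ + ρ₂₄))),

using `∫w dA = 2πσ²` for the truncated Gaussian (the 3σ cut-off changes the
integral by `e^{−4.5} ≈ 1 %`, ignored).  A printed form of this correction
carries a dimensionally ambiguous prefactor; the kernel-integral derivation
is used instead and the prefactor is overridable for comparison.  At
`γ_p = 0` the corrected estimate reduces to the naive one exactly.
Wound-area fold change is `W = w₂₄/w₀` (0 = closed, 1 = unchanged).

## Problem sizes and numerical choices

* The recovery benchmarks run at desk scale: 20 observations of ~300
  cells, `N_bs = 10`, `T = 3`, with `N_gen = 1200` proposals and
  `N_acc = 60` acceptances per generation (a 5 % acceptance rate).  These
  are the package's study conditions for a single-CPU run of roughly a
  quarter hour; full-scale defaults remain `2·10⁴/500/T = 4` at 2.5 %.
* Event selection refreshes its partial sums every 2¹⁴ events to shed
  floating-point drift.
* The kernel covariance receives a `1e−10`-scaled diagonal jitter only if
  near-singular; a fully degenerate particle set warns.
* Tie-breaks: acceptance ranking is a stable sort by score; density-profile
  bins are half-open `[jΔy, (j+1)Δy)`; a coordinate landing exactly on the
  domain edge wraps to 0.
* Degenerate inputs: empty populations simulate to empty (no spontaneous
  birth), summarise to zero vectors, and are rejected as ABC observations
  by the distance validation; a wound covering the whole domain is a
  validation error.

## Known limitations

* `γ_p` and `γ_b` are weakly identified from two snapshots — their
  posteriors stay close to the prior; recovery checks target `m`, `γ_m`
  and `p − d`.
* The von Mises concentration equals `‖B_n‖` literally, so its scale is
  tied to the units of `γ_b/σ²`; an alternative dimensionless scaling would
  change the meaning of `γ_b`.
* The incremental-rate engine is exact up to float rounding, not bitwise
  equal to full recomputation (see above).
* The KL stopping diagnostic estimates marginal, not joint, divergence;
  strongly correlated posteriors can appear converged earlier than they
  are.
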