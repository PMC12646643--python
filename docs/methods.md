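# Methods

## Model

`telinfer` works with the two-state ("telegraph") model of transcriptional
bursting: a promoter switches between an inactive state G and an active
state G* with rates `kon` (activation) and `koff` (deactivation); mRNA is
synthesized at rate `ksyn` only while the promoter is active and degrades
with first-order rate `kd`. All rates are expressed in units of `kd`, which
fixes `kd = 1` and leaves three free parameters `theta = (kon, koff, ksyn)`.
The observable is the steady-state distribution of mRNA copy number across
a snapshot of cells — the per-gene histogram that scRNA-seq (or smFISH)
yields — and the promoter state is not observed.

The stationary law is computed from the chemical master equation
`dP/dt = A P` on the state space {G, G*} × {0..M}: the generator `A` is
assembled sparsely (state index `promoter*(M+1) + x`, promoter 0 = G) and
the steady state solves `A p = 0` with one equation replaced by the
normalization constraint, by direct sparse factorization. An eigensolver
would do the same job; the replaced-row linear solve is deterministic and
has no iteration tolerance to tune at this problem size. Although the
telegraph model has an analytic stationary law (a Beta-Poisson mixture,
used as an independent oracle in the test suite), the CME route is the
implementation because it generalizes to models without a closed form.

### Truncation

The mRNA axis is truncated at a bound M chosen per parameter set. The
starting guess is `mean + 10*sqrt(mean*(1 + burst_size))` (burst size
`ksyn/koff`), clipped from above by a Poisson-style bound
`ksyn + 10*sqrt(ksyn) + 25` — the active-state quasi-stationary intensity
can never exceed `ksyn`, so the burst-size-based guess is wildly
pessimistic in the slow-deactivation corner — and from below by 16.
Synthesis out of `x = M` is suppressed (reflecting boundary), keeping the
generator exactly conservative so the stationarity residual
`||A p||_inf <= 1e-10` is checked exactly. The neglected tail is estimated
as the probability of the top two mRNA levels plus, when that mass is not
already negligible (below `1e-4 * tol`), the total-variation change against
a solve with the bound doubled; M doubles geometrically until the estimate
is below the tolerance (default `1e-4`), with a hard cap at `1e4` states
per promoter level. Failures at the cap raise a truncation error carrying
the achieved tail mass.

## Measurement noise

scRNA-seq capture is modeled as independent binomial thinning: each true
molecule is observed with known probability `beta` (the capture rate), so
distributions transform through the lower-triangular matrix
`B[y, x] = C(x, y) beta^y (1-beta)^(x-y)`, evaluated through the binomial
PMF in log space so large supports do not overflow. For the telegraph model
this is mathematically identical to scaling `ksyn` by `beta`; the matrix
transform is the canonical route (it applies to any model), the scaling
shortcut is kept as a fast path and as the oracle in the equivalence tests.
Thinning is applied to the normalized truncated marginal. Unknown-`beta`
inference, amplification bias, and ambient RNA are out of scope.

## Likelihood and profiles

For an observed histogram `n_x` over copy numbers, the log-likelihood of
`theta` is `LL = sum_x n_x log P_x(theta)` with `P_x` the
capture-transformed model marginal. Model probabilities are floored at
`1e-12` inside the logarithm: observed counts can land on states the
truncated model assigns essentially zero, and the floor (far below `1/N`
for any realistic cell count) keeps the objective finite and smooth.

Inference proceeds in two stages:

1. **Coarse surface.** A precomputed model library tabulates the captured
   marginal on a log10-spaced grid (production default 60 points per axis
   over `kon, koff` in `[1e-3, 1e3]` and `ksyn` in `[10^-0.3, 10^2.3]`;
   tests and the acceptance script use 12 points per axis over the same
   ranges). One vectorized pass gives `-LL` at every grid point; the argmin
   seeds the optimizer and the region within `1.92 + 2.0` of the minimum
   (the CI threshold plus a safety margin), expanded by one grid step and
   clipped to the ranges, becomes the optimization box.
2. **Refinement.** Bounded Nelder-Mead in log10-parameter space
   (`xatol = 1e-4` decades; function tolerance scaled to the objective
   magnitude so behavior is N-independent). The returned optimum is never
   worse than the seed. Seeds are nudged strictly inside the box: a seed
   exactly on a bound makes the default initial simplex degenerate after
   clipping and the search stalls in that coordinate.

Profile likelihoods fix one parameter on a log10 grid (40 points across
the library range plus 10 points within ±0.5 decades of the MLE, plus the
MLE itself) and minimize over the other two, sweeping outward from the MLE
with warm-started nuisance seeds. Confidence intervals cut the profile at
`chi2_1(0.95)/2 ≈ 1.9207` above the global minimum (the exact quantile is
used; the conventional "1.92" is what it rounds to), with crossings
linearly interpolated in (log10 value, profile) coordinates. A side that
never crosses within the library range is pinned to the range edge and
flagged; the pinned bound enters the APM as-is, which keeps the metric
finite while the flag preserves the information.

## APM and identifiability

Per parameter, `APM = log_T(theta_ub / theta_lb)` with tolerance factors
`T = 3` for `ksyn` and `T = 100` for `kon` and `koff` — switching
timescales in mammalian cells plausibly span several orders of magnitude,
synthesis rates do not. A parameter set is practically identifiable when
the maximum APM over the three parameters is below 1, i.e. when even the
worst-constrained parameter is pinned to within its tolerance factor.

## A priori (sampling-free) mode

For a hypothetical experiment with `N` cells at ground truth `theta_tar`,
the expected negative log-likelihood is the scaled cross-entropy
`H(theta) = -N sum_x P_tar(x) log P_sim(x | theta)`, minimized exactly at
`theta_tar` (Gibbs' inequality — the implementation evaluates `H` at the
target as a candidate, so the global minimum is exact rather than
optimizer-limited). Profiles built from `H` are the infinite-replicate
average of sampled-data profiles, so identifiability can be mapped without
generating data. Since `N` is a scalar multiple of `H`, profiles are
computed once per target at `N = 1` and rescaled; only the CI crossings
are re-found per `N`. This makes cell-number ladders (smallest `N`
reaching APM < 1) essentially free after the first profile, and the
verdict is monotone in `N` by construction.

Landscape scans profile every point of a (sub-)grid as its own ground
truth. The default scan computes a fine profile per point at reduced
profile-grid resolution (14 range-spanning points per parameter). A
grid-restricted mode (`fine=False`) that minimizes nuisance parameters
over the library grid only is roughly 50x faster but systematically
understates CI widths wherever parameters compensate along narrow valleys
(fast switching, slow kon/koff trade-offs) — at 12 grid points per axis it
can misclassify such points as identifiable — so it is reserved for rough
previews and for degenerate checks (e.g. that nothing is identifiable from
a single cell).

## Sensitivity analysis

Structural (as opposed to practical) identifiability is probed through the
sensitivity matrix `S[j, i] = d y_j / d theta_i` of the captured marginal
with respect to log10 rates, by central finite differences with step
`1e-3` decades on a common support (shorter solutions zero-padded; any
mass there is below the truncation tolerance). Columns of `S` sum to ~0
because distributions stay normalized. The minimum singular value of `S`
is reported per parameter set: strictly positive values mean no direction
in parameter space leaves the output unchanged to first order, even where
the value is so small that finite data cannot exploit it — which is
exactly the gap between structural and practical identifiability that the
profile pipeline quantifies.

## Synthetic data

Steady-state snapshots are exact multinomial draws of `N` cells from the
captured marginal (a stochastic-simulation run would sample the same law;
an SSA implementation exists only as an independent oracle in the test
suite). Bootstrap replicates refit the MLE per replicate with per-replicate
seeds spawned from a master seed. Summary statistics cover mean, variance,
Fano factor (variance/mean, reported missing at zero mean), skewness, zero
fraction, and a bimodality indicator (count of interior local maxima after
a window-3 moving-average smooth — the window suppresses single-bin noise
in sampled histograms without erasing genuine mode separation).

## Problem sizes and what the tests show

The test suite and the acceptance script run on a 12-points-per-axis
library, fine profiles at the default resolution for single targets, and
3-points-per-axis fine landscape scans at 1e4 cells; bootstrap and
coverage checks use 60-200 replicates at 200 cells. These sizes keep every
property at full fidelity (profiles re-optimize nuisance parameters
continuously; only grid seeding is coarser than the production default)
while a full 60-points-per-axis library build remains a documented CLI
operation (`telinfer build-library`).

The synthetic generator draws from the model itself, so passing tests
demonstrate correctness of the solver, the noise transform, the estimator,
and the identifiability machinery under the model's own assumptions. They
do not validate the telegraph model against real transcriptomes: real data
add amplification noise, cell-cycle and extrinsic variability, and
non-steady-state effects that the binomial-capture telegraph model does
not represent.

## Known limitations

- CI endpoints inherit the profile-grid resolution between grid nodes
  (linear interpolation); extremely narrow CIs at very large `N` are
  resolved by the densified patch around the MLE but their APM values are
  then dominated by optimizer precision.
- Parameter sets at the grid range edges can receive small APM values
  because their CIs clip at the edge; the boundary flags expose this.
- The profile optimizer is derivative-free and local within the search
  box; pathological multi-modal objectives outside the box radius are
  found only through the coarse surface's resolution.
- Capture rate is global per run and assumed known; per-gene or inferred
  `beta` is out of scope.
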