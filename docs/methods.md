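# Methods

## Model

The sediment column is discretised into `d` horizontal layers of equal
height (default 0.073 mm, one image pixel row), each holding exactly `w`
particles; depth index 0 is the sediment–water interface. Particles are
tracer (luminophore) or non-marked. A time step (default 5 min) is:

**Active displacement.** For every layer `i < round(range_frac · d)`,
the number of displaced tracers is Binomial(tᵢ, activity). Each
displaced particle draws direction down with probability `downwards`
and an integer magnitude `m` from the configured distribution with mean
`distance`; its target is `clamp(i ± m, 0, d−1)` (wall boundaries: a
particle that would leave the grid stops at the boundary layer; `m = 0`
leaves it in place). Only tracer particles are displaced actively: the
observable is the tracer profile, and the data contain no information
about individual non-marked moves. Non-marked transport is represented
implicitly by the rebalancing phase — a stated limitation, since a model
in which both populations jump actively would mix surface compositions
faster (see Limitations).

**Passive rebalancing.** Active moves leave layer totals ≠ `w`.
Sweeping from the bottom layer upward, any surplus is moved to the layer
above; the moved particles are drawn sequentially without replacement,
probability proportional to remaining weight (`tracerdif` per tracer, 1
per non-marked grain), from the layer's full current pool including
particles just received from below. If the surface layer then exceeds
`w` (net upward active motion), a symmetric top-down pass runs. One can
show the two passes always terminate with every layer exactly at
capacity, and both inventories are conserved exactly.

The sequential weighted draw follows Wallenius' noncentral
hypergeometric distribution. It is implemented through the equivalent
exponential-clocks representation — give each particle an independent
Exp(weight) key and move the `k` smallest — which is distributionally
identical to one-at-a-time selection and vectorises; the neutral case
`tracerdif = 1` short-circuits to a hypergeometric draw. Tests verify
both against `scipy.stats` pmfs by chi-square at α = 0.001.

## Parameters

| name | meaning | units | default / bounds |
|---|---|---|---|
| `activity` | P(active displacement) per tracer per step | – | fitted; [0, 1] |
| `distance` | mean displacement magnitude | layers | fitted; > 0 |
| `downwards` | P(displacement is downward) | – | 0.5 (symmetry assumption) |
| `range_frac` | fraction of depth open to reworking | – | 1.0 |
| `tracerdif` | tracer selection weight in rebalancing | – | fitted; (0, 1] |

The magnitude distribution is pluggable (`poisson` default, `fixed` =
floor + Bernoulli fraction, `geometric`); Poisson is the simplest
discrete family parameterised by its mean, and E[m²] = λ + λ² feeds the
diffusion-limit analysis. `tracerdif` weights the *tracer* (values < 1
make tracers lag the compensatory upward flow and are what lets the
model form non-exponential profile shapes); descriptions of the same
mechanism as "the likelihood that a non-marked particle is dislocated
upwards" refer to the complementary quantity.

Reference parameterisation (`bioturb.case_study`): *Hediste
diversicolor* on a 149 × 2980 grid, top 20 layers tracer, 24 × 5-min
steps, with activity 0.674, distance 4.30 layers (0.314 mm),
tracerdif 0.929.

## Calibration

The objective is Σ over layers and time points of (observed −
width_factor · simulated)². Simulating a narrower grid (default
width_factor 10, i.e. `w/10`) and rescaling is statistically neutral
because mixing is homogeneous across the width, and cuts cost tenfold.
When an observed series is longer than the simulation, columns are
subsampled by a configurable stride and truncated to the simulated
horizon.

The objective is stochastic. Three choices keep the optimisers honest:

* **Common random numbers.** Simulation seeds are frozen per
  optimisation run, so each run sees a piecewise-deterministic surface
  and finite differences estimate gradients of the expected surface.
* **Mean-profile replication.** An evaluation with R seeds compares the
  observation to the *mean* of the R simulated matrices, not the mean of
  R objectives. The latter carries the simulator's sampling variance as
  an additive, parameter-dependent penalty that biases fits towards
  low-variance parameter values; averaging profiles shrinks the penalty
  by R.
* **Chain arbitration.** The (distance, tracerdif) surface has a
  correlated valley with a spurious secondary basin at low values of
  both. The annealing stage therefore runs two independent chains
  (geometric cooling over ~100–300 Metropolis steps, Gaussian proposals
  shrinking with √(T/T₀), reflection at the box bounds) and picks the
  endpoint with the lower value on a smoother 8-replicate objective.

Refinement runs L-BFGS-B in box-scaled coordinates (finite-difference
step 0.02 of each box) from the annealing optimum, replicated with
independent frozen seed tuples; the replicate spread is the reported
uncertainty. `activity` is strongly confounded with `distance` (their
product controls the flux, producing a furrow rather than a point
minimum in scans), so the standard recipe fixes `activity` at the scan
optimum before fitting the remaining two parameters. Grid scans report
the first-encountered minimum in row-major order; the 12 × 8 sensitivity
grid spans −30 %..+30 % in distance and −30 %..+10 % in tracerdif
(capped at 1) around a fitted optimum, all cells sharing one seed.

## Biodiffusion reference

`diffuse` integrates ∂C/∂t = Db ∂²C/∂z² by backward Euler on the lattice
grid (spacing 1 layer) with zero-flux boundaries — the continuum
analogue of the lattice walls. The scheme is unconditionally stable,
conserves mass to machine precision and preserves non-negativity (the
system matrix is an M-matrix); a residual clip removes −0.0 noise only.
`fit_db` minimises the same sum-of-squares over Db ≥ 0 (coarse geometric
bracket, then bounded scalar minimisation) starting from the *observed*
initial column, and reports the per-time-step decomposition of the
objective, which sums to the total exactly. Db is reported in
layers²·min⁻¹ and mm²·min⁻¹ (conversion by layer height squared).

In the dilute symmetric limit (downwards 0.5, tracerdif 1, point release
far from boundaries) the lattice's depth variance grows at
activity · E[m²] per step, so the fitted Db should approach
activity · E[m²] / 2 per step. The fitted value runs some 10–20 % low at
the horizons tested: at short times the displacement process is
leptokurtic (a spike of never-displaced particles over a spread
component) and a least-squares Fickian fit underweights the tails, with
a smaller contribution from the mass-balance back-flow. This residual
bias is itself an illustration of why Db misdescribes event-driven
mixing.

## Synthetic data

`generate_synthetic` forward-simulates the lattice model and optionally
thins counts binomially (detection probability `p_detect`, drawn from an
RNG stream independent of the simulation's) to mimic luminophores missed
by imaging. It emulates the *counting* output of a profile-imaging
experiment, not the imaging itself: no interface drift, no segmentation
error, no spatially correlated detection loss, no animal behaviour
beyond the model's own rules. Passing recovery tests on such data
demonstrates that the calibration machinery is unbiased and converges —
not that the model family is adequate for any particular real species.

## Problem sizes and numerical choices

Tests and the acceptance script run the reference grid at fitting width
(149 × 298, 24 steps) and the full-width stand-in (149 × 2980) once;
recovery studies use 10 synthetic seeds with an 80–100-step annealing
budget per chain and a single refinement replicate; the reference
calibration uses a 300-step budget and 10 refinement replicates of 4
simulations each. Optimisation bounds: activity [10⁻³, 1], distance
[0.05, 20] layers, fractions [0.05, 1]. Ties in scans and grids break to
the first entry. Degenerate inputs fail loudly: all-zero observations
(Db undefined), removals exceeding a layer's tracer, global mass
mismatches and out-of-bounds starts raise typed errors rather than
propagating nonsense.

## Limitations

* Two-dimensional, single homogeneous behaviour: no explicit burrows,
  bout structure, multiple species, or pore-water advection;
  parameters are constant in space and time.
* Only tracers move actively (see above). One consequence is that the
  surface layer equilibrates tracer-rich in long runs — compositional
  turnover at the interface is driven solely by passive exchange.
* `tracerdif` is weakly identified on narrow grids (few thousand
  tracers): single realisations can prefer values ~15 % below truth,
  which is why replication and chain arbitration are defaults.
* The diffusion comparison shares the lattice discretisation; it is a
  like-for-like baseline, not a reference-quality PDE solver for other
  geometries.
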