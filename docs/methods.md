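# Methods

## The model

`heterospread` simulates a population expanding across a two-dimensional
square lattice — a generalized Eden model. Each lattice site is empty or
holds one individual. A quenched random environment is drawn once per run:
every site is independently a *disorder site* with probability ρ. Disorder
sites multiply the growth rate of their occupant by the transparency
k ∈ [0, 1]; at k = 0 they are *obstacles* and can never be colonized, so
the open sites form a site-percolation problem. Each occupied site with at
least one colonizable empty 4-neighbor (von Neumann adjacency) is a
*boundary site*; in every event one boundary site is chosen with
probability proportional to its growth rate and places a daughter on a
uniformly random colonizable empty neighbor. A wild-type division produces
a mutant daughter with probability μ; the mutation founds a clone with a
fresh id, confers relative growth rate 1 + s, and mutants never mutate
again. Time advances by Δt = 1/(Σ eligible rates) per division, in units
of wild-type generations — a deterministic mean-field increment that keeps
runs exactly reproducible while preserving the embedded jump chain of the
continuous-time process.

Geometries: *radial* (one protected wild-type founder at the lattice
center; stop at N occupied sites, at pinning, or when the colony nears the
lattice edge, which is flagged as a boundary artifact) and *linear* (a
protected fully occupied bottom row of width L, periodic in x; stop when
the mean front height reaches a target or at pinning).

Key modeling commitments, made once and fixed:

- **4-neighbor adjacency.** At k = 0 the arrested colonies are then square
  -lattice site-percolation clusters and the pinning threshold coincides
  with 1 − 0.5927… ≈ 0.407, which is what the spanning scan measures.
- **Obstacles are never occupied at k = 0.** For k > 0 disorder sites are
  colonizable and their occupants divide at rate k (× (1+s) for mutants).
  The k → 0⁺ and k = 0 cases therefore differ in occupancy; this
  discontinuity is intended behavior.
- **The daughter mutates, not the mother.** Standard Eden-model
  convention; the mother's recorded genotype history is never rewritten.
- **k = 1 collapses the disorder label.** With k = 1 all rates are
  disorder-independent, and the implementation selects mothers from rate
  classes that ignore the disorder mask in that case, so a k = 1 run is
  bit-identical to the ρ = 0 run with the same seed — a strong regression
  invariant checked by the test suite.
- **Seeding.** Each run derives two independent streams (disorder, growth)
  from its master seed; the growth stream does not depend on ρ or k.

Defaults mirror the reference study conditions: N = 10⁵ occupied sites and
μ = 5×10⁻⁴ per wild-type division for ensemble work; the selection grid
spans s ∈ [−0.15, 0.2]; radial lattices are auto-sized
(L ≥ 5·√(N/π(1−ρ)), odd) so colonies never reach the edge.

## Interface statistics

Linear-geometry fronts are summarized by the per-column height h(x) (max
occupied row; overhangs collapsed) and analyzed in the Family–Vicsek
frame: the global width W_G(t) (rms of h about its spatial mean) grows as
t^β before saturating at W ~ L^α on times of order L^z, z = α/β; the
saturated local width over windows of length l scales as l^α_loc.

- **β** is fit on the ensemble-mean W_G against *simulation time* over the
  decade below the point where the mean width first reaches half its
  maximum. Time, not mean height, is the abscissa: close to the pinning
  transition the front decelerates, so height- and time-based exponents
  differ there, and the scaling law is stated in time. Per-run curves are
  interpolated onto a common log-spaced time grid; only snapshots reached
  by ≥ 90 % of runs enter the average, so runs that pin early do not bias
  the growth regime.
- **α_loc** is fit on the saturated W_loc(l) over windows l ∈ [4, L/8].
  Runs for saturation studies grow to mean height 0.8·L^{3/2}, well past
  the observed crossover (≈ 0.06·L^{3/2} at ρ = 0).
- **ρ_c** is estimated from a spanning scan: at each ρ, the fraction of
  radial k = 0 colonies whose growth reaches within 2 sites of the border
  of an L = 128 lattice; ρ_c interpolates the ½-crossing, with a logistic
  fit supplying the width. The ½-crossing at finite L sits slightly above
  the percolation threshold (the one-arm probability at criticality decays
  only as R^(−5/48)), a known finite-size bias of order 0.01 at L = 128.

Measured at desk scale these give β ≈ 0.29–0.32 and α_loc ≈ 0.49–0.53
without disorder (KPZ: 1/3 and 1/2) and β ≈ 0.78–0.80 at ρ = 0.4, k = 0
(quenched-EW moving regime).

## Clones

A clone is a founding mutant and all its descendants, identified by the
clone id stamped at the founding division (identity by descent — a clone
fragmented around obstacles is one clone). A clone is a *sector* if any of
its sites touches the final front, else a *bubble*. The front is the set
of occupied sites 4-adjacent to the border-connected empty region (flood
fill; at k = 0 unoccupied obstacles are barriers), so interior holes and
obstacle-sealed pockets are excluded.

- **Size spectrum.** The pooled empirical survival function P(X > x) of
  normalized clone sizes uses the strictly-greater convention. The tail
  exponent is fit on survival values resampled at log-spaced sizes (equal
  weight per decade) over x ∈ [8/N, 0.01]: below ~8 sites lattice
  discreteness distorts the law, above ~1 % of the colony the finite-size
  cutoff bends it. Clones in this window are overwhelmingly bubbles, whose
  survival is expected to scale as a^(−1/(1+z)).
- **Shape.** For clones of ≥ 5 sites, l∥ and l⊥ are the max−min+1 extents
  of site projections on the radial unit vector through the clone centroid
  and its perpendicular; the orientation angle comes from the covariance
  principal axis, folded to [0, π/2]. ζ is fit on log-binned l∥ (bins with
  ≥ 10 clones, median l⊥ per bin) because clone sizes are heavy-tailed.
  *Sectors are excluded by default*: a surviving sector is a wedge whose
  width grows essentially linearly with radial extent by geometry, which
  contaminates the fluctuation-driven scaling ζ is meant to capture — with
  sectors pooled in, the fitted exponent rises by ≈ 0.1 at ρ = 0 and
  ≈ 0.05 at ρ = 0.4. Protocols that explicitly pool every clone (as the
  critical-density anisotropy recomputation in `scripts/acceptance.py`
  does) pass `include_sectors=True`. The radial-frame reading of l∥ is a
  documented choice; the principal-axis alternative is recoverable from
  the stored per-clone covariance axes.

## Lineages and coalescence

Every division is logged, so the ancestry of each final-front cell is a
walk through the parent map back to the founder. Two summaries:

- **Transverse fluctuations.** For each front leaf the reference ray runs
  from the colony center through that leaf; each path point at radius r
  contributes its perpendicular distance d from the ray. Because *both*
  endpoints of a lineage lie on its own reference ray (founder and leaf),
  the raw rms is bridge-suppressed near both ends and a naive central-
  decade fit underestimates the wandering exponent badly (≈ 0.45–0.53
  where 0.66 is expected at ρ = 0). The estimator therefore keeps only the
  first half of each path (r ≤ leaf_radius/2), divides each d² by the
  bridge endpoint factor (1 − r/leaf_radius)^(2ξ*) with a fixed
  compensation exponent ξ* = 0.75 (midway between the KPZ 2/3 and
  quenched-EW ≈ 0.86 wandering exponents; over the retained half-path the
  factor varies by less than 2×, so the residual sensitivity to ξ* is a
  few percent), and fits l⊥²(t) = w₀² + A²t^(2ξ) on unit radius bins — w₀
  absorbs the intrinsic lattice-scale width. Validated on both study
  conditions over independent seed sets: ξ ≈ 0.63–0.67 (ρ = 0) and
  0.81–0.88 (ρ = 0.4). A self-consistent refinement (re-correcting with
  the fitted ξ) is available but not default.
- **Pair coalescence.** For front-leaf pairs (all pairs up to a 2×10⁵
  budget, else uniformly subsampled with a recorded seed), T₂ is the
  backward time from the final time point to the birth of the MRCA, found
  by walking the younger branch up (exact, because birth events strictly
  order every ancestor chain); Δx is the Euclidean leaf distance. Both are
  normalized — T₂ by the total run time, Δx by the front diameter (convex
  hull) — and binned. The persistence curve U(T₂) is the survival function
  of normalized T₂ conditioned on Δx/Δx_max below a cutoff (default 0.05).

## Selection response and rate of adaptation

Ensemble sweeps record the final mutant frequency f_MT per (ρ, k, s). The
heuristic exponential law f_MT(s) = f₀·e^(k_s·s) is fit by weighted least
squares on ln f_MT (exactly linear in log space; weights from the delta
method; unweighted OLS exposed as an option). The master-curve check
rescales all sweeps to (k_s·s, f_MT/f₀) and reports the rms log deviation
from e^(k_s·s).

The distribution of fitness effects is two-sided exponential,
D(s) = [e^(−s/s̄) for s > 0; R·e^(−|s|/s̄) for s < 0] / (s̄(1+R)): both
branches share the scale s̄ and R is the total deleterious:beneficial
frequency ratio (deleterious mass R/(1+R)). For constant f_MT = c the rate
of adaptation ∫D(s)·s·f_MT(s)ds is c·s̄·(1−R)/(1+R) — the identity the
tests assert. The integral uses trapezoid quadrature on the tabulated
f_MT(s) refined to step 0.005 by linear interpolation, plus analytic tail
corrections with f_MT frozen at its boundary values; if the DFE mass
outside the tabulated range exceeds 1 % the call refuses rather than
extrapolate. Deleterious frequencies come from simulated negative-s
sweeps, not extrapolation. Rates across a (ρ, k) sweep are normalized by
the ρ = 0 value.

## Mutation-rate inference

The plating experiment is emulated per replicate as discrete generations
from a Poisson(λ₀ = 10) inoculum (zero redrawn) for 7 generations
(~10 → ~1280 cells): wild-type counts double each generation, each
division contributing a mutant daughter with probability μ (binomial), so
the endpoint mutant fraction accrues ≈ μ/2 per generation; mutant counts
grow deterministically by 2^(1+s), i.e. a relative gain of 2^(gs) over g
generations. Endpoint fractions per (μ, s) are histogrammed (50 equal bins
on [0, 1], add-one smoothing so observations never meet zero density) and
the observed replicate fractions scored by summed log densities. The grid
maximizer (default μ log-spaced over 10^−3.5…10^−1.5, s ∈ −0.1…0.4)
treats s as a free nuisance parameter; δμ = 1/√|∂²ℓ/∂μ²| from a
nonuniform 3-point second difference at the maximizer, floored at half the
local grid spacing (a grid estimator cannot resolve μ below its own
resolution; the curvature rule is a lower bound). Monte-Carlo recovery at
(μ = 0.003, s = 0.3) with 48 replicates shows the curvature error covers
the truth at ±2δμ in ≈ 90 % of repetitions when s is known; with s
profiled, the μ–s trade-off widens the sampling spread and coverage drops
to ≈ 65–80 %, which is why reported δμ should be read as a lower bound
exactly as the error rule's inequality indicates.

## What the synthetic generators do and do not emulate

The lattice model reduces a colony to uniform division-limited growth on
uncorrelated binary disorder: no nutrient or mechanical interactions, no
cell geometry, no correlated substrate structure, one mutant type per run.
The plating generator reduces a batch culture to synchronized generations
with deterministic growth and stochastic mutation only. Passing tests
therefore demonstrate the internal consistency of the model and its
analysis stack and reproduce the universal (exponent-level) behaviors;
they do not certify agreement with any particular organism's colonies,
where correlated heterogeneity and establishment-size effects are known to
matter.

## Problem sizes and numerical choices

Ensemble studies run at N = 10⁵, μ = 5×10⁻⁴ with 20–50 colonies per
condition, linear systems at L = 256–512; these sizes reproduce the
exponent-level results while keeping a full analysis pass in minutes on
one core. The event loop and the MRCA/path kernels are numba-compiled;
everything else is numpy/scipy/pandas. Degenerate inputs are handled
explicitly: pinned colonies report speed 0; empty clone pools, fronts with
fewer than two leaves, unbracketed percolation grids, nonpositive fit
inputs and boundary-hitting likelihood maximizers all raise or flag rather
than return silent numbers. Fit windows are stated above next to each
estimator; power-law fits are OLS on log-log with slope standard errors
from the regression.

## Known limitations

- Exponents carry finite-size biases of a few hundredths at these sizes
  (documented per estimator above); the ½-crossing overestimates ρ_c by
  ~0.01 at L = 128.
- The depinning exponent θ and the crossover length ℓ(ρ) are not
  measured (no well-defined lattice protocol at these scales).
- The ξ estimator's bridge compensation uses a fixed exponent; its
  residual bias is a few percent and condition-dependent.
- Clone shape statistics need pooled ensembles (hundreds of clones above
  the area cutoff) before the binned fit stabilizes.
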