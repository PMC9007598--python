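# Methods

## Problem setting

A two-drug combination therapy is characterized by its success-rate
response surface: at each dose pair (AMT1, AMT2) a population PK/PD model
predicts the fraction of subjects whose clinical endpoint is met. Given a
prespecified efficacy target ŷ (say, a 95% success rate), the *effective
isobole* of one population realization is the curve of minimum dose
combinations reaching ŷ; it separates the dosing rectangle
[0, AMT1max] × [0, AMT2max] into a non-efficacious region (toward the
origin) and an efficacious one. Because the population parameters are
themselves estimates, an ensemble of population realizations drawn from
the parameter-uncertainty distribution induces a distribution of effective
isoboles; the fraction of realizations meeting the target at a given dose
pair is the *confidence level* of that dose pair, and its gridded field is
the confidence-level response surface.

Scanning a 129 × 129 dose lattice by brute force costs
129² ≈ 1.7 × 10⁴ population simulations per realization. The package
avoids most of that cost by evaluating the success rate only near the
isobole being traced.

## Hierarchical population simulation (`popsim`)

Sampling is two-level. Population parameters are drawn multivariate
normal on a transformed scale — log for positive-constrained parameters,
mirroring standard NLME asymptotics — from the mean/covariance of the
uncertainty distribution, then back-transformed. Conditional on a
population draw, each subject's parameters are the population values
multiplied by log-normal random effects with the configured
inter-individual-variability (IIV) variances ω²; a diagonal IIV structure
is the default and a correlation matrix may be supplied. If an ω² name
appears among the uncertainty parameters, the drawn value is used, so
uncertainty about the IIV magnitude itself propagates.

Randomness discipline: one master seed. The population-level draw uses the
stream keyed `[seed, 1]`; subjects of population *p* use `[seed, 2, p]`.
Ensembles are therefore bit-reproducible and independent of the order in
which populations are later evaluated or parallelized.

The subject sample of each population is frozen before any dose is
evaluated (common random numbers), which makes the per-population
success-rate surface deterministic — a prerequisite for treating isobole
finding as a deterministic root-finding problem.

One-dimensional machinery: the effective dose of a monotone dose-response
curve is found by bisection (two bracket checks + n halvings = n + 2
evaluations; the midpoint of the final bracket is returned), and the
confidence level at a dose is the right-continuous empirical CDF of the
effective-dose ensemble evaluated there.

## Adaptive isobole search (`fastisoboles`)

The 2D generalization of bisection. Level-j lattices are dyadic:
(2^j + 1) doses per axis at normalized coordinates i/2^j.

1. Initialize at level 1: evaluate the nine nodes {0, max/2, max}².
2. Extract the isobole estimate from the current full-lattice matrix by
   marching squares with linear interpolation along cell edges.
3. Double the resolution; evaluate a new node only if its normalized
   Euclidean distance to the current estimate (measured to segments, all
   contour components) is strictly below the pre-refinement spacing 2^-j.
   Nodes outside the band keep bilinear surrogate values upsampled from
   the previous level — for a monotone surface these are on the correct
   side of the threshold, so the contour is unaffected away from the band.
4. Repeat until the discrete Fréchet distance between successive estimates
   falls below `tol` (default 2⁻⁷ normalized, one cell at the practical
   maximum resolution) or `max_iter` (default 6) is reached.

All distances are computed in normalized dose units (each axis divided by
its maximum dose) so the thresholds are meaningful when the two drugs have
different ranges. When contour extraction yields several components, all
are used for the refinement band but the longest is reported, keeping
spurious micro-components from derailing the search. If the nine initial
nodes all fall on one side of the target, one full-lattice refinement at
level 2 (25 nodes total) guards against an isobole hidden inside a single
coarse cell before the run is classified as "entire space efficacious" /
"entire space non-efficacious".

Convergence is measured with the *discrete* Fréchet distance (exact
dynamic program over vertex pairs); the polylines are dense relative to
the tolerance, so the discretization gap is immaterial. Contours are
canonically oriented (first vertex lexicographically before the last)
because the Fréchet distance is orientation-sensitive and an accidental
reversal between iterations would report an O(1) step. On the analytic
fixtures the estimate at iteration j stays within √2·2⁻ʲ of the
closed-form isobole, and the successive-step sequence decays
geometrically in envelope — the raw sequence oscillates by about a factor
of two as the contour alternately aligns with lattice nodes, which is why
the tests assert the envelope rather than strict monotonicity.

Cost: the evaluation band is one cell wide around a curve, so per-level
evaluations grow ~2× while the lattice grows ~4×; at j = 6 the built-in
fixtures need 10–12× fewer evaluations than the full 65² scan and the
malaria testbed about 9×. The exact factor depends on isobole shape and
curvature.

The algorithm assumes a monotone surface (one contour per level); like
bisection on a non-monotone function it can otherwise overlook the curve.
`check_monotonicity` probes a small lattice for a few populations and
reports any adjacent-node decreases beyond a tolerance; run it before
committing to a large ensemble.

## Aggregation (`aggregate`)

Each population's isobole, whose endpoints lie on the dosing-space
boundary, is closed into the failure polygon by walking the boundary
through the origin (inserting the corners (AMT1max, 0) / (0, AMT2max) when
an endpoint terminates on a far edge). A fresh uniform lattice — by
default twice the final search resolution — is classified against each
polygon: covered nodes are failures (coded 0) except nodes on the isobole
itself, which meet the target exactly and are coded 1 ("achieved or
exceeded"); the closure boundary along the axes stays 0, so the origin is
always a failure for a non-degenerate isobole. Degenerate runs contribute
constant fields (all-1 for "entire space efficacious", all-0 otherwise).
Averaging the binary fields over populations gives the confidence surface,
whose values are exact multiples of 1/n_pop; confidence-level isoboles at
any probability in (0, 1) are extracted from it by the same
linear-interpolation contour routine. On the stepwise surface, ties at the
requested level resolve by that interpolation rule — the extracted curve
lies within one aggregation cell of the true step.

`rank_parameter_influence` summarizes each population's isobole by the
area of its failure polygon in normalized dose space and reports the
Spearman rank correlation of each population parameter with that summary,
sorted by |ρ| — a cheap sensitivity analysis of which parameters move the
isobole most.

## Malaria-like testbed (`models`)

Structure per the combination-therapy setting: per drug a two-compartment
linear-elimination PK model with first-order absorption (single
simultaneous oral dose at t = 0), and a parasite population growing
exponentially and killed at rate

    k_kill(C1, C2) = e1 + e2 − e1·e2 / max(Emax1, Emax2),
    e_i = Emax_i C_i^{h_i} / (EC50_i^{h_i} + C_i^{h_i}),

a Bliss-independence rule normalized by the larger maximal effect so the
combination caps at max(Emax) and reduces exactly to a single drug when
the partner concentration is zero. Success is parasitemia below the limit
of quantification (10 parasites/ml) at day 28.

Because d log P/dt = k_grow − k_kill(C1(t), C2(t)) is linear in log P, the
endpoint is exactly log P(28) = log P0 + 28·k_grow − ∫k_kill dt, and the
concentrations have the standard closed tri-exponential form. The model
therefore evaluates ∫k_kill by composite 5-point Gauss–Legendre quadrature
(quarter-day panels over the absorption transient of the first two days,
half-day panels after), vectorized over subjects — no ODE solver in the
hot path. `simulate_individual` integrates the full ODE system (LSODA,
rtol 10⁻⁸ / atol 10⁻¹⁰) in log-parasitemia as an independent cross-check
and for trajectory output; the two paths agree to ~3×10⁻³ log₁₀ units.
Integrating in log space keeps the parasite count positive by
construction, so no positivity floor is needed and the quadrature and ODE
paths describe the same model.

Default parameters are hypothetical but plausible for long-acting
antimalarials (terminal half-lives ~22 and ~12 days, Hill coefficients
2.5–3, growth ≈ 1.15/day ≈ ten-fold per 48 h, baseline 10⁸ parasites/ml):
they are chosen once so that single-drug cures occur within the 0–800 mg
dosing window (~280 mg for drug 1, ~460 mg for drug 2 at the typical
subject) and the success-rate surface is monotone in each dose — which the
structure guarantees, since concentrations are linear in dose and
∂k_kill/∂e_i ≥ 0. They describe no specific compound, so headline numbers
(e.g. savings folds) are properties of this testbed, not of any published
model. The default study conditions in `default_malaria_config` put
log-scale standard errors of 5–12% on clearances, potencies, maximal kill
rates and growth, and log-normal IIV of 30% CV on clearances and 40% CV on
EC50s — magnitudes typical of a moderately informed popPK/PD fit.

Analytic fixtures (additive, Bliss, probit-additive) provide closed-form
surfaces and exact isoboles used as oracles for the search and aggregation
algorithms; the non-monotone bump family adds a localized Gaussian bump to
the additive surface to exercise the monotonicity checker's positive path.

## What the synthetic testbeds do and do not show

The generator reproduces the structural features the algorithms rely on:
hierarchical variability, monotone dose-response, isoboles that terminate
on the domain boundary. It does not emulate model misspecification,
covariate effects, non-monotone PD (e.g. paradoxical high-dose growth),
dosing schedules beyond a fixed single administration, or estimation noise
in the uncertainty covariance. Passing tests demonstrate the correctness
and economics of the algorithms under these assumptions, not the clinical
realism of the defaults.

## Numerical choices and sizes

- Dose resolutions: search depth j = 6 (65 per axis) by default,
  aggregation at 2·2^j + 1 nodes; the heavy end-to-end comparison uses
  n_pop = 25, n_subj = 200 at j = 4 against a full 17 × 17 brute-force
  scan, and the savings measurement uses 25 populations at j = 6.
- Bisection: bracket violations raise distinguishing "always" from "never"
  efficacious; evaluation count is exactly n_iter + 2.
- Ties and boundaries: polygon containment counts boundary as inside
  (`point_in_polygon`); success encoding overrides isobole nodes to 1;
  refinement uses strict `<` against the pre-refinement spacing.
- Serialization: CSV with `#` provenance headers, 17-significant-digit
  floats, `float_precision="round_trip"` on read — all outputs round-trip
  bit-exactly, and rerunning a seeded pipeline reproduces files
  byte-identically.

## Known limitations

- One isobole per level: non-monotone surfaces are out of scope beyond
  detection by `check_monotonicity`.
- Two drugs only; higher-dimensional combinations would need
  cross-sections.
- The success-rate objective is treated as exact for a frozen subject
  sample; finite-n_subj noise enters only through the sample itself, so
  small n_subj quantizes success rates in steps of 1/n_subj and can shift
  isoboles by up to that quantization.
- The parameter-influence ranking uses one scalar summary (failure-polygon
  area); parameters that deform the isobole without changing its area are
  invisible to it.
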