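# Methods

## Model

The continuation-ratio (CR) model describes a trinomial dose-response
(no response / efficacy without toxicity / toxicity) through two
logistic submodels: marginal toxicity `pT(d) = expit(a1 + b1 d)` and
conditional efficacy `pE|Tc(d) = expit(a2 + b2 d)`, with `b1, b2 > 0`.
The likelihood factorises, which has two consequences used throughout:

- the Fisher information of one observation is block diagonal in the
  parameter order `(a1, b1, a2, b2)`: a toxicity block
  `pT(1-pT) v v'` and an efficacy block `(1-pT) pE|Tc(1-pE|Tc) v v'`
  with `v = (1, d)'` — the `(1-pT)` factor reflecting that conditional
  efficacy is only observed in patients without toxicity;
- the maximum-likelihood fit splits into two independent binary
  logistic regressions.

The analytic block form is cross-validated in the test suite against a
Monte Carlo average of score outer products over 10^6 simulated
outcomes.

Target doses: the MTD solves `pT(d) = Γ` in closed form; the OBD
maximises `pi1(d) = pE|Tc(d)(1-pT(d))` over the study interval.
Literature conventions also require `a1 ≥ a2 < 0`; these are documented
but not enforced at construction, because realistic nominal sets
(including the worked example used in the tests) violate the first
inequality while remaining perfectly valid dose-response curves.  Only
slope positivity is enforced.

## OBD and its gradient

`obd()` uses a deterministic 1001-point grid followed by bounded scalar
refinement to an absolute tolerance of 1e-6.  The grid guards against
multimodality (possible only in pathological corners); the refinement
makes the result grid-independent.  If `pi1` is monotone the interval
boundary is returned.

The c-optimality criterion needs `c = ∂OBD/∂θ`.  Interior optima
satisfy `h(d, θ) = b2 (1 - pE|Tc(d)) - b1 pT(d) = 0` (the derivative of
`pi1` divided by its positive prefactor), so the implicit function
theorem gives `c_j = -(∂h/∂θ_j)/(∂h/∂d)` with fully analytic partials.
Two exact identities — dose-shift invariance
(`-b1 c_a1 - b2 c_a2 = 1`) and dose-scale invariance
(`b1 c_b1 + b2 c_b2 = -OBD`) — are property-tested over random
parameter draws.  A boundary OBD has no two-sided gradient; the
c-optimal search then aborts with an explicit error rather than using a
one-sided derivative.

## Design criteria and numerical conventions

`d_criterion` returns `-ln det M`; `c_criterion` returns `c' M⁻¹ c` via
a linear solve (pseudoinverse only when `M` is singular but `c` lies in
its range).  Singular information — e.g. fewer support points than
needed — yields `+inf` rather than an exception, so the PSO objective
is total on its search box.  The block structure reduces both criteria
to 2×2 determinants and solves; the batched kernels used inside the
search are tested to agree with the scalar path to 1e-10.

## PSO search

Particles encode a design as a `2k`-vector: `k` doses in the design
interval plus `k` weight scores in `[0, 1]` normalised onto the simplex
(an all-zero score vector maps to uniform weights).  `k` defaults to 4,
the number of parameters; support points a criterion does not need lose
their weight and are merged/dropped by `collapse_design` (merge
tolerance 0.05 dose units, drop tolerance 1e-3 weight).

Swarm updates follow the standard position/velocity recursions with
cognitive weight 2.5, social weight 0.5, 25 particles and 700
iterations.  The inertia follows a power-law decay with relaxation
exponent 1.5, rescaled affinely to run from 0.9 to 0.4 — the raw power
law would run from 1 to 0, which contradicts the intended endpoints.
Velocities start at zero and are clipped to 20% of the box width;
positions leaving the box are clamped with the offending velocity
component zeroed.  Five independently seeded restarts guard against
stalls on the c-criterion's flat regions; all randomness flows from one
master seed through `numpy` `SeedSequence` spawning, making runs
bitwise reproducible.

On the worked example all four design problems converge to
equivalence-theorem certificates with maximum sensitivity below 1e-6,
far inside the 1e-3 acceptance tolerance.

## Optimality certificates and the grid oracle

For the D-criterion the sensitivity function is
`φ(d) = tr(M⁻¹ μ(d)) - 4`; for the c-criterion
`φ(d) = (c'M⁻¹μ(d)M⁻¹c)/(c'M⁻¹c) - 1`.  A design is certified when
`φ ≤ tol` on a 1001-point grid (support doses are inserted into the
grid so they are checked exactly) and `|φ| ≤ tol` at every support
dose; `tol` defaults to 1e-3, decisive at the two-decimal reporting
precision of the designs.

An independent check, `grid_oracle`, runs a multiplicative-weight
(Fedorov–Wynn/Titterington) algorithm on a fixed 1001-point grid:
weights are rescaled by `ψ(d)/4` (D) or by the square root of the
normalised quadratic form (c) and renormalised, for 5000 iterations.
After finitely many iterations the mass still straddles a short run of
adjacent grid points around each true support dose, so the oracle's
collapse step merges clusters up to 0.25 dose units wide (the PSO
output, which concentrates exactly, keeps the tighter 0.05 default).
PSO and oracle criterion values agree to better than 1e-5 relative on
all four worked-example problems.

## Exact designs and trial simulation

`round_design` apportions weights by the efficient rounding rule
`count_i = ceil((n - K/2) ρ_i)`, adjusted to sum to `n` by decrementing
the largest `count_i/ρ_i` (or incrementing the smallest), ties to the
lower dose.  Naive nearest-integer rounding fails to hit `n` exactly
for weights like (0.409, 0.182, 0.409) at `n = 40`; efficient rounding
reproduces the natural 16:8:16 split.  Its deviation guarantee is
`|count_i - n ρ_i| < 1` whenever `(K/2) max ρ ≤ 1` (always true for the
designs here); the general divisor-method bound
`(K/2) ρ_i + 1` is what the property tests assert.

Simulated trials draw each patient's outcome from the trinomial at
their dose.  Refitting uses the factorised likelihood: two aggregated
binomial logistic regressions (IRLS via statsmodels, 100 iterations,
tolerance 1e-10).  A fit is **undetermined** when either regression
fails, does not converge, or yields a linear predictor beyond ±30 at an
observed dose (the practical signature of complete or quasi-complete
separation); an estimated toxicity slope that is non-positive — or
numerically zero, below 1e-8 — also leaves the MTD formula meaningless
and reclassifies the replicate.  Undetermined replicates are excluded
from bias/SD/RMSE and reported as `Pr(NoMLE)`.  The MTD estimate is the
raw percentile formula, deliberately not truncated to the study
interval; the OBD estimate is an interval-constrained argmax and is
always inside the study range.  SD uses the population convention so
`RMSE² = bias² + SD²` holds exactly.  Replicate `r` of a run with seed
`s` uses the substream `(s, r)`, so any single replicate can be rerun
in isolation.

### What the simulation does and does not show

With `n = 40` and realistic toxicity rates, separation is not an edge
case: it affects roughly 12% of replicates under the three-dose
D-optimal design and the majority under the two-dose c-optimal designs
(e.g. zero toxicities at the lower dose).  Bias/SD/RMSE summaries at
this sample size therefore depend materially on the undetermined-MLE
rule; under the rule above, `Pr(NoMLE)` is large for designs whose
lower doses rarely produce events, and the retained estimates still
include heavy-tailed MTD extrapolations from near-flat fitted toxicity
curves.  Published summaries computed with a different (unreported)
handling of such boundary fits are not directly comparable entry by
entry.  The asymptotic comparisons are unaffected: at `n = 4000` the
fitted parameters are unbiased to Monte Carlo precision and the RMSE
contracts as theory predicts, which the test suite checks.

The generator simulates exactly the model assumed by the design theory
— no dropout, no dose-allocation errors, no model misspecification, no
adaptive re-allocation — so passing tests demonstrate internal
consistency of design, fitting and asymptotics, not robustness of the
designs to violations a real trial would face.

## Problem sizes

Defaults were chosen to make every computation a desk-scale run: PSO
uses 25×700×5 criterion evaluations per design (seconds via the batched
kernels), the grid oracle 5000×1001 updates, and operating
characteristics 1000 replicates of 40 patients (about ten seconds per
design).  The consistency checks use 400–1000 replicates at up to
`n = 4000`.

## Known limitations

- Locally optimal only: all designs condition on nominal parameters;
  no Bayesian/minimax robustness over parameter uncertainty.
- Single scalar dose, monotone toxicity; no covariates or alternative
  response families.
- The undetermined-MLE rule is one reasonable operationalisation;
  small-sample operating characteristics are sensitive to it (see
  above).
- `find_design` with `k` well above the true support size relies on
  `collapse_design` to merge duplicates; extremely small criterion
  differences between merged and unmerged supports are resolved by the
  collapse tolerances, not by the optimiser.
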