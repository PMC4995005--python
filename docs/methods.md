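# Methods

This note records the statistical model, the numerical choices and the
known limits of the pipeline, in the order the data flow through it.

## Isotope mass balance

Respired CO₂ from an amended microcosm is treated as a two-endmember
mixture of native soil carbon and labelled residue carbon. Writing Rt
for the total flux in an interval and A¹³ₜ for its ¹³C abundance, the
carbon and ¹³C balances solve to

    Rr = Rt · (A¹³t − A¹³s) / (A¹³r − A¹³s),   Rs = Rt − Rr.

Any consistent abundance scale works (atom % by convention here); the
endmembers must differ by more than a configurable ε (default 10⁻⁶).
Measurement noise can push A¹³ₜ slightly outside the endmember
interval, producing a negative component; such solutions are clamped to
zero, flagged (`clamped`), and the pair rescaled so Rs + Rr = Rt. The
alternative — discarding the cell — is available by filtering on the
flag; clamping was chosen so that a noisy real dataset still runs end
to end while keeping an audit trail.

The priming effect is the ratio PE = Rs,amended/Rs,control, computed by
pairing amended replicate *u* with control replicate *u*. Index pairing
is deterministic and keeps replicate noise in both numerator and
denominator; a replicate-mean denominator is available
(`pe_pairing="mean"`) for designs where replicates are not aligned.
Cells with Rs,control ≤ 0 raise an explicit error rather than returning
an undefined ratio.

Responses for modelling are natural logarithms of interval-mean rates,
rate = ΔR/Δt over each interval of the sampling schedule (default 3, 7,
14, 21, 28, 44, 60, 80 days; the first interval starts at day 0).
Nonpositive amounts are excluded and counted.

## Diversity indexes

Richness, Shannon H′ (natural log; base configurable), evenness
J′ = H′/ln S (undefined at S = 1 and reported as NaN), inverse Simpson
1/D = 1/Σpᵢ². Zero-count OTUs are dropped everywhere (0·ln 0 := 0). No
rarefaction is applied — sequencing depth is carried through for QC
only — so indexes from samples at very different depths are not
directly comparable; that caveat travels with the data, not the code.

## The additive model

Each kinetic's log rate is modelled with a Gaussian additive model,
identity link (the log transform already stabilizes the variance):

    E(y) = α + Σⱼ fⱼ(xⱼ) + time.

* **Functional forms.** fⱼ is identity, an orthogonalized polynomial of
  degree 2 or 3 (orthogonal rather than raw powers purely for
  conditioning; fitted values are identical), or a penalized cubic
  regression spline. The spline uses the cardinal natural-spline basis
  on k knots placed at quantiles of the distinct covariate values
  (k = 5 by default — there are only 20 distinct site values per
  covariate, so a richer basis would be noise), the exact
  second-derivative penalty (rank k − 2), a sum-to-zero constraint
  absorbed by reparameterization, and linear extension beyond the
  boundary knots. The construction reproduces the reference
  implementation in R's mgcv (`bs="cr"`) to machine precision; the
  frozen comparison lives in the test suite.
* **Time as a random factor.** Sampling dates are temporal
  pseudo-replication, so time enters as per-date intercepts shrunk by a
  ridge penalty — the penalized-regression equivalent of a random
  intercept. The indicator columns are mean-centered so every model
  component averages zero over the training rows and the intercept is
  interpretable.
* **Land-use interactions.** A term may carry one basis copy per
  land-use level, each active only on its level's rows. Whenever any
  interaction is present the land-use main effect is added
  automatically: an interaction without its main effect would force
  both levels through a common centre, which is ill-posed.
* **Covariate standardization.** Covariates are z-scored on the
  training rows (per cross-validation fold) before basis construction;
  knots and polynomial maps are likewise training-fitted and reused at
  prediction time.
* **Smoothing selection.** The ridge weight for time and one curvature
  weight per spline are chosen by GCV (n·RSS/(n − edf)²), the
  historical default of the penalized-GAM ecosystem this design
  follows; REML (Gaussian, scale profiled out) is available via
  `GAMConfig(criterion="reml")`. Optimization is bounded golden-section
  for one penalty and Nelder–Mead on log λ for several, over
  precomputed cross-products, with log λ ∈ [−10, 16] and a λ floor of
  10⁻⁷ so the centered time indicators never make the normal equations
  singular. Search tolerances (`scalar_xatol`, `nm_maxfev_per_lam`) are
  deliberately modest: the GCV surface is flat near its optimum and
  prediction is insensitive to the last digits of λ.
* **Term tests.** Each block is dropped and the model refit; the F
  statistic uses the block's effective degrees of freedom as numerator
  df and n − edf as denominator df. For an unpenalized single-column
  term this is the exact F test (type-I error verified by simulation);
  for smooths it is the usual edf approximation. Significance codes:
  `***` ≤ 0.001 < `**` ≤ 0.01 < `*` ≤ 0.05 < `°` ≤ 0.1 < `ns`.

## Stepwise selection by cross-validated MSEP

The fold unit is an entire soil: all its dates, treatments and
replicates leave together, so predictions for a soil never see that
soil (smoothing parameters are re-optimized inside every fold from a
fixed start; the fold-hygiene perturbation test in the suite asserts
that changing a held-out soil's responses leaves its predictions
bit-identical). MSEP is the mean squared error over all held-out rows.

Two computational shortcuts keep the fold loop affordable without
changing its results. For models without spline terms, the fold's
normal equations are formed by subtracting the held-out soil's
cross-product blocks from the full-data ones; identity, polynomial,
land-use and time bases are affine families whose centering constants
are absorbed by the intercept, so this is algebraically identical to
rebuilding the design per fold (verified to ~1e−12 in the suite).
Spline models always rebuild per fold, because their knots are
quantiles of the training covariate values and must not see the
held-out soil. Second, single-penalty GCV profiles are minimized
exactly through the Demmler–Reinsch eigendecomposition (edf and RSS
become O(p) functions of λ), leaving iterative search only for models
with several penalties.

Each iteration: (1) MSEP of the current model; (2) VIF prescreen of the
remaining covariates against the selected ones — site-level rows, raw
covariate values, threshold 4; forms and interactions are properties of
terms, not covariates, so the screen ignores them; (3) candidate moves:
add one admissible covariate under each form (I, poly2, poly3, s), with
and/or without the land-use interaction (`interaction_mode` = both /
always / never; default both, since nothing forces an interaction), or
remove one selected term; (4) accept the best move only if its MSEP is
*strictly* smaller, else stop. Removed covariates return to the pool
and may re-enter. Enumeration order is fixed (covariates in config
order; forms I, poly2, poly3, s; plain before interacting) and ties are
broken by fewer effective degrees of freedom, then enumeration order,
so the whole procedure is deterministic.

A property of this accept rule worth knowing: the MSEP difference for
adding a *useless* site-level covariate has expectation ≈ +var(β̂)·E[x²]
but a standard deviation of the same order (the ratio is ≈ ½ regardless
of noise scale or design size), so each useless candidate has a ≈ 30 %
chance of showing a spurious CV improvement, and with tens of
candidates the search usually picks up one or two small-importance
terms under a pure null. The trace records every accepted move's MSEP
drop, so such terms are recognizable by their tiny improvements; a
one-standard-error-style acceptance margin would suppress them but is
deliberately not applied, because the strict rule is the procedure
being reproduced.

## Assessment

* **%Dev** = 100·(1 − RSS/TSS) for the Gaussian identity fit.
* **RPIQ** = IQR(y)/√MSEP with linear-interpolation quantiles (the
  quantile convention matters at n = 480 less than at n = 20, but it is
  fixed and documented here).
* **BIC** = n·ln(RSS/n) + edf·ln n, with edf the penalized fit's
  effective degrees of freedom — intended for *ordering* model
  families on the same data, not as an absolute quantity.
* **Relative importance.** The per-term columns of the linear predictor
  (time first, then terms in selection order) are the explanatory
  matrix of a redundancy analysis of the single response; each
  component is credited its sequential sum of squares over TSS × 100.
  Sequential attribution gives shared variance to the earlier
  component, which is why time — always first — absorbs the shared
  seasonal signal; a `marginal` mode (standalone R² per component) is
  available. Importances are nonnegative and, with the reported
  remainder, sum exactly to %Dev.
* **Kinetics ANOVA.** Two-way ANOVA per kinetic with land use fixed and
  time random: land-use and time mean squares are tested against the
  interaction mean square, the interaction against the residual
  (statsmodels supplies the sums of squares; type II when unbalanced).
  Tukey HSD letters compare sampling times; per-time land-use contrasts
  use Welch t tests. All significance codes as above.

## Synthetic experiments

The generator emulates the incubation design: 20 soils (10 cropland,
10 grassland), 2 treatments × 3 replicates × 8 dates. Covariates are
drawn per land use from multivariate normals whose bacterial and fungal
diversity blocks share a configurable correlation (default 0.8 —
diversity indexes of one organism group are strongly intercorrelated in
real surveys); sand closes the texture triplet to 1000 g/kg and
clay+fine-silt is derived from clay and silt, so the texture block
carries realistic near-collinearity for the VIF screen to bite on.
Grassland soils get a higher mean bacterial 1/D (the clearest land-use
contrast in such surveys) and slightly higher SOC and biomass. Index
invariants (J′ ∈ [0,1], 1 ≤ 1/D ≤ S, H′ ≤ ln S) are enforced by
clipping after the draw — the indexes are simulated summary statistics,
not derived from a common community, so they satisfy the invariants
without being mutually consistent the way indexes of one OTU table
would be.

Kinetics are double-pool first-order decays (fast + slow) for both soil
C (defaults 150 µg/g at 0.08 d⁻¹ + 6000 µg/g at 0.0015 d⁻¹) and residue
C (600 µg/g at 0.15 d⁻¹ + 900 µg/g at 0.004 d⁻¹) — the simplest shape
giving the observed monotone rate decline over 80 days. Injected
covariate effects (linear / centered quadratic / Hermite cubic / sine,
amplitude in ln units per covariate SD, optionally sign-flipped by land
use) multiply the rates; the amended soil flux additionally carries a
priming multiplier (default 1.2). Interval amounts get independent
multiplicative lognormal noise (σ = 0.15 by default — replicate CVs of
10–20 % are typical of microcosm respirometry; the log-scale responses
then have additive Gaussian noise, which is exactly the model's
assumption). The amended ¹³C abundance is computed as the exact
abundance-weighted endmember mix of the realized components (endmembers
1.08 / 3.0 atom %), so partitioning inverts the generator to rounding
error; this checks the mass-balance algebra, not robustness to isotopic
measurement error, which the generator deliberately does not put on
A¹³ₜ.

What passing on synthetic data does **not** show: robustness to
isotopic measurement error on A¹³ₜ, non-lognormal noise, missing design
cells, or covariate measurement error. Those enter real datasets
through the clamping/exclusion paths, which are exercised separately.

OTU tables with target (richness, J′) use a geometric abundance series
whose decay parameter is found by bisection; counts are multinomial at
the requested depth, and `depth=None` returns the exact expected
composition.

## Problem sizes used in the checks

The acceptance script runs the full pipeline at the study's design size
(480 rows per response) over the complete 16-covariate pool with all
four forms and land-use interactions searched. The operating-rate
simulations (selection power and null behaviour, test-calibration
sweeps) use 50–1000 seeded replicates with a 10-covariate pool and no
interaction search — sizes chosen so the whole suite stays in the
tens-of-minutes range on one CPU while keeping Monte-Carlo error well
below the asserted margins.

## Known limitations

* Gaussian identity-link models only; no non-normal families, tensor
  smooths, or autocorrelation beyond the random time factor.
* The greedy search can land in local minima; the exhaustive-search
  comparison in the tests bounds the gap on small model spaces only.
* VIF screening at 20 site-level rows is itself noisy; the threshold 4
  is the conventional one, not an estimated quantity.
* BIC for penalized fits uses edf heuristically; treat differences of a
  few units with caution.
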