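# Methods

## Data model and units

A degradation experiment is a `DegradationSeries`: sampling times in
minutes (strictly increasing, starting at t = 0) and concentration ratios
C/C₀ in (0, 1] with the t = 0 ratio pinned at exactly 1.  C₀ is the
concentration after the dark-adsorption equilibrium, so the ratios already
discount adsorption; the package never renormalizes them.  Readers accept
seconds/hours and convert on ingest; a missing t = 0 row is prepended with
ratio 1 and a warning rather than rejected, since instruments commonly omit
the trivial point.  The composition label x (Cd fraction in the spinel
lattice, 0–0.5) is carried as an abstract real; nothing in the fitting
depends on its chemical interpretation.

The reference study's printed tables are packaged as CSV fixtures and load
through `load_fixture`: six 8-point concentration series, the textural
descriptors (BET surface area, pore volume/diameter), the printed kinetic
transforms with their rate constants, and the band gaps (1.62–1.87 eV).
They are verification inputs: fixture values are compared against, never
fitted to.

## Kinetic model family

Three nested descriptions of a decay curve:

* first order, ln(C/C₀) = −k₁t;
* pseudo-n-order, C/C₀ = [(n−1)kₙt + 1]^(−1/(n−1)), n > 1, which
  degenerates to the exponential as n → 1 (the law is singular at n = 1
  exactly, so fits flag arrival at the lower bound instead of crossing it);
* the quadratic-log ("modified") law ln(C/C₀) = −a₁t + a₂t² = −a₁t(1−αt),
  whose increment α = a₂/a₁ (min⁻¹) measures departure from first order.

**Estimator conventions.**  The integrated first-order law has no
intercept, so the default estimator regresses ln ratio on t through the
origin (closed form −Σty/Σt²).  An OLS-with-intercept variant and a
nonlinear fit of exp(−k₁t) to the ratios are provided because the three
answer different questions (diagnostics of a nonzero intercept; weighting
in concentration rather than log space).  On the reference tables the three
estimators differ by up to ~60% at x = 0.5 and none reproduces the printed
rate constants exactly — the estimator behind those is unstated, so printed
k₁ values are treated as reference inputs and compared with relative
deviations, not asserted.  Reported correlation is the magnitude of
Pearson's R of the linearized point cloud including the origin.

The quadratic-log fit solves its 2×2 intercept-free normal equations in
closed form; degenerate time grids surface as a singular determinant.  The
pseudo-n-order fit minimizes summed squared ratio residuals with one shared
n and a per-series kₙ, bounded n ∈ (1, 5], multi-started from
n₀ ∈ {1.2, 1.65, 2.5} (deterministic — no random restarts).  The joint fit
over the six reference series lands near n ≈ 3.5: the printed curves drop
fast early and flatten late, which a shared-order law can only express
through a high order.  The reference analysis quotes n ≈ 1.65 without
stating the regression's dataset or residual space; we could not reproduce
that value under ratio-space or log-space residuals, per-series or jointly,
and therefore report the joint estimate without asserting the quoted one.

Degradation percentage is 100·(1 − C/C₀) at the final sampling time
(180 min in the reference grid).  The intrinsic rate divides k₁ by total
catalyst area: surface area (m²/g) × load (g/L) × volume (L), defaulting to
the study conditions 1 g/L and 0.030 L.

## Intra-diffusion model

When intra-particle transport limits the kinetics, ln(C/C₀) = −K_d√t.  K_d
comes from the intercept-free slope on √t (closed form −Σ√t·y/Σt), honoring
the law's zero intercept; a boundary-layer intercept (the classical
Weber–Morris diagnostic) is outside this model.  The characteristic time
τ = 1/K_d² and K_d = 1/√τ are exact reciprocal identities, enforced to
machine precision.

Across compositions, τ(x) = τ₀·e^(−θ(x−x₀)) per domain, fitted as a line on
(x, ln(τ/τ₀)) with θ the negated slope and x₀ the line's root; θ ≤ 0 is
flagged as non-decaying with x₀ undefined.  τ₀ defaults to the τ observed
at the smallest x — the initial maximum the decay starts from — rather than
a free parameter.  The implied rate constant K_d(x) = K_d0·e^(+θ/2·(x−x₀))
with K_d0 = 1/√τ₀; the positive half-exponent is forced by the duality
(τ falling ⇒ K_d rising) and round-trips exactly with evaluating τ(x) and
taking 1/√τ.

**Domain membership.**  Default domain edges are x = 0.2 and 0.3, the
boundaries the reference analysis identifies.  On a six-point composition
grid a closed-open middle domain would hold a single point, so for fitting
each domain includes both its edge compositions (the shared boundary point
anchors the two-point middle domain), while prediction assigns each x to
exactly one closed-open domain.  Predictions outside the fitted range warn
and extrapolate with the nearest domain.

**Segmentation.**  `segment_domains` searches 2-breakpoint piecewise-linear
fits exhaustively: candidate breakpoints are midpoints of consecutive
observed x, each segment needs ≥ 2 points, total residual sum of squares
decides, ties go to the earliest breakpoints.  Exhaustive search is exact
and deterministic at these problem sizes (≤ ~20 points); automatic
breakpoint selection stays opt-in for the analysis because six points
over-fit easily.  On the reference ln k₁ values the single admissible
partition puts the breaks at 0.15 and 0.35, bracketing the reported domain
edges.

## Arrhenius propagation

With ln k₁(x) approximately linear in x (slope ε), differentiating
ln k₁ = ln A − E_a/(RT) in x and integrating gives
E_a(x) = E_a0 + RT[(ln A(x) − ln A₀) − εx].  Substituting back reproduces
ln k₁(x) = ln k₁(0) + εx identically — the module's invariant.  ε defaults
to 4.9; the least-squares slope of the printed rate constants reproduces
that value (4.900), and `epsilon_from_lnk` recomputes it from any fitted
set.  No multi-temperature data exist, so absolute (ln A₀, E_a0) levels are
user-supplied and only shifts are meaningful; T defaults to 293.15 K, the
study's bath temperature.

## Band-gap extraction

Diffuse reflectance (fraction in (0, 1]; percent input auto-detected above
1.5 and rescaled with a warning, since a true fraction cannot exceed 1)
passes through the Kubelka–Munk transform F(R) = (1−R)²/(2R) and the Tauc
ordinate (F·hν)^(1/n) with n = 1/2 for direct-allowed transitions (3/2, 2, 3
supported).  Energies come from E[eV] = 1239.84193/λ[nm].

The linear edge window is chosen automatically: all contiguous windows of
at least 5 points starting at or above the edge onset are scored by R², and
the widest window within 10⁻³ of the best score wins; its abscissa
intercept −b/m is the gap.  The onset anchor is the first point where a
5-point-smoothed derivative of the transformed curve reaches half its
maximum.  On noiseless data this coincides with the first maximum-slope
point (the derivative is constant across the linear region); under noise it
is far more stable than the raw argmax, which wanders across the linear
region and can strand the search on a few high-energy points, and the
widest-near-optimum rule counters the known bias of raw R² maximization
toward very short, accidentally well-fitting windows.  Explicit window
bounds override the search.  A window with non-positive slope means no
absorption edge and raises.

The reference band gaps exist only as figure annotations (no tabulated
spectra), so extraction is validated on synthetic edges: noiseless recovery
is better than 10⁻³ eV across 1.6–1.9 eV, and the median absolute error
under 1% multiplicative reflectance noise is ~3 meV over 50 seeds.

## Synthetic data

`simulate_series` evaluates any of the four laws on the study's sampling
grid {0, 10, 20, 30, 60, 90, 120, 180} min (the default, so synthetic and
fixture analyses are directly comparable).  Noise defaults to multiplicative
lognormal on ratios — concentration readings are positive with roughly
proportional error — with truncated additive Gaussian as an alternative;
either is clipped back into (0, 1], the t = 0 point is never perturbed, and
the empirical coefficient of variation matches the requested scale (tested
at 20% tolerance over 1000 draws).  Seeds are mandatory; identical seeds
give identical series.

`simulate_reflectance` runs the extraction backwards: the Tauc ordinate is
exactly A₂(hν − eg) above eg + w, blends C¹-smoothly (quadratically) to zero
across ±w around the gap, and vanishes below; inverting Kubelka–Munk yields
R(hν) on a 200–800 nm grid (3 nm step, ~200 points).  A₂ is set so the
deep-absorption reflectance plateau equals the `baseline` parameter
(default 0.13, the 13–15% plateau regime of the reference instrument), and
the curve relaxes toward transparency below the gap.  `simulate_tau_profile`
evaluates the piecewise exponential τ(x) law.

What the generators do not emulate: instrument drift, heteroscedastic HPLC
error at low concentrations, adsorption–desorption transients, scattering
backgrounds or Urbach tails in the spectra.  Passing recovery tests
therefore demonstrate estimator correctness under the stated noise models,
not robustness to every artifact of real instruments.

## Numerical choices

* Nonlinear fits use bounded trust-region least squares with
  xtol = ftol = gtol = 10⁻¹⁴ so noiseless round trips recover parameters to
  ≤ 10⁻⁸ relative error.
* Closed forms are used wherever they exist (through-origin slopes, 2×2
  normal equations, reciprocal identities) and cross-checked in the test
  suite against independent generic linear algebra.
* Ties in discrete searches break deterministically (earliest breakpoints;
  widest Tauc window).
* Forward evaluation of any law clips predictions back into (0, 1] with a
  warning when parameters push them out (e.g. the quadratic law past
  t = a₁/a₂); `clip=False` returns raw values.

## Known limitations and open points

* The printed first-order rate constants are not reproducible by standard
  regressions on the printed series (deviations ~10–20% depending on the
  estimator); their generating convention is unknown.  They are shipped as
  reference inputs, and the enhancement factor (13.5×) is computed from
  them directly.
* The reported deviation increment α decreases with doping except at
  x = 0.4, whose series is visibly the noisiest; the strict-monotonicity
  property holds for k₁, a₁, K_d (increasing) and τ (decreasing) but not
  for α on the reference data.
* The printed removal percentages for x = 0.1 and x = 0.4 are one
  last-digit unit off their own concentration table, as is one printed
  ln(C/C₀) entry (x = 0, t = 180); comparisons allow ±1 unit at printed
  precision.
* Per-domain (θ, x₀) values and the x = 0 Arrhenius parameters are not
  available in the reference text, so those paths are property-tested
  (exact recovery from synthetic truth) rather than value-tested.
* Langmuir–Hinshelwood saturation kinetics, film-vs-pore diffusion
  attribution, multi-stage Weber–Morris fits within one time series, and
  Urbach-tail modeling are out of scope.
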