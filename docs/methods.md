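# Methods

## Model

`sigmacomp` treats the partition of core RNA polymerase (E_c) among N sigma
factor species as a quasi-steady-state binding problem.  The cell is a
well-mixed volume V (default 1.32 fL); abundances are copies per cell at the
interface and molar internally, converted by n = C·N_A·V.  For each species

    K_i = [E_free][sigma_i,free] / [E sigma_i]

holds together with one conservation law per sigma species and one for core.
All layers reduce to a single scalar unknown, the free core concentration x:

* every species' free sigma follows from x in closed form (a quadratic when
  an anti-sigma factor with its own conservation law is present);
* non-specific DNA binding multiplies each free pool by 1 + D/K_NS under the
  excess-sites approximation (D ≈ 3.8 genome equivalents × 4.6 Mbp sites;
  free sites ≈ total sites, justified because D ~ 10^7 far exceeds the ~10^4
  molecules that could occupy them);
* the core conservation residual is strictly increasing in x, so the root in
  [0, E_c,tot] is unique and found by Brent's method at relative tolerance
  ~1e-15 (≤ 200 iterations).

Degenerate inputs (zero core or zero sigma) return the exact all-zero
holoenzyme state.  kd = 0 is rejected everywhere; the strong-binding limit
is exposed explicitly (`holoenzyme_strong_limit`, `strong_binding_partition`)
because the ratio law 0/0 is otherwise ill-defined.  The single-species
holoenzyme level uses the cancellation-free quadratic form
h = 2cs/(b + sqrt(b² − 4cs)), b = c + s + K, stable down to K twelve orders
below the totals.

## Transcription and the sigma cycle

Initiation is Michaelis–Menten in the free cognate holoenzyme h:
rate = kmax·[P]·h/(K_M + h).  Multi-step initiation schemes (closed/open
complex, abortive rounds) map onto the same form with
K_M = (koff_p + kinit)/kon_p, kmax = kinit; promoters with kinit well below
koff_p are "saturated" at cellular holoenzyme levels and thereby insulated
from sigma competition.  Non-transcribing holoenzymes that bind a promoter
repress it through competitive single-site occupancy,
rate ∝ (h/K_M)/(1 + h/K_M + Σ r/K_rep).  This standard occupancy form is an
interpretive choice: it treats repressor binding as equilibrated and does
not count the repressor's own sequestration on the shared promoter.

Transcript elongation feeds back on the competition in two ways:

1. **Sequestration.**  Each occupied promoter holds one holoenzyme; each
   initiation commits a core for tau_c = L_op/v seconds and a sigma for
   tau_sigma = L_ret/v (separate release) or tau_c (release as holoenzyme).
   Steady-state sequestered pools are flux × residence (Little's law).
   Stochastic sigma release is represented by its mean retention length
   only, consistent with the deterministic steady-state treatment.
2. **Effective affinity.**  With separate release, initiation is an extra
   sigma–core separation pathway on top of spontaneous unbinding, giving
   K_eff = K + alpha/(k_on·h) where alpha is the initiation flux per volume.
   At the steady state of the explicit kinetic scheme this relation is exact
   (k_on·E·sigma − k_off·h = alpha), which the ODE oracle tests confirm;
   with release as a holoenzyme K_eff = K.

The cycle is solved by damped fixed-point iteration (default damping 0.5)
alternating (a) the inner equilibrium with sequestered pools removed and
K_eff substituted, and (b) recomputation of occupancies, fluxes and
sequestration, until all pools change by < 1e-9 relative.  Promoter-bound
complexes are updated through the finite-pool quadratic (holoenzymes
available to a class = free + currently bound, partitioned against the
promoter sites at effective K_M) — identical to the Michaelis occupancy at
the fixed point but bounded during iteration, which keeps scarce-sigma
scenarios stable.  If the iteration still oscillates (strong K_eff feedback),
the damping factor is halved every 500 unconverged iterations before the
solver gives up with a diagnostic.

## Competition analysis

The competition onset is the smallest control value (typically the
alternative sigma total) at which the housekeeping holoenzyme falls to 95%
of its reference level; the 5% threshold is a named, configurable constant.
The criterion is applied to free holoenzymes when non-specific binding or
elongation perturb the pools, and to totals in the bare binding model (where
they coincide).  The crossing is bracketed on a log grid and refined by
Brent bisection to relative 1e-6.  A separate `start` argument marks the
operating point: when the criterion is already violated there (housekeeping
sigma in excess of core, where any competitor bites immediately), the onset
is reported at `start` with a flag.

Sensitivity is the logarithmic response factor R = d ln(rate)/d ln(x),
computed as second-order finite differences of log rate on a log grid
(default 200 points, so R is a plain slope) and, for maxima, refined on the
derivative of a cubic spline in log–log space by bounded scalar
minimization.  R > 1 is hypersensitivity.  A necessary (not sufficient)
condition for an interior maximum of the response to core availability is
that the alternative sigma pool be strictly smaller than the housekeeping
pool (equality counts as false).

### Stringent-response preset

A rapidly growing cell (2.5 doublings/h) holds 11400 core RNAPs: 1100
immature, 2600 on rRNA operons, 700 on mRNA, 7000 free or non-specifically
bound.  rRNA shutdown leaves 11400 − 1100 = 10300 cores available (7700
before).  Available sigma70 is set to 9000 (total sigma70 minus the fraction
sequestered by its anti-sigma factor) and sigmaAlt to 5000; both promoter
classes use K_M = 10 µM (unsaturated, the regime in which passive
up-regulation can be hypersensitive).

The preset's sigma–core dissociation constants are not fixed by any single
measurement; the package adopts K_70 = 1 nM and K_Alt = 4 nM.  This choice
keeps both constants at the experimentally observed nM scale with the
housekeeping factor binding more tightly, and it is the regime in which the
scenario's qualitative features hold together: the response factor peaks
above 1 (≈1.4) near E_c = sigma70 = 9000, the competition stripe spans both
the exponential-growth and stringent core counts, and the stripe's upper
edge sits at the total sigma pool (≈14000 cores).  A much steeper hierarchy
(e.g. the ~16-fold in-vitro spread between the housekeeping and stationary
phase factors) raises the peak response (≈2.7) but pulls the stripe's upper
edge well below the total sigma pool; both constants are plain fields on
`StringentScenario` for users who want that regime.

## Fitting

Titration fits are unweighted nonlinear least squares (`scipy.optimize.
least_squares`) over log10 of the constants, multi-started from a log grid
(1e-12…1e-6 M) to avoid the local minima of the saturating regime;
boundary-pinned estimates and degenerate designs (no variation in x or y)
are flagged rather than raised.  Binding curves are normalized by the
model's own plateau (all cores bound), not by a fitted amplitude;
transcription curves by the rate at that plateau.  Standard errors use the
heteroscedasticity-robust sandwich estimator, since assay noise scales with
signal and the classical s²(JᵀJ)⁻¹ form understates the estimator's spread
there (interval coverage in the recovery tests confirms the calibration).

Relative-affinity fitting from equimolar mixes uses the strong-binding
partition (all kds → 0 at fixed ratios) as the forward model, so only kd
ratios enter and the gauge property — rescaling all constants leaves
predictions unchanged — is exact.  This matches the regime of nM constants
at hundreds-of-nM assay concentrations; the general solver with scaled-down
absolute constants reproduces the same partition in the tests.

## Synthetic data

The generator emulates equilibrium in-vitro titrations: fixed core
(default 400 nM), one species or an equimolar mix titrated over a log grid,
readout proportional to signal.  Noise is multiplicative Gaussian,
y → y·(1 + ε), ε ~ N(0, sd²) truncated at ±3 sd — truncation keeps the noise
unbiased and the readout within [0, 1 + 3·sd].  Default recovery-test
conditions: 24 design points over 5 nM–2 µM, 1–2% noise, explicit seeds
everywhere (no global random state).  The generator shares the forward
model with the fitters by construction, so recovery tests demonstrate
estimator correctness and calibration, not robustness to assay artifacts
(baseline offsets, band saturation, correlated pipetting errors are not
modeled).

## Validation strategy

The scalar-root and fixed-point solvers are checked against an independent
oracle: explicit mass-action rate equations (binding, anti-sigma,
site-resolved non-specific binding, promoter complexes and staged
elongation) integrated to stationarity with a stiff ODE solver, agreeing to
1e-6 relative (free binding) and 1e-4 (full cycle) on randomized small
instances.  Closed forms (proportional allocation, rescaling property,
ratio law, power-law response factors) serve as exact anchors.  Test and
acceptance problem sizes (20 random oracle instances, 200-point scans,
50-seed recovery batches) are chosen to exercise every regime while keeping
the full suite under a minute of compute.

## Known limitations

* Quasi-steady state only: no time courses, no sigma-factor synthesis or
  degradation, no pulsing dynamics.
* Non-specific site depletion is not modeled (excess-sites approximation is
  hard-coded), and free sigma factors do not bind DNA non-specifically.
* Repressor holoenzymes occupy shared promoters without being counted as
  sequestered there.
* Retained sigma on an elongating complex is assumed invisible to anti-sigma
  factors.
* The relative-kd fitter assumes the strong-binding regime; far from it,
  absolute constants become identifiable and the gauge property is only
  approximate.
* ppGpp mechanics, polymerase traffic/collisions and premature termination
  are out of scope.
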