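# Methods

This note records the models, numerical choices, and synthetic study
conditions behind `claysorb`, and what the test suite does and does not
establish about real data.

## Batch isotherms and mass balance

A batch adsorption experiment mixes a nucleotide solution (initial
concentration C0, volume V) with a mineral powder (mass m); after
equilibration the supernatant concentration Ceq is measured by UV/vis
spectrophotometry.  The adsorbed quantity follows from mass balance,

    q = (C0 - Ceq) V / m        [mol/g],

an identity that holds to machine precision by construction and is asserted
as such.  Spectrophotometric calibration is Beer-Lambert linear
(C = A / (eps * l)); when a multi-point standard curve is supplied, eps is
re-estimated by a closed-form line-through-origin least-squares fit.
Linearity is assumed over the 0-3.5 mM working range, the standard
spectrophotometric regime; no correction is applied for absorbance shifts of
nucleotide-metal complexes.  Negative adsorbed quantities (Ceq > C0) are
reported with a warning, never clipped: silently clipping would bias
isotherms near zero coverage and hide desorption or measurement errors.

Replicates are matched on identical C0 and solution conditions (1e-9
relative tolerance) and aggregated to mean +/- sample standard deviation.
Internal units are fixed (mol/L, L, g, mol/g); conversions happen only at
the I/O boundary, and all floats are serialized with 17 significant digits
so every text artifact round-trips bit-identically.

## Normalization and the collapse score

Two coordinate changes make isotherms comparable:

* **Solubility reduction** — x = Ceq / S with S the solute's molar
  solubility at the experiment temperature.  Homologous molecules adsorbing
  by a common mechanism superimpose on this axis.  The molar convention at
  experiment temperature is adopted throughout; solubilities are
  user-supplied per nucleotide, and the values shipped with the synthetic
  generators are placeholders for testing, not literature data.
* **Areal density** — d = q / SSA_basis with basis total, basal, or edge
  (lateral) specific surface area in m^2/g.  Only the basis that actually
  carries the adsorbate collapses curves across grain sizes and minerals;
  for nucleotides on phyllosilicates that is the edge area.

Superposition is quantified by the **collapse score**: each curve is
interpolated (monotone piecewise-linear, never extrapolated) onto a common
log-spaced grid restricted to the shared support, and the score is the mean
over grid points of the cross-curve coefficient of variation (sample sd /
mean).  The score is dimensionless and invariant to a common rescaling of
all curves, so per-gram and per-area families can be compared directly;
identical curves score 0.  Higher-order interpolation was rejected because
sparse, noisy isotherms make overshoot likely.

Plateau (saturation) densities are the mean +/- sd over the top quarter
(`tail_fraction = 0.25`) of the abscissa range; a relative spread above 0.1
flags "no plateau".  Both thresholds were set by matching visual plateau
judgement on synthetic saturating curves and are configurable.

## Langmuir models

Two variants are fitted side by side:

* classic: q = q_max K C / (1 + K C), K in L/mol;
* modified (solid/liquid): q = q_max K_ML C / (C_s - C + K_ML C) with C_s
  fixed to the solute solubility and K_ML dimensionless, so that
  dG0 = -R T ln K_ML is convention-free.  The modified form reduces to the
  classic one with K = K_ML / C_s for C << C_s and degenerates to the linear
  partition q = q_max C / C_s at K_ML = 1; both limits are tested.  C_s is
  never co-fitted: it is an independently known constant and joint
  estimation is ill-conditioned.

Fitting is weighted nonlinear least squares (weights 1/sd when replicate sds
exist), with positivity enforced by optimizing log-parameters, initialized
from the reciprocal linearization, and multi-started from five deterministic
multiplicative perturbations of the affinity to avoid local minima.
Parameter standard deviations come from the Jacobian at the optimum (local
curvature, delta method).  Fitted parameters are reported as descriptive
curve summaries: a Langmuir shape in a solution/solid system does not by
itself establish the gas-phase Langmuir mechanism (homogeneous surface,
monolayer, no lateral interactions).

## Derivative isotherm summation (DIS)

Low-pressure (P/P0 < 0.05) quasi-equilibrium argon adsorption resolves
surface heterogeneity: sites fill in order of adsorption energy, so plotting
dV/du against u = ln(P/P0) (a free-energy axis in kT) turns distinct face
families into distinct peaks.  Numerical differentiation first projects
V(u) onto the monotone non-decreasing cone (isotonic regression) — the
physical constraint on a cumulative adsorbed volume — which suppresses
negative-slope noise *without* the upward bias that pointwise truncation of
negative derivatives would introduce; the projected series is then
differentiated by sliding local cubic fits (Savitzky-Golay convention,
window default 7, shrunk at the ends).  Residual negative values are clamped
to zero and counted.  With this estimator the derivative of a synthetic
single-domain isotherm at 0.1% instrument noise matches the analytic curve
to under 3% RMS of the peak height, and the integral of the derivative
conserves the monolayer capacity to under 2% even at 1% noise.

The local (single-domain) isotherm is a Langmuir isotherm with
Bragg-Williams mean-field lateral interactions, defined implicitly by
u = u_half + ln(theta/(1-theta)) - omega (theta - 1/2).  For omega < 4 kT
the map is strictly monotone, theta(u) is solved by vectorized bisection,
and the local derivative v_m / (1/(theta(1-theta)) - omega) is a unimodal
peak of height v_m/(4 - omega) at u_half whose integral is v_m.  This is the
simplest member of the DIS local-isotherm family with an explicit
single-valuedness bound; multilayer/BET-type local forms are deliberately
out of scope, and fitting is restricted to the monolayer window
u <= ln 0.05.

The experimental derivative is fitted as a sum of such domains by bounded
trust-region least squares (v_m >= 0, u_half inside the data range, omega in
[0, 4)), multi-started deterministically (10 starts) from peaks of a
pre-smoothed derivative ranked by prominence; restarts stop early once three
consecutive starts fail to improve the optimum by 1%.  Domains are labelled
edge (high energy, low u_half) or basal by a split threshold that defaults
to the deepest experimental minimum between the two most separated fitted
u_half values and is user-overridable — the override is the intended tool
when comparing a pristine surface against one whose high-energy sites have
been blocked by an adsorbate, since the blocked sample no longer has two
clusters to split automatically.  Monolayer capacities convert to areas via
the conventional argon cross-section 0.138 nm^2 (configurable).

## MD trajectory analysis

Frames are orthorhombic-periodic; triclinic input is rejected explicitly.
The molecule is **adsorbed** when the minimum-image distance between any
molecule atom and any surface atom is <= 4.0 A (threshold inclusive).
Adsorbed frames split by the tilt between the nucleobase ring plane
(least-squares plane through the ring atoms, smallest principal axis) and
the surface plane: tilt <= 30 deg is the **parallel** state 2, otherwise
state 1; free frames are state 0.  The 30 deg default quantifies "parallel",
which has no standard numeric value; the tilt angle is always emitted so
users can re-threshold.  The surface plane is normal to the longest box axis
by default (slab geometry), configurable.  The ion-complexation cutoff
defaults to the same 4.0 A as adsorption, there being no separate
established complexation radius for this analysis.

The duration ratio is (frames in states 1 or 2) / (frames in state 0),
reported as infinite with a flag when no frame is free.  Dwell smoothing
(`min_dwell_frames`) is off by default — raw state traces are the primary
object — and when enabled relabels fleeting visits to the flanking state,
first on the adsorbed/free dichotomy, then within the adsorbed sub-states.

The complexed-molecule ("global") charge convention is: sum of the
molecule's partial charges plus the charges of all cations *and anions* with
any atom within the ion cutoff of any molecule atom (minimum image).  This
is a declared bookkeeping convention, embedded verbatim in every output;
alternative conventions (heavy atoms only, cations only) can be obtained by
editing roles/charges in the sidecar.  Per-state charge tables are
frame-weighted means, and replicate simulations combine by frame-count
weighting.

## Synthetic study conditions

The generators produce every input with known truth; all randomness flows
from one `numpy.random.default_rng(seed)` per scenario, so identical
(seed, parameters) give bit-identical artifacts.

* **Batch isotherms** — C0 grid over (0, 3.5e-3] mol/L (20 points), 1 mL
  solution over 10 mg mineral, seawater-analog composition (0.5 M NaCl +
  0.05 M MgCl2).  Ceq solves the chosen model jointly with mass balance
  (Brent's method, ~1e-15 tolerance) so the balance closes exactly before
  noise; 2% multiplicative Gaussian noise on Ceq emulates the
  spectrophotometric readout.  Default truths: q_max = 1e-4 mol/g and
  K = 5000 L/mol (classic) or K_ML = 100 with S = 0.02 mol/L (modified),
  giving strong saturation (K C0max ~ 17) at plateau loadings typical of
  clay powders.
* **Homologous family** — three nucleotides sharing one reduced-axis
  Langmuir shape, solubilities spread 5-fold; collapse on the reduced axis
  is true by construction, so the acceptance check measures only whether the
  score detects it.
* **Grain pair** — coarse/fine grains with edge areas 10 and 30 m^2/g and
  basal areas deliberately not proportional (20, 40), uptake proportional to
  edge area; only the edge basis can collapse.
* **Argon isotherms** — 300 log-spaced points over P/P0 in (1e-7, 0.05],
  default two domains: edge (30% of the monolayer, u_half = -12, omega =
  0.8) and basal (70%, u_half = -5, omega = 2.0), 1% multiplicative noise.
  The "edge-blocked" variant zeroes the edge domain.  Note the default basal
  domain keeps a few percent of its capacity beyond the monolayer window, so
  monolayer-conservation checks use a variant centred at u_half = -6,
  omega = 2.5 whose domains are complete within the window.
* **Trajectories** — a rigid 9-atom molecule (planar 5-ring + short
  phosphate-bearing arm, net charge exactly -2 e) over a static 143-atom
  slab in a 41.44 x 35.88 x 62.5 A box, 2000 frames of 0.05 ns.
  Adsorption/desorption is a two-state Markov chain: Na-like p_on = 0.02,
  p_off = 0.05 per frame (stationary adsorbed fraction 2/7, expected
  duration ratio 0.4); Ca-like p_on = 0.06, p_off = 0.02 (fraction 3/4,
  ratio 3).  Adsorbed frames sample the minimum distance uniformly in
  [2.5, 4.0] A with the lowest atom placed directly above a surface atom, so
  the sampled distance is realized exactly; free frames in (4.5, 20] A.
  Parallel sub-states draw tilts in [0, 24] deg, non-parallel in [40, 90]
  deg.  Bound-ion counts are state-dependent Poisson draws — Na-like means
  3.4 (adsorbed) / 2.85 (free) monovalent ions, Ca-like 2.8 / 2.46 divalent
  — placed within the ion cutoff, remaining ions rejected-sampled at least
  1 A beyond it.  These means put the mean adsorbed-state global charge near
  +1.4 e (Na-like) and +3.6 e (Ca-like), a 2-3x contrast with matching
  free-state values near +0.85 e and +2.9 e.  Positional jitter is Gaussian
  with a 0.1 A RMS displacement magnitude (per-coordinate sigma 0.1/sqrt(3),
  the B-factor convention for an RMS displacement).  Because the adsorbed
  distance window touches the 4.0 A cutoff, a fraction of a percent of
  frames is inherently misclassified under jitter; classification remains
  >= 99% accurate.

## What the tests do and do not show

Passing tests demonstrate that the estimators recover known truth under the
generators' assumptions: Langmuir-shaped uptake with multiplicative readout
noise, Bragg-Williams domains with white volume noise, memoryless two-state
residence kinetics, and rigid geometry with isotropic jitter.  Real systems
violate all of these to some degree — heterogeneous site energies beyond two
domains, correlated instrument drift, ion exchange and solvent structure,
flexible molecules — so the suite validates the *bookkeeping and inference
machinery*, not the physics of any particular clay-nucleotide pair.  In
particular the toy trajectories contain no water, no force field, and no
clay crystallography; they exercise the classifiers, not molecular dynamics.

## Problem sizes

Default sizes were chosen so the statistics are stable at interactive cost:
100 seeds for Langmuir Monte-Carlo recovery, 20 seeds for collapse, DIS, and
trajectory ensembles, 2000 frames (100 ns emulated) per trajectory, 300
points per argon isotherm, 10^4 samples for the mass-balance sweep.

## Known limitations

* The modified-Langmuir equation is implemented in the dimensionless-K_ML
  form stated above; other solid/liquid conventions exist in the literature
  and are not auto-detected.
* The DIS auto-split needs at least two fitted energy clusters; single-class
  surfaces require an explicit `split_u`.
* `collapse_score` requires overlapping abscissa supports and at least two
  curves; it does not extrapolate.
* The trajectory reader supports only the package's extended-XYZ dialect
  with a roles sidecar; other formats should be converted or read through a
  custom adapter producing `TrajectoryFrame` objects.
* Derivative-isotherm accuracy degrades with per-point volume noise; at 1%
  white noise the pointwise derivative is noisy even though integral
  bookkeeping stays within 2%.
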