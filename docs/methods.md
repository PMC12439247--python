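# Methods

`nanocolloid` analyzes the colloidal interactions of ligand-coated
nanoparticle dispersions (amphiphilic gold nanoparticles stabilized by
hydrophilic/hydrophobic thiol mixtures are the motivating system, but
nothing in the code is specific to gold).  Three experimental observables
drive the design: 3D particle centroids segmented from cryo-electron
tomograms, aggregation-state statistics from the same volumes, and
small-angle X-ray scattering (SAXS) curves of non-aggregating dispersions.
Because such raw data are instrument-bound, the package ships a seeded
simulator that generates both kinds of input from a known pair potential, so
every analysis stage can be validated against a ground truth.

## Pair interaction model

All interactions use the hard-core two-Yukawa potential

    beta V(r) = +inf,                                     r < sigma
    beta V(r) = - [ K1 e^(-Z1 (x-1)) + K2 e^(-Z2 (x-1)) ] / x,   x = r/sigma >= 1

with `sigma` the effective hard-core diameter in nm (core plus ligand
shell; default 7 nm for a 3.8 nm core), `K_i` dimensionless contact
strengths in kT (K > 0 attractive under this sign convention), and
`Z_i = 1/lambda_i` inverse decay ranges in units of `sigma`.  One term
usually models short-range hydrophobic attraction and the other screened
electrostatic repulsion, but terms are stored signed and the
attractive/repulsive labels are always recomputed from `sign(K)`; fits may
swap the roles.  This is the standard convention of SAXS/SANS structure-
factor analysis tools.  The hard core is represented by a genuine `+inf`
sentinel (never a large finite number), so Monte Carlo rejects overlaps
exactly and the integral-equation solver treats the core as a boundary
condition.  Energies are kT throughout; joules appear only at I/O edges via
`Environment` (default temperature 293.15 K, the 20 degC at which the
underlying measurements are made).

## Monte Carlo generator

`simulate.run_mc` is a plain Metropolis sampler: single-particle uniform
trial displacements, acceptance `min(1, exp(-dbetaV))`, minimum-image
convention on periodic axes and outright rejection of hard-wall crossings.
Yukawa tails are truncated at `r_cut = sigma (1 + 8/Z_min)` with no tail
correction (the neglected energy is below `e^-8` kT).  The step size is
tuned toward 30–50% acceptance during equilibration (factor 0.8/1.2 every
50 sweeps) and then frozen for production, preserving detailed balance
where samples are taken.  Starting configurations are simple-cubic
lattices, which are overlap-free up to volume fraction pi/6; denser
requests fail loudly before sampling.

Two geometries are exercised: fully periodic cubes (used by all property
tests) and a slab — periodic in x,y with hard walls in z — emulating the
~100 nm vitrified films that tomography images.  The slab thickness is an
emulation choice, not a measured quantity, and is flagged as such in
configurations.

Defaults mirror the study conditions: number concentrations of
3–12 x 10^22 particles/m^3 (volume fractions below ~2% for 7 nm
particles), boxes of 110–160 nm, a few hundred particles, and a few
hundred to a couple of thousand sweeps.  These sizes were chosen so the
full validation sweep completes on a laptop-class machine in minutes while
keeping counting noise in pooled histograms at the percent level.

One global seed drives everything; per-condition and per-curve sub-seeds
are derived with `numpy.random.SeedSequence` spawn keys, so identical
configurations give byte-identical artifacts and duplicate series members
get independent streams.

What the generator does *not* emulate: segmentation errors and missed
particles, the missing-wedge anisotropy of tomography, polydispersity of
the core in the particle coordinates (positions are ideal hard spheres),
hydrodynamics, and any time correlation — frames are equilibrium samples,
not a trajectory.  Passing tests therefore certify the analysis chain on
ideal centroid sets, not robustness to segmentation artifacts.

## RDF and PMF

`structure.compute_rdf` bins unordered pair distances on half-open bins
`[r_i, r_{i+1})` (default width sigma/20, positions reported at bin
centers) and normalizes by the ideal-gas expectation at the same number
concentration.  Edge corrections:

* periodic axes: minimum image with exact spherical-shell volumes
  (requires `r_max <= L/2`);
* one hard-wall axis (slab): per-particle shell volumes cut analytically by
  the two wall planes (spherical-cap geometry, exact);
* two or three hard-wall axes: the shell-in-box fraction is evaluated with
  a deterministic 2000-direction Fibonacci-sphere quadrature.  This is a
  deliberate trade: the exact 3D shell–box intersection is an unwieldy
  inclusion–exclusion formula, and no shipped workflow uses more than one
  walled axis.

The potential of mean force is the Boltzmann inversion `W = -ln g` in kT.
Bins with `g = 0` map to a `+inf` sentinel instead of being dropped, so
curves from different conditions stay aligned on a common axis.  The
inversion is exact (round trip to machine precision on the support of g).

`pmf_features` reports the well/barrier geometry that summarizes each
profile: the contact well (the deepest prominent minimum before the first
barrier — the left edge of the finite domain counts, since a hard-core PMF
has its well at contact), the highest barrier beyond it, their positions,
the signed difference, and an optional secondary minimum past the barrier.
Counting noise produces spurious wiggles, so extrema must clear a
configurable prominence (default 0.15 kT) on a centered moving average
(default 3 bins); heights are read from the smoothed curve.  The secondary
minimum is reported only if it dips more than a noise floor (default
0.05 kT) below the large-r plateau.  Monotone profiles yield an explicit
absent-well flag — features are never fabricated.  Adding a constant to W
shifts reported heights but not positions.

## Aggregation census

Aggregates are single-linkage connected components of the contact graph:
particles closer than a cutoff (default 1.2 x sigma, configurable —
segmentation pipelines never publish their exact touching criterion) are
in the same aggregate, transitively.  Components come from a KD-tree pair
search plus `scipy.sparse.csgraph`; cluster labels are renumbered by lowest
member index so output is deterministic.

The census reports both conventions used in dispersion work: the
particle-weighted *percentage* histogram (a size-s aggregate contributes s
particles; "30% monomers" means 30 of 100 particles are monomeric) and the
entity-weighted *mole-fraction* histogram (each aggregate counts once).
With `c_s` aggregates of size s and N particles, `percentage_s =
100 s c_s / N` and `mole_s = c_s / sum c_s`; the two are exactly
cross-consistent (`percentage_s / mole_s` proportional to s) except in the
pooled top class (default ">= 6"), which mixes sizes.

## SAXS forward model and inversion

Intensities follow the decoupling approximation

    I(q) = scale * <P(q)> * S(q) + background

with `<P(q)> = <V^2 P> / <V^2>` the intensity-weighted sphere form factor
averaged over a log-normal radius distribution (median ~1.85 nm, relative
width ~0.1, fixed from a dilute measurement as is standard practice) and a
single effective hard-core diameter in S(q).  The log-normal average uses
Gauss–Hermite quadrature in log-radius with automatic node doubling until
stable to 1e-6 relative.  A beta(q) polydispersity correction is not
implemented; with one fixed sigma the effective-monodisperse reading is
the intended model.

S(q) is computed by solving the Ornstein–Zernike equation on a radial grid
(4096 points, dr = sigma/64, fast sine transforms) under an explicit
closure: Percus–Yevick (PY) for hard-sphere validation, hypernetted chain
(HNC) by default for Yukawa tails.  Numerical details that matter:

* The jump of the Boltzmann factor at the core boundary lies exactly on a
  grid node; assigning that node the jump midpoint restores second-order
  accuracy (max relative error vs the Wertheim closed-form PY structure
  factor: 7e-4 at phi = 0.3, ~3e-5 at phi = 0.05, versus percent-level
  with naive sampling).
* Iteration: damped Picard with Ng's two-history (Anderson) extrapolation,
  converged when the max-norm change of the indirect correlation falls
  below 1e-8; typically 10–40 sweeps.  If extrapolation overshoots (it can,
  near instability), the solver falls back to plain damped Picard, and
  finally to a 10-stage continuation ramp on the tail strength.  States
  with no solution (inside the spinodal — a physically aggregating sample)
  raise a `OZConvergenceError` carrying the residual history.
* Warm starts: a caller may seed the iteration with a previous solution;
  the fit layer does this between optimizer trials.

The Wertheim analytic PY hard-sphere structure factor is implemented
separately (`hard_sphere_sq_py`) purely as an independent reference; the
solver never calls it.

The inverse problem minimizes `sum [(I_model - I)/sigma_I]^2` with lmfit's
trust-region least squares; missing uncertainties fall back to
counting-statistics weights (`sigma_I ~ sqrt(I)`).  The form factor is
always fixed; sigma is fixed by default; volume fraction may be fitted or
fixed from the known concentration (`phi = n (pi/6) sigma^3`).  Solver
failures at trial points return a large penalty sloped toward weaker
interactions so the optimizer can retreat smoothly.  Fitted potentials are
decomposed into attractive (K > 0) and repulsive (K < 0) components, and
paired results yield difference curves per component.

Two identifiability facts, measured on synthetic data and worth knowing
before interpreting any 2-Yukawa fit:

* The *total* potential V(r) is far better determined than its
  parametrization: noiseless fits from displaced initials can end 20% off
  in K1 yet within 0.07 kT in V(r) at every r.
* The attractive/repulsive *split* of a difference between two conditions
  is reliable only when the two ranges are well separated.  The shipped
  attribution check therefore uses a long-range attraction (Z = 1,
  lambda = sigma) against a short-range repulsion (Z = 6), fits only the
  four Yukawa parameters (phi, scale, background fixed at their known
  preparation values), and initializes at the generating parameters: it is
  a calibrated attribution test of the pipeline, complementing the blind
  perturbed-initials recovery battery, which uses the full default free set.

## Validation summary

The test suite and `scripts/acceptance.py` check, among others: OZ/PY
against the Wertheim closed form (phi = 0.05–0.3, < 1%); S = 1 and g = 1
ideal limits; exact PMF round trips; cluster partitions against a
brute-force BFS oracle (5000 frame x cutoff combinations); hard-sphere
contact values against Carnahan–Starling `(1 - phi/2)/(1 - phi)^3`;
two-particle Metropolis sampling against direct Boltzmann quadrature
(Kolmogorov–Smirnov); OZ-vs-MC structure factors at the correlation peak;
parameter recovery from noiseless and 1%-noise curves; and the qualitative
trends the pipeline exists to expose — monomer fraction strictly falling
with attraction strength, and a reduced attraction raising the PMF barrier
while shifting the census toward monomers.

## Known limitations

* HNC is an approximate closure; near the spinodal its solution vanishes
  before the physical one would, and no MSA/analytic 2-Yukawa route is
  provided for comparison.
* The decoupling approximation couples polydispersity and structure only
  through the fixed form factor.
* PMFs from concentrated or aggregating systems are many-body objects; the
  dilute-limit reading W ~ beta V holds only for non-aggregating samples,
  and the simulator shows visible many-body offsets (~0.2 kT) already at
  ~10^23 m^-3 with strong attraction.
* Single-linkage "touching" is one of several defensible aggregate
  definitions; density-based alternatives are out of scope.
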