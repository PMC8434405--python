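# Methods

This note documents the models and estimators implemented in `hydrashell`,
the defaults they ship with, what the synthetic generators do and do not
emulate, and the numerical choices made where the literature leaves the
design open. Internal units are nm and ps throughout; parameters quoted in
Å in the hydration literature are converted at the API boundary
(1 Å = 0.1 nm).

## Trajectory model and periodic geometry

A trajectory is a uniformly sampled stack of coordinate frames over one
topology. Only orthorhombic periodic boxes are supported; triclinic input
is rejected with an explicit error rather than silently mis-imaged.
Minimum-image displacements are computed per component as
d − L·⌊d/L + 1/2⌋, which places every component in [−L/2, L/2) and is
verified in the tests against exhaustive search over the 27 neighbour
images. Unwrapping integrates minimum-image frame-to-frame steps from the
first frame; it is reliable only when no atom moves half a box edge per
frame, and steps within 1% of L/2 trigger a warning naming the affected
atoms.

File parsing (PDB, GRO, XTC, DCD) is delegated to MDAnalysis and converted
to nm on entry. When a structure carries no connectivity, bonds are
inferred by a covalent-radius heuristic (cutoff 1.2 × the summed radii;
H–H bonds excluded) — PDB waters routinely lack CONECT records. Donor and
acceptor flags follow the standard heuristic: N and O are acceptors, and
N/O with at least one bonded hydrogen are donors. Atom indices are 0-based;
residue numbers are preserved from the input file, so selections expressed
in author numbering are the caller's responsibility.

## Structural metrics

RMSF is sqrt((1/T)·Σ_t |x_i(t) − x̄_i|²) per atom — the time-normalised
form, without which the quantity would grow with trajectory length and
could not serve as a per-residue flexibility measure. Optional per-residue
aggregation is the unweighted mean over the residue's selected atoms, and
`align_first` superposes every frame onto the first over the analysis
selection so rigid-body drift does not masquerade as flexibility.

RMSD uses the same selection logic with an optional Kabsch superposition
(SVD with determinant correction, so the rotation is always proper).
Superposition and RMSD ignore periodic images: the analysed molecule is
assumed contiguous, and re-imaging is a pre-processing step.

SASA uses numerical sphere-point burial counting: each atom is dressed
with quasi-uniform golden-spiral points at radius r_vdw + probe, points
inside any other extended sphere are buried, and the exposed fraction
scales the extended-sphere area. Defaults are Bondi van der Waals radii, a
0.14 nm water probe and 960 points (≲1% error against the isolated-sphere
and two-sphere-cap closed forms; the tests also cross-check against an
independent implementation). Missing radii raise an error naming the
element rather than guessing.

## Transport metrics

The MSD estimator averages squared displacements over all selected atoms
and all time origins on a configurable stride grid, for every frame lag up
to `max_lag`; it equals a direct double-loop computation to 1e-10 and
detects (and rejects) wrapped input by its box-edge-sized jumps. The
windowed variant divides the span into non-overlapping periods, takes each
period's start-to-end squared displacement averaged over atoms, and
reports the mean and sample standard deviation over periods — the form
used to summarise long runs as one value per temperature. The diffusion
coefficient is the least-squares MSD slope over a user-chosen lag range
divided by 6; the reported R² exposes non-diffusive (ballistic or caged)
regimes where the linear model is inappropriate.

g(r) histograms minimum-image centre–target distances per frame and
normalises by the exact spherical-shell volume (4/3)π(r₂³−r₁³) — not the
4πr²Δr approximation, which biases the first bins — and by the
instantaneous bulk target density N_B/V. Self-pairs are excluded.
Defaults: bin width 0.002 nm, r_max 3.0 nm (hydration structure is
measurable out to ~3 nm around charged sites), both configurable and
bounded by half the smallest box edge. First-peak statistics smooth with a
5-bin moving average by default (raw histograms are noisy and no standard
rule exists), then take the first local maximum after the first non-zero
bin and the first local minimum after it; the ratio g_min/g_max measures
de-packing of the first hydration layer.

The dynamical-transition detector fits two independent straight lines on
either side of every interior grid point (the candidate sample belongs to
both segments, each needing ≥ 2 points) and returns the split minimising
total squared error. Continuity at the break is deliberately not enforced
— with the typical six-temperature grid a constrained fit buys nothing and
can bias the breakpoint. Perfectly linear input is flagged `degenerate`
instead of reporting a spurious transition, and breakpoints are never
placed on the grid boundary.

## Hydration-shell residence and reorientation

A water belongs to the shell when its **oxygen** lies within the cutoff
(default 0.6 nm) of **any** reference atom; oxygen-based distances keep
the cutoff semantics consistent with oxygen-centred RDFs. The residence
correlation averages, over time origins, the fraction of the waters
present at t₀ that are present again at t₀+t. The default convention is
*intermittent* — membership is evaluated at t₀+t regardless of excursions
in between, exactly as the counting rule N_t/N_t₀ reads — with a
*continuous* variant (water removed at first exit) available by flag,
since both appear in the literature. Origins with an empty shell are
skipped and counted in the metadata.

The biphasic model n_s·exp(−(t/τ_s)^γ) + n₁·exp(−t/τ₁) couples a
stretched-exponential (KWW) slow term, describing collective escape from a
heterogeneous, disordered surface, with a fast exponential for exchange at
the shell boundary. Fitting uses bounded nonlinear least squares with
multi-start (a heuristic start from the 1/e crossing plus ≥ 5 seeded
log-uniform restarts, best objective kept): the model is multi-modal in
(τ_s, γ, n_s) and single-start fits routinely land in the wrong basin.
Bounds: amplitudes in [0, 1.5], γ ∈ (0.2, 1], time constants in
(dt, 10 × span). The amplitudes are not constrained to sum to 1; a
deviation |n_s + n₁ − 1| > 0.1 attaches a warning instead, and components
are relabelled post hoc so τ_s > τ₁. `fix_gamma=1` pins the stretch
exponent for plain biexponential fits (useful when the data are known to
be Markovian, where the decay rate is k_on + k_off). Parameter
uncertainties come from the local quadratic model at the optimum,
cov = (JᵀJ)⁻¹·s². A series with no decay returns `converged=False` rather
than a meaningless fit.

The water dipole is defined geometrically — the unit vector from the
oxygen along the bisector of the two O–H bonds, with hydrogens taken
minimum-image relative to the oxygen so boundary-straddling waters behave
like their re-imaged copies. For 3-site waters with symmetric charges
(SPC/E and relatives) this coincides with the charge dipole while
requiring no charge metadata. C_μ(t) averages dipole dot products over
waters and origins, optionally restricted to waters in the shell at each
origin, and is fitted by A_μ·exp(−t/t_μ) with a log-linear initial guess.

## Hydrogen-bond kinetics

A triple (D, H, A) is bonded when the minimum-image D–A distance is
strictly below 0.35 nm and the angle at the donor between D→H and D→A is
strictly below 30°. The angle vertex sits at the donor — the convention of
the major MD analysis toolchains; an H-vertex reading would change results
materially, which is why the convention is stated here. Ties at either
cutoff are excluded (strict inequalities). Same-molecule pairs are never
counted. Detection is validated against an exhaustive all-triples loop on
randomised water boxes.

Two time scales summarise the population dynamics. The continuous lifetime
τ_HB is the mean duration of maximal unbroken bonded intervals; runs
touching either trajectory end are censored (their true length is
unknown) and excluded, keeping the mean unbiased. The intermittent
correlation c(t) = ⟨h(0)h(t)⟩/⟨h⟩ counts a pair bonded at both t₀ and
t₀+t regardless of breaks in between; the default estimator pools
numerator and denominator over pairs and origins (the plain ensemble
average, and an unbiased conditional-probability estimator — the per-pair
ratio average, available via `weighting="pair"`, carries a small Jensen
bias when per-pair bonded time fluctuates). Normalisation is per lag, so
c(0) = 1 exactly. τ_R is the first crossing of c(t) below 1/e, located by
linear interpolation between the bracketing lags — a model-free estimator.
When c plateaus above 1/e (large stationary occupancy, or frozen systems
whose slow decay exceeds the observation window) the function reports the
plateau value as an error unless tail-fit extrapolation is explicitly
enabled, in which case the result is flagged extrapolated. On
intermittently re-forming systems τ_HB ≤ τ_R by construction.

Because "lifetime" is used ambiguously in the literature (continuous-run
mean versus the fast component of a fit to c(t)), both are available —
`continuous_lifetime` and the fast component of a `fix_gamma=1` biphasic
fit to c(t) — and are labelled distinctly.

## Synthetic generators

The generators produce data whose dynamical parameters are known exactly,
so every estimator has an analytic oracle:

- `gen_brownian`: independent Gaussian steps with per-component variance
  2·D·dt, wrapped into a cubic box, with the unwrapped walk retained in
  the metadata. The 3-D Einstein relation MSD = 6·D·t is exact.
- `gen_rotors`: rigid 3-site waters (O–H 0.1 nm, H–O–H 109.47°, SPC/E
  geometry, dipole along the H–H bisector) whose orientations evolve by
  small random rotations with rotation-vector components i.i.d.
  N(0, 2·D_rot·dt). This realises ⟨û(0)·û(t)⟩ = exp(−2·D_rot·t) for the
  rank-1 correlation: a small rotation by angle θ about a uniform random
  axis decorrelates a fixed vector by ⟨θ²⟩/3 per step, so the total angle
  variance 6·D_rot·dt (2·D_rot·dt per component) yields the per-step
  factor exp(−2·D_rot·dt). The integrator requires dt·D_rot ≤ 0.05.
  Centres are static: translation–rotation coupling is deliberately absent.
- `gen_two_state_series`: discrete-time first-order sampling of the
  two-state Markov chain, P(0→1) = k_on·dt, P(1→0) = k_off·dt, with the
  bound dt·(k_on+k_off) ≤ 0.1. This mirrors frame-sampled MD data; the
  discrete chain's decay factor per step is 1 − (k_on+k_off)·dt, an O(dt)
  difference from exp(−(k_on+k_off)·dt) that the tests budget explicitly.
  Stationary occupancy is k_on/(k_on+k_off); on-state dwell times are
  geometric with mean 1/k_off.
- `gen_shell_system`: a single immobile reference site (an amide-like
  nitrogen, so it is also a valid H-bond acceptor) at the box centre, and
  waters whose occupancy follows independent two-state chains. In-shell
  waters are placed uniformly inside 0.9 × cutoff, out-of-shell waters
  beyond 1.1 × cutoff; the 10% margins make geometric membership recovery
  exact, so the occupancy matrix is a bit-for-bit oracle.
- `gen_piecewise_linear`: a continuous two-slope curve with optional
  Gaussian noise and a planted breakpoint, the fixture for transition
  detection.

All generators are deterministic under a fixed seed. What they do **not**
emulate: a real protein surface (one site instead of a heterogeneous
residue patch), coupling between translation, rotation and bond states,
force-field energetics, and temperature as an explicit variable — the
rates *are* the temperature surrogate. Passing tests therefore demonstrate
estimator correctness on data that obey the model assumptions exactly;
they do not validate force fields or sampling adequacy on real systems.

## Pipeline

`run_pipeline` executes structure → transport → hydration → H-bond stages
from a validated YAML config whose defaults encode the conventional
parameter set (0.6 nm shell, 0.35 nm / 30° H-bond criterion, 200 ps
residence window). Unknown keys and invalid values are rejected with their
key paths before any computation. Stages fail independently and the report
records diagnostics; per-stage frame strides mirror the common practice of
analysing fast observables at fine saving frequency and slow ones at
coarse frequency from a single trajectory. Outputs are a pure function of
(inputs, config, seed); every output table carries the config hash in its
metadata header.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at desk scale:
Brownian recovery uses 400 particles × 2000 frames (D within 5%),
reorientation 1500 rotors × 301 frames (t_μ within 5%), the two-state
kinetics 10⁴ series × 10⁴ frames at dt = 0.01 ps (c(t) within 3 standard
errors of the closed form; τ_HB and τ_R within 5%), and the end-to-end
shell system 400 waters × 6000 frames at dt = 0.02 ps (occupancy recovered
exactly; residence decay rate within 10%, scatter across seeds ≈ 3–5%).
Residence-fit self-consistency is exact to better than 1% on noiseless
model curves; at 1% additive noise the replicate-averaged parameter errors
are 2–8%, consistent with the Cramér–Rao bound for this five-parameter
model (the bound alone puts the 1σ scatter of τ_s at ≈ 8.6%).

## Known limitations

Orthorhombic boxes only; no velocities or forces; residue-based molecule
identification (sufficient for protein-plus-water systems without shared
residue ids); O(n²) neighbour search in H-bond detection and RDF (adequate
for the selection sizes these analyses target, not for all-atom
water–water analyses of large boxes); no Luzar–Chandler reactive-flux
decomposition of the bond kinetics; and no l=2 reorientation correlators,
which NMR and anisotropy experiments probe.
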