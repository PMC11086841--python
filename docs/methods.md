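# Methods

`cvpath` implements the free-energy machinery used to map two-state
conformational transitions of proteins in collective-variable (CV) space —
extended-system adaptive biasing force (eABF) with the CZAR estimator, the
swarms-of-trajectories string method, umbrella sampling analyzed by
Umbrella Integration (UI) and MBAR, and conformer clustering — and
validates every estimator on analytically tractable model systems. This
note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic fixtures do and do not show.

## Units and the toy engine

Energies are kcal/mol, lengths Å, temperatures K; the Boltzmann constant
is k_B = 0.0019872 kcal/mol/K. The toy Langevin engine works in *reduced*
time units in which a unit mass has thermal velocity √(k_B T); the mass
unit is therefore kcal/mol·τ²/Å². All equilibrium observables — the only
quantities the estimators consume — are independent of this convention; it
simply makes the engine's closed forms (equipartition, the Euler–Maruyama
single-step moments, the Ornstein–Uhlenbeck relaxation e^(−κt/γ)) exact
without unit-conversion factors.

Two integrators are provided. The underdamped scheme is a BAOAB splitting
(exact Ornstein–Uhlenbeck substep); with friction → 0 it reduces to
velocity Verlet and conserves energy to <1e-3 kcal/mol over 10⁴ steps on a
harmonic well. The overdamped scheme is Euler–Maruyama; it is stable for
κ·dt/(mγ) < 2 and inflates configurational variances by a factor
≈ 2/(2 − κ·dt/(mγ)), so stiff restrained sampling uses either a small
timestep or the underdamped scheme. Trajectory divergence (coordinates
exceeding a guard bound) raises an error naming the step.

Randomness flows from one master seed through named substreams
(`substream(seed, *tags)`, CRC32-stable string tags), so every stage of a
pipeline is independently reproducible bit-for-bit.

## Model systems

* **Two-basin surface** `make_two_basin_potential(barrier, separation,
  asymmetry)`: U(x, y) = A(x²/a² − 1)² + t·x/a + y², with (A, t) solved
  numerically so that saddle − lower minimum = `barrier` exactly (to 1e-6)
  and the minima differ by exactly `asymmetry`. The transverse mode is
  harmonic (2 kcal/mol/Å²). The study fixture uses barrier 6 kcal/mol —
  the scale of a converter-repriming barrier — basins 2 Å apart, and a
  1 kcal/mol tilt so the end states are inequivalent.
* **Müller–Brown** in its standard four-Gaussian form, with stationary
  points located by multi-start polishing (gradient norm < 1e-10):
  minima at −146.700, −108.167, −80.768 and saddles at −40.665, −72.249.
* **Toy bead helix**: an ideal α-helix-like bead chain (rise 1.5 Å, radius
  2.3 Å, 100°/bead) and a "kinked" copy bent 40° at mid-chain — a
  desk-scale analogue of a straight-vs-kinked helix rearrangement. The
  ensemble generator mixes rigid-body copies of the two references
  (largest-remainder apportionment, so noise-free occupancies equal the
  requested mixture exactly) with isotropic Gaussian coordinate noise.

## The quadrature oracle

`reference_pmf_quadrature` computes F(z) = −k_B T ln ∫ e^(−βU) δ(cv − z) dx
by dense-mesh summation. When a CV is literally a coordinate
(`align_axes`), the mesh has one node per CV bin at its center, making the
oracle the *point-value* marginal — exactly what gradient-based estimators
reconstruct — and machine-exact for separable potentials. Generic CV maps
use cloud-in-cell deposition to suppress mesh/bin aliasing in ln ρ. The
oracle is grid-refinement stable to <0.01 kcal/mol on the fixtures.

## eABF + CZAR

Each CV z is tethered to an extended coordinate λ by ½k(λ − z)²; λ carries
its own underdamped Langevin dynamics (friction 10 τ⁻¹, 300 K; fictitious
mass defaulting to k/ω² with an oscillation period of 50 timesteps — slow
against the integrator, fast against bin diffusion). The adaptive bias on
λ is the negated running mean of the instantaneous coupling force in λ's
bin, ramped by min(1, N/full_samples); unvisited bins carry zero bias.
One-sided harmonic walls (default 100 kcal/mol/U²) confine λ to the grid
and to stratification windows; samples taken beyond a wall are excluded
from accumulation. Grids accumulate per-z-bin {N, Σz, Σλ} and per-λ-bin
{N, ΣF}; they serialize to restartable text and merge bin-wise
(associative, order-independent), which is how stratified windows combine.

The CZAR estimator per occupied bin is
dA/dz = −k_B T ∂/∂z ln ρ(z) + k(⟨λ⟩_z − ⟨z⟩_z),
with the log-density derivative by centered differences (one-sided at
occupied-region edges; bins with N < 5 excluded). Two numerical choices
matter:

* the correction term uses the per-bin mean of λ − z rather than the bin
  center, avoiding an O(k·width²) discretization bias that the center
  introduces;
* production estimation is two-phase: an adaptive warmup builds the bias,
  then a frozen-bias phase (`bias_source=`) samples a stationary ensemble
  whose statistics feed CZAR. The CZAR identity is exact for any *static*
  bias; continuous adaptation leaves a small systematic residue.

Gradients integrate to a surface by cumulative trapezoid (1D) or a sparse
least-squares solve of the finite-difference system (2D), which projects
out curl-inconsistent noise; disconnected occupied components integrate
separately with undefined relative offsets. "Well-sampled" bins for
quantitative comparisons are those with N ≥ full_samples, eroded two bins
away from the sampled-region boundary: at the rim the biased density
decays within a bin, displacing the estimator's effective evaluation point
on a steep landscape.

On the study fixture (29×21 grid over [−2, 2]×[−1.4, 1.4], coupling 25
kcal/mol/Å², 1.2M warmup + 1.4–2M estimation steps — two to four minutes
on one CPU), the CZAR-integrated surface agrees with the oracle to ≈0.1 kcal/mol
RMS over ~300 well-sampled bins; the per-bin maximum runs ≈3× the RMS, as
expected for approximately Gaussian per-bin errors.

## String method (swarms of trajectories)

CVs are normalized to [0, 1] by the absolute endpoint difference per CV
(with an explicit fallback scale for CVs identical at both ends), so
reparametrization weighs heterogeneous CVs evenly. One iteration:
restrained equilibration at each interior image (harmonic CV restraints,
default 100 kcal/mol/U²), S unbiased trajectories from trailing
equilibrated snapshots with Maxwell–Boltzmann velocities, image moved by
the swarm-mean final-minus-initial CV displacement, then equal-arc-length
reparametrization along the piecewise-linear interpolant (duplicate
adjacent images merged first). Endpoints stay fixed. Convergence is
monitored as the RMSD (normalized CV space) against the initial string;
analysis uses the image-wise average over the trailing iterations (the
fixture runs average 10 of 25; production-scale campaigns would average
50), reparametrized once. Low-dimensional strings lift into a larger CV
set by restrained sampling of the extra CVs' conditional means, window-3
moving-average smoothing along the path, and reparametrization.

The swarm update obeys the Ornstein–Uhlenbeck closed form on an overdamped
harmonic well — mean drift (z_min − z₀)(1 − e^(−κt/γ)) — within swarm
standard error; this is the quantitative handle on "drift points down the
free-energy gradient".

## Umbrella sampling, UI, MBAR

A converged string refines by linear interpolation to more equally spaced
images (e.g. 24 → 49 in the fixtures; 32 → 128 at production scale); each
image becomes a window sampled under ½Σkᵢ(zᵢ − cᵢ)², with an exclusion
list for CVs restrained during string optimization but not during
umbrella sampling. The first 10% of each window is discarded as burn-in.

UI estimates the local mean force per window from the Gaussian
approximation, ∂A/∂zᵢ ≈ (zᵢ − z̄)/(βσ²) − kᵢ(zᵢ − cᵢ) — exact for Gaussian
samples on a quadratic PMF — projects it onto the path tangent (central
differences of the raw images over α), combines windows with
count-times-normal-density weights, and integrates over α by cumulative
trapezoid. Adjacent windows with Bhattacharyya overlap below 0.01 trigger
a warning; windows under 50 samples are excluded.

MBAR solves the self-consistent window free energies as the minimum of the
convex per-sample-normalized likelihood (L-BFGS with analytic gradient,
polished by self-consistent sweeps to 1e-8), checks window-overlap
connectivity first (disconnected groups are reported), and accumulates
unbiased per-sample weights on a 1–2D observable grid with a Gaussian
kernel (Scott's-rule bandwidth by default; the fixture analyses use an
explicit 0.04 Å bandwidth, small against the barrier curvature, since
Scott's rule over-smooths sharply peaked PMFs). F = −k_B T ln(density),
min-gauged; per-bin effective sample sizes are reported.

On the fixture path both estimators track the free energy along the path
to ≲0.2 kcal/mol RMS and agree with each other to ≲0.3 kcal/mol RMS,
mirroring the cross-method consistency check that justifies trusting
either at production scale.

Profile post-processing finds interior extrema by sign changes of discrete
differences after optional moving-average smoothing; plateau ties resolve
toward lower α; the barrier between adjacent minima is the intervening
maximum minus the *left* minimum (the direction of increasing α). The
Arrhenius helper exp(ΔΔG‡/k_B T) converts a barrier difference into a rate
ratio under the equal-prefactor assumption; 12 vs 6 kcal/mol at 300 K
gives ≈2.3×10⁴.

## Structure analysis

Frames compare by Kabsch-minimal RMSD (SVD with determinant sign fix; <3
atoms or collinear selections raise). Clustering is average-linkage
agglomerative on the precomputed RMSD matrix (scipy linkage; labels
renumbered by first appearance; most-populated ties break toward the
lowest label); a helper raises the cluster count until at least two
clusters exceed 10% occupancy. The representative structure of a cluster
is the coordinate-wise mean after aligning members to the first member
over a configurable anchor selection; the typical frame minimizes RMSD to
the ensemble-average structure over a (possibly different) selection, ties
toward the lowest index. Metastable-state membership uses axis-aligned
elliptical regions in CV space (boundary inclusive; first-listed region
wins overlaps). Swing percentages are calibrated by a reference
(displacement, fraction) pair: total = ref_disp·100/ref_frac, value =
100·|d|/total.

Crystal-CV spot checks (`cvpath.crystal`) evaluate the Relay-kink ΔRMSD —
backbone heavy atoms C, CA, O, N of residues 485–493, two-reference signed
RMSD difference — on the PR (2VAS) and PTS (5O2L) myosin VI structures,
loaded from disk or RCSB when a network is available. The principal-axes
frame convention (gyration-tensor axes, descending eigenvalue, signs
matched to a reference after body superposition) is this package's
declared dialect; projections onto it are continuous and rigid-motion
invariant, but absolute values are not claimed identical to any other
code's converter-coordinate convention.

## What the fixtures do and do not show

The synthetic systems exercise every estimator end-to-end with exact
ground truth: basin/saddle recovery, Boltzmann statistics, estimator
consistency, cross-estimator agreement, and clustering correctness. They
do not emulate the hard parts of all-atom sampling — slow orthogonal
degrees of freedom, CV-space metric distortion, force-field error, or
barrier heights of tens of kT — so passing here establishes the
*estimators*, not the feasibility of any particular protein campaign.
Problem sizes (1–2 ×10⁶-step eABF phases, 25 string iterations × 20-member
swarms, 49 windows × 1–1.6 ×10⁴ steps) were chosen as the smallest that give the
estimators clean statistics on the fixtures.

## Known limitations

* 1–2D bias grids only; no multiple-walker shared-bias eABF, no
  metadynamics, no WHAM, no replica exchange, no Voronoi-cell string.
* The 2D gradient integration assumes a mostly connected sampled region;
  offsets between disconnected components are undefined by construction.
* The KDE density route inherits kernel smoothing bias ~½h²|F″|β near
  sharp barriers; choose the bandwidth against the narrowest feature.
* `uplift_path` assumes the extra CVs relax quickly under restraints on
  the low-dimensional set; slowly relaxing extra CVs would need longer
  per-image sampling than the default.
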