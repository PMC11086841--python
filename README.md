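# cvpath

Collective-variable free-energy methods for mapping two-state
conformational transitions — the estimator stack used to characterize
large protein rearrangements such as the myosin recovery stroke — built
as a tested library and exercised end-to-end on analytically tractable
model systems.

## What it does

Mapping a conformational transition in collective-variable (CV) space
takes four cooperating pieces, all implemented here:

1. **CV geometry** (`cvpath.geometry`, `cvpath.conformers`): Kabsch
   superposition and RMSD; the signed two-reference order parameter
   ΔRMSD(x) = RMSD(x, B) − RMSD(x, A) that separates a straight from a
   kinked helix; center-of-geometry projections onto a body's
   principal-axes frame; fragment orientation angles; distances,
   center-of-geometry distances, dihedrals; heavy-atom contact counts
   (strict 4.5 Å cutoff). PDB I/O via biotite, plus a plain-text fixture
   format.
2. **eABF + CZAR** (`cvpath.eabf`): extended-system adaptive biasing
   force on 1–2 CVs — each CV harmonically tethered (k of order 10–100
   kcal/mol/U²) to an extended coordinate carrying the adaptive bias with
   a min(1, N/full_samples) ramp — with the corrected-z-averaged restraint
   estimator

       dA/dz = −k_B T ∂_z ln ρ(z) + k (⟨λ⟩_z − z),

   stratification into windows separated by harmonic walls, gradient
   integration (cumulative trapezoid in 1D, least-squares in 2D), and
   convergence/error reporting.
3. **String method** (`cvpath.stringmethod`): swarms-of-trajectories
   relaxation of an M-image path in CV space normalized to [0, 1] per CV,
   with equal-arc-length reparametrization each iteration, straight-line
   and uplift initialization, RMSD-vs-initial convergence monitoring, and
   trailing-iteration averaging.
4. **Umbrella sampling analysis** (`cvpath.umbrella`): path refinement
   (e.g. 32 → 128 images), restrained window sampling, the potential of
   mean force along the path by Umbrella Integration with the chain rule,
   arbitrary 1–2D PMFs by MBAR with Gaussian kernel density estimation,
   profile extrema/barriers, and Arrhenius barrier-difference rate ratios.

`cvpath.clustering` post-processes conformer ensembles: pairwise-RMSD
average-linkage clustering, occupancy bookkeeping (≥10% rule),
representative (cluster-average) structures, typical frames, elliptical
metastable-state assignment, and lever-arm swing fractions.
`cvpath.potentials` and `cvpath.dynamics` provide the model systems
(two-basin surfaces with exact barrier control, Müller–Brown, toy bead
helices) and a seeded Langevin engine, together with a brute-force
quadrature oracle every estimator is validated against. See
`docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Recover a 6 kcal/mol barrier with eABF + CZAR and check it against the
exact marginal:

```python
import numpy as np
from cvpath.dynamics import LangevinConfig
from cvpath.eabf import (BiasGrid, ExtendedState, coordinate_cv,
                         czar_gradient, integrate_gradient, run_eabf)
from cvpath.potentials import make_two_basin_potential, reference_pmf_quadrature

pot = make_two_basin_potential(barrier_height=6.0, basin_separation=2.0,
                               asymmetry=1.0)
cv = coordinate_cv([0, 1], 2)
cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
edges = [np.linspace(-2, 2, 29), np.linspace(-1.4, 1.4, 21)]

warm = BiasGrid(edges=edges, full_samples=200)
run_eabf(pot, cfg, cv, warm, ExtendedState(coupling=[25.0, 25.0]),
         1_200_000, seed=11, start=[-1.0, 0.0])          # adaptive warmup
est = BiasGrid(edges=edges, full_samples=200)
run_eabf(pot, cfg, cv, est, ExtendedState(coupling=[25.0, 25.0]),
         1_400_000, seed=12, start=[-1.0, 0.0], bias_source=warm)

grad = czar_gradient(est, 300.0, coupling=[25.0, 25.0])
fes = integrate_gradient(grad, est.edges, est.z_counts)
oracle = reference_pmf_quadrature(pot, lambda p: p, edges, 300.0,
                                  n_quad=500, align_axes={0: 0, 1: 1})
mask = est.z_counts >= est.full_samples
dev = fes.values - oracle.values
dev -= np.nanmean(dev[mask])
print(f"RMS vs oracle: {np.sqrt(np.nanmean(dev[mask]**2)):.2f} kcal/mol")
```

prints (exact value depends on the seeds)

```
RMS vs oracle: 0.14 kcal/mol
```

i.e. the adaptively biased run reconstructs the free-energy surface of
the double well to about a tenth of a kcal/mol; restricting to the
interior of the sampled region (two bins away from its rim, where the
estimator's binning assumptions hold) brings this to ≈0.10 kcal/mol.
Feeding the same surface's barrier difference into
`cvpath.umbrella.arrhenius_ratio(12.0, 6.0, 300.0)` gives `2.3e4` — the
rate advantage a 6 kcal/mol-barrier mechanism holds over a 12 kcal/mol
one at 300 K.

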