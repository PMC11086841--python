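"""Extended-system adaptive biasing force (eABF) with the CZAR estimator.

In eABF, each collective variable z(x) is harmonically tethered to a
fictitious extended coordinate λ carrying its own Langevin dynamics; the
adaptive bias acts on λ, built from the running mean of the coupling force
so that, once converged, the extended system diffuses on a flattened
landscape. The unbiased free-energy gradient along z is recovered by the
corrected-z-averaged restraint (CZAR) estimator

    dA/dz ≈ −k_B T · d/dz ln ρ(z) + k (⟨λ⟩_z − z),

where ρ is the biased histogram of the *true* CV and ⟨λ⟩_z the per-bin
mean extended coordinate (the binned correction uses the per-bin mean of
λ − z, which avoids an O(k·width²) discretization bias that the bin
center would introduce). Gradients are integrated to a free-energy surface by
cumulative trapezoid (1D) or a least-squares Poisson-like solve (2D).

Defaults mirror a production setup: coupling constants of order 10–125
kcal/mol/U², extended-thermostat friction 10 (inverse time), 300 K, a
full-samples ramp of 2000 counts, and stratification into non-overlapping
windows separated by harmonic walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import lsqr

from .constants import KB
from .dynamics import LangevinConfig, substream
from .potentials import FreeEnergySurface, ModelPotential

__all__ = [
    "CVMapping",
    "coordinate_cv",
    "linear_cv",
    "ExtendedState",
    "BiasGrid",
    "StratificationPlan",
    "run_eabf",
    "czar_gradient",
    "integrate_gradient",
    "stratified_eabf",
    "convergence_report",
]


@dataclass(frozen=True)
class CVMapping:
    """Differentiable map from configuration space to 1–2 CVs."""

    n_cvs: int
    value: callable  # x (dim,) -> z (n_cvs,)
    jacobian: callable  # x (dim,) -> (n_cvs, dim)


def coordinate_cv(indices, dimension: int) -> CVMapping:
    """CVs that are plain coordinates (e.g. z = x)."""
    indices = [int(i) for i in np.atleast_1d(indices)]
    jac = np.zeros((len(indices), dimension))
    for row, i in enumerate(indices):
        jac[row, i] = 1.0
    return CVMapping(
        n_cvs=len(indices),
        value=lambda x: np.asarray(x, dtype=float)[indices],
        jacobian=lambda x, _j=jac: _j,
    )


def linear_cv(weights) -> CVMapping:
    """CVs that are fixed linear combinations of the coordinates."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    return CVMapping(n_cvs=w.shape[0], value=lambda x: w @ np.asarray(x, dtype=float),
                     jacobian=lambda x: w)


@dataclass
class ExtendedState:
    """Extended-coordinate dynamics parameters and state.

    ``coupling`` k (kcal/mol/U²) tethers λ to z; λ is thermostatted by
    underdamped Langevin with its own ``friction`` and ``temperature``.
    The fictitious ``mass`` defaults to k/ω² with oscillation period 50
    timesteps, slow against the integrator but fast against bin diffusion.
    """

    coupling: np.ndarray  # per-CV k
    mass: np.ndarray | None = None
    friction: float = 10.0
    temperature: float = 300.0
    position: np.ndarray | None = None
    velocity: np.ndarray | None = None

    def __post_init__(self):
        self.coupling = np.atleast_1d(np.asarray(self.coupling, dtype=float))
        if np.any(self.coupling <= 0):
            raise ValueError("coupling force constants must be positive")
        if self.mass is not None:
            self.mass = np.atleast_1d(np.asarray(self.mass, dtype=float))
            if np.any(self.mass <= 0):
                raise ValueError("fictitious mass must be positive")


@dataclass
class BiasGrid:
    """Regular 1–2D grid accumulating eABF statistics.

    Per z-bin (true CV): sample count and running sum of λ — the CZAR
    inputs. Per λ-bin: count and running sum of the instantaneous force
    k(z − λ) felt by the extended coordinate — the ABF inputs. The applied
    bias in a λ-bin is the negated running mean force scaled by the ramp
    factor min(1, N/full_samples), so never-visited bins carry zero bias.
    """

    edges: list
    full_samples: int = 2000
    z_counts: np.ndarray = None
    z_sums: np.ndarray = None
    lambda_sums: np.ndarray = None
    abf_counts: np.ndarray = None
    force_sums: np.ndarray = None

    def __post_init__(self):
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if not np.allclose(np.diff(e), e[1] - e[0]):
                raise ValueError("bias grids require uniform bin widths")
        self._inv_width = [1.0 / (e[1] - e[0]) for e in self.edges]
        self._last_bin = [len(e) - 2 for e in self.edges]
        shape = tuple(len(e) - 1 for e in self.edges)
        d = len(self.edges)
        if self.z_counts is None:
            self.z_counts = np.zeros(shape)
            self.z_sums = np.zeros(shape + (d,))
            self.lambda_sums = np.zeros(shape + (d,))
            self.abf_counts = np.zeros(shape)
            self.force_sums = np.zeros(shape + (d,))

    @property
    def n_cvs(self) -> int:
        return len(self.edges)

    @property
    def shape(self):
        return self.z_counts.shape

    @property
    def centers(self):
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def widths(self):
        return [float(np.mean(np.diff(e))) for e in self.edges]

    def bin_index(self, z, clamp: bool = True):
        # uniform-grid arithmetic (edges are checked uniform in __post_init__)
        idx = []
        for d in range(len(self.edges)):
            e = self.edges[d]
            i = int((z[d] - e[0]) * self._inv_width[d])
            if i < 0 or i > self._last_bin[d]:
                if not clamp:
                    return None
                i = min(max(i, 0), self._last_bin[d])
            idx.append(i)
        return tuple(idx)

    def copy(self) -> "BiasGrid":
        return BiasGrid(edges=[e.copy() for e in self.edges],
                        full_samples=self.full_samples,
                        z_counts=self.z_counts.copy(),
                        z_sums=self.z_sums.copy(),
                        lambda_sums=self.lambda_sums.copy(),
                        abf_counts=self.abf_counts.copy(),
                        force_sums=self.force_sums.copy())

    def merge(self, other: "BiasGrid") -> "BiasGrid":
        """Bin-wise sum of statistics (associative, order-independent)."""
        if any(len(a) != len(b) or not np.allclose(a, b)
               for a, b in zip(self.edges, other.edges)):
            raise ValueError("grids have different edges")
        out = self.copy()
        out.z_counts += other.z_counts
        out.z_sums += other.z_sums
        out.lambda_sums += other.lambda_sums
        out.abf_counts += other.abf_counts
        out.force_sums += other.force_sums
        return out

    def bias_force(self, lam) -> np.ndarray:
        """ABF bias applied to λ at its current bin (ramped mean force)."""
        idx = self.bin_index(lam)
        n = self.abf_counts[idx]
        if n == 0:
            return np.zeros(self.n_cvs)
        ramp = min(1.0, n / self.full_samples)
        return -ramp * self.force_sums[idx] / n

    # -- restartable text serialization -----------------------------------
    def to_text(self) -> str:
        lines = [f"# eabf-grid ncv {self.n_cvs} full_samples {self.full_samples}"]
        for e in self.edges:
            lines.append("edges " + " ".join(f"{v:.12g}" for v in e))
        for name, arr in (("z_counts", self.z_counts),
                          ("z_sums", self.z_sums),
                          ("lambda_sums", self.lambda_sums),
                          ("abf_counts", self.abf_counts),
                          ("force_sums", self.force_sums)):
            lines.append(name + " " + " ".join(f"{v:.12g}" for v in arr.ravel()))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BiasGrid":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = lines[0].split()
        full_samples = int(head[head.index("full_samples") + 1])
        edges, arrays = [], {}
        for ln in lines[1:]:
            tok = ln.split()
            if tok[0] == "edges":
                edges.append(np.array([float(v) for v in tok[1:]]))
            else:
                arrays[tok[0]] = np.array([float(v) for v in tok[1:]])
        g = cls(edges=edges, full_samples=full_samples)
        d = g.n_cvs
        g.z_counts = arrays["z_counts"].reshape(g.shape)
        g.z_sums = arrays["z_sums"].reshape(g.shape + (d,))
        g.lambda_sums = arrays["lambda_sums"].reshape(g.shape + (d,))
        g.abf_counts = arrays["abf_counts"].reshape(g.shape)
        g.force_sums = arrays["force_sums"].reshape(g.shape + (d,))
        return g


@dataclass
class Window:
    """One stratification window: an axis-0 CV slab with harmonic walls."""

    lo: float
    hi: float
    start: np.ndarray = None
    n_steps: int = 50_000


@dataclass
class StratificationPlan:
    """Non-overlapping windows tiling the first CV axis.

    ``wall_k`` is the one-sided harmonic wall constant (kcal/mol/U²)
    applied to λ beyond a window boundary; wall regions are excluded from
    ABF accumulation.
    """

    windows: list
    wall_k: float = 100.0

    def __post_init__(self):
        ws = sorted(self.windows, key=lambda w: w.lo)
        for a, b in zip(ws, ws[1:]):
            if b.lo < a.hi - 1e-12:
                raise ValueError(f"windows overlap: [{a.lo},{a.hi}] and [{b.lo},{b.hi}]")
        self.windows = ws


def _default_mass(extended: ExtendedState, timestep: float) -> np.ndarray:
    period = 50.0 * timestep
    omega = 2.0 * np.pi / period
    return extended.coupling / omega**2


def run_eabf(
    potential: ModelPotential,
    config: LangevinConfig,
    cv_map: CVMapping,
    grid: BiasGrid,
    extended: ExtendedState,
    n_steps: int,
    seed,
    start=None,
    window: tuple | None = None,
    wall_k: float = 100.0,
    clamp: bool = True,
    bias_source: "BiasGrid | None" = None,
):
    """Run eABF, accumulating statistics into ``grid`` (returned with the
    sampled (z, λ) series).

    The physical coordinates follow the configured Langevin scheme under
    U(x) + Σ ½kᵢ(λᵢ − zᵢ(x))²; each λᵢ follows underdamped Langevin under
    the coupling force, the ramped ABF bias of its current bin, and — when
    a ``window`` (lo, hi on CV axis 0) is given — one-sided harmonic walls.
    Samples taken while λ sits beyond a wall are excluded from ABF
    accumulation. λ leaving the grid is clamped to the boundary bin when
    ``clamp`` (the default), else raises; one-sided harmonic walls at the
    grid boundary keep excursions rare.

    When ``bias_source`` is given, the applied bias reads from that frozen
    grid while statistics accumulate into ``grid`` — the production
    pattern for estimation phases: adapt first, then sample against the
    frozen bias so the ensemble is stationary.
    """
    rng_x = substream(seed, "eabf-x") if not isinstance(seed, np.random.Generator) else seed
    rng_l = substream(seed, "eabf-lambda") if not isinstance(seed, np.random.Generator) else seed
    d = cv_map.n_cvs
    k = extended.coupling
    m = extended.mass if extended.mass is not None else _default_mass(extended, config.timestep)
    kT_ext = KB * extended.temperature
    dt = config.timestep
    x = np.array(start if start is not None else
                 (np.asarray(potential.domain[0]) + np.asarray(potential.domain[1])) / 2.0,
                 dtype=float)
    z = np.asarray(cv_map.value(x), dtype=float)
    lam = np.array(extended.position if extended.position is not None else z, dtype=float)
    vlam = np.array(extended.velocity if extended.velocity is not None else
                    rng_l.normal(0.0, np.sqrt(kT_ext / m)), dtype=float)

    c1 = np.exp(-extended.friction * dt)
    c2 = np.sqrt(kT_ext / m * (1.0 - c1 * c1))

    # physical BAOAB constants
    gamma, mx, kT = config.friction, config.mass, KB * config.temperature
    cx1 = np.exp(-gamma * dt)
    cx2 = np.sqrt(kT / mx * (1.0 - cx1 * cx1))
    vx = rng_x.normal(0.0, np.sqrt(kT / mx), size=x.shape)

    def phys_force(x, z):
        # -∇U + coupling pull toward λ through the CV jacobian
        return -potential.gradient(x) + (k * (lam - z)) @ cv_map.jacobian(x)

    bias_of = grid if bias_source is None else bias_source

    def lam_force(lam, z):
        f = k * (z - lam) + bias_of.bias_force(lam)
        # one-sided harmonic walls confine lambda to the grid box
        for dd, e in enumerate(grid.edges):
            if lam[dd] < e[0]:
                f[dd] += wall_k * (e[0] - lam[dd])
            elif lam[dd] > e[-1]:
                f[dd] += wall_k * (e[-1] - lam[dd])
        if window is not None:
            lo, hi = window
            if lam[0] < lo:
                f[0] += wall_k * (lo - lam[0])
            elif lam[0] > hi:
                f[0] += wall_k * (hi - lam[0])
        return f

    z_series = np.empty((n_steps, d))
    lam_series = np.empty((n_steps, d))
    fx = phys_force(x, z)
    fl = lam_force(lam, z)
    for i in range(n_steps):
        # BAOAB for x
        vx = vx + 0.5 * dt * fx / mx
        x = x + 0.5 * dt * vx
        vx = cx1 * vx + cx2 * rng_x.standard_normal(x.shape)
        x = x + 0.5 * dt * vx
        # BAOAB for λ
        vlam = vlam + 0.5 * dt * fl / m
        lam = lam + 0.5 * dt * vlam
        vlam = c1 * vlam + c2 * rng_l.standard_normal(lam.shape)
        lam = lam + 0.5 * dt * vlam
        z = np.asarray(cv_map.value(x), dtype=float)
        fx = phys_force(x, z)
        fl = lam_force(lam, z)
        vx = vx + 0.5 * dt * fx / mx
        vlam = vlam + 0.5 * dt * fl / m

        in_window = window is None or (window[0] <= lam[0] <= window[1])
        zi = grid.bin_index(z, clamp=clamp)
        li = grid.bin_index(lam, clamp=clamp)
        if zi is None or li is None:
            raise ValueError(f"CV left the grid at step {i}: z={z}, λ={lam}")
        if in_window:
            grid.z_counts[zi] += 1
            grid.z_sums[zi] += z
            grid.lambda_sums[zi] += lam
            grid.abf_counts[li] += 1
            grid.force_sums[li] += k * (z - lam)
        z_series[i] = z
        lam_series[i] = lam

    extended.position, extended.velocity = lam.copy(), vlam.copy()
    return grid, z_series, lam_series


def czar_gradient(grid: BiasGrid, temperature: float, coupling=None,
                  min_count: int = 5) -> np.ndarray:
    """CZAR free-energy gradient per z-bin.

    Returns an array of shape ``grid.shape + (n_cvs,)`` holding, for each
    occupied bin, −k_B T ∂/∂z ln ρ(z) + k(⟨λ⟩_z − z). The log-density
    derivative uses centered differences over bins (one-sided stencils at
    occupied-region edges); bins with fewer than ``min_count`` samples are
    excluded (NaN). ``coupling`` must match the constants used when the
    grid was accumulated (defaults to 1).
    """
    if grid.z_counts.sum() == 0:
        raise ValueError("grid holds no samples")
    k = np.atleast_1d(np.asarray(1.0 if coupling is None else coupling, dtype=float))
    kT = KB * temperature
    n = grid.z_counts
    good = n >= min_count
    # E[ln N] ~ ln(EN) - 1/(2 EN) for Poisson counts; the +1/(2N) term
    # debiases the log-density in sparsely visited stencil neighbors
    logn = np.where(good, np.log(np.maximum(n, 1e-300))
                    + 1.0 / (2.0 * np.maximum(n, 1.0)), np.nan)
    d = grid.n_cvs
    out = np.full(grid.shape + (d,), np.nan)
    centers = grid.centers
    widths = grid.widths
    for axis in range(d):
        h = widths[axis]
        ln = np.moveaxis(logn, axis, 0)
        g = np.moveaxis(good, axis, 0)
        pad = np.zeros((1,) + g.shape[1:], dtype=bool)
        g_up = np.concatenate([g[1:], pad])  # neighbor at i+1 occupied?
        g_dn = np.concatenate([pad, g[:-1]])
        ln_up = np.concatenate([ln[1:], np.full((1,) + ln.shape[1:], np.nan)])
        ln_dn = np.concatenate([np.full((1,) + ln.shape[1:], np.nan), ln[:-1]])
        dl = np.full(g.shape, np.nan)
        centered = g & g_up & g_dn
        fwd = g & g_up & ~g_dn
        bwd = g & ~g_up & g_dn
        dl[centered] = (ln_up[centered] - ln_dn[centered]) / (2 * h)
        dl[fwd] = (ln_up[fwd] - ln[fwd]) / h
        dl[bwd] = (ln[bwd] - ln_dn[bwd]) / h
        dlog = np.moveaxis(dl, 0, axis)
        mean_lam = np.where(good[..., None], grid.lambda_sums / np.maximum(n, 1)[..., None],
                            np.nan)[..., axis]
        if np.any(grid.z_sums):
            mean_z = np.where(good[..., None], grid.z_sums / np.maximum(n, 1)[..., None],
                              np.nan)[..., axis]
        else:  # grids accumulated without z sums fall back to bin centers
            mean_z = np.broadcast_to(
                centers[axis].reshape([-1 if a == axis else 1 for a in range(d)]),
                grid.shape)
        ki = k[axis] if k.size > 1 else k[0]
        out[..., axis] = -kT * dlog + ki * (mean_lam - mean_z)
    return out


def integrate_gradient(gradient: np.ndarray, edges, counts=None) -> FreeEnergySurface:
    """Integrate a (possibly noisy) gradient field to a free-energy surface.

    1D: cumulative trapezoid over bin centers. 2D: least-squares solution of
    the finite-difference system ∇F ≈ g over non-NaN bins, which projects
    out any curl-inconsistent component. The result is min-gauged to zero;
    bins outside the largest set of defined bins stay NaN. Disconnected
    occupied components are each integrated with their own (undefined
    relative) offset, minimum-gauged jointly.
    """
    edges = [np.asarray(e, dtype=float) for e in edges]
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    if gradient.ndim == 2 and len(edges) == 1:
        g = gradient[:, 0]
        good = np.isfinite(g)
        f = np.full(g.shape, np.nan)
        idx = np.flatnonzero(good)
        if idx.size == 0:
            raise ValueError("no defined bins to integrate")
        segs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for seg in segs:
            z = centers[0][seg]
            vals = np.concatenate([[0.0], np.cumsum(0.5 * (g[seg][1:] + g[seg][:-1]) * np.diff(z))])
            f[seg] = vals
        return FreeEnergySurface(edges=edges, values=f, counts=counts).gauge()

    if gradient.ndim != 3 or len(edges) != 2:
        raise ValueError("gradient must be (n,) + (1,) or (nx, ny, 2)")
    nx, ny, _ = gradient.shape
    good = np.all(np.isfinite(gradient), axis=-1)
    if not good.any():
        raise ValueError("no defined bins to integrate")
    index = -np.ones((nx, ny), dtype=int)
    index[good] = np.arange(good.sum())
    hx = float(np.mean(np.diff(centers[0])))
    hy = float(np.mean(np.diff(centers[1])))
    rows, cols, data, rhs = [], [], [], []
    eq = 0
    for i in range(nx):
        for j in range(ny):
            if not good[i, j]:
                continue
            if i + 1 < nx and good[i + 1, j]:
                rows += [eq, eq]
                cols += [index[i + 1, j], index[i, j]]
                data += [1.0, -1.0]
                rhs.append(0.5 * (gradient[i, j, 0] + gradient[i + 1, j, 0]) * hx)
                eq += 1
            if j + 1 < ny and good[i, j + 1]:
                rows += [eq, eq]
                cols += [index[i, j + 1], index[i, j]]
                data += [1.0, -1.0]
                rhs.append(0.5 * (gradient[i, j, 1] + gradient[i, j + 1, 1]) * hy)
                eq += 1
    n_unknown = good.sum()
    # gauge row pinning the first defined bin of each connected component
    comp = _components(good)
    for c in np.unique(comp[comp >= 0]):
        first = np.argwhere(comp == c)[0]
        rows.append(eq)
        cols.append(index[tuple(first)])
        data.append(1.0)
        rhs.append(0.0)
        eq += 1
    a = coo_matrix((data, (rows, cols)), shape=(eq, n_unknown)).tocsr()
    sol = lsqr(a, np.asarray(rhs), atol=1e-12, btol=1e-12, iter_lim=20000)[0]
    f = np.full((nx, ny), np.nan)
    f[good] = sol
    return FreeEnergySurface(edges=edges, values=f, counts=counts).gauge()


def _components(good: np.ndarray) -> np.ndarray:
    """4-connected component labels over a boolean mask (−1 outside)."""
    from scipy.ndimage import label

    lab, _ = label(good)
    return lab - 1


def stratified_eabf(
    potential: ModelPotential,
    config: LangevinConfig,
    cv_map: CVMapping,
    grid_template: BiasGrid,
    extended_template: ExtendedState,
    plan: StratificationPlan,
    seed,
    inherited: BiasGrid | None = None,
):
    """Run one eABF window per plan entry and merge the statistics.

    Each window starts from a copy of the ``inherited`` grid (typically the
    exploratory run), so its bias is warm from step one; the merged result
    counts the inherited statistics exactly once plus every window's novel
    accumulation. Windows confine λ with the plan's harmonic walls and are
    seeded independently from the master seed.
    """
    base = inherited.copy() if inherited is not None else grid_template.copy()
    merged = base.copy()
    for w_idx, w in enumerate(plan.windows):
        work = base.copy()
        ext = replace(extended_template,
                      position=None, velocity=None,
                      coupling=extended_template.coupling.copy())
        start = w.start if w.start is not None else None
        if start is None:
            # put the walker mid-window along axis 0, domain middle elsewhere
            mid = 0.5 * (np.asarray(potential.domain[0]) + np.asarray(potential.domain[1]))
            start = mid.copy()
            start[0] = 0.5 * (w.lo + w.hi)
        run_eabf(potential, config, cv_map, work, ext, w.n_steps,
                 substream(seed, "window", w_idx), start=start,
                 window=(w.lo, w.hi), wall_k=plan.wall_k)
        novel = work.copy()
        novel.z_counts -= base.z_counts
        novel.z_sums -= base.z_sums
        novel.lambda_sums -= base.lambda_sums
        novel.abf_counts -= base.abf_counts
        novel.force_sums -= base.force_sums
        merged = merged.merge(novel)
    return merged


def convergence_report(snapshots, temperature: float, coupling=None,
                       n_boot: int = 200, seed: int = 0) -> list[dict]:
    """Convergence metrics from a time-ordered list of grid snapshots.

    For each snapshot after the first: RMS change of the CZAR gradient
    field versus the previous snapshot (over bins defined in both), the
    fraction of bins at or above full_samples, and min/median bin counts.
    A block-bootstrap per-bin error map of the mean force is estimated by
    treating inter-snapshot increments as blocks and resampling them.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots")
    grads = [czar_gradient(s, temperature, coupling) for s in snapshots]
    report = []
    for prev, cur, gp, gc, snap in zip(snapshots, snapshots[1:], grads, grads[1:],
                                       snapshots[1:]):
        both = np.all(np.isfinite(gp), axis=-1) & np.all(np.isfinite(gc), axis=-1)
        rms = float(np.sqrt(np.mean((gc[both] - gp[both]) ** 2))) if both.any() else np.nan
        counts = snap.z_counts
        report.append({
            "rms_gradient_change": rms,
            "fraction_full": float(np.mean(counts >= snap.full_samples)),
            "min_count": float(counts.min()),
            "median_count": float(np.median(counts)),
        })
    # block bootstrap on mean-force increments
    last = snapshots[-1]
    blocks_f = [b.force_sums - a.force_sums for a, b in zip(snapshots, snapshots[1:])]
    blocks_n = [b.abf_counts - a.abf_counts for a, b in zip(snapshots, snapshots[1:])]
    rng = substream(seed, "bootstrap")
    nb = len(blocks_f)
    means = np.empty((n_boot,) + last.force_sums.shape)
    for b in range(n_boot):
        pick = rng.integers(0, nb, size=nb)
        fs = sum(blocks_f[p] for p in pick)
        ns = sum(blocks_n[p] for p in pick)
        means[b] = fs / np.maximum(ns, 1)[..., None]
    report[-1]["force_error_map"] = means.std(axis=0, ddof=1)
    return report
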