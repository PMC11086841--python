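"""Umbrella sampling along a path, with Umbrella Integration and MBAR.

A converged string is refined by linear interpolation to a denser set of
equally spaced images (e.g. 32 → 128); each image becomes an umbrella
window: restrained Langevin sampling under ½ Σᵢ kᵢ(zᵢ − cᵢ)². Two
estimators consume the window samples:

* Umbrella Integration (UI) — per window, the local free-energy gradient
  is estimated from the Gaussian approximation of the biased marginal,
  ∂A/∂zᵢ ≈ (zᵢ − z̄ᵂᵢ)/(β σ²ᵂᵢ) − kᵢ(zᵢ − cᵂᵢ); the chain rule projects it
  onto the path tangent dz/dα and window-weighted gradients are integrated
  cumulatively over the path parameter α.
* MBAR — the multistate Bennett acceptance ratio solves the self-consistent
  window free energies, yields unbiased per-sample weights, and densities
  of arbitrary 1–2D observables are accumulated with a Gaussian kernel;
  F = −k_B T ln(density), min-gauged.

Profile post-processing (extrema and barriers) and the Arrhenius
barrier-difference rate ratio round out the analysis.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .dynamics import LangevinConfig, simulate_langevin, substream
from .eabf import CVMapping
from .potentials import FreeEnergySurface, ModelPotential
from .stringmethod import PathString, _embed_start, _equal_arc_positions, _restraint_force

__all__ = [
    "UmbrellaWindow",
    "WindowEnsemble",
    "refine_path",
    "run_umbrella",
    "pmf_umbrella_integration",
    "mbar_solve",
    "pmf_mbar",
    "profile_extrema",
    "arrhenius_ratio",
]


@dataclass
class UmbrellaWindow:
    """One image's restraint definition and its CV time series."""

    index: int
    centers: np.ndarray  # raw CV units
    force_constants: np.ndarray  # kcal/mol/U²; 0 marks an excluded CV
    alpha: float  # path parameter in [0, 1]
    samples: np.ndarray | None = None  # (n_frames, n_cvs), raw units

    def __post_init__(self):
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.force_constants = np.atleast_1d(np.asarray(self.force_constants, dtype=float))
        if np.any(self.force_constants < 0):
            raise ValueError("force constants must be non-negative")
        if self.samples is not None:
            self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
            if not np.all(np.isfinite(self.samples)):
                raise ValueError("window samples must be finite")

    def bias_energy(self, z) -> np.ndarray:
        d = np.atleast_2d(np.asarray(z, dtype=float)) - self.centers
        return 0.5 * (self.force_constants * d * d).sum(axis=-1)


@dataclass
class WindowEnsemble:
    """Ordered umbrella windows sharing one CV set, plus the path they straddle."""

    windows: list
    temperature: float = 300.0
    path: PathString | None = None

    def __post_init__(self):
        alphas = [w.alpha for w in self.windows]
        if any(b <= a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("window path parameters must increase with index")

    @property
    def n_cvs(self) -> int:
        return len(self.windows[0].centers)

    def to_table(self) -> str:
        """One row per frame: window id, α, CV values."""
        lines = ["# window alpha " + " ".join(f"z{i+1}" for i in range(self.n_cvs))]
        for w in self.windows:
            for row in (w.samples if w.samples is not None else []):
                lines.append(f"{w.index} {w.alpha:.10g} "
                             + " ".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"


def refine_path(path: PathString, n_images: int) -> PathString:
    """Linear-interpolation refinement to ``n_images`` equally spaced images
    (e.g. 32 → 128); endpoints are preserved exactly."""
    if n_images < 3:
        raise ValueError("need at least 3 images")
    if n_images < path.n_images:
        raise ValueError("refinement cannot reduce the image count")
    new = path.copy()
    new.images = _equal_arc_positions(path.images, n_images)
    return new


def run_umbrella(potential: ModelPotential, config: LangevinConfig,
                 cv_map: CVMapping, path: PathString, force_constants,
                 steps_per_window: int, seed, burn_in_fraction: float = 0.1,
                 exclude: tuple = ()) -> WindowEnsemble:
    """Sample every image of ``path`` under harmonic CV restraints.

    ``force_constants`` follow the string-optimization constants; CV
    indices in ``exclude`` get no restraint (their samples are still
    recorded). The first ``burn_in_fraction`` of each window is discarded.
    Warns when a window's sample mean drifts more than 5σ from its center.
    """
    k = np.atleast_1d(np.asarray(force_constants, dtype=float)).copy()
    k[list(exclude)] = 0.0
    raw = path.raw_images()
    arcs = path.arc_lengths()
    alphas = arcs / arcs[-1]
    burn = int(burn_in_fraction * steps_per_window)
    windows = []
    for idx in range(path.n_images):
        rng = substream(seed, "umbrella", idx)
        x0 = _embed_start(potential, cv_map, raw[idx])
        traj = simulate_langevin(potential, config, x0, steps_per_window, rng,
                                 extra_force=_restraint_force(cv_map, raw[idx], k))
        z = np.array([cv_map.value(x) for x in traj[burn:]])
        restrained = k > 0
        if restrained.any():
            sig = z[:, restrained].std(axis=0)
            drift = np.abs(z[:, restrained].mean(axis=0) - raw[idx][restrained])
            if np.any(drift > 5 * np.maximum(sig, 1e-12)):
                _warnings.warn(f"window {idx}: sample mean drifted > 5 sigma from "
                               "its restraint center (poor restraint?)")
        windows.append(UmbrellaWindow(index=idx, centers=raw[idx],
                                      force_constants=k, alpha=float(alphas[idx]),
                                      samples=z))
    return WindowEnsemble(windows=windows, temperature=config.temperature, path=path)


def _overlap_coefficient(w1: UmbrellaWindow, w2: UmbrellaWindow) -> float:
    """Gaussian overlap (Bhattacharyya coefficient) of two windows' samples,
    taken along the line connecting their centers."""
    d = w2.centers - w1.centers
    n = np.linalg.norm(d)
    if n == 0:
        return 1.0
    u = d / n
    a = w1.samples @ u
    b = w2.samples @ u
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return 0.0
    bd = 0.25 * (a.mean() - b.mean()) ** 2 / (va + vb) \
        + 0.5 * np.log(0.5 * (va + vb) / np.sqrt(va * vb))
    return float(np.exp(-bd))


def pmf_umbrella_integration(ensemble: WindowEnsemble,
                             min_samples: int = 50) -> FreeEnergySurface:
    """PMF along the path parameter α by Umbrella Integration + chain rule.

    Per window w, the Gaussian mean-force estimate for each restrained CV,
    evaluated at the window centers z(α), is projected onto the path tangent
    (central differences of the raw images over α). Estimates from all
    windows are combined with weights ∝ sample count × normal density at
    the evaluation point, and the combined dA/dα is integrated by cumulative
    trapezoid, min-gauged to zero.
    """
    wins = [w for w in ensemble.windows
            if w.samples is not None and len(w.samples) >= min_samples]
    skipped = len(ensemble.windows) - len(wins)
    if skipped:
        _warnings.warn(f"{skipped} window(s) below {min_samples} samples excluded")
    if len(wins) < 2:
        raise ValueError("umbrella integration needs at least 2 usable windows")
    for a, b in zip(wins, wins[1:]):
        if _overlap_coefficient(a, b) < 0.01:
            _warnings.warn(f"windows {a.index} and {b.index} barely overlap "
                           "(coefficient < 0.01)")
    beta = 1.0 / (KB * ensemble.temperature)
    alphas = np.array([w.alpha for w in wins])
    centers = np.array([w.centers for w in wins])
    restrained = wins[0].force_constants > 0
    # path tangent dz/dα by central differences of the images over α
    tangent = np.gradient(centers, alphas, axis=0)

    means = np.array([w.samples.mean(axis=0) for w in wins])
    variances = np.array([w.samples.var(axis=0, ddof=1) for w in wins])
    counts = np.array([len(w.samples) for w in wins], dtype=float)

    dAda = np.empty(len(wins))
    for i, w_eval in enumerate(wins):
        z = w_eval.centers
        # local estimates from every window at this evaluation point
        grads = ((z - means) / (beta * variances)
                 - np.array([w.force_constants for w in wins]) * (z - centers))
        # normal-density log-weights along restrained CVs
        logw = (np.log(counts)
                - 0.5 * (((z - means)[:, restrained] ** 2
                          / variances[:, restrained]).sum(axis=1))
                - 0.5 * np.log(variances[:, restrained]).sum(axis=1))
        logw -= logsumexp(logw)
        wgt = np.exp(logw)
        g = (wgt[:, None] * grads).sum(axis=0)
        dAda[i] = float((g * tangent[i])[restrained].sum())
    f = np.concatenate([[0.0],
                        np.cumsum(0.5 * (dAda[1:] + dAda[:-1]) * np.diff(alphas))])
    edges = np.concatenate([[alphas[0] - (alphas[1] - alphas[0]) / 2],
                            (alphas[1:] + alphas[:-1]) / 2,
                            [alphas[-1] + (alphas[-1] - alphas[-2]) / 2]])
    return FreeEnergySurface(edges=[edges], values=f, counts=counts).gauge()


def mbar_solve(bias_energies: np.ndarray, counts: np.ndarray, temperature: float,
               tol: float = 1e-8, max_iter: int = 1000):
    """Self-consistent MBAR window free energies and per-sample log-weights.

    ``bias_energies[k, n]`` is window k's bias evaluated on pooled sample n
    (kcal/mol); ``counts[k]`` the number of samples drawn from window k.
    Returns (f_k in kcal/mol with f_0 = 0, log unbiased weights normalized
    so logsumexp = 0). Raises with a diagnostic listing disconnected window
    groups when the overlap graph is disconnected.
    """
    beta = 1.0 / (KB * temperature)
    u = beta * np.asarray(bias_energies, dtype=float)  # reduced potentials
    n_k = np.asarray(counts, dtype=float)
    n_win, n_tot = u.shape
    if n_k.sum() != n_tot:
        raise ValueError("counts do not sum to the pooled sample size")
    _check_overlap(u, n_k)
    log_nk = np.log(n_k)

    # maximum-likelihood form: the MBAR estimating equations are the
    # stationarity conditions of a convex objective in f (normalized per
    # sample so the optimizer tolerances are size-independent)
    def objective(f):
        log_den = logsumexp(log_nk[None, :] + f[None, :] - u.T, axis=1)
        obj = (log_den.sum() - float(n_k @ f)) / n_tot
        w = np.exp(log_nk[:, None] + f[:, None] - u - log_den[None, :])
        grad = (w.sum(axis=1) - n_k) / n_tot
        return obj, grad

    from scipy.optimize import minimize

    res = minimize(objective, np.zeros(n_win), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-11})
    f = res.x - res.x[0]
    # polish with self-consistent sweeps to the requested tolerance
    for _ in range(50):
        log_den = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
        new_f = -logsumexp(-u - log_den[None, :], axis=1)
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            break
    log_den = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
    logw = -log_den
    logw -= logsumexp(logw)
    return f / beta, logw


def _check_overlap(u: np.ndarray, n_k: np.ndarray, threshold: float = 30.0):
    """Connectivity of the window-overlap graph: windows k, l are linked if
    some sample has low bias energy under both."""
    n_win = u.shape[0]
    adj = np.zeros((n_win, n_win), dtype=bool)
    umin = u.min(axis=0)
    low = u - umin[None, :] < threshold
    for k in range(n_win):
        for l in range(k + 1, n_win):
            adj[k, l] = adj[l, k] = bool(np.any(low[k] & low[l]))
    seen = np.zeros(n_win, dtype=bool)
    groups = []
    for start in range(n_win):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for l in np.flatnonzero(adj[k]):
                if not seen[l]:
                    seen[l] = True
                    stack.append(l)
        groups.append(sorted(comp))
    if len(groups) > 1:
        raise ValueError(f"umbrella windows do not overlap; disconnected groups: {groups}")


def _scott_bandwidth(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scott's-rule bandwidth per dimension with effective sample size."""
    ess = np.exp(-np.sum(weights * np.log(np.maximum(weights, 1e-300))))
    d = values.shape[1]
    mean = weights @ values
    var = weights @ (values - mean) ** 2
    return np.sqrt(var) * ess ** (-1.0 / (d + 4))


def pmf_mbar(ensemble: WindowEnsemble, observable=None, grid_edges=None,
             kde_bandwidth=None, tol: float = 1e-8,
             stride: int = 1) -> FreeEnergySurface:
    """PMF over arbitrary 1–2D observables by MBAR + Gaussian KDE.

    ``observable`` maps a (n, n_cvs) sample block to (n, d) observable
    values (default: the first CV). Unbiased per-sample weights from MBAR
    are accumulated on the grid with a Gaussian kernel (Scott's-rule
    bandwidth unless overridden); F = −k_B T ln density, min-gauged.
    """
    wins = [w for w in ensemble.windows if w.samples is not None and len(w.samples)]
    pooled = np.concatenate([w.samples[::stride] for w in wins])
    counts = np.array([len(w.samples[::stride]) for w in wins])
    bias = np.stack([w.bias_energy(pooled) for w in wins])
    f_k, logw = mbar_solve(bias, counts, ensemble.temperature, tol=tol)
    w = np.exp(logw)
    obs = (pooled[:, :1] if observable is None
           else np.atleast_2d(np.asarray(observable(pooled), dtype=float)))
    if obs.shape[0] != pooled.shape[0]:
        obs = obs.T
    d = obs.shape[1]
    if d not in (1, 2):
        raise ValueError("observables must be 1- or 2-dimensional")
    if grid_edges is None:
        grid_edges = [np.linspace(obs[:, j].min(), obs[:, j].max(), 51)
                      for j in range(d)]
    edges = [np.asarray(e, dtype=float) for e in grid_edges]
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    h = (np.atleast_1d(np.asarray(kde_bandwidth, dtype=float))
         if kde_bandwidth is not None else _scott_bandwidth(obs, w))
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    # Gaussian-kernel weighted density at grid points
    dens = np.zeros(pts.shape[0])
    ess_acc = np.zeros(pts.shape[0])
    chunk = 2048
    for lo in range(0, obs.shape[0], chunk):
        hi = lo + chunk
        diff = (pts[:, None, :] - obs[None, lo:hi, :]) / h
        kern = np.exp(-0.5 * (diff ** 2).sum(axis=-1)) / np.prod(np.sqrt(2 * np.pi) * h)
        dens += kern @ w[lo:hi]
        ess_acc += kern @ np.ones(min(hi, obs.shape[0]) - lo)
    with np.errstate(divide="ignore"):
        f = -KB * ensemble.temperature * np.log(dens)
    f[~np.isfinite(f)] = np.nan
    shape = tuple(len(c) for c in centers)
    return FreeEnergySurface(edges=edges, values=f.reshape(shape),
                             counts=ess_acc.reshape(shape)).gauge()


def profile_extrema(profile, smoothing_window: int = 1):
    """Local minima/maxima and barriers of a 1D free-energy profile.

    After optional moving-average smoothing (odd window, endpoints kept),
    interior extrema are found by sign changes of discrete differences,
    with plateaus resolved toward lower α. Boundary points count as minima
    when the profile rises away from them. Barrier between adjacent minima
    = maximum between them minus the left minimum (the direction of
    increasing α). Returns dict with 'minima', 'maxima' (index lists) and
    'barriers' (list of (left_min_idx, max_idx, height)).
    """
    if isinstance(profile, FreeEnergySurface):
        values = profile.values
        coords = profile.centers[0]
    else:
        values = np.asarray(profile, dtype=float)
        coords = np.arange(len(values), dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 profile points")
    v = values.astype(float).copy()
    if smoothing_window > 1:
        w = int(smoothing_window) | 1
        half = w // 2
        sm = v.copy()
        for i in range(half, len(v) - half):
            sm[i] = v[i - half:i + half + 1].mean()
        v = sm
    d = np.diff(v)
    sign = np.sign(d)
    # zero-difference plateaus take the sign of the next change, so a
    # plateau extremum lands on its first point (ties toward lower α)
    for i in range(len(sign) - 2, -1, -1):
        if sign[i] == 0:
            sign[i] = sign[i + 1]
    minima, maxima = [], []
    if sign[0] > 0:
        minima.append(0)
    elif sign[0] < 0:
        maxima.append(0)
    for i in range(1, len(sign)):
        if sign[i - 1] < 0 and sign[i] > 0:
            minima.append(i)
        elif sign[i - 1] > 0 and sign[i] < 0:
            maxima.append(i)
    if sign[-1] < 0:
        minima.append(len(v) - 1)
    elif sign[-1] > 0:
        maxima.append(len(v) - 1)
    barriers = []
    for a, b in zip(minima, minima[1:]):
        seg = slice(a, b + 1)
        top = a + int(np.argmax(v[seg]))
        barriers.append((a, top, float(v[top] - v[a])))
    return {"minima": minima, "maxima": maxima, "barriers": barriers,
            "coords": coords, "smoothed": v}


def arrhenius_ratio(barrier_slow: float, barrier_fast: float,
                    temperature: float = 300.0) -> float:
    """Rate ratio exp((ΔG‡_slow − ΔG‡_fast)/k_B T) assuming equal
    pre-exponential factors.

    With barriers of 12 and 6 kcal/mol at 300 K this evaluates to ≈2.3×10⁴:
    the lower-barrier mechanism outruns the higher-barrier one by four
    orders of magnitude.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp((barrier_slow - barrier_fast) / (KB * temperature)))
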