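"""Swarms-of-trajectories string method in normalized CV space.

A discretized path (string) of M images between two end states is relaxed
toward the minimum free energy path: each interior image is equilibrated
under harmonic CV restraints, a swarm of short unbiased trajectories is
launched from equilibrated snapshots, and the image is moved by the mean
CV drift of the swarm — which, up to mobility effects, points down the
local free-energy gradient. After every move the string is reparametrized
to equal arc length along its piecewise-linear interpolant, projecting out
tangential motion so only the orthogonal component evolves the path.

CVs are normalized to [0, 1] by their total variation between the two end
states so reparametrization weighs heterogeneous CVs (Å vs deg) evenly.
Convergence is monitored as RMSD in normalized CV space against the
initial string; converged analysis uses the image-wise average over the
trailing iterations, reparametrized once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .dynamics import LangevinConfig, simulate_langevin, substream
from .eabf import CVMapping
from .potentials import ModelPotential

__all__ = [
    "NormalizationMap",
    "normalize_cvs",
    "PathString",
    "initialize_string",
    "reparametrize",
    "SwarmConfig",
    "swarm_drift",
    "swarm_iteration",
    "string_convergence",
    "average_string",
    "uplift_path",
]


@dataclass(frozen=True)
class NormalizationMap:
    """Per-CV affine map raw → (raw − offset) / scale."""

    offsets: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        if np.any(self.scales <= 0):
            raise ValueError("normalization scales must be positive")

    def normalize(self, raw):
        return (np.asarray(raw, dtype=float) - self.offsets) / self.scales

    def denormalize(self, norm):
        return np.asarray(norm, dtype=float) * self.scales + self.offsets


def normalize_cvs(endpoint_a, endpoint_b, fallback_scale=None,
                  names=None) -> NormalizationMap:
    """Normalization by total variation between the two end states.

    offset = min(aᵢ, bᵢ) and scale = |bᵢ − aᵢ| per CV, so each endpoint maps
    to 0 or 1 per coordinate. A CV with zero variation raises (naming the
    CV) unless ``fallback_scale`` supplies its scale.
    """
    a = np.asarray(endpoint_a, dtype=float)
    b = np.asarray(endpoint_b, dtype=float)
    scales = np.abs(b - a)
    zero = scales == 0
    if np.any(zero):
        if fallback_scale is None:
            bad = (np.asarray(names)[zero] if names is not None
                   else np.flatnonzero(zero))
            raise ValueError(f"zero total variation for CV(s) {list(bad)}; "
                             "supply fallback_scale")
        scales = np.where(zero, np.broadcast_to(fallback_scale, scales.shape), scales)
    return NormalizationMap(offsets=np.minimum(a, b), scales=scales)


@dataclass
class PathString:
    """M images × D normalized CVs plus normalization and iteration history."""

    images: np.ndarray
    norm: NormalizationMap
    lock_endpoints: bool = True
    iteration: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 2 or self.images.shape[0] < 3:
            raise ValueError("a string needs at least 3 images")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def n_cvs(self) -> int:
        return self.images.shape[1]

    def raw_images(self) -> np.ndarray:
        return self.norm.denormalize(self.images)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length along the polyline, starting at 0."""
        seg = np.linalg.norm(np.diff(self.images, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def copy(self) -> "PathString":
        return PathString(self.images.copy(), self.norm, self.lock_endpoints,
                          self.iteration, [h.copy() for h in self.history])

    # -- tabular text serialization ---------------------------------------
    def to_table(self) -> str:
        lines = [f"# string M {self.n_images} D {self.n_cvs} iteration {self.iteration}"]
        lines.append("offsets " + " ".join(f"{v:.12g}" for v in self.norm.offsets))
        lines.append("scales " + " ".join(f"{v:.12g}" for v in self.norm.scales))
        for it, imgs in enumerate([*self.history, self.images]):
            for m, row in enumerate(imgs):
                lines.append(f"{it} {m} " + " ".join(f"{v:.12g}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "PathString":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = lines[0].split()
        it = int(head[head.index("iteration") + 1])
        offsets = [float(v) for v in lines[1].split()[1:]]
        scales = [float(v) for v in lines[2].split()[1:]]
        rows = [[float(v) for v in ln.split()] for ln in lines[3:]]
        iters = sorted({int(r[0]) for r in rows})
        frames = []
        for i in iters:
            sub = sorted((r for r in rows if int(r[0]) == i), key=lambda r: int(r[1]))
            frames.append(np.array([r[2:] for r in sub]))
        path = cls(frames[-1], NormalizationMap(offsets, scales), iteration=it,
                   history=frames[:-1])
        return path


def initialize_string(endpoint_a, endpoint_b, n_images: int,
                      norm: NormalizationMap | None = None,
                      mode: str = "straight") -> PathString:
    """Straight-line initial guess between two end states in normalized space."""
    if n_images < 3:
        raise ValueError("need at least 3 images")
    if mode != "straight":
        raise ValueError(f"unknown initialization mode {mode!r}")
    if norm is None:
        norm = normalize_cvs(endpoint_a, endpoint_b)
    a = norm.normalize(endpoint_a)
    b = norm.normalize(endpoint_b)
    t = np.linspace(0.0, 1.0, n_images)[:, None]
    return PathString(images=(1 - t) * a + t * b, norm=norm)


def _merge_degenerate(images: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    keep = np.concatenate([[True], seg > tol])
    keep[-1] = True
    out = images[keep]
    if out.shape[0] < 2:
        raise ValueError("string is fully degenerate (all images coincide)")
    return out


def _equal_arc_positions(images: np.ndarray, n_images: int) -> np.ndarray:
    """New image positions at equal arc length along the piecewise-linear
    interpolant through ``images``."""
    pts = _merge_degenerate(images)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_images)
    out = np.empty((n_images, images.shape[1]))
    out[0], out[-1] = images[0], images[-1]
    for i, t in enumerate(targets[1:-1], start=1):
        j = min(int(np.searchsorted(s, t, side="right")) - 1, len(seg) - 1)
        frac = (t - s[j]) / seg[j]
        out[i] = pts[j] + frac * (pts[j + 1] - pts[j])
    return out


def reparametrize(path: PathString) -> PathString:
    """Equal-arc-length reparametrization along the piecewise-linear
    interpolant; endpoints and total path length are preserved."""
    new = path.copy()
    new.images = _equal_arc_positions(path.images, path.n_images)
    return new


@dataclass
class SwarmConfig:
    """Per-iteration sampling budget of the swarms-of-trajectories update.

    ``restraint_k`` are per-CV harmonic constants in raw units
    (kcal/mol/U²); equilibration and swarm lengths are in integrator steps;
    ``swarm_size`` S trajectories are launched per image per iteration with
    velocities resampled from Maxwell–Boltzmann.
    """

    restraint_k: np.ndarray
    equil_steps: int = 500
    swarm_size: int = 20
    swarm_steps: int = 50
    drift_scale: float = 1.0

    def __post_init__(self):
        self.restraint_k = np.atleast_1d(np.asarray(self.restraint_k, dtype=float))
        if self.swarm_size < 1 or self.swarm_steps < 1 or self.equil_steps < 1:
            raise ValueError("swarm sizes and lengths must be >= 1")
        if np.any(self.restraint_k <= 0):
            raise ValueError("restraint constants must be positive")


def _restraint_force(cv_map: CVMapping, center_raw, k):
    def force(x, step):
        z = np.asarray(cv_map.value(x), dtype=float)
        return (k * (center_raw - z)) @ cv_map.jacobian(x)
    return force


def _embed_start(potential: ModelPotential, cv_map: CVMapping, center_raw):
    """Heuristic configuration realizing given CV values: start from the
    domain midpoint and relax onto the restraint center by damped descent."""
    lo, hi = (np.asarray(b, dtype=float) for b in potential.domain)
    x = 0.5 * (lo + hi)
    for _ in range(200):
        z = np.asarray(cv_map.value(x), dtype=float)
        step = (center_raw - z) @ cv_map.jacobian(x)
        if np.linalg.norm(step) < 1e-10:
            break
        x = x + 0.5 * step
    return x


def swarm_drift(potential: ModelPotential, config: LangevinConfig,
                cv_map: CVMapping, center_raw, cfg: "SwarmConfig", rng,
                scales=None):
    """Mean CV drift of one swarm launched from a restrained image.

    Equilibrates under harmonic restraints at ``center_raw``, launches
    ``cfg.swarm_size`` unbiased trajectories of ``cfg.swarm_steps`` steps
    from trailing equilibrated snapshots (velocities resampled at launch),
    and returns ``(mean_drift, per_member_drifts)`` where drift is the
    final-minus-initial CV displacement, divided by ``scales`` when given
    (normalized units).
    """
    center_raw = np.asarray(center_raw, dtype=float)
    x0 = _embed_start(potential, cv_map, center_raw)
    eq = simulate_langevin(potential, config, x0, cfg.equil_steps, rng,
                           extra_force=_restraint_force(cv_map, center_raw,
                                                        cfg.restraint_k))
    take = np.linspace(cfg.equil_steps // 2, cfg.equil_steps - 1,
                       cfg.swarm_size).astype(int)
    drifts = np.empty((cfg.swarm_size, cv_map.n_cvs))
    for s, frame in enumerate(take):
        xs = eq[frame]
        z0 = np.asarray(cv_map.value(xs), dtype=float)
        traj = simulate_langevin(potential, config, xs, cfg.swarm_steps, rng)
        z1 = np.asarray(cv_map.value(traj[-1]), dtype=float)
        drifts[s] = (z1 - z0) / (scales if scales is not None else 1.0)
    return drifts.mean(axis=0), drifts


def swarm_iteration(path: PathString, potential: ModelPotential,
                    config: LangevinConfig, cv_map: CVMapping,
                    cfg: SwarmConfig, seed) -> PathString:
    """One string update: equilibrate, launch swarms, move by mean drift,
    reparametrize.

    Per interior image: (1) restrained Langevin equilibration at the image
    center; (2) S unbiased trajectories from equilibrated snapshots with
    Maxwell–Boltzmann velocities; (3) drift = swarm mean of final-minus-
    initial CV displacement, expressed in normalized units; (4) image moved
    by ``drift_scale`` × drift. Endpoints stay fixed. The updated string is
    reparametrized, the iteration count incremented, and the pre-update
    images appended to the history. Identical seeds give bit-identical
    updates.
    """
    new = path.copy()
    new.history.append(path.images.copy())
    raw_centers = path.raw_images()
    for idx in range(1, path.n_images - 1):
        rng = substream(seed, "swarm", path.iteration, idx)
        drift, _ = swarm_drift(potential, config, cv_map, raw_centers[idx],
                               cfg, rng, scales=path.norm.scales)
        new.images[idx] = path.images[idx] + cfg.drift_scale * drift
    new.images = _equal_arc_positions(new.images, new.n_images)
    new.iteration = path.iteration + 1
    return new


def string_convergence(path_or_history) -> np.ndarray:
    """Per-iteration RMSD (normalized CV space, all images) vs the initial
    string."""
    history = (path_or_history.history + [path_or_history.images]
               if isinstance(path_or_history, PathString) else list(path_or_history))
    if not history:
        raise ValueError("empty string history")
    ref = np.asarray(history[0], dtype=float)
    return np.array([float(np.sqrt(np.mean((np.asarray(h) - ref) ** 2)))
                     for h in history])


def is_converged(path: PathString, window: int = 50, rel_tol: float = 0.01) -> bool:
    """Convergence call: the RMSD-vs-initial series varies by less than
    ``rel_tol`` (relative) over the trailing ``window`` iterations."""
    series = string_convergence(path)
    if len(series) < window + 1:
        return False
    tail = series[-window:]
    scale = max(abs(tail).max(), 1e-12)
    return float(tail.max() - tail.min()) / scale < rel_tol


def average_string(path_or_history, last_n: int = 50) -> PathString:
    """Image-wise mean over the last ``last_n`` iterations, reparametrized once."""
    if isinstance(path_or_history, PathString):
        frames = path_or_history.history + [path_or_history.images]
        norm = path_or_history.norm
    else:
        raise TypeError("average_string expects a PathString")
    if not frames:
        raise ValueError("empty string history")
    if last_n > len(frames):
        raise ValueError(f"last_n={last_n} exceeds history length {len(frames)}")
    mean = np.mean(frames[-last_n:], axis=0)
    avg = PathString(mean, norm, iteration=path_or_history.iteration)
    return reparametrize(avg)


def uplift_path(low_path: PathString, potential: ModelPotential,
                config: LangevinConfig, low_cv_map: CVMapping,
                extra_cv_map: CVMapping, restraint_k,
                norm_full: NormalizationMap,
                sampling_steps: int = 2000, seed=0,
                variance_threshold: float = np.inf):
    """Lift a low-dimensional string into a larger CV set.

    For each image, restrained sampling is run with restraints on the
    low-D CVs only; the extra CVs take their sampled means. Each extra-CV
    profile is then smoothed along the path with a window-3 moving average
    (endpoints kept) and the lifted string is reparametrized under the
    full-space normalization. Returns (path, warnings) where warnings
    lists image indices whose restrained sampling failed to localize
    (low-D CV variance above ``variance_threshold``).
    """
    k = np.atleast_1d(np.asarray(restraint_k, dtype=float))
    raw_low = low_path.raw_images()
    m = low_path.n_images
    d_extra = extra_cv_map.n_cvs
    extra = np.empty((m, d_extra))
    warnings = []
    for idx in range(m):
        rng = substream(seed, "uplift", idx)
        x0 = _embed_start(potential, low_cv_map, raw_low[idx])
        traj = simulate_langevin(potential, config, x0, sampling_steps, rng,
                                 extra_force=_restraint_force(low_cv_map,
                                                              raw_low[idx], k))
        zs = np.array([extra_cv_map.value(x) for x in traj[sampling_steps // 5:]])
        low = np.array([low_cv_map.value(x) for x in traj[sampling_steps // 5:]])
        if np.any(low.var(axis=0) > variance_threshold):
            warnings.append(idx)
        extra[idx] = zs.mean(axis=0)
    smoothed = extra.copy()
    for j in range(d_extra):
        smoothed[1:-1, j] = (extra[:-2, j] + extra[1:-1, j] + extra[2:, j]) / 3.0
    full_raw = np.concatenate([raw_low, smoothed], axis=1)
    lifted = PathString(norm_full.normalize(full_raw), norm_full)
    return reparametrize(lifted), warnings
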