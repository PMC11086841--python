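"""Trajectory post-processing: RMSD clustering, representatives, states.

Frames are compared by the Kabsch-minimal RMSD over a chosen atom
selection (for a motor domain: the CA atoms of the Relay and SH1 helices),
grouped by deterministic average-linkage agglomerative clustering, and
summarized by per-cluster occupancies, the average structure of the most
populated cluster, and the "typical frame" closest to the ensemble mean.
Metastable-state membership is assigned by elliptical regions in CV space,
and lever-arm-swing displacements are expressed as percentages of the full
transition via a calibration pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .conformers import Conformation
from .geometry import superpose_kabsch

__all__ = [
    "pairwise_rmsd_matrix",
    "ClusterModel",
    "cluster_frames",
    "choose_n_clusters",
    "representative_structure",
    "typical_frame",
    "StateRegion",
    "assign_states",
    "swing_fraction",
]


def pairwise_rmsd_matrix(frames, selection=None) -> np.ndarray:
    """Symmetric matrix of Kabsch-minimal RMSDs (Å) between all frame pairs."""
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, _ = superpose_kabsch(frames[i], frames[j], selection)
            mat[i, j] = mat[j, i] = r
    return mat


@dataclass
class ClusterModel:
    """Cluster labels (contiguous from 0), occupancies, and linkage metadata."""

    labels: np.ndarray
    occupancies: np.ndarray
    most_populated: int
    linkage_method: str = "average"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if not np.isclose(self.occupancies.sum(), 1.0):
            raise ValueError("occupancies must sum to 1")

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def to_table(self) -> str:
        lines = ["# frame cluster"]
        lines += [f"{i} {l}" for i, l in enumerate(self.labels)]
        lines.append("# cluster occupancy")
        lines += [f"# {c} {o:.6f}" for c, o in enumerate(self.occupancies)]
        return "\n".join(lines) + "\n"


def cluster_frames(matrix: np.ndarray, n_clusters: int) -> ClusterModel:
    """Deterministic average-linkage agglomerative clustering of a
    precomputed distance matrix.

    Labels are renumbered contiguously from 0 in order of first appearance;
    the most populated cluster breaks ties toward the lowest label.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T):
        raise ValueError("matrix must be square and symmetric")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n_clusters == n:
        raw = np.arange(n)
    else:
        z = linkage(squareform(matrix, checks=False), method="average")
        raw = fcluster(z, t=n_clusters, criterion="maxclust")
    # contiguous relabel by first appearance
    relabel, labels = {}, np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(r, len(relabel))
    k = len(relabel)
    occ = np.bincount(labels, minlength=k) / n
    return ClusterModel(labels=labels, occupancies=occ,
                        most_populated=int(np.argmax(occ)))


def choose_n_clusters(matrix: np.ndarray, occupancy_threshold: float = 0.10,
                      min_high_occupancy: int = 2, max_clusters: int = 10):
    """Advisory cluster count: the smallest n giving at least
    ``min_high_occupancy`` clusters above the occupancy threshold."""
    for n in range(min_high_occupancy, max_clusters + 1):
        model = cluster_frames(matrix, n)
        if np.count_nonzero(model.occupancies > occupancy_threshold) >= min_high_occupancy:
            return n, model
    return max_clusters, cluster_frames(matrix, max_clusters)


def representative_structure(frames, model: ClusterModel,
                             align_selection=None) -> Conformation:
    """Average structure of the most populated cluster.

    Members are aligned to the first member over ``align_selection``
    (for real proteins: a structurally invariant anchor such as the
    N-terminal subdomain CA atoms), then averaged coordinate-wise over all
    atoms.
    """
    idx = model.members(model.most_populated)
    if idx.size == 0:
        raise ValueError("most populated cluster is empty")
    ref = frames[idx[0]]
    acc = np.zeros_like(ref.coords)
    for i in idx:
        _, (rot, trans) = superpose_kabsch(frames[i], ref, align_selection)
        acc += frames[i].coords @ rot.T + trans
    return ref.with_coords(acc / idx.size)


def typical_frame(frames, align_selection=None, rmsd_selection=None) -> int:
    """Index of the frame closest (in RMSD over ``rmsd_selection``) to the
    ensemble-average structure.

    Frames are first aligned over ``align_selection`` onto the first frame,
    the all-atom average structure is computed, and the returned index
    minimizes the plain (post-alignment) RMSD to that average; ties break
    toward the lowest index.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    if len(frames) == 1:
        return 0
    ref = frames[0]
    aligned = []
    for f in frames:
        _, (rot, trans) = superpose_kabsch(f, ref, align_selection)
        aligned.append(f.coords @ rot.T + trans)
    aligned = np.array(aligned)
    mean = aligned.mean(axis=0)
    sel = (slice(None) if rmsd_selection is None
           else np.asarray(rmsd_selection))
    if isinstance(sel, np.ndarray) and sel.dtype == bool:
        sel = np.flatnonzero(sel)
    diffs = aligned[:, sel, :] - mean[sel, :]
    rmsds = np.sqrt((diffs ** 2).sum(axis=(1, 2)) / diffs.shape[1])
    return int(np.argmin(rmsds))


@dataclass(frozen=True)
class StateRegion:
    """Named elliptical region in CV space: center and per-axis semi-axes."""

    name: str
    center: dict
    semi_axes: dict

    def __post_init__(self):
        if set(self.center) != set(self.semi_axes):
            raise ValueError("center and semi_axes must share CV names")
        if any(v <= 0 for v in self.semi_axes.values()):
            raise ValueError("semi-axes must be positive")

    def contains(self, point: dict) -> bool:
        try:
            q = sum(((point[k] - c) / self.semi_axes[k]) ** 2
                    for k, c in self.center.items())
        except KeyError as e:
            raise ValueError(f"CV {e} missing from the series") from e
        return q <= 1.0


def assign_states(cv_series, regions) -> list:
    """Per-frame metastable-state labels from elliptical CV-space regions.

    ``cv_series`` is a sequence of {cv_name: value} mappings (or a dict of
    equal-length arrays). A frame belongs to a region iff
    Σ ((zᵢ − cᵢ)/aᵢ)² ≤ 1; boundary points are assigned. Overlaps resolve
    to the first-listed region; otherwise the frame is labelled
    ``"unassigned"``.
    """
    if isinstance(cv_series, dict):
        names = list(cv_series)
        n = len(next(iter(cv_series.values())))
        cv_series = [{k: cv_series[k][i] for k in names} for i in range(n)]
    labels = []
    for point in cv_series:
        for region in regions:
            if region.contains(point):
                labels.append(region.name)
                break
        else:
            labels.append("unassigned")
    return labels


def swing_fraction(displacement, reference_displacement: float,
                   reference_fraction: float) -> float:
    """Express a displacement as a percentage of the full transition swing.

    The calibration pair (``reference_displacement`` Å ↦
    ``reference_fraction`` %) fixes the total swing as
    ``reference_displacement × 100 / reference_fraction``; the return value
    is ``100 × |displacement| / total``. E.g. with calibration
    (15.3 Å, 64.2 %), a 14.7 Å converter displacement is 61.7 % of the
    total swing.
    """
    if not 0 < reference_fraction <= 100:
        raise ValueError("reference_fraction must be in (0, 100]")
    if reference_displacement <= 0:
        raise ValueError("reference_displacement must be positive")
    norm = (float(np.linalg.norm(displacement))
            if np.ndim(displacement) else abs(float(displacement)))
    total = reference_displacement * 100.0 / reference_fraction
    return 100.0 * norm / total
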