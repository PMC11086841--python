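"""Geometric collective variables on conformations.

Implements the CV catalogue used to describe a two-state conformational
transition of a motor domain: optimal (Kabsch) superposition and RMSD,
the signed ΔRMSD order parameter distinguishing two reference states,
center-of-geometry projections onto a body's principal axes, fragment
orientation angles, interatomic / center-of-geometry distances, dihedral
angles, and heavy-atom contact counts.

All CVs are invariant under global rigid motion of the conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .conformers import Conformation

__all__ = [
    "SelectionError",
    "DegenerateGeometryError",
    "superpose_kabsch",
    "rmsd_after_superposition",
    "delta_rmsd",
    "principal_axes",
    "principal_axes_projection",
    "orientation_angle",
    "dihedral",
    "distances_and_dihedrals",
    "count_contacts",
    "CVDefinition",
]


class SelectionError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


def _selected_coords(conf: Conformation, selection) -> np.ndarray:
    if selection is None:
        return conf.coords
    mask = np.asarray(selection)
    if mask.dtype == bool:
        return conf.coords[mask]
    return conf.coords[mask.astype(int)]


def superpose_kabsch(mobile: Conformation, reference: Conformation, selection=None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rmsd, (rotation, translation))`` where the proper rotation R
    (det = +1) and translation t minimize the selection RMSD of
    ``R x + t`` against the reference. Raises on mismatched selection sizes
    or degenerate (<3 atoms or collinear) geometry.
    """
    p = _selected_coords(mobile, selection)
    q = _selected_coords(reference, selection)
    if p.shape != q.shape:
        raise SelectionError(f"selection sizes differ: {p.shape[0]} vs {q.shape[0]}")
    if p.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms for superposition")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    # collinearity check: rank of the centered cloud
    if min(np.linalg.matrix_rank(p0, tol=1e-8), np.linalg.matrix_rank(q0, tol=1e-8)) < 2:
        raise DegenerateGeometryError("selection atoms are collinear")
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    diff = p0 @ rot.T - q0
    rmsd = float(np.sqrt((diff * diff).sum() / p.shape[0]))
    return rmsd, (rot, trans)


def rmsd_after_superposition(mobile: Conformation, reference: Conformation,
                             selection=None) -> float:
    return superpose_kabsch(mobile, reference, selection)[0]


def delta_rmsd(x: Conformation, ref_b: Conformation, ref_a: Conformation,
               selection=None) -> float:
    """Signed two-reference order parameter RMSD(x, B) − RMSD(x, A).

    Each RMSD is computed after its own optimal superposition. With
    B = the kinked-state reference and A = the straight-state reference
    this is positive near A and negative near B; for the Relay-helix kink
    it is evaluated on backbone heavy atoms (C, CA, O, N) of residues
    485–493 and takes values ≈ +1.4 Å in the post-rigor state and
    ≈ −1.4 Å in the pre-transition state.
    """
    return (rmsd_after_superposition(x, ref_b, selection)
            - rmsd_after_superposition(x, ref_a, selection))


def backbone_selection(conf: Conformation, res_range: tuple) -> np.ndarray:
    """Backbone heavy atoms (C, CA, O, N) of a 1-based residue range."""
    return conf.select(residues=res_range, atom_names=("C", "CA", "O", "N"))


def principal_axes(coords: np.ndarray, degeneracy_tol: float = 1e-6):
    """Principal axes of a coordinate cloud's gyration tensor.

    Axes are rows, ordered by descending eigenvalue. Raises on a degenerate
    (symmetric) tensor whose eigenvalue gaps fall below ``degeneracy_tol``
    relative to the leading eigenvalue, since axis directions are then
    ill-defined.
    """
    c = coords - coords.mean(axis=0)
    gyr = c.T @ c / len(c)
    w, v = np.linalg.eigh(gyr)  # ascending
    w, v = w[::-1], v[:, ::-1]
    scale = max(w[0], 1e-300)
    if (w[0] - w[1]) / scale < degeneracy_tol or (w[1] - w[2]) / scale < degeneracy_tol:
        raise DegenerateGeometryError("gyration tensor is (near-)degenerate; "
                                      "principal axes ambiguous")
    return v.T, w  # rows are axes


def _canonical_axes(coords: np.ndarray):
    """Reference-free sign fix: make the largest-|component| entry of each
    axis positive, then enforce right-handedness via the third axis."""
    axes, w = principal_axes(coords)
    for i in range(2):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def _kabsch_arrays(p: np.ndarray, q: np.ndarray):
    """Proper rotation+translation minimizing RMSD of p onto q (raw arrays)."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, qc - rot @ pc


def principal_axes_projection(conf: Conformation, body_selection, probe_selection,
                              reference: Conformation | None = None):
    """Probe center of geometry in the body's principal-axes frame.

    Returns (X, Y, Z) in Å: the probe selection's center of geometry,
    relative to the body's center of geometry, expressed along the body's
    gyration-tensor principal axes (descending eigenvalue order). When a
    reference conformation is given, the body is first superposed onto the
    reference's body and each axis sign is then chosen to maximize the dot
    product with the corresponding reference axis — this makes the map both
    continuous under small perturbations and exactly invariant under rigid
    motion of the whole conformation.
    """
    body = _selected_coords(conf, body_selection)
    probe = _selected_coords(conf, probe_selection)
    if reference is not None:
        ref_body = _selected_coords(reference, body_selection)
        rot, trans = _kabsch_arrays(body, ref_body)
        body = body @ rot.T + trans
        probe = probe @ rot.T + trans
        axes = _canonical_axes(body)
        ref_axes = _canonical_axes(ref_body)
        for i in range(2):
            if np.dot(axes[i], ref_axes[i]) < 0:
                axes[i] = -axes[i]
        axes[2] = np.cross(axes[0], axes[1])
    else:
        axes = _canonical_axes(body)
    rel = probe.mean(axis=0) - body.mean(axis=0)
    return axes @ rel


def _principal_direction(coords: np.ndarray) -> np.ndarray:
    """Leading principal axis of a fragment, oriented head-to-tail (from the
    first atom toward the last) so the direction is unambiguous."""
    c = coords - coords.mean(axis=0)
    if len(coords) < 3 or np.linalg.matrix_rank(c, tol=1e-10) < 1:
        raise DegenerateGeometryError("fragment direction undefined")
    _, _, vt = np.linalg.svd(c)
    d = vt[0]
    if np.dot(d, coords[-1] - coords[0]) < 0:
        d = -d
    return d


def orientation_angle(conf: Conformation, fragment_selection,
                      reference: Conformation, anchor_selection=None) -> float:
    """Angle (deg, in [0, 180]) between a fragment's principal direction in
    ``conf`` and in ``reference``.

    When ``anchor_selection`` is given, ``conf`` is first superposed onto the
    reference over the anchor, so the angle measures internal re-orientation
    of the fragment relative to the anchoring body rather than global
    rotation.
    """
    work = conf
    if anchor_selection is not None:
        _, (rot, trans) = superpose_kabsch(conf, reference, anchor_selection)
        work = conf.transformed(rot, trans)
    d1 = _principal_direction(_selected_coords(work, fragment_selection))
    d0 = _principal_direction(_selected_coords(reference, fragment_selection))
    cosang = np.clip(np.dot(d1, d0), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p0, p1, p2, p3) -> float:
    """Standard four-point dihedral in degrees, in (−180, 180]; 0 is cis."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


@dataclass
class CVDefinition:
    """One catalogue entry: what to measure and, for biased use, how stiffly.

    ``kind`` is one of ``principal_axes_projection``, ``delta_rmsd``,
    ``orientation_angle``, ``distance``, ``cog_distance``, ``dihedral``.
    ``selections`` maps role names ("atoms", "group_a", "body", ...) to
    selection masks or (conformation -> mask) callables. ``references``
    carries zero, one or two reference conformations (delta_rmsd needs
    exactly two). ``force_constant`` is in kcal/mol/U² with U the CV unit
    (Å or deg).
    """

    name: str
    kind: str
    selections: dict = field(default_factory=dict)
    references: tuple = ()
    force_constant: float = 1.0

    def __post_init__(self):
        kinds = {"principal_axes_projection", "delta_rmsd", "orientation_angle",
                 "distance", "cog_distance", "dihedral"}
        if self.kind not in kinds:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "delta_rmsd" and len(self.references) != 2:
            raise ValueError("delta_rmsd requires exactly two references (B, A)")

    def _sel(self, conf, role):
        s = self.selections[role]
        return s(conf) if callable(s) else s

    def evaluate(self, conf: Conformation):
        if self.kind == "distance":
            i, j = self._sel(conf, "atoms")
            return float(np.linalg.norm(conf.coords[int(i)] - conf.coords[int(j)]))
        if self.kind == "cog_distance":
            a = _selected_coords(conf, self._sel(conf, "group_a")).mean(axis=0)
            b = _selected_coords(conf, self._sel(conf, "group_b")).mean(axis=0)
            return float(np.linalg.norm(a - b))
        if self.kind == "dihedral":
            idx = [int(k) for k in self._sel(conf, "atoms")]
            if len(idx) != 4:
                raise SelectionError("dihedral needs exactly 4 atoms")
            return dihedral(*conf.coords[idx])
        if self.kind == "delta_rmsd":
            sel = self._sel(conf, "atoms") if "atoms" in self.selections else None
            return delta_rmsd(conf, self.references[0], self.references[1], sel)
        if self.kind == "orientation_angle":
            anchor = (self._sel(conf, "anchor")
                      if "anchor" in self.selections else None)
            return orientation_angle(conf, self._sel(conf, "fragment"),
                                     self.references[0], anchor)
        if self.kind == "principal_axes_projection":
            ref = self.references[0] if self.references else None
            xyz = principal_axes_projection(conf, self._sel(conf, "body"),
                                            self._sel(conf, "probe"), ref)
            axis = self.selections.get("axis", None)
            return tuple(xyz) if axis is None else float(xyz[int(axis)])
        raise AssertionError


def distances_and_dihedrals(conf: Conformation, cv_set) -> dict:
    """Evaluate a list of CVDefinitions on one conformation.

    Returns an ordered mapping name -> value (Å for distances, degrees for
    dihedrals/angles) — a point in the CV space the definitions span.
    """
    point = {}
    for cv in cv_set:
        point[cv.name] = cv.evaluate(conf)
    return point


def count_contacts(conf: Conformation, group_a, group_b, cutoff: float = 4.5) -> int:
    """Number of heavy-atom pairs across two disjoint groups closer than
    ``cutoff`` Å (strict inequality; hydrogens excluded by element)."""
    a = np.flatnonzero(np.asarray(group_a)) if np.asarray(group_a).dtype == bool \
        else np.asarray(group_a, dtype=int)
    b = np.flatnonzero(np.asarray(group_b)) if np.asarray(group_b).dtype == bool \
        else np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise SelectionError("contact groups overlap")
    heavy = conf.elements != "H"
    a = a[heavy[a]]
    b = b[heavy[b]]
    if a.size == 0 or b.size == 0:
        return 0
    d = cdist(conf.coords[a], conf.coords[b])
    return int(np.count_nonzero(d < cutoff))
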