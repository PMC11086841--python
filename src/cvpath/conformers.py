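"""Conformations, PDB interoperability, and toy bead-helix ensembles.

A :class:`Conformation` is an ordered set of atom records — the unit all
geometric collective variables and clustering operate on. Real structures
round-trip through PDB via biotite (highest-occupancy altloc kept); toy
conformers additionally round-trip through a plain whitespace fixture
format so test inputs stay human-readable.

The toy helix ensemble emulates a local helix rearrangement: a "straight"
reference chain and a "kinked" one bent mid-chain, mixed in chosen
proportions with Gaussian coordinate noise and random rigid motions — a
desk-scale analogue of conformer populations with two structurally
distinct clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import substream

__all__ = [
    "Conformation",
    "read_pdb",
    "write_pdb",
    "read_fixture",
    "write_fixture",
    "make_straight_helix",
    "make_kinked_helix",
    "ToyHelixEnsemble",
    "generate_toy_helix_ensemble",
    "random_rigid_motion",
]


@dataclass
class Conformation:
    """Ordered atom records with Cartesian coordinates in Å."""

    names: np.ndarray  # atom names, e.g. "CA"
    res_ids: np.ndarray  # 1-based residue indices
    elements: np.ndarray  # element symbols, e.g. "C"
    coords: np.ndarray  # (n_atoms, 3) float
    chains: np.ndarray | None = None

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype="U6")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.names)
        if not (len(self.res_ids) == len(self.elements) == self.coords.shape[0] == n):
            raise ValueError("atom record arrays must have equal length")
        if self.coords.shape[1:] != (3,):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.chains is None:
            self.chains = np.full(n, "A", dtype="U4")
        else:
            self.chains = np.asarray(self.chains, dtype="U4")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def copy(self) -> "Conformation":
        return Conformation(self.names.copy(), self.res_ids.copy(),
                            self.elements.copy(), self.coords.copy(), self.chains.copy())

    def with_coords(self, coords) -> "Conformation":
        return Conformation(self.names, self.res_ids, self.elements,
                            np.asarray(coords, dtype=float), self.chains)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Apply the rigid motion x ↦ R x + t."""
        return self.with_coords(self.coords @ np.asarray(rotation).T + translation)

    # -- selections -------------------------------------------------------
    def select(self, residues=None, atom_names=None, elements=None,
               exclude_hydrogens: bool = False) -> np.ndarray:
        """Boolean mask over atoms; selection grammar is residue ranges plus
        atom-name lists, 1-based residue numbering as in PDB."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            if isinstance(residues, tuple) and len(residues) == 2:
                lo, hi = residues
                mask &= (self.res_ids >= lo) & (self.res_ids <= hi)
            else:
                mask &= np.isin(self.res_ids, np.asarray(list(residues), dtype=int))
        if atom_names is not None:
            mask &= np.isin(self.names, np.asarray(list(atom_names), dtype="U6"))
        if elements is not None:
            mask &= np.isin(self.elements, np.asarray(list(elements), dtype="U2"))
        if exclude_hydrogens:
            mask &= self.elements != "H"
        return mask

    def subset(self, mask) -> "Conformation":
        mask = np.asarray(mask)
        return Conformation(self.names[mask], self.res_ids[mask],
                            self.elements[mask], self.coords[mask], self.chains[mask])


# -- PDB interoperability (biotite-backed) --------------------------------

def read_pdb(path, model: int = 1) -> Conformation:
    """Read a PDB file, keeping the highest-occupancy altloc per atom."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = pdb.get_structure(f, model=model, altloc="occupancy")
    return Conformation(
        names=arr.atom_name, res_ids=arr.res_id,
        elements=np.char.capitalize(arr.element),
        coords=arr.coord, chains=arr.chain_id,
    )


def write_pdb(path, conf: Conformation, res_name: str = "GLY") -> None:
    """Write a conformation as a single-model PDB (toy residue names allowed)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = struc.AtomArray(conf.n_atoms)
    arr.coord = conf.coords
    arr.atom_name = conf.names
    arr.res_id = conf.res_ids
    arr.element = np.char.upper(conf.elements)
    arr.chain_id = conf.chains
    arr.res_name = np.full(conf.n_atoms, res_name)
    arr.hetero = np.zeros(conf.n_atoms, dtype=bool)
    f = pdb.PDBFile()
    pdb.set_structure(f, arr)
    f.write(str(path))


# -- plain-text fixture format --------------------------------------------

def write_fixture(path, conformations) -> None:
    """Serialize conformations as whitespace text: one MODEL block per frame,
    one ``name res_id element x y z`` line per atom (Å)."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    with open(path, "w") as fh:
        for i, c in enumerate(conformations):
            fh.write(f"MODEL {i}\n")
            for j in range(c.n_atoms):
                x, y, z = c.coords[j]
                fh.write(f"{c.names[j]} {c.res_ids[j]} {c.elements[j]} "
                         f"{x:.10g} {y:.10g} {z:.10g}\n")
            fh.write("ENDMDL\n")


def read_fixture(path) -> list[Conformation]:
    frames, rows = [], []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "MODEL":
                rows = []
            elif tok[0] == "ENDMDL":
                frames.append(Conformation(
                    names=[r[0] for r in rows],
                    res_ids=[int(r[1]) for r in rows],
                    elements=[r[2] for r in rows],
                    coords=[[float(r[3]), float(r[4]), float(r[5])] for r in rows],
                ))
            else:
                rows.append(tok)
    return frames


# -- toy helix references -------------------------------------------------

def make_straight_helix(n_beads: int = 12, rise: float = 1.5,
                        radius: float = 2.3, twist_deg: float = 100.0) -> Conformation:
    """Ideal helix of CA-like beads (α-helix-like geometry by default)."""
    t = np.arange(n_beads)
    ang = np.deg2rad(twist_deg) * t
    coords = np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * t], axis=1)
    return Conformation(
        names=np.full(n_beads, "CA"), res_ids=t + 1,
        elements=np.full(n_beads, "C"), coords=coords,
    )


def make_kinked_helix(n_beads: int = 12, kink_angle_deg: float = 40.0,
                      **helix_kwargs) -> Conformation:
    """Straight helix with its C-terminal half bent by ``kink_angle_deg``
    about an axis through the mid-chain bead — the "kinked" reference."""
    conf = make_straight_helix(n_beads, **helix_kwargs)
    coords = conf.coords.copy()
    mid = n_beads // 2
    pivot = coords[mid]
    theta = np.deg2rad(kink_angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # bend about x-axis
    coords[mid:] = (coords[mid:] - pivot) @ rot.T + pivot
    return conf.with_coords(coords)


@dataclass
class ToyHelixEnsemble:
    """Frames of an N-bead chain with ground-truth state labels."""

    frames: list
    state_labels: np.ndarray
    reference_straight: Conformation
    reference_kinked: Conformation

    def __post_init__(self):
        self.state_labels = np.asarray(self.state_labels, dtype="U12")
        n = self.frames[0].n_atoms
        for f in self.frames:
            if f.n_atoms != n or not np.array_equal(f.names, self.frames[0].names):
                raise ValueError("all frames must share atom count and ordering")


def random_rigid_motion(rng: np.random.Generator, max_translation: float = 10.0):
    """Uniform random rotation (QR-based Haar measure) plus translation."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return q, t


def generate_toy_helix_ensemble(
    n_frames: int,
    mixture: dict | None = None,
    noise_amplitude: float = 0.0,
    seed: int = 0,
    n_beads: int = 12,
    kink_angle_deg: float = 40.0,
) -> ToyHelixEnsemble:
    """Generate labelled noisy rigid-body copies of the two reference helices.

    ``mixture`` maps state name ("straight" | "kinked") to its fraction;
    fractions must sum to 1. Frame counts per state are the rounded
    fractions (largest-remainder), so at noise 0 cluster occupancies equal
    the requested mixture exactly. Each frame gets isotropic Gaussian noise
    of standard deviation ``noise_amplitude`` (Å) per coordinate and an
    independent random rotation + translation.
    """
    if mixture is None:
        mixture = {"straight": 0.7, "kinked": 0.3}
    fracs = np.array(list(mixture.values()), dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must be non-negative and sum to 1")
    if noise_amplitude < 0:
        raise ValueError("noise_amplitude must be non-negative")

    ref_s = make_straight_helix(n_beads)
    ref_k = make_kinked_helix(n_beads, kink_angle_deg=kink_angle_deg)
    refs = {"straight": ref_s, "kinked": ref_k}

    # largest-remainder apportionment of frames to states
    ideal = fracs * n_frames
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    for i in np.argsort(-rem)[: n_frames - counts.sum()]:
        counts[i] += 1

    labels = []
    for name, c in zip(mixture, counts):
        labels += [name] * c
    rng_noise = substream(seed, "ensemble-noise")
    rng_rigid = substream(seed, "rigid-motions")
    order = substream(seed, "frame-order").permutation(n_frames)
    labels = [labels[i] for i in order]

    frames = []
    for name in labels:
        ref = refs[name]
        coords = ref.coords + noise_amplitude * rng_noise.standard_normal(ref.coords.shape)
        rot, trans = random_rigid_motion(rng_rigid)
        frames.append(ref.with_coords(coords @ rot.T + trans))
    return ToyHelixEnsemble(frames=frames, state_labels=np.array(labels),
                            reference_straight=ref_s, reference_kinked=ref_k)
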