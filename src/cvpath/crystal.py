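"""Crystal-structure spot checks for the Relay-helix kink order parameter.

The ΔRMSD CV distinguishing the straight (post-rigor, PR) from the kinked
(pre-transition, PTS) Relay helix is defined on the backbone heavy atoms
(C, CA, O, N) of residues 485–493 of the myosin VI motor domain, with the
two crystal structures (PR: PDB 2VAS, PTS: PDB 5O2L) as references. By
construction it evaluates to +RMSD(PR, PTS) ≈ +1.4 Å on the PR crystal and
−RMSD(PR, PTS) ≈ −1.4 Å on the PTS crystal.

These helpers load the crystal structures (from a local file or RCSB when
a network is available) and evaluate the CV on them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .conformers import Conformation, read_pdb
from .geometry import delta_rmsd

__all__ = ["RELAY_KINK_RESIDUES", "load_crystal", "relay_kink_selection",
           "crystal_delta_rmsd"]

#: 1-based residue range of the Relay-helix kink region.
RELAY_KINK_RESIDUES = (485, 493)

#: Backbone heavy atoms used for the kink ΔRMSD.
BACKBONE_ATOMS = ("C", "CA", "O", "N")


def load_crystal(pdb_id: str, search_dirs=(".", "data")) -> Conformation:
    """Load a crystal structure from disk, falling back to RCSB download.

    Looks for ``<pdb_id>.pdb`` (case-insensitive) in ``search_dirs``; if not
    found, attempts to fetch from RCSB, which requires network access.
    """
    for d in search_dirs:
        for name in (f"{pdb_id.lower()}.pdb", f"{pdb_id.upper()}.pdb"):
            p = Path(d) / name
            if p.exists():
                return read_pdb(p)
    try:
        from urllib.request import urlopen

        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        with urlopen(url, timeout=30) as resp:
            text = resp.read().decode()
        import io
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
            fh.write(text)
            tmp = fh.name
        return read_pdb(tmp)
    except Exception as err:
        raise RuntimeError(
            f"crystal structure {pdb_id} not found locally "
            f"({', '.join(search_dirs)}) and RCSB fetch failed: {err}"
        ) from err


def relay_kink_selection(conf: Conformation, chain: str | None = None) -> np.ndarray:
    """Backbone heavy atoms (C, CA, O, N) of residues 485–493 (one chain)."""
    mask = conf.select(residues=RELAY_KINK_RESIDUES, atom_names=BACKBONE_ATOMS)
    chains = np.unique(conf.chains[mask])
    use = chain if chain is not None else (chains[0] if len(chains) else None)
    if use is not None:
        mask &= conf.chains == use
    return mask


def crystal_delta_rmsd(structure: Conformation, pr: Conformation,
                       pts: Conformation) -> float:
    """Relay-kink ΔRMSD = RMSD(x, PTS) − RMSD(x, PR) on the kink backbone.

    The selection is resolved per structure (crystals may differ in atom
    ordering outside the kink region); atoms are matched by (residue,
    atom-name) within the kink range.
    """
    def extract(c):
        m = relay_kink_selection(c)
        sub = c.subset(m)
        order = np.lexsort((sub.names, sub.res_ids))
        return sub.subset(order)

    x, a, b = extract(structure), extract(pr), extract(pts)
    for other in (a, b):
        if (not np.array_equal(x.res_ids, other.res_ids)
                or not np.array_equal(x.names, other.names)):
            raise ValueError("kink-region atom records do not match between "
                             "structures; check for missing residues/altlocs")
    return delta_rmsd(x, b, a, None)
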