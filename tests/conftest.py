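"""Shared fixtures: hand-built trajectories and random complexes."""

from __future__ import annotations

import numpy as np
import pytest

from kdacsel.peptides import PeptideSequence
from kdacsel.trajectory import Trajectory

FAR = 50.0  # nm; parks mandatory topology atoms out of interaction range


def build_trajectory(atom_rows, coords, kac_residue=3, peptide="FRKacWR"):
    """Construct a Trajectory from explicit atom rows and coordinates.

    ``atom_rows``: list of (chain, res_id, res_name, atom_name);
    ``coords``: (n_frames, n_atoms, 3) in nm.  A Zn ion and an
    acetyllysine carbonyl oxygen are appended automatically (far away)
    unless the rows already provide them.
    """
    atom_rows = list(atom_rows)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    names = [r[3] for r in atom_rows]
    extra = []
    if "ZN" not in names:
        extra.append(("A", 999, "ZN", "ZN", [FAR, 0.0, 0.0]))
    if not any(r[3] == "OH" and r[1] == kac_residue for r in atom_rows):
        extra.append(("B", kac_residue, "ALY", "OH", [FAR, 5.0, 0.0]))
    if extra:
        pad = np.asarray([e[4] for e in extra], dtype=float)
        coords = np.concatenate(
            [coords, np.repeat(pad[None], coords.shape[0], axis=0)], axis=1
        )
        atom_rows = atom_rows + [e[:4] for e in extra]
    return Trajectory(
        coords_nm=coords,
        atom_name=np.asarray([r[3] for r in atom_rows], dtype=object),
        element=np.asarray(
            ["ZN" if r[3] == "ZN" else r[3][0] for r in atom_rows],
            dtype=object,
        ),
        res_id=np.asarray([r[1] for r in atom_rows], dtype=int),
        res_name=np.asarray([r[2] for r in atom_rows], dtype=object),
        chain_id=np.asarray([r[0] for r in atom_rows], dtype=object),
        enzyme_chain="A",
        substrate_chain="B",
        kac_residue=kac_residue,
        peptide=PeptideSequence.parse(peptide),
    )


#: atom layout of the random-complex fixture: four enzyme residues covering
#: all chemistry classes, substrate GLU(+1)/ARG(+2) plus the acetyllysine
RANDOM_COMPLEX_ROWS = [
    ("A", 1, "ARG", "CA"), ("A", 1, "ARG", "NH1"), ("A", 1, "ARG", "HH11"),
    ("A", 1, "ARG", "NE"), ("A", 1, "ARG", "HE"),
    ("A", 2, "ASP", "CA"), ("A", 2, "ASP", "OD1"), ("A", 2, "ASP", "OD2"),
    ("A", 3, "SER", "CA"), ("A", 3, "SER", "OG"), ("A", 3, "SER", "HG"),
    ("A", 4, "LEU", "CA"), ("A", 4, "LEU", "CB"),
    ("B", 3, "ALY", "CA"), ("B", 3, "ALY", "NZ"), ("B", 3, "ALY", "HZ"),
    ("B", 3, "ALY", "OH"),
    ("B", 4, "GLU", "N"), ("B", 4, "GLU", "H"), ("B", 4, "GLU", "CA"),
    ("B", 4, "GLU", "C"), ("B", 4, "GLU", "O"),
    ("B", 4, "GLU", "OE1"), ("B", 4, "GLU", "OE2"),
    ("B", 5, "ARG", "N"), ("B", 5, "ARG", "H"), ("B", 5, "ARG", "CA"),
    ("B", 5, "ARG", "C"), ("B", 5, "ARG", "O"),
    ("B", 5, "ARG", "NH1"), ("B", 5, "ARG", "HH11"),
    ("A", 999, "ZN", "ZN"),
]


def random_complex(seed: int, n_frames: int) -> Trajectory:
    """Random coordinates in a 1.2 nm box: dense enough that every
    interaction type fires by chance."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.2, size=(n_frames, len(RANDOM_COMPLEX_ROWS), 3))
    return build_trajectory(
        RANDOM_COMPLEX_ROWS, coords, kac_residue=3, peptide="FRKacER"
    )


def frame_residues(traj, frame_index):
    """{(chain, res_id): (res_name, {atom_name: xyz})} for the oracle."""
    out = {}
    for i in range(traj.n_atoms):
        key = (traj.chain_id[i], int(traj.res_id[i]))
        res_name = traj.res_name[i]
        out.setdefault(key, (res_name, {}))[1][
            traj.atom_name[i]
        ] = traj.coords_nm[frame_index, i]
    return out


@pytest.fixture
def toy_trajectory():
    """Two residues (enzyme LEU, substrate TRP at +1) 0.25 nm apart."""
    rows = [
        ("A", 10, "LEU", "CA"),
        ("B", 4, "TRP", "CB"),
    ]
    coords = [[[0.0, 0.0, 0.0], [0.0, 0.0, 0.25]]]
    return build_trajectory(rows, coords)
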