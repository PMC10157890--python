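"""Trajectory container and multi-model PDB I/O.

A trajectory is one replicate simulation of an enzyme–acetylpeptide complex:
an ordered set of frames sharing a single topology.  Frames arrive as MODEL
records of a multi-model PDB file (coordinates in Å, converted to nm on
load).  The topology distinguishes the enzyme chain, the substrate chain,
the catalytic Zn²⁺ ion and the acetyllysine acetyl group; the Zn-to-acetyl-
carbonyl-oxygen distance defines whether a frame is in a catalytically
relevant conformation.

Internally coordinates are kept as a dense ``(n_frames, n_atoms, 3)`` array
for vectorised analysis; `Frame` and `Atom` are light views for one-off
inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chemistry import ChemistryTables
from .peptides import PeptideSequence

ANGSTROM_PER_NM = 10.0


class TopologyError(ValueError):
    """A required selector (chain, Zn, acetyl atom) is missing."""


class MalformedTrajectoryError(ValueError):
    """Models of a multi-model PDB do not share one topology."""


class SelectionError(KeyError):
    """A residue selection matched no atoms."""


ResidueId = tuple[str, int, str]  # (chain label, residue number, residue name)


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_id: ResidueId
    coords: np.ndarray  # nm
    is_hydrogen: bool
    charge_class: str  # "cationic" | "anionic" | "neutral"


@dataclass
class Frame:
    """Single-frame view into a trajectory."""

    index: int
    trajectory: "Trajectory"

    @property
    def coords(self) -> np.ndarray:
        return self.trajectory.coords_nm[self.index]

    @property
    def zn_position(self) -> np.ndarray:
        return self.trajectory.coords_nm[self.index, self.trajectory.zn_index]

    @property
    def kac_carbonyl_position(self) -> np.ndarray:
        return self.trajectory.coords_nm[
            self.index, self.trajectory.kac_carbonyl_index
        ]

    @property
    def atoms(self) -> list[Atom]:
        t = self.trajectory
        out = []
        for i in range(t.n_atoms):
            out.append(
                Atom(
                    serial=i + 1,
                    name=t.atom_name[i],
                    element=t.element[i],
                    residue_id=(t.chain_id[i], int(t.res_id[i]), t.res_name[i]),
                    coords=t.coords_nm[self.index, i],
                    is_hydrogen=t.element[i] == "H",
                    charge_class=t.charge_class[i],
                )
            )
        return out


@dataclass
class Trajectory:
    """All frames of one replicate plus topology annotation.

    Coordinates are in nm.  Substrate residues are addressed by their signed
    offset from the acetyllysine (offset = residue number − ``kac_residue``;
    substrate numbering is assumed sequential).
    """

    coords_nm: np.ndarray          # (F, N, 3)
    atom_name: np.ndarray          # (N,) str
    element: np.ndarray            # (N,) str
    res_id: np.ndarray             # (N,) int
    res_name: np.ndarray           # (N,) str
    chain_id: np.ndarray           # (N,) str
    enzyme_chain: str
    substrate_chain: str
    kac_residue: int
    kac_carbonyl_atom: str = "OH"
    peptide: PeptideSequence | None = None
    replicate_id: int = 1
    chemistry: ChemistryTables = field(default_factory=ChemistryTables)

    def __post_init__(self) -> None:
        if self.coords_nm.ndim != 3 or self.coords_nm.shape[0] < 1:
            raise MalformedTrajectoryError("need ≥1 frame of (N, 3) coords")
        if not np.isfinite(self.coords_nm).all():
            raise MalformedTrajectoryError("non-finite coordinates")
        for chain, what in (
            (self.enzyme_chain, "enzyme chain"),
            (self.substrate_chain, "substrate chain"),
        ):
            if not (self.chain_id == chain).any():
                raise TopologyError(f"{what} {chain!r} not present")
        zn = np.flatnonzero(
            (self.element == "ZN") | (self.atom_name == "ZN")
        )
        if zn.size == 0:
            raise TopologyError("no Zn atom found (element or name 'ZN')")
        self.zn_index = int(zn[0])
        carbonyl = np.flatnonzero(
            (self.chain_id == self.substrate_chain)
            & (self.res_id == self.kac_residue)
            & (self.atom_name == self.kac_carbonyl_atom)
        )
        if carbonyl.size == 0:
            raise TopologyError(
                f"acetyl carbonyl atom {self.kac_carbonyl_atom!r} not found "
                f"on substrate residue {self.kac_residue}"
            )
        self.kac_carbonyl_index = int(carbonyl[0])
        self.charge_class = self._classify_charges()

    # -- topology helpers ---------------------------------------------------
    def _classify_charges(self) -> np.ndarray:
        chem = self.chemistry
        cls = np.full(self.n_atoms, "neutral", dtype=object)
        for res_name, groups in chem.cationic.items():
            names = {h for heavy, hs in groups for h in hs}
            names |= {heavy for heavy, _ in groups}
            mask = (self.res_name == res_name) & np.isin(
                self.atom_name, sorted(names)
            )
            cls[mask] = "cationic"
        for res_name, oxygens in chem.anionic.items():
            mask = (self.res_name == res_name) & np.isin(
                self.atom_name, list(oxygens)
            )
            cls[mask] = "anionic"
        return cls

    @property
    def n_frames(self) -> int:
        return self.coords_nm.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords_nm.shape[1]

    @property
    def frames(self) -> list[Frame]:
        return [Frame(i, self) for i in range(self.n_frames)]

    def residue_indices(self, chain: str, res_number: int) -> np.ndarray:
        idx = np.flatnonzero(
            (self.chain_id == chain) & (self.res_id == res_number)
        )
        if idx.size == 0:
            raise SelectionError(
                f"no atoms for residue {res_number} in chain {chain!r}"
            )
        return idx

    def residue_name(self, chain: str, res_number: int) -> str:
        return str(self.res_name[self.residue_indices(chain, res_number)[0]])

    def residue_id(self, chain: str, res_number: int) -> ResidueId:
        return (chain, res_number, self.residue_name(chain, res_number))

    def enzyme_residues(self) -> list[ResidueId]:
        """Residue ids of the enzyme chain, ordered by residue number."""
        mask = (self.chain_id == self.enzyme_chain) & (self.res_name != "ZN")
        numbers = sorted(set(self.res_id[mask].tolist()))
        return [self.residue_id(self.enzyme_chain, int(n)) for n in numbers]

    def substrate_offsets(self) -> list[int]:
        """Signed substrate-position offsets present (acetyllysine = 0)."""
        mask = self.chain_id == self.substrate_chain
        numbers = sorted(set(self.res_id[mask].tolist()))
        return [int(n) - self.kac_residue for n in numbers]

    def substrate_residue(self, offset: int) -> ResidueId:
        return self.residue_id(self.substrate_chain, self.kac_residue + offset)

    # -- catalytic-pose geometry -------------------------------------------
    def zn_carbonyl_distances(self) -> np.ndarray:
        """Per-frame Zn-to-acetyl-carbonyl-oxygen distance (nm)."""
        delta = (
            self.coords_nm[:, self.zn_index]
            - self.coords_nm[:, self.kac_carbonyl_index]
        )
        return np.linalg.norm(delta, axis=1)


def _stack_from_file(path) -> struc.AtomArrayStack:
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise MalformedTrajectoryError(
            f"models in {path} do not share one topology: {exc}"
        ) from exc
    if not isinstance(stack, struc.AtomArrayStack):
        stack = struc.stack([stack])
    return stack


def load_trajectory(
    path,
    enzyme_chain: str,
    substrate_chain: str,
    kac_residue: int,
    *,
    kac_carbonyl_atom: str = "OH",
    peptide: PeptideSequence | None = None,
    replicate_id: int = 1,
    chemistry: ChemistryTables | None = None,
) -> Trajectory:
    """Load a multi-model PDB file as a `Trajectory` (one frame per MODEL).

    Coordinates are converted from Å to nm.  Raises `TopologyError` when a
    chain, the Zn ion or the acetyl carbonyl atom is missing, and
    `MalformedTrajectoryError` when models disagree on topology.
    """
    stack = _stack_from_file(path)
    return Trajectory(
        coords_nm=np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM,
        atom_name=np.asarray(stack.atom_name, dtype=object),
        element=np.asarray(stack.element, dtype=object),
        res_id=np.asarray(stack.res_id, dtype=int),
        res_name=np.asarray(stack.res_name, dtype=object),
        chain_id=np.asarray(stack.chain_id, dtype=object),
        enzyme_chain=enzyme_chain,
        substrate_chain=substrate_chain,
        kac_residue=kac_residue,
        kac_carbonyl_atom=kac_carbonyl_atom,
        peptide=peptide,
        replicate_id=replicate_id,
        chemistry=chemistry or ChemistryTables(),
    )


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as a multi-model PDB file (nm → Å)."""
    n = traj.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3))
    array.atom_name = traj.atom_name.astype("U6")
    array.element = traj.element.astype("U2")
    array.res_id = traj.res_id
    array.res_name = traj.res_name.astype("U5")
    array.chain_id = traj.chain_id.astype("U4")
    array.hetero = np.asarray(traj.res_name == "ZN")
    stack = struc.stack([array] * traj.n_frames)
    stack.coord = np.asarray(traj.coords_nm, dtype=np.float32) * ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    path = Path(path)
    pdb.write(str(path))
    return path
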