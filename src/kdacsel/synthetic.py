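"""Seeded generators for every input the pipeline consumes.

Three generators mirror the study's data shapes:

* `generate_trajectory` — a toy enzyme–acetylpeptide complex whose planted
  interactions switch on and off as two-state Markov chains (so occurrence
  autocorrelation resembles real trajectories), written as multi-model PDB
  if asked.  Default 2500 frames per replicate (5 ns at one frame / 2 ps)
  and five replicates, matching the simulated ensembles the analysis was
  designed for.
* `generate_activity_panel` — replicate specific activities with planted
  multiplicative cluster effects and log-normal noise.
* `generate_timecourses` — Michaelis–Menten product-formation timecourses.

The scaffold geometry is deliberately schematic: enzyme residues sit on a
1.5 nm grid with the substrate threaded past a fixed Zn site, so planted
interactions are detectable without cross-talk.  Physical realism is not
the goal; detectability geometry is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityRecord
from .chemistry import ChemistryTables
from .peptides import AA_THREE, PeptideSequence
from .trajectory import Trajectory, write_trajectory

GRID_NM = 1.5          # enzyme-residue spacing
HOME_Y_NM = 5.0        # substrate "parked" row, out of reach of everything
ZN_POS = np.array([-3.0, 0.5, 0.0])

ON_CONTACT = (0.20, 0.29)
OFF_CONTACT = (0.40, 0.80)
ON_IONIC = (0.18, 0.24)
OFF_IONIC = (0.30, 0.60)
ON_HBOND = (0.28, 0.34)
OFF_HBOND_DIST = 0.30
OFF_HBOND_ANGLE = 45.0
CATALYTIC_ON = (0.28, 0.31)
CATALYTIC_OFF = (0.33, 0.50)


class GeometryError(ValueError):
    """Planted interactions cannot be realised on the toy scaffold."""


@dataclass(frozen=True)
class PlantedInteraction:
    """One enzyme-residue/substrate-position interaction to plant.

    The per-frame occurrence follows a two-state Markov chain with
    transition probabilities ``p_on`` (off→on) and ``p_off`` (on→off), so
    the stationary occupancy is f = p_on / (p_on + p_off).
    """

    enzyme_residue: int
    substrate_position: int
    itype: str
    p_on: float
    p_off: float
    enzyme_res_name: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_on < 1.0 and 0.0 < self.p_off < 1.0):
            raise GeometryError("transition probabilities must be in (0, 1)")
        if self.itype not in (
            "contact", "ionic", "hbond_sidechain", "hbond_to_backbone"
        ):
            raise GeometryError(f"unknown interaction type {self.itype!r}")

    @property
    def stationary_occupancy(self) -> float:
        return self.p_on / (self.p_on + self.p_off)

    @property
    def autocorrelation(self) -> float:
        """Lag-1 autocorrelation of the occurrence chain, 1 − p_on − p_off."""
        return 1.0 - self.p_on - self.p_off

    def effective_n(self, n_frames: int) -> float:
        """Effective sample size n/(1+2ρ/(1−ρ)) for the AR(1)-like chain."""
        rho = self.autocorrelation
        return n_frames * (1.0 - rho) / (1.0 + rho)


def markov_chain(
    rng: np.random.Generator, n: int, p_on: float, p_off: float
) -> np.ndarray:
    """Sample a stationary two-state (off/on) Markov chain of length n."""
    f = p_on / (p_on + p_off)
    u = rng.random(n)
    state = np.empty(n, dtype=bool)
    state[0] = u[0] < f
    for i in range(1, n):
        state[i] = (u[i] < p_on) if not state[i - 1] else (u[i] >= p_off)
    return state


# ---------------------------------------------------------------------------
# scaffold construction
# ---------------------------------------------------------------------------

_SC_EXTRA_ATOMS = {
    # minimal side-chain atoms per one-letter code, placed near the backbone
    "R": ("NE", "HE", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22"),
    "K": ("NZ", "HZ1", "HZ2", "HZ3"),
    "H": ("ND1", "HD1", "NE2", "HE2"),
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "S": ("OG", "HG"),
    "T": ("OG1", "HG1"),
    "Y": ("OH", "HH"),
    "N": ("OD1", "ND2", "HD21", "HD22"),
    "Q": ("OE1", "NE2", "HE21", "HE22"),
    "W": ("NE1", "HE1"),
    "C": ("SG", "HG"),
    "M": ("SD",),
}

_ELEMENT_BY_INITIAL = {"N": "N", "O": "O", "C": "C", "H": "H", "S": "S"}

_SC_ACCEPTOR_PROBE = {
    "S": "OG", "T": "OG1", "Y": "OH", "D": "OD1", "E": "OE1",
    "N": "OD1", "Q": "OE1", "H": "ND1", "M": "SD",
}
_SC_DONOR_PROBE = {
    "S": ("OG", "HG"), "T": ("OG1", "HG1"), "Y": ("OH", "HH"),
    "C": ("SG", "HG"), "N": ("ND2", "HD21"), "Q": ("NE2", "HE21"),
    "W": ("NE1", "HE1"), "H": ("ND1", "HD1"),
    "R": ("NH1", "HH11"), "K": ("NZ", "HZ1"),
}


def _element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            if ch.isdigit():
                continue
            return _ELEMENT_BY_INITIAL.get(ch, "C")
    return "C"


class _Scaffold:
    """Accumulates atoms with static base positions plus per-frame movers."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.res_names: list[str] = []
        self.res_ids: list[int] = []
        self.chains: list[str] = []
        self.base: list[np.ndarray] = []

    def add(self, chain, res_id, res_name, atom_name, pos) -> int:
        idx = len(self.names)
        self.names.append(atom_name)
        self.res_names.append(res_name)
        self.res_ids.append(res_id)
        self.chains.append(chain)
        # deterministic sub-picometre jitter keeps atoms from exact overlap
        self.base.append(np.asarray(pos, float) + np.array([0, 0, 1e-4 * idx]))
        return idx


def _plant_geometry(plant, peptide):
    """Resolve probe/anchor atom names and residue types for one plant."""
    letter = peptide.residue_at(plant.substrate_position)
    if letter is None:
        raise GeometryError(
            f"peptide has no residue at position {plant.substrate_position:+d}"
        )
    if plant.substrate_position == 0:
        letter_key = "kac"
    else:
        letter_key = letter
    if plant.itype == "contact":
        enz_name = plant.enzyme_res_name or "LEU"
        return enz_name, "CA", ("CB",), "contact"
    if plant.itype == "ionic":
        if plant.substrate_position == 0:
            raise GeometryError("acetyllysine is neutral; cannot plant ionic")
        if letter in "RKH":
            enz_name = plant.enzyme_res_name or "ASP"
            if enz_name not in ("ASP", "GLU"):
                raise GeometryError(
                    f"ionic with cationic substrate {letter} needs an "
                    f"anionic enzyme residue, not {enz_name}"
                )
            anchor = "OD1" if enz_name == "ASP" else "OE1"
            probe = {"R": ("NH1", "HH11"), "K": ("NZ", "HZ1"),
                     "H": ("ND1", "HD1")}[letter]
            return enz_name, anchor, probe, "ionic-sub-cationic"
        if letter in "DE":
            enz_name = plant.enzyme_res_name or "ARG"
            if enz_name not in ("ARG", "LYS", "HIS"):
                raise GeometryError(
                    f"ionic with anionic substrate {letter} needs a cationic "
                    f"enzyme residue, not {enz_name}"
                )
            anchor = {"ARG": "HH11", "LYS": "HZ1", "HIS": "HD1"}[enz_name]
            probe = ("OD1",) if letter == "D" else ("OE1",)
            return enz_name, anchor, probe, "ionic-sub-anionic"
        raise GeometryError(
            f"substrate residue {letter} at {plant.substrate_position:+d} "
            "carries no charged group"
        )
    if plant.itype == "hbond_sidechain":
        if letter_key != "kac" and letter in _SC_ACCEPTOR_PROBE:
            enz_name = plant.enzyme_res_name or "SER"
            return enz_name, "OG", (_SC_ACCEPTOR_PROBE[letter],), "hb-enz-donor"
        if letter_key == "kac":
            # acetyl carbonyl oxygen accepts; but OH is reserved for the
            # catalytic-pose chain, so donate from the side-chain amide
            enz_name = plant.enzyme_res_name or "SER"
            return enz_name, "OG", ("NZ", "HZ"), "hb-sub-donor"
        if letter in _SC_DONOR_PROBE:
            enz_name = plant.enzyme_res_name or "SER"
            return enz_name, "OG", _SC_DONOR_PROBE[letter], "hb-sub-donor"
        raise GeometryError(
            f"substrate residue {letter} has no side-chain donor/acceptor"
        )
    # hbond_to_backbone: enzyme side-chain donor to substrate backbone O
    enz_name = plant.enzyme_res_name or "SER"
    return enz_name, "OG", ("O",), "hb-enz-donor"


def generate_trajectory(
    planted: list[PlantedInteraction],
    peptide: PeptideSequence | str = "FRKacWR",
    n_frames: int = 2500,
    catalytic_p_on: float = 0.27,
    catalytic_p_off: float = 0.03,
    seed: int = 0,
    replicate_id: int = 1,
    path=None,
) -> Trajectory:
    """Build one replicate trajectory with planted interaction episodes.

    Enzyme residues referenced by the plants are laid out on a 1.5 nm grid;
    each plant moves a probe atom of its substrate residue between an "on"
    shell (within the relevant cutoff) and an "off" shell (outside it)
    following its Markov chain.  The acetyl carbonyl oxygen tracks a
    separate catalytic-pose chain relative to the Zn site (default
    stationary catalytic fraction 0.9).  Identical seeds reproduce the
    trajectory (and any written PDB file) byte for byte.

    If ``path`` is given, the trajectory is also written as multi-model PDB.
    """
    if isinstance(peptide, str):
        peptide = PeptideSequence.parse(peptide)
    if len({(p.substrate_position, p.itype) for p in planted}) != len(planted):
        raise GeometryError(
            "at most one planted interaction per (position, type): the "
            "probe atom would need to be in two places at once"
        )
    rng = np.random.default_rng(seed)
    kac_resnum = peptide.kac_index + 1

    # enzyme residue grid: one slot per distinct enzyme residue number
    enz_numbers = sorted({p.enzyme_residue for p in planted})
    grid = {num: np.array([GRID_NM * i, 0.0, 0.0])
            for i, num in enumerate(enz_numbers)}
    enz_names: dict[int, str] = {}
    plant_geoms = []
    for plant in planted:
        enz_name, anchor, probe_atoms, mode = _plant_geometry(plant, peptide)
        prev = enz_names.setdefault(plant.enzyme_residue, enz_name)
        if prev != enz_name:
            raise GeometryError(
                f"enzyme residue {plant.enzyme_residue} assigned two types "
                f"({prev}, {enz_name})"
            )
        plant_geoms.append((plant, anchor, probe_atoms, mode))

    scaffold = _Scaffold()
    # --- enzyme chain A ----------------------------------------------------
    anchor_index: dict[tuple[int, str], int] = {}
    for num in enz_numbers:
        g = grid[num]
        name = enz_names[num]
        if name in ("ASP", "GLU"):
            scaffold.add("A", num, name, "CA", g + [0.0, -0.20, 0.0])
            o1, o2 = ("OD1", "OD2") if name == "ASP" else ("OE1", "OE2")
            anchor_index[(num, o1)] = scaffold.add("A", num, name, o1, g)
            scaffold.add("A", num, name, o2, g + [0.12, -0.05, 0.0])
        elif name in ("ARG", "LYS", "HIS"):
            scaffold.add("A", num, name, "CA", g + [0.0, -0.20, 0.0])
            heavy, hydro = {
                "ARG": ("NH1", "HH11"), "LYS": ("NZ", "HZ1"),
                "HIS": ("ND1", "HD1"),
            }[name]
            scaffold.add("A", num, name, heavy, g + [0.0, -0.10, 0.0])
            anchor_index[(num, hydro)] = scaffold.add("A", num, name, hydro, g)
        elif name == "SER":
            scaffold.add("A", num, name, "CA", g + [0.0, -0.20, 0.0])
            anchor_index[(num, "OG")] = scaffold.add("A", num, name, "OG", g)
            scaffold.add("A", num, name, "HG", g + [0.0, 0.10, 0.0])
        else:
            anchor_index[(num, "CA")] = scaffold.add("A", num, name, "CA", g)
            scaffold.add("A", num, name, "CB", g + [0.12, -0.10, 0.0])
    # Zn ion (hetero residue, excluded from enzyme-residue enumeration)
    scaffold.add("A", 999, "ZN", "ZN", ZN_POS)

    # --- substrate chain B -------------------------------------------------
    probe_index: dict[tuple[int, str], int] = {}
    moved_atoms = {
        (p.substrate_position, a) for p, _, atoms, _ in plant_geoms
        for a in atoms
    }
    kac_oh_key = (0, "OH")
    for offset in peptide.offsets:
        letter = peptide.residue_at(offset)
        resnum = kac_resnum + offset
        res_name = "ALY" if offset == 0 else AA_THREE[letter]
        home = np.array([GRID_NM * offset, HOME_Y_NM, 0.0])
        backbone = [
            ("N", home + [-0.12, 0.0, 0.0]),
            ("H", home + [-0.12, 0.10, 0.0]),
            ("CA", home),
            ("C", home + [0.12, 0.0, 0.0]),
            ("O", home + [0.12, 0.12, 0.0]),
            ("CB", home + [0.0, -0.12, 0.0]),
        ]
        extras = ("NZ", "HZ", "CH", "CH3", "OH") if offset == 0 else \
            _SC_EXTRA_ATOMS.get(letter, ())
        atoms = backbone + [
            (a, home + [0.05 * i, -0.24, 0.0]) for i, a in enumerate(extras)
        ]
        for atom_name, pos in atoms:
            idx = scaffold.add("B", resnum, res_name, atom_name, pos)
            if (offset, atom_name) in moved_atoms or (
                offset == 0 and atom_name == "OH"
            ):
                probe_index[(offset, atom_name)] = idx

    base = np.stack(scaffold.base)                    # (N, 3)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)

    # --- catalytic-pose chain ----------------------------------------------
    cat_state = markov_chain(rng, n_frames, catalytic_p_on, catalytic_p_off)
    d_cat = np.where(
        cat_state,
        rng.uniform(*CATALYTIC_ON, n_frames),
        rng.uniform(*CATALYTIC_OFF, n_frames),
    )
    oh_idx = probe_index[kac_oh_key]
    coords[:, oh_idx, :] = ZN_POS + np.outer(d_cat, [0.0, 1.0, 0.0])

    # --- planted interaction movers ----------------------------------------
    for plant, anchor, probe_atoms, mode in plant_geoms:
        state = markov_chain(rng, n_frames, plant.p_on, plant.p_off)
        g = grid[plant.enzyme_residue]
        anchor_pos = base[anchor_index[(plant.enzyme_residue, anchor)]][:2]
        anchor_pos = np.array([anchor_pos[0], anchor_pos[1], 0.0])
        if mode in ("contact", "ionic-sub-cationic", "ionic-sub-anionic"):
            on_lo, on_hi = ON_CONTACT if mode == "contact" else ON_IONIC
            off_lo, off_hi = OFF_CONTACT if mode == "contact" else OFF_IONIC
            d = np.where(
                state,
                rng.uniform(on_lo, on_hi, n_frames),
                rng.uniform(off_lo, off_hi, n_frames),
            )
            probe_pos = anchor_pos + np.outer(d, [0.0, 1.0, 0.0])
            main = probe_atoms[-1] if mode == "ionic-sub-cationic" else probe_atoms[0]
            if mode == "ionic-sub-cationic":
                heavy, hydro = probe_atoms
                coords[:, probe_index[(plant.substrate_position, hydro)], :] = \
                    probe_pos
                coords[:, probe_index[(plant.substrate_position, heavy)], :] = \
                    probe_pos + [0.0, 0.10, 0.0]
            else:
                coords[:, probe_index[(plant.substrate_position, main)], :] = \
                    probe_pos
        elif mode == "hb-enz-donor":
            # enzyme OG–HG donates along +y; acceptor collinear when on
            d = rng.uniform(*ON_HBOND, n_frames)
            on_pos = anchor_pos + np.outer(d, [0.0, 1.0, 0.0])
            s45 = math.sin(math.radians(OFF_HBOND_ANGLE))
            c45 = math.cos(math.radians(OFF_HBOND_ANGLE))
            off_pos = anchor_pos + OFF_HBOND_DIST * np.array([s45, c45, 0.0])
            acc = probe_atoms[0]
            idx = probe_index[(plant.substrate_position, acc)]
            coords[:, idx, :] = np.where(state[:, None], on_pos, off_pos)
        else:  # hb-sub-donor: substrate D–H donates down toward enzyme OG
            heavy, hydro = probe_atoms
            d = rng.uniform(*ON_HBOND, n_frames)
            d_on = anchor_pos + np.outer(d, [0.0, 1.0, 0.0])
            s45 = math.sin(math.radians(OFF_HBOND_ANGLE))
            c45 = math.cos(math.radians(OFF_HBOND_ANGLE))
            d_off = anchor_pos + OFF_HBOND_DIST * np.array([s45, c45, 0.0])
            d_pos = np.where(state[:, None], d_on, d_off)
            i_heavy = probe_index[(plant.substrate_position, heavy)]
            i_h = probe_index[(plant.substrate_position, hydro)]
            coords[:, i_heavy, :] = d_pos
            coords[:, i_h, :] = d_pos + [0.0, -0.10, 0.0]

    traj = Trajectory(
        coords_nm=coords,
        atom_name=np.asarray(scaffold.names, dtype=object),
        element=np.asarray(
            ["ZN" if n == "ZN" else _element(n) for n in scaffold.names],
            dtype=object,
        ),
        res_id=np.asarray(scaffold.res_ids, dtype=int),
        res_name=np.asarray(scaffold.res_names, dtype=object),
        chain_id=np.asarray(scaffold.chains, dtype=object),
        enzyme_chain="A",
        substrate_chain="B",
        kac_residue=kac_resnum,
        peptide=peptide,
        replicate_id=replicate_id,
        chemistry=ChemistryTables(),
    )
    if path is not None:
        write_trajectory(traj, path)
    return traj


def generate_replicates(
    planted: list[PlantedInteraction],
    peptide: PeptideSequence | str = "FRKacWR",
    n_frames: int = 2500,
    n_replicates: int = 5,
    seed: int = 0,
    **kwargs,
) -> list[Trajectory]:
    """Independent replicate trajectories with seeds spawned from ``seed``."""
    children = np.random.SeedSequence(seed).generate_state(n_replicates)
    return [
        generate_trajectory(
            planted,
            peptide,
            n_frames,
            seed=int(children[r] % 2**31),
            replicate_id=r + 1,
            **kwargs,
        )
        for r in range(n_replicates)
    ]


# ---------------------------------------------------------------------------
# activity panels
# ---------------------------------------------------------------------------

def derivative_panel_peptides() -> list[PeptideSequence]:
    """The 16 FRKacXY derivative peptides varied at +1/+2 (X, Y ∈ AERWY
    in the combinations assayed)."""
    combos = sorted(
        {"WW", "WA", "WY", "WE", "WR", "YW", "YA", "EW", "EA",
         "RW", "RA", "AW", "AY", "AE", "AR", "AA"}
    )
    return [PeptideSequence.parse(f"FRKac{c}") for c in combos]


@dataclass
class SyntheticPanelSpec:
    """Recipe for a synthetic activity panel with planted cluster effects.

    ``cluster_effects`` maps (position, residue-set) to a multiplicative
    activity effect applied to every peptide carrying one of those residues
    at that position.  Replicate noise is log-normal with standard deviation
    ``noise_sd_log`` on the natural-log scale.
    """

    peptides: list[PeptideSequence] = field(
        default_factory=derivative_panel_peptides
    )
    baseline_activity: float = 0.02  # s^-1
    cluster_effects: dict[tuple[int, frozenset[str]], float] = field(
        default_factory=dict
    )
    noise_sd_log: float = 0.15
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.cluster_effects.values()):
            raise ValueError("effects must be > 0")
        if self.replicates < 1:
            raise ValueError("need ≥1 replicate")


def generate_activity_panel(spec: SyntheticPanelSpec) -> list[ActivityRecord]:
    """Replicate specific activities under the planted effect model.

    log(activity) = log(baseline) + Σ log(effect) over matching clusters
    + N(0, noise_sd_log²), independently per replicate.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for peptide in spec.peptides:
        log_mu = math.log(spec.baseline_activity)
        for (position, residues), effect in spec.cluster_effects.items():
            if peptide.has_residue_at(position, residues):
                log_mu += math.log(effect)
        eps = rng.normal(0.0, spec.noise_sd_log, spec.replicates)
        reps = np.exp(log_mu + eps)
        records.append(
            ActivityRecord(peptide=peptide, replicates=list(reps))
        )
    return records


# ---------------------------------------------------------------------------
# kinetic timecourses
# ---------------------------------------------------------------------------

def generate_timecourses(
    K_M: float,
    k_cat: float,
    enzyme_conc: float,
    concentrations=None,
    timepoints=(300.0, 600.0, 900.0, 1200.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Product-formation timecourses under the Michaelis–Menten model.

    K_M in μM, k_cat in s⁻¹, enzyme concentration in nM, times in seconds.
    Concentrations default to seven points log-spaced over 0.1×–10× K_M.
    product(t) = v₀·t·(1 + ε), ε ~ N(0, noise_sd²) i.i.d. per point.
    """
    if concentrations is None:
        concentrations = np.geomspace(0.1 * K_M, 10.0 * K_M, 7)
    concentrations = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    e_um = enzyme_conc * 1e-3
    rows = []
    for s in concentrations:
        v0 = k_cat * e_um * s / (K_M + s)
        for t in timepoints:
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {"concentration": s, "time": t, "product": v0 * t * (1 + eps)}
            )
    return pd.DataFrame(rows)
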