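"""Geometric interaction detection and frequency aggregation.

Four interaction types are scored between each enzyme residue and each
substrate position, frame by frame:

``contact``
    any enzyme-residue atom within 0.30 nm of any substrate-residue atom
    (van der Waals / total contact);
``ionic``
    any hydrogen of a cationic group within 0.25 nm of either oxygen of an
    anionic group;
``hbond_sidechain``
    side-chain/side-chain hydrogen bond: donor–acceptor heavy atoms within
    0.35 nm with the H–donor–acceptor angle within 30°;
``hbond_to_backbone``
    same geometry between the enzyme residue side chain and the substrate
    residue backbone (either donor direction).

Per-interaction occurrence vectors are aggregated to percent-of-time values,
averaged over replicate simulations and truncated to integer percent (floor,
so retained entries are ≥ 1%).  Two exclusion rules apply: an interaction
seen only in frames where the substrate is out of the catalytically relevant
pose (Zn-to-acetyl-carbonyl distance > 0.32 nm) is discarded outright, and
interactions averaging < 1% across all peptides capable of forming them are
dropped panel-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chemistry import ChemistryTables
from .peptides import AA_THREE, PeptideSequence
from .trajectory import Frame, ResidueId, SelectionError, Trajectory

logger = logging.getLogger(__name__)

ITYPES = ("contact", "hbond_sidechain", "hbond_to_backbone", "ionic")

BACKBONE_ATOMS = ("N", "H", "CA", "HA", "C", "O", "OXT")


class PairingError(ValueError):
    """Residue pair cannot form the requested charged interaction."""


class ArgumentError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance/angle cutoffs for the geometric detectors (nm, degrees)."""

    contact_cutoff: float = 0.30
    ionic_cutoff: float = 0.25
    hbond_heavy_cutoff: float = 0.35
    hbond_angle_max: float = 30.0
    catalytic_cutoff: float = 0.32

    def __post_init__(self) -> None:
        for name in (
            "contact_cutoff", "ionic_cutoff", "hbond_heavy_cutoff",
            "hbond_angle_max", "catalytic_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")


@dataclass
class InteractionRecord:
    """Per-frame occurrence of one (enzyme residue, position, type) triple."""

    enzyme_residue: ResidueId
    substrate_position: int
    itype: str
    occurrence: np.ndarray      # bool (F,)
    catalytic_mask: np.ndarray  # bool (F,)

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=bool)
        self.catalytic_mask = np.asarray(self.catalytic_mask, dtype=bool)
        if self.occurrence.shape != self.catalytic_mask.shape:
            raise ArgumentError("occurrence and catalytic_mask length differ")

    @property
    def key(self) -> tuple[ResidueId, int, str]:
        return (self.enzyme_residue, self.substrate_position, self.itype)

    @property
    def percent_time(self) -> float:
        return 100.0 * float(self.occurrence.mean())


@dataclass
class FrequencyTable:
    """Replicate-averaged, truncated percent-time per interaction key.

    ``entries`` holds the retained integer percentages; ``raw_means`` the
    pre-truncation replicate means for every key that occurred at all
    (useful for recovery diagnostics); ``excluded`` maps dropped keys to
    their reason (``"noncatalytic-only"`` or ``"low-frequency"``).
    """

    entries: dict[tuple[ResidueId, int, str], int] = field(default_factory=dict)
    replicate_count: int = 0
    excluded: dict[tuple[ResidueId, int, str], str] = field(default_factory=dict)
    raw_means: dict[tuple[ResidueId, int, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _as_coords(atoms) -> np.ndarray:
    if isinstance(atoms, np.ndarray) and atoms.ndim == 2:
        return atoms
    return np.asarray([a.coords for a in atoms], dtype=float)


def min_interatomic_distance(a, b) -> float:
    """Minimum Euclidean distance (nm) over all cross-pairs of two atom sets.

    Accepts sequences of `Atom` or ``(n, 3)`` coordinate arrays.
    """
    ca, cb = _as_coords(a), _as_coords(b)
    if ca.size == 0 or cb.size == 0:
        raise ArgumentError("atom sets must be non-empty")
    delta = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((delta ** 2).sum(-1)).min())


def _residue_number(residue) -> int:
    """Accept a ResidueId tuple, (chain, number) pair, or a bare number."""
    if isinstance(residue, tuple):
        return int(residue[1])
    return int(residue)


def _frame_residue_indices(frame: Frame, residue, chain: str) -> np.ndarray:
    return frame.trajectory.residue_indices(chain, _residue_number(residue))


def detect_contact(
    frame: Frame,
    enzyme_residue,
    substrate_position: int,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> bool:
    """Any-atom/any-atom proximity within the contact cutoff."""
    traj = frame.trajectory
    idx_e = _frame_residue_indices(frame, enzyme_residue, traj.enzyme_chain)
    idx_s = traj.residue_indices(
        traj.substrate_chain, traj.kac_residue + substrate_position
    )
    d = min_interatomic_distance(frame.coords[idx_e], frame.coords[idx_s])
    return d <= criteria.contact_cutoff


def _charged_atom_indices(traj: Trajectory, chain: str, res_number: int):
    """(cationic H indices, anionic O indices) of one residue."""
    idx = traj.residue_indices(chain, res_number)
    res_name = str(traj.res_name[idx[0]])
    chem = traj.chemistry
    h_names = set(chem.cationic_hydrogens(res_name))
    o_names = set(chem.anionic_oxygens(res_name))
    h_idx = idx[np.isin(traj.atom_name[idx], sorted(h_names))]
    o_idx = idx[np.isin(traj.atom_name[idx], sorted(o_names))]
    return h_idx, o_idx


def detect_ionic(
    frame: Frame,
    cationic_residue,
    anionic_residue,
    criteria: InteractionCriteria = InteractionCriteria(),
    *,
    cationic_chain: str | None = None,
    anionic_chain: str | None = None,
) -> bool:
    """Cationic-group hydrogen within the ionic cutoff of an anionic oxygen.

    The first residue must bear the cationic group and the second the
    anionic group; a residue qualifying for neither (or the pair for both
    roles at once) raises `PairingError`.  Chains default to enzyme for the
    first residue and substrate for the second.
    """
    traj = frame.trajectory
    c_chain = cationic_chain or traj.enzyme_chain
    a_chain = anionic_chain or traj.substrate_chain
    h_idx, _ = _charged_atom_indices(
        traj, c_chain, _residue_number(cationic_residue)
    )
    _, o_idx = _charged_atom_indices(
        traj, a_chain, _residue_number(anionic_residue)
    )
    if h_idx.size == 0 or o_idx.size == 0:
        raise PairingError(
            "ionic detection needs one cationic residue (with hydrogens) "
            "and one anionic residue (with oxygens)"
        )
    d = min_interatomic_distance(frame.coords[h_idx], frame.coords[o_idx])
    return d <= criteria.ionic_cutoff


def _donor_triples(traj, idx, scope: str):
    """(donor heavy index, hydrogen index) pairs for a residue selection."""
    res_name = str(traj.res_name[idx[0]])
    names = {str(traj.atom_name[i]): i for i in idx}
    if scope == "sidechain":
        pairs = traj.chemistry.sidechain_donor_pairs(res_name)
    else:
        pairs = [("N", "H")]
    return [
        (names[d], names[h]) for d, h in pairs if d in names and h in names
    ]


def _acceptor_indices(traj, idx, scope: str):
    res_name = str(traj.res_name[idx[0]])
    if scope == "sidechain":
        wanted = traj.chemistry.sidechain_acceptor_atoms(res_name)
    else:
        wanted = ("O", "OXT")
    return idx[np.isin(traj.atom_name[idx], list(wanted))]


def detect_hbond(
    frame: Frame,
    donor_residue,
    acceptor_residue,
    criteria: InteractionCriteria = InteractionCriteria(),
    acceptor_scope: str = "sidechain",
    *,
    donor_scope: str = "sidechain",
    donor_chain: str | None = None,
    acceptor_chain: str | None = None,
) -> bool:
    """Hydrogen bond: heavy atoms within cutoff at an acceptable angle.

    Geometry: donor heavy atom D with bonded hydrogen H, acceptor heavy atom
    A; requires |D−A| ≤ 0.35 nm and angle(H–D–A) ≤ 30°.  A donor residue
    without hydrogens yields ``False`` with a logged note.
    """
    traj = frame.trajectory
    d_chain = donor_chain or traj.enzyme_chain
    a_chain = acceptor_chain or traj.substrate_chain
    idx_d = traj.residue_indices(d_chain, _residue_number(donor_residue))
    idx_a = traj.residue_indices(a_chain, _residue_number(acceptor_residue))
    triples = _donor_triples(traj, idx_d, donor_scope)
    acceptors = _acceptor_indices(traj, idx_a, acceptor_scope)
    if not triples:
        logger.debug(
            "no donor hydrogens on %s residue %s", d_chain, donor_residue
        )
        return False
    if acceptors.size == 0:
        return False
    c = frame.coords
    for d_i, h_i in triples:
        da = c[acceptors] - c[d_i]
        dist = np.linalg.norm(da, axis=1)
        dh = c[h_i] - c[d_i]
        cosang = (da @ dh) / np.maximum(dist * np.linalg.norm(dh), 1e-12)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if np.any(
            (dist <= criteria.hbond_heavy_cutoff)
            & (angle <= criteria.hbond_angle_max)
        ):
            return True
    return False


def is_catalytic_frame(
    frame: Frame, criteria: InteractionCriteria = InteractionCriteria()
) -> bool:
    """Zn-to-acetyl-carbonyl distance within the catalytic cutoff.

    A frame stops being catalytically relevant only when the distance
    strictly exceeds the cutoff, so exactly 0.32 nm still counts.
    """
    d = float(np.linalg.norm(frame.zn_position - frame.kac_carbonyl_position))
    return d <= criteria.catalytic_cutoff


# ---------------------------------------------------------------------------
# vectorised whole-trajectory scan
# ---------------------------------------------------------------------------

def _min_dist_all_frames(coords, idx_a, idx_b) -> np.ndarray:
    """Per-frame min cross-pair distance; coords is (F, N, 3)."""
    delta = coords[:, idx_a, None, :] - coords[:, None, idx_b, :]
    return np.sqrt((delta ** 2).sum(-1)).min(axis=(1, 2))


def _hbond_all_frames(traj, idx_don, idx_acc, criteria, donor_scope, acceptor_scope):
    triples = _donor_triples(traj, idx_don, donor_scope)
    acceptors = _acceptor_indices(traj, idx_acc, acceptor_scope)
    out = np.zeros(traj.n_frames, dtype=bool)
    if not triples or acceptors.size == 0:
        return out
    c = traj.coords_nm
    for d_i, h_i in triples:
        da = c[:, acceptors, :] - c[:, d_i, None, :]      # (F, A, 3)
        dist = np.linalg.norm(da, axis=2)
        dh = c[:, h_i, :] - c[:, d_i, :]                  # (F, 3)
        dots = np.einsum("fad,fd->fa", da, dh)
        denom = np.maximum(dist * np.linalg.norm(dh, axis=1)[:, None], 1e-12)
        angle = np.degrees(np.arccos(np.clip(dots / denom, -1.0, 1.0)))
        out |= np.any(
            (dist <= criteria.hbond_heavy_cutoff)
            & (angle <= criteria.hbond_angle_max),
            axis=1,
        )
    return out


def catalytic_mask(
    traj: Trajectory, criteria: InteractionCriteria = InteractionCriteria()
) -> np.ndarray:
    return traj.zn_carbonyl_distances() <= criteria.catalytic_cutoff


def scan_interactions(
    traj: Trajectory, criteria: InteractionCriteria = InteractionCriteria()
) -> list[InteractionRecord]:
    """Score every interaction type for every enzyme-residue/substrate-
    position pair across all frames.

    Returns one record per key with at least one occurrence.  ``ionic`` is
    only attempted for pairs where one residue is cationic and the other
    anionic; hydrogen bonds always involve the enzyme side chain, paired
    with either the substrate side chain (``hbond_sidechain``) or backbone
    (``hbond_to_backbone``), in both donor directions.
    """
    cat_mask = catalytic_mask(traj, criteria)
    records: list[InteractionRecord] = []
    for enz in traj.enzyme_residues():
        idx_e = traj.residue_indices(traj.enzyme_chain, enz[1])
        for offset in traj.substrate_offsets():
            sub = traj.substrate_residue(offset)
            idx_s = traj.residue_indices(traj.substrate_chain, sub[1])
            occ = {}
            d = _min_dist_all_frames(traj.coords_nm, idx_e, idx_s)
            occ["contact"] = d <= criteria.contact_cutoff

            occ["hbond_sidechain"] = _hbond_all_frames(
                traj, idx_e, idx_s, criteria, "sidechain", "sidechain"
            ) | _hbond_all_frames(
                traj, idx_s, idx_e, criteria, "sidechain", "sidechain"
            )
            occ["hbond_to_backbone"] = _hbond_all_frames(
                traj, idx_e, idx_s, criteria, "sidechain", "backbone"
            ) | _hbond_all_frames(
                traj, idx_s, idx_e, criteria, "backbone", "sidechain"
            )

            ionic = np.zeros(traj.n_frames, dtype=bool)
            h_e, o_e = _split_charged(traj, idx_e)
            h_s, o_s = _split_charged(traj, idx_s)
            if h_e.size and o_s.size:
                ionic |= (
                    _min_dist_all_frames(traj.coords_nm, h_e, o_s)
                    <= criteria.ionic_cutoff
                )
            if h_s.size and o_e.size:
                ionic |= (
                    _min_dist_all_frames(traj.coords_nm, h_s, o_e)
                    <= criteria.ionic_cutoff
                )
            occ["ionic"] = ionic

            for itype in ITYPES:
                if occ[itype].any():
                    records.append(
                        InteractionRecord(
                            enzyme_residue=enz,
                            substrate_position=offset,
                            itype=itype,
                            occurrence=occ[itype],
                            catalytic_mask=cat_mask,
                        )
                    )
    return records


def _split_charged(traj, idx):
    res_name = str(traj.res_name[idx[0]])
    chem = traj.chemistry
    h_names = chem.cationic_hydrogens(res_name)
    o_names = chem.anionic_oxygens(res_name)
    h_idx = idx[np.isin(traj.atom_name[idx], list(h_names))] if h_names else idx[:0]
    o_idx = idx[np.isin(traj.atom_name[idx], list(o_names))] if o_names else idx[:0]
    return h_idx, o_idx


# ---------------------------------------------------------------------------
# aggregation and exclusion
# ---------------------------------------------------------------------------

def aggregate_frequencies(
    records_by_replicate: list[list[InteractionRecord]],
) -> FrequencyTable:
    """Average percent-time over replicates, apply exclusions, truncate.

    Per key the replicate percentage is 100 × occurrences / frames (a key
    absent from a replicate contributes 0).  A key whose occurrences fall
    entirely outside catalytically relevant frames in *every* replicate is
    excluded as ``noncatalytic-only``.  Means are floored to integer
    percent; keys flooring to 0 are dropped (the 1% lower limit).
    """
    if not records_by_replicate:
        raise ArgumentError("need at least one replicate")
    n_rep = len(records_by_replicate)
    percents: dict[tuple, list[float]] = {}
    catalytic_seen: dict[tuple, bool] = {}
    for rep in records_by_replicate:
        for rec in rep:
            if rec.occurrence.size == 0:
                raise ArgumentError("zero-frame replicate")
            percents.setdefault(rec.key, [0.0] * n_rep)
    for r, rep in enumerate(records_by_replicate):
        for rec in rep:
            percents[rec.key][r] = rec.percent_time
            if (rec.occurrence & rec.catalytic_mask).any():
                catalytic_seen[rec.key] = True

    table = FrequencyTable(replicate_count=n_rep)
    for key, vals in percents.items():
        mean = float(np.mean(vals))
        table.raw_means[key] = mean
        if not catalytic_seen.get(key, False):
            table.excluded[key] = "noncatalytic-only"
            continue
        truncated = int(mean)  # floor toward zero; percentages are ≥ 0
        if truncated >= 1:
            table.entries[key] = truncated
    return table


_SC_DONOR_LETTERS = set("STYCNQWHRK")
_SC_ACCEPTOR_LETTERS = set("STYDENQHM")


def default_capability(
    peptide: PeptideSequence, key: tuple[ResidueId, int, str]
) -> bool:
    """Whether a peptide can in principle form the keyed interaction.

    Contact needs only a residue at the position; ionic needs opposite
    charges between the enzyme residue and the substrate residue; a
    side-chain hydrogen bond needs a substrate side chain with a donor or
    acceptor; a bond to the substrate backbone is always possible.
    """
    enzyme_residue, position, itype = key
    letter = peptide.residue_at(position)
    if letter is None:
        return False
    if position == 0:
        letter = "K"  # acetyllysine: neutral, H-bond capable amide/carbonyl
        if itype == "ionic":
            return False
    if itype in ("contact", "hbond_to_backbone"):
        return True
    if itype == "hbond_sidechain":
        if position == 0:
            return True
        return letter in (_SC_DONOR_LETTERS | _SC_ACCEPTOR_LETTERS)
    if itype == "ionic":
        enz_name = enzyme_residue[2]
        chem = ChemistryTables()
        if chem.is_cationic_residue(enz_name):
            return letter in "DE"
        if chem.is_anionic_residue(enz_name):
            return letter in "RKH"
        return False
    raise ArgumentError(f"unknown interaction type {itype!r}")


def apply_low_frequency_filter(
    tables_by_peptide: dict[PeptideSequence, FrequencyTable],
    capability=default_capability,
    threshold: float = 1.0,
) -> dict[PeptideSequence, FrequencyTable]:
    """Drop interactions averaging below ``threshold`` percent across all
    peptides capable of forming them.

    Incapable peptides are left out of the mean's denominator entirely, so a
    single capable peptide with a frequency at or above the threshold keeps
    the interaction.  Returns new tables; dropped keys move to ``excluded``
    with reason ``low-frequency``.
    """
    all_keys = set()
    for table in tables_by_peptide.values():
        all_keys |= set(table.entries)
    keep = {}
    for key in all_keys:
        capable = [p for p in tables_by_peptide if capability(p, key)]
        if not capable:
            keep[key] = False
            continue
        mean = float(
            np.mean(
                [tables_by_peptide[p].entries.get(key, 0) for p in capable]
            )
        )
        keep[key] = mean >= threshold
    out = {}
    for peptide, table in tables_by_peptide.items():
        filtered = FrequencyTable(
            replicate_count=table.replicate_count,
            excluded=dict(table.excluded),
            raw_means=dict(table.raw_means),
        )
        for key, value in table.entries.items():
            if keep[key]:
                filtered.entries[key] = value
            else:
                filtered.excluded[key] = "low-frequency"
        out[peptide] = filtered
    return out


def compute_occupancy(
    records: list[InteractionRecord],
    site_def_p1: set,
    site_def_p2: set,
) -> tuple[float, float, float]:
    """Fractions of frames with dual, single and no pocket occupancy.

    A frame is +1-occupied when the +1 residue is simultaneously in contact
    with every enzyme residue in ``site_def_p1``, and +2-occupied likewise
    for ``site_def_p2``.  Residues may be given as residue numbers or
    residue-id tuples.  Fractions sum to 1 exactly.
    """
    if not site_def_p1 or not site_def_p2:
        raise ArgumentError("site definitions must be non-empty")
    contact: dict = {}
    for r in records:
        if r.itype != "contact":
            continue
        num, name = r.enzyme_residue[1], r.enzyme_residue[2]
        contact[(num, r.substrate_position)] = r.occurrence
        contact[(str(name), r.substrate_position)] = r.occurrence
    if not contact:
        return (0.0, 0.0, 1.0)
    n_frames = next(iter(contact.values())).size

    def _site_key(res):
        if isinstance(res, tuple):
            return int(res[1])
        if isinstance(res, int) or str(res).isdigit():
            return int(res)
        return str(res)

    def site_mask(site_def, position):
        mask = np.ones(n_frames, dtype=bool)
        for res in site_def:
            occ = contact.get((_site_key(res), position))
            if occ is None:
                return np.zeros(n_frames, dtype=bool)
            mask &= occ
        return mask

    p1 = site_mask(site_def_p1, +1)
    p2 = site_mask(site_def_p2, +2)
    dual = float((p1 & p2).mean())
    single = float((p1 ^ p2).mean())
    return dual, single, 1.0 - dual - single
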