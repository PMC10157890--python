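"""Acetylpeptide sequence handling.

Substrate peptides are short sequences carrying exactly one acetyllysine
(written ``Kac``, ``K^ac^`` or ``K(ac)``), which defines position 0 of the
substrate register.  Flanking residues are addressed by their signed offset
from the acetyllysine: the residue immediately before it is −1, the residue
immediately after is +1, and so on.  Peptides are N-terminally acetylated and
C-terminally amidated by default, so both termini are charge-neutral.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: three-letter residue names, used when building synthetic structures
AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

_KAC_TOKEN = re.compile(r"K\^ac\^|K\(ac\)|Kac")


class PeptideError(ValueError):
    """Raised for malformed peptide notation."""


@dataclass(frozen=True)
class PeptideSequence:
    """A substrate peptide with one acetyllysine.

    Parameters
    ----------
    residues : str
        One-letter sequence including the acetyllysine as ``K``.
    kac_index : int
        0-based index of the acetyllysine within ``residues``.
    n_terminal_acetyl, c_terminal_amide : bool
        Terminal capping; capped termini carry no charge.
    """

    residues: str
    kac_index: int
    n_terminal_acetyl: bool = True
    c_terminal_amide: bool = True
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not set(self.residues) <= AA_LETTERS:
            bad = sorted(set(self.residues) - AA_LETTERS)
            raise PeptideError(f"unknown residue letters: {bad}")
        if not 0 <= self.kac_index < len(self.residues):
            raise PeptideError("kac_index outside sequence")
        if self.residues[self.kac_index] != "K":
            raise PeptideError("acetyllysine position is not a lysine")

    @classmethod
    def parse(cls, text: str, **kwargs) -> "PeptideSequence":
        """Parse ``Kac`` notation, e.g. ``"FRKacWR"`` or ``"FRK^ac^WR"``."""
        text = text.replace(" ", "")
        hits = list(_KAC_TOKEN.finditer(text))
        if len(hits) != 1:
            raise PeptideError(
                f"expected exactly one acetyllysine marker in {text!r}, "
                f"found {len(hits)}"
            )
        m = hits[0]
        plain = text[: m.start()] + "K" + text[m.end():]
        return cls(plain, kac_index=m.start(), name=text, **kwargs)

    def __str__(self) -> str:
        i = self.kac_index
        return self.residues[:i] + "Kac" + self.residues[i + 1:]

    @property
    def offsets(self) -> range:
        """Valid position offsets, acetyllysine = 0."""
        return range(-self.kac_index, len(self.residues) - self.kac_index)

    def residue_at(self, offset: int) -> str | None:
        """One-letter residue at a signed offset from the acetyllysine.

        Returns ``None`` if the peptide does not extend to that offset.
        Offset 0 is the acetyllysine itself.
        """
        i = self.kac_index + offset
        if 0 <= i < len(self.residues):
            return self.residues[i]
        return None

    def has_residue_at(self, offset: int, residues: str | set[str]) -> bool:
        r = self.residue_at(offset)
        return r is not None and r in set(residues)
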