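"""Packaged activity and kinetics tables.

Two validation panels of acetylpeptides derived from human proteins with
lysines known to be acetylated in cells — one assayed with KDAC6 (30
peptides, detection limit 0.0013 s⁻¹) and one with KDAC8 (29 peptides,
detection limit 0.0004 s⁻¹) — plus the steady-state kinetic parameters of
both enzymes with the six FRKacXY derivative peptides.  An empty activity
mean encodes "below the limit of reliable detection".
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .activity import ActivityRecord
from .peptides import PeptideSequence

KDAC6_DETECTION_LIMIT = 0.0013  # s^-1
KDAC8_DETECTION_LIMIT = 0.0004  # s^-1


def _data_path(name: str):
    return resources.files("kdacsel.data") / name


def _load_panel(
    name: str, enzyme: str, detection_limit: float
) -> list[ActivityRecord]:
    with resources.as_file(_data_path(name)) as path:
        df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        peptide = PeptideSequence.parse(
            row.sequence,
            c_terminal_amide=str(row.c_terminal_amide).lower() == "true",
        )
        records.append(
            ActivityRecord(
                peptide=peptide,
                enzyme=enzyme,
                mean=float(row.activity_mean)
                if pd.notna(row.activity_mean)
                else float("nan"),
                sd=float(row.activity_sd)
                if pd.notna(row.activity_sd)
                else float("nan"),
                detection_limit=detection_limit,
            )
        )
    return records


def kdac6_panel() -> list[ActivityRecord]:
    """Specific activities of KDAC6 with 30 putative-substrate peptides."""
    return _load_panel("table2_kdac6.csv", "KDAC6", KDAC6_DETECTION_LIMIT)


def kdac8_panel() -> list[ActivityRecord]:
    """Specific activities of KDAC8 with 29 putative-substrate peptides."""
    return _load_panel("table3_kdac8.csv", "KDAC8", KDAC8_DETECTION_LIMIT)


def kinetic_parameters() -> pd.DataFrame:
    """Steady-state K_M, k_cat and efficiency of KDAC6/KDAC8 with the
    FRKacXY derivative peptides (K_M in μM, k_cat in s⁻¹, efficiency in
    M⁻¹ s⁻¹)."""
    with resources.as_file(_data_path("table1_kinetics.csv")) as path:
        return pd.read_csv(path)
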