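"""Heat-map style export of interaction frequency tables.

One table per substrate position: rows are enzyme residues ordered by
residue number, columns the four interaction types.  Cells are blank where
the interaction was not observed or was excluded, mirroring the convention
that a box is drawn only where the interaction is possible and seen.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .interactions import ITYPES, FrequencyTable
from .trajectory import ResidueId


def heatmap_frame(
    freqs: FrequencyTable,
    position: int,
    annotations: dict[tuple[ResidueId, int, str], bool] | None = None,
) -> pd.DataFrame:
    """Frequency table for one substrate position as a tidy DataFrame.

    ``annotations`` marks keys that passed the two-stage significance
    procedure; they appear in ``significant_<itype>`` columns.
    """
    residues = sorted(
        {k[0] for k in freqs.entries if k[1] == position},
        key=lambda r: (r[0], r[1]),
    )
    rows = []
    for res in residues:
        row: dict = {
            "chain": res[0],
            "residue_number": res[1],
            "residue_name": res[2],
        }
        for itype in ITYPES:
            key = (res, position, itype)
            row[itype] = freqs.entries.get(key, pd.NA)
            if annotations is not None:
                row[f"significant_{itype}"] = bool(annotations.get(key, False))
        rows.append(row)
    columns = ["chain", "residue_number", "residue_name", *ITYPES]
    if annotations is not None:
        columns += [f"significant_{t}" for t in ITYPES]
    return pd.DataFrame(rows, columns=columns)


def export_heatmap(
    freqs: FrequencyTable,
    position: int,
    path,
    annotations: dict | None = None,
) -> Path:
    """Write the per-position heat-map table as TSV (blank = not observed)."""
    df = heatmap_frame(freqs, position, annotations)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_heatmap(path, position: int) -> FrequencyTable:
    """Parse an exported heat-map TSV back into a `FrequencyTable`.

    Lossless for retained entries; exclusion reasons are not round-tripped.
    """
    df = pd.read_csv(path, sep="\t")
    table = FrequencyTable()
    for row in df.itertuples(index=False):
        res: ResidueId = (str(row.chain), int(row.residue_number),
                          str(row.residue_name))
        for itype in ITYPES:
            value = getattr(row, itype)
            if pd.notna(value):
                table.entries[(res, position, itype)] = int(value)
    return table
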