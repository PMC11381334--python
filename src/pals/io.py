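"""Reading and writing the formats the workflow touches.

FASTA for protein/peptide sequences (via Biopython), CSV/TSV for inclusion
lists, panel reports and peak tables.  Numeric columns are written with
fixed precision so identical inputs produce byte-identical reports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import BarcodePanel
from .quant import validate_peak_table

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_inclusion_list",
    "write_panel_report",
    "panel_to_fasta",
    "read_peak_table",
    "write_peak_table",
    "read_panel_assignment",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence for every record in a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _mz_columns(panel: BarcodePanel, charges: Sequence[int] = (1, 2, 3)) -> pd.DataFrame:
    rows = []
    for bid, cand in zip(panel.barcode_ids(), panel.members):
        mzs = dict(cand.precursor_mzs)
        row = {
            "barcode_id": bid,
            "sequence": cand.full_peptide,
            "monoisotopic_mass": round(cand.mass, 5),
        }
        for z in charges:
            row[f"mz_z{z}"] = round(mzs[z], 5) if z in mzs else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_inclusion_list(panel: BarcodePanel, path: str | Path) -> pd.DataFrame:
    """Targeted-acquisition inclusion list: one row per barcode, m/z at z=1..3."""
    df = _mz_columns(panel)
    df.to_csv(path, index=False)
    return df


def write_panel_report(panel: BarcodePanel, path: str | Path) -> pd.DataFrame:
    """Panel report TSV with per-barcode nearest-neighbour mass distance."""
    df = _mz_columns(panel)
    df = df.rename(columns={"sequence": "full_peptide", "monoisotopic_mass": "mass"})
    df.insert(1, "core", [c.core for c in panel.members])
    masses = np.array([c.mass for c in panel.members])
    nn = np.full(len(masses), np.inf)
    if len(masses) > 1:
        order = np.argsort(masses)
        sorted_m = masses[order]
        gaps_left = np.diff(sorted_m, prepend=np.inf)
        gaps_right = np.diff(sorted_m, append=np.inf)
        nn_sorted = np.minimum(gaps_left, gaps_right)
        nn[order] = nn_sorted
    df["nearest_neighbor_distance_Da"] = np.round(nn, 6)
    df["lnp_label"] = [panel.assignment.get(bid) for bid in df["barcode_id"]]
    df.to_csv(path, sep="\t", index=False)
    return df


def panel_to_fasta(panel: BarcodePanel, path: str | Path) -> None:
    write_fasta(
        [(bid, c.full_peptide) for bid, c in zip(panel.barcode_ids(), panel.members)],
        path,
    )


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_peak_table(df)


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_peak_table(table)
    table.to_csv(path, index=False)


def read_panel_assignment(path: str | Path) -> dict[str, str | None]:
    """barcode_id -> LNP label from a panel report TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, str | None] = {}
    for _, row in df.iterrows():
        label = row.get("lnp_label")
        out[row["barcode_id"]] = None if pd.isna(label) else str(label)
    return out
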