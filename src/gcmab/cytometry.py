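"""Index-sort flow-cytometry integration.

Index sorting records each sorted cell's compensated fluorescence
parameters keyed by (plate, well).  Values are attached to cell metadata
both raw and after the hyperbolic-arcsine transform asinh(value/cofactor),
which linearizes compensated data around zero and is defined for the
negative values compensation can produce.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

DEFAULT_COFACTOR = 100.0

#: Convention for antigen positivity on the asinh scale: signal above
#: background noise corresponds to asinh(MFI/cofactor) > 1.
DEFAULT_BACKGROUND_CUTOFF = 1.0

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")  # 96-well geometry A1-H12


def asinh_transform(value, cofactor: float = DEFAULT_COFACTOR):
    """asinh(value / cofactor); odd in value, strictly increasing."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return np.arcsinh(np.asarray(value, dtype=float) / cofactor)


def validate_well(well: str) -> str:
    if not _WELL_RE.match(str(well)):
        raise ValueError(f"well {well!r} violates 96-well geometry (A1-H12)")
    return well


def validate_index_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check (plate, well) uniqueness and well geometry of an index table."""
    for col in ("plate", "well"):
        if col not in table.columns:
            raise ValueError(f"index-sort table missing column {col!r}")
    for well in table["well"]:
        validate_well(well)
    dup = table.duplicated(subset=["plate", "well"])
    if dup.any():
        bad = table.loc[dup, ["plate", "well"]].iloc[0]
        raise ValueError(f"duplicate (plate, well): {tuple(bad)}")
    return table


def attach_index_sort(
    table: pd.DataFrame,
    well_to_cell: pd.DataFrame,
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[pd.DataFrame, dict]:
    """Attach per-cell raw and asinh-transformed fluorescence values.

    Parameters
    ----------
    table : index-sort table with columns plate, well, and one column per
        fluorescence channel.
    well_to_cell : columns plate, well, cell_id mapping sorted wells to
        cells.

    Returns
    -------
    (cells × channels DataFrame indexed by cell_id with ``<channel>`` raw
    and ``asinh_<channel>`` columns, report dict with unmapped wells).
    """
    validate_index_table(table)
    for col in ("plate", "well", "cell_id"):
        if col not in well_to_cell.columns:
            raise ValueError(f"well map missing column {col!r}")
    if well_to_cell.duplicated(subset=["plate", "well"]).any():
        raise ValueError("duplicate cell_id mapping for one well")
    if well_to_cell["cell_id"].duplicated().any():
        raise ValueError("one cell_id mapped to multiple wells")

    channels = [c for c in table.columns if c not in ("plate", "well")]
    merged = well_to_cell.merge(table, on=["plate", "well"], how="left")
    missing = merged[channels].isna().all(axis=1)
    report = {
        "n_cells": len(well_to_cell),
        "n_wells": len(table),
        "unmapped_wells": [
            tuple(r)
            for r in table.merge(
                well_to_cell[["plate", "well"]],
                on=["plate", "well"],
                how="left",
                indicator=True,
            )
            .query("_merge == 'left_only'")[["plate", "well"]]
            .itertuples(index=False)
        ],
        "cells_without_well": list(merged.loc[missing, "cell_id"]),
    }
    out = merged.set_index("cell_id")[channels].astype(float)
    for ch in channels:
        out[f"asinh_{ch}"] = asinh_transform(out[ch].to_numpy(), cofactor)
    return out, report
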