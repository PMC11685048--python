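"""Bundled reference panel of recombinant mAbs from OVA-specific GC B cells.

The panel lists 37 published recombinant monoclonal antibodies — 32 derived
from single germinal-center B cells of five expanded clonotypes (c179,
c248, c127, c87, c184) obtained after ovalbumin immunization of mice, plus
the five unmutated germline-revertant constructs — with their heavy/light
chain CDR and framework mutation counts, ELISA Binding Threshold (ng;
">1000" marks mAbs never reaching detectable binding) and the OVA-AF647
surface binding of the cell of origin on the asinh(MFI/100) scale (not
available for the synthesized germline constructs).

It serves as a worked real-data example for the semi-log fit and the
FACS-vs-ELISA outlier rule.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

CENSOR_CAP_NG = 1000.0


def _parse_threshold(value: str) -> tuple[float, bool]:
    s = str(value).strip()
    if s.startswith(">"):
        return float(s[1:]), True
    return float(s), False


def load_mab_panel() -> pd.DataFrame:
    """Load the bundled mAb panel.

    Adds parsed columns: ``threshold_ng`` (censored entries at their
    bound), ``censored`` and numeric ``asinh_OVA-AF647`` (NaN for germline
    constructs), plus ``is_germline``.
    """
    with resources.files("gcmab.data").joinpath("mab_panel.csv").open() as fh:
        df = pd.read_csv(fh)
    parsed = df["elisa_threshold"].map(_parse_threshold)
    df["threshold_ng"] = [v for v, _ in parsed]
    df["censored"] = [c for _, c in parsed]
    df["asinh_OVA-AF647"] = pd.to_numeric(df["ova_asinh"], errors="coerce")
    df["is_germline"] = df["mab_id"] == "germline"
    df["cell_id"] = np.where(df["is_germline"], pd.NA, df["mab_id"])
    return df


def load_cell_mabs() -> pd.DataFrame:
    """The 32 cell-derived (non-germline) mAbs of the panel."""
    df = load_mab_panel()
    return df[~df["is_germline"]].reset_index(drop=True)
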