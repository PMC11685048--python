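"""Per-cell quality control and log-normalization of UMI counts.

Counts are genes × cells DataFrames.  ERCC spike-in rows (identified by id
prefix) are excluded from cell totals and from the normalized output; they
serve only to assess per-cell quantification accuracy against their known
input concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ERCC_PREFIX = "ERCC-"
MITO_PREFIX = "mt-"

#: Minimum number of detected spike-in species for a meaningful accuracy
#: estimate; below this the metric is undefined and the cell fails QC.
MIN_DETECTED_ERCC = 3


@dataclass
class QCThresholds:
    """Pass/fail cut-offs; all four criteria must hold for a cell to pass.

    The defaults are typical for plate-based scRNA-seq with ERCC spike-ins
    and are configuration, not constants.
    """

    min_total_umi: float = 2000
    min_genes: int = 500
    max_pct_mito: float = 20.0
    min_ercc_accuracy: float = 0.8

    def __post_init__(self) -> None:
        for name in ("min_total_umi", "min_genes", "max_pct_mito", "min_ercc_accuracy"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not -1 <= self.min_ercc_accuracy <= 1:
            raise ValueError("min_ercc_accuracy must be in [-1, 1]")


def split_ercc(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a counts matrix into (endogenous, ERCC) row blocks."""
    is_ercc = counts.index.str.startswith(ERCC_PREFIX)
    return counts.loc[~is_ercc], counts.loc[is_ercc]


def compute_qc_metrics(
    counts: pd.DataFrame,
    ercc_expected: pd.Series | dict,
    mito_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics: total UMI, genes detected, %mito, ERCC accuracy.

    ``ercc_accuracy`` is the Pearson correlation of log1p(observed spike-in
    count) against log10(expected concentration) across spike-in species
    with expected concentration > 0; NaN when fewer than 3 species are
    detected in the cell.

    Parameters
    ----------
    mito_genes : explicit mitochondrial gene list; default is every gene
        with the mouse ``mt-`` prefix.
    """
    endo, ercc = split_ercc(counts)
    ercc_expected = pd.Series(ercc_expected, dtype=float)
    if mito_genes is None:
        mito_genes = [g for g in endo.index if g.startswith(MITO_PREFIX)]
    unknown = set(mito_genes) - set(endo.index)
    if unknown:
        raise ValueError(f"mito genes absent from the matrix: {sorted(unknown)}")

    total = endo.sum(axis=0)
    n_genes = (endo > 0).sum(axis=0)
    mito = endo.loc[mito_genes].sum(axis=0) if mito_genes else 0.0
    with np.errstate(invalid="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito / total, 0.0)

    expected = ercc_expected[ercc_expected > 0]
    species = [s for s in expected.index if s in ercc.index]
    log_exp = np.log10(expected[species].to_numpy())
    accuracy = np.full(counts.shape[1], np.nan)
    for j, cell in enumerate(counts.columns):
        obs = ercc.loc[species, cell].to_numpy(dtype=float)
        if (obs > 0).sum() < MIN_DETECTED_ERCC:
            continue  # undefined; stays NaN and fails QC
        log_obs = np.log1p(obs)
        if log_obs.std() == 0 or log_exp.std() == 0:
            continue
        accuracy[j] = np.corrcoef(log_obs, log_exp)[0, 1]

    return pd.DataFrame(
        {
            "total_umi": total.astype(float),
            "n_genes_detected": n_genes.astype(int),
            "pct_mito": pct_mito,
            "ercc_accuracy": accuracy,
        },
        index=counts.columns.rename("cell_id"),
    )


def filter_cells(
    metrics: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the four QC criteria; returns metrics + pass flag + reasons.

    A cell passes iff all criteria hold; an undefined ERCC accuracy (NaN)
    fails the accuracy criterion.
    """
    t = thresholds or QCThresholds()
    reasons = []
    for _, row in metrics.iterrows():
        why = []
        if row["total_umi"] < t.min_total_umi:
            why.append("low_total_umi")
        if row["n_genes_detected"] < t.min_genes:
            why.append("few_genes")
        if row["pct_mito"] > t.max_pct_mito:
            why.append("high_pct_mito")
        if not (row["ercc_accuracy"] >= t.min_ercc_accuracy):  # NaN fails
            why.append("low_ercc_accuracy")
        reasons.append(";".join(why))
    report = metrics.copy()
    report["fail_reasons"] = reasons
    report["pass_qc"] = [r == "" for r in reasons]
    return report


def lognormalize(counts: pd.DataFrame, scale_factor: float = 10_000) -> pd.DataFrame:
    """ln(1 + scale_factor · count / cell_total), ERCC rows excluded.

    Cell totals are computed over endogenous genes only.  Cells with zero
    total must be removed by QC first and raise an error here.
    """
    endo, _ = split_ercc(counts)
    total = endo.sum(axis=0)
    zero = total[total <= 0]
    if len(zero):
        raise ValueError(
            f"zero-total cells (remove via QC first): {list(zero.index[:5])}"
        )
    return np.log1p(endo * (scale_factor / total))
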