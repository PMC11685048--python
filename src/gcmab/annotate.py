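"""Gene-signature module scoring, GC subset gating, and cell-cycle phasing.

Cells are scored for subset-specific gene signatures by comparing the mean
normalized expression of signature genes against bin-matched control genes
(the classic module-score construction: genes are binned by average
expression so that controls share the signature's expression regime), then
gated into germinal-center (GC) B-cell states by a fixed sequence of
threshold rules.

The bundled default signatures are the top marker genes of each GC state in
OVA-immunized mouse lymph nodes: light zone (LZ), dark zone (DZ), recycling
LZ-to-DZ, memory precursors (preMem), plasma-cell precursors (prePC) and
plasma cells (PC).  Because LZ/DZ biology is entangled with proliferation,
cell-cycle genes are removed from the LZ and DZ signatures before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSETS = ["LZ", "DZ", "LZtoDZ", "preMem", "prePC", "PC"]

#: Top-5 marker genes per GC subset (mouse symbols).
DEFAULT_SIGNATURES: dict[str, list[str]] = {
    "LZ": ["Fcer2a", "Cd83", "H2-Oa", "Cd86", "Nfkbia"],
    "DZ": ["Gcsam", "Ccnb2", "Hmces", "Pafah1b3", "Stmn1"],
    "LZtoDZ": ["C1qbp", "Pa2g4", "Apex1", "Nop58", "Exosc7"],
    "preMem": ["Serpinb1a", "Capg", "Ms4a4c", "Gpr183", "Btg1"],
    "prePC": ["Sub1", "Pdia4", "Emb", "Glo1", "Polr2h"],
    "PC": ["Sdc1", "Fam46c", "Irf4", "Bst2", "Glipr1"],
}

S_PHASE_GENES = ["Mcm2", "Mcm5", "Pcna", "Tyms", "Rrm1"]
G2M_PHASE_GENES = ["Ccnb1", "Cdk1", "Ube2c", "Top2a", "Birc5"]

#: Default cell-cycle gene list (stand-in for a GO-derived list); note it
#: overlaps the DZ signature (Ccnb2, Stmn1), which is exactly why LZ/DZ
#: signatures are cycle-filtered before gating.
DEFAULT_CC_GENES = S_PHASE_GENES + G2M_PHASE_GENES + ["Ccnb2", "Stmn1"]

G1_LABEL = "G1/quiescent"


@dataclass
class Signature:
    name: str
    genes: list[str]
    cc_filtered: bool = False

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name}: duplicate genes")


@dataclass
class GatingConfig:
    """Empirical gate thresholds and their evaluation order.

    The default thresholds are 0 for every gate — the natural
    signal-above-control boundary of module scores; they are meant to be
    tuned per dataset.
    """

    thresholds: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in SUBSETS}
    )
    order: tuple[str, ...] = ("PC", "prePC", "preMem", "LZtoDZ")

    def __post_init__(self) -> None:
        missing = [s for s in SUBSETS if s not in self.thresholds]
        if missing:
            raise ValueError(f"thresholds missing for {missing}")
        for name, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ValueError(f"non-finite threshold for {name}")


def module_score(
    norm_matrix: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Signature score per cell: mean(signature) − mean(bin-matched controls).

    All genes are ranked by mean normalized expression across cells and cut
    into ``n_bins`` equal-size bins; for each signature gene, ``n_ctrl``
    control genes are drawn (seeded) from its bin, excluding signature
    genes.  If a bin holds fewer candidates than ``n_ctrl`` the draw is
    with replacement (with a warning).

    Parameters
    ----------
    norm_matrix : DataFrame, genes × cells, log-normalized expression.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sig = [g for g in gene_set if g in norm_matrix.index]
    if not sig:
        raise ValueError("no signature gene found in the expression matrix")
    rng = np.random.default_rng(seed)

    means = norm_matrix.mean(axis=1)
    # deterministic order: by mean then name, so ties cannot reshuffle bins
    order = means.to_frame("mean").assign(name=means.index)
    ordered = order.sort_values(["mean", "name"]).index.to_numpy()
    bins = np.array_split(ordered, n_bins)
    bin_of = {g: i for i, b in enumerate(bins) for g in b}

    sig_set = set(sig)
    ctrl: list[str] = []
    for g in sig:
        pool = [x for x in bins[bin_of[g]] if x not in sig_set]
        if not pool:
            raise ValueError(f"no control candidates in the bin of gene {g!r}")
        if len(pool) < n_ctrl:
            warnings.warn(
                f"bin of {g!r} has {len(pool)} control candidates < "
                f"n_ctrl={n_ctrl}; sampling with replacement",
                stacklevel=2,
            )
            ctrl.extend(rng.choice(pool, size=n_ctrl, replace=True))
        else:
            ctrl.extend(rng.choice(pool, size=n_ctrl, replace=False))

    score = norm_matrix.loc[sig].mean(axis=0) - norm_matrix.loc[ctrl].mean(axis=0)
    score.name = "module_score"
    return score


def remove_cc_genes(
    gene_set: list[str], cc_gene_list: list[str]
) -> tuple[list[str], list[str]]:
    """Drop cell-cycle genes from a signature; returns (kept, removed)."""
    cc = set(cc_gene_list)
    kept = [g for g in gene_set if g not in cc]
    removed = [g for g in gene_set if g in cc]
    return kept, removed


def score_signatures(
    norm_matrix: pd.DataFrame,
    signatures: dict[str, list[str]] | None = None,
    cc_genes: list[str] | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score all subset signatures (cells × subsets), cycle-filtering LZ/DZ."""
    signatures = dict(DEFAULT_SIGNATURES if signatures is None else signatures)
    cc_genes = DEFAULT_CC_GENES if cc_genes is None else cc_genes
    scores = {}
    for name, genes in signatures.items():
        if name in ("LZ", "DZ"):
            genes, _removed = remove_cc_genes(genes, cc_genes)
            if not genes:
                raise ValueError(
                    f"{name} signature empty after cell-cycle filtering"
                )
        scores[name] = module_score(
            norm_matrix, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
        )
    return pd.DataFrame(scores)


def gate_subsets(scores: pd.DataFrame, config: GatingConfig | None = None) -> pd.Series:
    """Assign one GC-subset label per cell by sequential threshold gates.

    PC → prePC → preMem are gated on their own scores; LZtoDZ requires both
    the LZ and DZ scores above their thresholds; remaining cells fall to
    whichever of LZ/DZ scores higher, with exact ties left "unassigned".
    """
    config = config or GatingConfig()
    needed = set(SUBSETS)
    missing = needed - set(scores.columns)
    if missing:
        raise ValueError(f"missing score columns: {sorted(missing)}")
    t = config.thresholds
    labels = pd.Series("unassigned", index=scores.index, dtype=object)
    unset = pd.Series(True, index=scores.index)
    for gate in config.order:
        if gate == "LZtoDZ":
            hit = (scores["LZ"] > t["LZ"]) & (scores["DZ"] > t["DZ"])
        else:
            hit = scores[gate] > t[gate]
        labels[unset & hit] = gate
        unset &= ~hit
    lz, dz = scores.loc[unset, "LZ"], scores.loc[unset, "DZ"]
    labels[unset & (lz > dz).reindex(labels.index, fill_value=False)] = "LZ"
    labels[unset & (dz > lz).reindex(labels.index, fill_value=False)] = "DZ"
    labels.name = "subset"
    return labels


def cell_cycle_phase(
    norm_matrix: pd.DataFrame,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Infer cell-cycle phase per cell from S and G2M module scores.

    Phase is the argmax of the two scores when either is positive,
    otherwise "G1/quiescent".  Returns a DataFrame with columns
    ``S_score``, ``G2M_score``, ``phase``.
    """
    s_genes = S_PHASE_GENES if s_genes is None else s_genes
    g2m_genes = G2M_PHASE_GENES if g2m_genes is None else g2m_genes
    s = module_score(norm_matrix, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g2m = module_score(
        norm_matrix, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    )
    phase = pd.Series(G1_LABEL, index=s.index, dtype=object)
    phase[(s > 0) & (s >= g2m)] = "S"
    phase[(g2m > 0) & (g2m > s)] = "G2M"
    return pd.DataFrame({"S_score": s, "G2M_score": g2m, "phase": phase})
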