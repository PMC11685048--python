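"""Integrated per-cell table and the study-level statistics.

Covers: building the per-cell union of expression, subset, cell-cycle, BCR,
index-sort and ELISA metadata; Kruskal–Wallis with Dunn's post hoc
(tie-corrected, Bonferroni-adjusted by default); the semi-log least-squares
fit of surface antigen binding against the log10 ELISA binding threshold
with explicit censoring policies; clonotype summaries and selection; and
the FACS-vs-ELISA outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def build_integrated_table(
    cell_metadata: pd.DataFrame, *sources: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Left-join any number of per-cell sources onto cell metadata.

    All inputs must be indexed (or indexable) by a unique ``cell_id``.
    Returns the joined table and a per-source matched/unmatched report.
    """

    def keyed(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if df.index.name != "cell_id":
            if "cell_id" not in df.columns:
                raise ValueError(f"source {name}: no cell_id key")
            df = df.set_index("cell_id")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"source {name}: duplicate cell_id {dup!r}")
        return df

    table = keyed(cell_metadata, "cell_metadata")
    report = {}
    for k, src in enumerate(sources):
        name = getattr(src, "name", None) or f"source_{k + 1}"
        src = keyed(src, name)
        matched = int(src.index.isin(table.index).sum())
        report[name] = {
            "matched": matched,
            "unmatched": int(len(src) - matched),
        }
        table = table.join(src, how="left")
    return table, report


def kruskal_dunn(
    groups: dict[str, list | np.ndarray], adjustment: str = "bonferroni"
) -> dict:
    """Kruskal–Wallis omnibus test with Dunn's pairwise post hoc.

    Dunn's z compares mean ranks of the pooled sample with the tie
    correction Σ(t³−t)/(12(N−1)); pairwise p-values are two-sided normal
    and adjusted over all pairs (``bonferroni`` — the classical procedure —
    ``holm`` or ``none``).  Pairwise results are only meaningful alongside
    the omnibus p, which is always reported with them.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 observations")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # degenerate case: no rank information at all
        pairwise = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "z": 0.0, "p_raw": 1.0, "p_adjusted": 1.0}
                for a, b in combinations(names, 2)
            ]
        )
        return {"H": 0.0, "p": 1.0, "pairwise": pairwise, "adjustment": adjustment}
    H, p = sps.kruskal(*arrays)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = ranks[start : start + len(arr)].mean()
        sizes[name] = len(arr)
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (N - 1)))

    pairs = list(combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(
            (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw.append((a, b, z, 2 * sps.norm.sf(abs(z))))

    m = len(pairs)
    if adjustment == "bonferroni":
        adjusted = [min(1.0, pr * m) for *_, pr in raw]
    elif adjustment == "holm":
        order = np.argsort([pr for *_, pr in raw])
        adjusted = [np.nan] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx][3])
            adjusted[idx] = min(1.0, running)
    elif adjustment == "none":
        adjusted = [pr for *_, pr in raw]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    pairwise = pd.DataFrame(
        [
            {"group_a": a, "group_b": b, "z": z, "p_raw": pr, "p_adjusted": pa}
            for (a, b, z, pr), pa in zip(raw, adjusted)
        ]
    )
    return {"H": float(H), "p": float(p), "pairwise": pairwise, "adjustment": adjustment}


def semilog_fit(
    x: np.ndarray,
    y: np.ndarray,
    censored: np.ndarray | None = None,
    censor_policy: str = "cap",
) -> dict:
    """Least-squares fit of y = a + b·log10(x) with censored-x handling.

    ``censored`` marks x values that are detection bounds rather than
    measurements (e.g. ">1000").  Policy ``cap`` keeps them at the bound;
    ``exclude`` drops those points.  Reports slope b, intercept a, R²
    (= squared Pearson correlation of y with log10 x), and n used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    censored = (
        np.zeros(len(x), dtype=bool) if censored is None else np.asarray(censored, bool)
    )
    if censor_policy == "cap":
        keep = np.ones(len(x), dtype=bool)
    elif censor_policy == "exclude":
        keep = ~censored
    else:
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    keep &= np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 usable points after censor policy")
    if np.any(x <= 0):
        raise ValueError("all x must be > 0")
    if np.ptp(y) == 0:
        raise ValueError("zero variance in y: R^2 undefined")
    lx = np.log10(x)
    slope, intercept = np.polyfit(lx, y, 1)
    resid = y - (intercept + slope * lx)
    r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r2),
        "n": int(len(x)),
        "censor_policy": censor_policy,
    }


@dataclass
class ClonotypeSummary:
    clonotype_id: str
    size: int
    mean_binding: float  # mean asinh OVA binding over members with values
    n_above_background: int
    samples: tuple


def summarize_clonotypes(
    table: pd.DataFrame,
    binding_col: str = "asinh_OVA-AF647",
    background: float = 1.0,
) -> pd.DataFrame:
    """Per-clonotype size, mean binding and above-background member count."""
    if "clonotype_id" not in table.columns:
        raise ValueError("table lacks clonotype_id")
    rows = []
    for cid, grp in table.dropna(subset=["clonotype_id"]).groupby("clonotype_id"):
        vals = grp[binding_col].dropna()
        rows.append(
            {
                "clonotype_id": cid,
                "size": len(grp),
                "mean_binding": float(vals.mean()) if len(vals) else np.nan,
                "n_above_background": int((vals > background).sum()),
                "samples": ",".join(sorted(grp["sample"].dropna().unique()))
                if "sample" in grp
                else "",
            }
        )
    return pd.DataFrame(rows).sort_values("clonotype_id").reset_index(drop=True)


def select_clonotypes(
    summary: pd.DataFrame,
    min_size: int = 5,
    min_above_background: int = 1,
    k: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Clonotypes with size ≥ min_size and enough members above background;
    optionally a seeded random subsample of k candidates."""
    hits = summary[
        (summary["size"] >= min_size)
        & (summary["n_above_background"] >= min_above_background)
    ]["clonotype_id"].tolist()
    if k is not None and k < len(hits):
        rng = np.random.default_rng(seed)
        hits = sorted(str(c) for c in rng.choice(hits, size=k, replace=False))
    return sorted(hits)


def detect_outliers(
    table: pd.DataFrame,
    binding_cutoff: float = 1.0,
    range_ng: tuple[float, float] = (10.0, 100.0),
    binding_col: str = "asinh_OVA-AF647",
    threshold_col: str = "threshold_ng",
    censored_col: str = "censored",
) -> pd.DataFrame:
    """Cells whose surface binding is below background yet whose mAb has an
    uncensored ELISA threshold strictly inside ``range_ng``.

    These are cells the FACS assay misses but the ELISA detects.
    """
    lo, hi = range_ng
    usable = table.dropna(subset=[binding_col, threshold_col])
    if censored_col in usable.columns:
        usable = usable[~usable[censored_col].astype(bool)]
    mask = (
        (usable[binding_col] < binding_cutoff)
        & (usable[threshold_col] > lo)
        & (usable[threshold_col] < hi)
    )
    return usable[mask]
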