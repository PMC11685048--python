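"""ELISA dilution series and the binding-threshold statistic.

Each monoclonal antibody (mAb) is assayed as a 4-fold serial dilution
(default: starting at 1 µg = 1000 ng per well) in replicate wells.  The
ELISA Binding Threshold is the minimum amount of antibody (ng) at which the
mean optical density (OD) reaches a detection threshold; it is refined by
log-linear interpolation between bracketing dilution points and censored as
">max" when even the largest amount stays below threshold (or "<min" when
already the smallest amount is above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"


@dataclass
class ElisaSeries:
    """One mAb's dilution curve: amounts (ng, strictly decreasing geometric
    series) and replicate OD readings per amount."""

    mab_id: str
    amounts: np.ndarray
    od_replicates: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amounts = np.asarray(self.amounts, dtype=float)
        if len(self.amounts) < 2:
            raise ValueError("need at least 2 dilution points")
        if not np.all(np.diff(self.amounts) < 0):
            raise ValueError("amounts must be strictly decreasing")
        ratios = self.amounts[:-1] / self.amounts[1:]
        # tolerance accommodates values round-tripped at 6 significant digits
        if not np.allclose(ratios, ratios[0], rtol=1e-3):
            raise ValueError("dilution factor must be constant")
        if len(self.od_replicates) != len(self.amounts):
            raise ValueError("one OD replicate list per amount required")
        for ods in self.od_replicates:
            if len(ods) < 1:
                raise ValueError("each amount needs >= 1 OD reading")
            if any(od < 0 for od in ods):
                raise ValueError("OD readings must be >= 0")

    @property
    def mean_od(self) -> np.ndarray:
        return np.array([float(np.mean(o)) for o in self.od_replicates])


@dataclass
class ElisaThresholdResult:
    """Binding threshold in ng, or a censoring bound.

    Exactly one of ``threshold_ng`` / ``censored_above`` /
    ``censored_below`` is set; ``display`` renders censored results as
    ">X" / "<X" strings.
    """

    mab_id: str
    od_threshold_used: float
    threshold_ng: float | None = None
    censored_above: float | None = None
    censored_below: float | None = None

    def __post_init__(self) -> None:
        n_set = sum(
            v is not None
            for v in (self.threshold_ng, self.censored_above, self.censored_below)
        )
        if n_set != 1:
            raise ValueError("exactly one of threshold/censored fields must be set")

    @property
    def censored(self) -> bool:
        return self.threshold_ng is None

    @property
    def display(self) -> str:
        if self.censored_above is not None:
            return f">{self.censored_above:g}"
        if self.censored_below is not None:
            return f"<{self.censored_below:g}"
        return f"{self.threshold_ng:g}"

    @property
    def numeric(self) -> float:
        """Numeric stand-in: censored results map to their bound."""
        if self.censored_above is not None:
            return self.censored_above
        if self.censored_below is not None:
            return self.censored_below
        return float(self.threshold_ng)


def make_dilution_series(
    start_ng: float = 1000.0, factor: float = 4.0, n_points: int = 6
) -> np.ndarray:
    """amounts[k] = start_ng / factor**k, k = 0..n_points-1."""
    if start_ng <= 0:
        raise ValueError("start_ng must be > 0")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return start_ng / factor ** np.arange(n_points, dtype=float)


def od_threshold_from_controls(
    negative_control_ods, override: float | None = None
) -> float:
    """Detection threshold OD: mean + 3·sd of the no-primary-antibody
    negative controls, or a fixed override."""
    if override is not None:
        return float(override)
    ods = np.asarray(list(negative_control_ods), dtype=float)
    if len(ods) < 2:
        raise ValueError("need >= 2 negative-control readings")
    return float(ods.mean() + 3 * ods.std(ddof=1))


def binding_threshold(series: ElisaSeries, od_threshold: float) -> ElisaThresholdResult:
    """ELISA Binding Threshold of one dilution series.

    Mean ODs are scanned from the smallest to the largest amount; the
    threshold is the smallest amount whose mean OD reaches ``od_threshold``,
    refined by interpolation in (log10 amount, log10 mean OD) between the
    bracketing points when the crossing falls between grid points.
    """
    if od_threshold <= 0:
        raise ValueError("od_threshold must be > 0")
    amounts = series.amounts[::-1]  # increasing
    ods = series.mean_od[::-1]
    above = ods >= od_threshold
    if not above.any():
        return ElisaThresholdResult(
            series.mab_id, od_threshold, censored_above=float(amounts[-1])
        )
    first = int(np.argmax(above))
    if (~above[first:]).any():
        warnings.warn(
            f"{series.mab_id}: non-monotone curve with multiple crossings; "
            "using the crossing at the lowest amount",
            stacklevel=2,
        )
    if first == 0:
        return ElisaThresholdResult(
            series.mab_id, od_threshold, censored_below=float(amounts[0])
        )
    if ods[first] == od_threshold:
        return ElisaThresholdResult(
            series.mab_id, od_threshold, threshold_ng=float(amounts[first])
        )
    lo, hi = first - 1, first
    # interpolate in (log10 amount, log10 OD): below saturation the OD of a
    # binding curve is proportional to amount, so the crossing is recovered
    # essentially exactly; fall back to linear OD when the lower OD is 0
    if ods[lo] > 0:
        frac = (np.log10(od_threshold) - np.log10(ods[lo])) / (
            np.log10(ods[hi]) - np.log10(ods[lo])
        )
    else:
        frac = (od_threshold - ods[lo]) / (ods[hi] - ods[lo])
    log_a = np.log10(amounts[lo]) + frac * (np.log10(amounts[hi]) - np.log10(amounts[lo]))
    return ElisaThresholdResult(
        series.mab_id, od_threshold, threshold_ng=float(10 ** log_a)
    )


def series_from_table(plate: pd.DataFrame) -> list[ElisaSeries]:
    """Build per-mAb dilution series from a long plate table.

    Expected columns: mab_id, amount_ng, replicate, od.  Control rows
    (mab_id == "negative_control"/"positive_control") are skipped here; use
    :func:`negative_controls` for the threshold rule.
    """
    for col in ("mab_id", "amount_ng", "od"):
        if col not in plate.columns:
            raise ValueError(f"plate table missing column {col!r}")
    out = []
    mabs = plate[~plate["mab_id"].isin([NEGATIVE_CONTROL, POSITIVE_CONTROL])]
    for mab_id, grp in mabs.groupby("mab_id", sort=True):
        amounts = np.sort(grp["amount_ng"].unique())[::-1]
        reps = [
            list(grp.loc[grp["amount_ng"] == a, "od"].astype(float)) for a in amounts
        ]
        out.append(ElisaSeries(str(mab_id), amounts, reps))
    return out


def negative_controls(plate: pd.DataFrame) -> list[float]:
    ods = plate.loc[plate["mab_id"] == NEGATIVE_CONTROL, "od"]
    return list(ods.astype(float))


_THRESHOLD_COLUMNS = [
    "mab_id", "elisa_threshold", "threshold_ng", "censored", "od_threshold_used"
]


def threshold_table(
    plate: pd.DataFrame, od_threshold: float | None = None
) -> pd.DataFrame:
    """Binding thresholds for every mAb on a plate.

    ``od_threshold`` defaults to mean+3sd of the plate's negative controls.
    Censored values are serialized both as display strings (">1000") and as
    (numeric bound, flag) pairs.
    """
    if od_threshold is None:
        od_threshold = od_threshold_from_controls(negative_controls(plate))
    rows = []
    for series in series_from_table(plate):
        res = binding_threshold(series, od_threshold)
        rows.append(
            {
                "mab_id": res.mab_id,
                "elisa_threshold": res.display,
                "threshold_ng": res.numeric,
                "censored": res.censored,
                "od_threshold_used": res.od_threshold_used,
            }
        )
    return pd.DataFrame(rows, columns=_THRESHOLD_COLUMNS)
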