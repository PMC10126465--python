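"""Viable-titer reconstruction and log-linear inactivation fits.

The wet-heat killing assay serially dilutes treated spores 10-fold and
spots 10 uL aliquots in duplicate on plates; colonies are counted after
incubation.  This module turns those spot counts back into CFU/mL
titers (choosing a countable dilution), expresses survival as log10
reductions, and fits the first-order model
``log10 N(t) = log10 N0 - t / D`` to obtain the decimal reduction time
D and rate constant ``k = ln(10) / D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpotCountRecord",
    "TiterEstimate",
    "SurvivalSeries",
    "titer_from_spots",
    "fit_decay",
    "analyze_survival",
]

COUNTABLE_WINDOW = (3.0, 30.0)  # mean colonies per 10 uL spot


@dataclass(frozen=True)
class SpotCountRecord:
    """Replicate colony counts for one (time, dilution) cell."""

    time: float  # minutes
    dilution_exponent: int  # 10-fold steps, >= 0
    counts: tuple[int, ...]  # replicate colony counts (duplicates on the bench)
    spot_volume: float = 0.01  # mL (10 uL)

    def __post_init__(self) -> None:
        if self.dilution_exponent < 0:
            raise ValueError("dilution_exponent must be >= 0")
        if len(self.counts) < 1 or any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0 with at least one replicate")

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))


@dataclass
class TiterEstimate:
    titer: float  # CFU/mL
    dilution_used: int
    flagged: bool = False  # no dilution inside the countable window
    below_detection: bool = False


@dataclass
class SurvivalSeries:
    """Per-timepoint titers and the fitted log-linear inactivation."""

    times: np.ndarray
    titers: np.ndarray
    below_detection: np.ndarray
    log10_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    slope: float = float("nan")  # log10 CFU/mL per minute
    intercept: float = float("nan")
    d_value: float = float("nan")  # minutes per 10-fold reduction
    k: float = float("nan")  # ln(10)/D per minute
    no_killing: bool = False


def titer_from_spots(
    records: list[SpotCountRecord],
    countable_window: tuple[float, float] = COUNTABLE_WINDOW,
) -> TiterEstimate:
    """Reconstruct the viable titer from one timepoint's dilution series.

    Replicates are averaged per dilution; the largest dilution whose
    mean count lies in the countable window is used
    (``titer = mean * 10**dilution / spot_volume``).  If no dilution
    qualifies, the dilution with mean closest to the window is used and
    the estimate flagged.  All-zero counts everywhere report the
    detection limit (one colony at the least-diluted spot), flagged.
    """
    if not records:
        raise ValueError("need at least one record")
    lo, hi = countable_window
    by_dil = {}
    for r in records:
        if r.dilution_exponent in by_dil:
            raise ValueError(f"duplicate dilution {r.dilution_exponent}")
        by_dil[r.dilution_exponent] = r

    if all(r.mean_count == 0 for r in by_dil.values()):
        d_min = min(by_dil)
        r = by_dil[d_min]
        limit = 1.0 * 10.0**d_min / r.spot_volume
        return TiterEstimate(titer=limit, dilution_used=d_min, flagged=True, below_detection=True)

    qualifying = [d for d, r in by_dil.items() if lo <= r.mean_count <= hi]
    if qualifying:
        d = max(qualifying)
        flagged = False
    else:
        def dist(d: int) -> float:
            m = by_dil[d].mean_count
            return 0.0 if lo <= m <= hi else min(abs(m - lo), abs(m - hi))

        d = min(by_dil, key=lambda dd: (dist(dd), dd))
        flagged = True
    r = by_dil[d]
    return TiterEstimate(
        titer=r.mean_count * 10.0**d / r.spot_volume, dilution_used=d, flagged=flagged
    )


def fit_decay(
    times: np.ndarray,
    titers: np.ndarray,
    below_detection: np.ndarray | None = None,
) -> SurvivalSeries:
    """Least-squares line through log10(titer) vs time.

    Below-detection points are excluded from the fit.  A non-negative
    slope means no measurable killing: D is reported infinite and the
    series flagged rather than producing a negative D.
    """
    times = np.asarray(times, dtype=float)
    titers = np.asarray(titers, dtype=float)
    if below_detection is None:
        below_detection = np.zeros(times.shape, dtype=bool)
    below_detection = np.asarray(below_detection, dtype=bool)
    use = (~below_detection) & (titers > 0)
    if use.sum() < 3:
        raise ValueError("need >= 3 timepoints with positive titers above detection")
    logt = np.log10(titers[use])
    res = stats.linregress(times[use], logt)
    slope, intercept = float(res.slope), float(res.intercept)

    log10_fraction = np.log10(titers / titers[0])
    series = SurvivalSeries(
        times=times,
        titers=titers,
        below_detection=below_detection,
        log10_fraction=log10_fraction,
        slope=slope,
        intercept=intercept,
    )
    if slope >= 0:
        series.d_value = float("inf")
        series.k = 0.0
        series.no_killing = True
    else:
        series.d_value = -1.0 / slope
        series.k = float(np.log(10.0) / series.d_value)
    return series


def records_from_frame(df: pd.DataFrame) -> dict[float, list[SpotCountRecord]]:
    """Group a long-format count table by timepoint.

    Expected columns: time_min, dilution_exponent, spot_volume_ml and
    count_rep1, count_rep2, ...
    """
    rep_cols = sorted(c for c in df.columns if c.startswith("count_rep"))
    if not rep_cols:
        raise ValueError("no count_rep* columns found")
    out: dict[float, list[SpotCountRecord]] = {}
    for _, row in df.iterrows():
        rec = SpotCountRecord(
            time=float(row["time_min"]),
            dilution_exponent=int(row["dilution_exponent"]),
            counts=tuple(int(row[c]) for c in rep_cols if pd.notna(row[c])),
            spot_volume=float(row.get("spot_volume_ml", 0.01)),
        )
        out.setdefault(rec.time, []).append(rec)
    return out


def analyze_survival(
    df: pd.DataFrame, countable_window: tuple[float, float] = COUNTABLE_WINDOW
) -> SurvivalSeries:
    """Full pipeline: count table -> per-time titers -> decay fit."""
    grouped = records_from_frame(df)
    times = np.array(sorted(grouped))
    estimates = [titer_from_spots(grouped[t], countable_window) for t in times]
    titers = np.array([e.titer for e in estimates])
    below = np.array([e.below_detection for e in estimates])
    return fit_decay(times, titers, below)
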