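"""Pointwise pattern-deviation statistics with FDR correction.

Median splits on blind-spot distance/angle with per-location two-sample
t-tests, Benjamini-Hochberg adjustment over the 52 analysis locations,
average-difference-for-significant-points (ADSP) summaries, per-location
multiple regression against fixation loss, and the blind-spot-distance /
refraction correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .vf_core import (
    DEFAULT_NBSL,
    VFLocation,
    VFRecord,
    location_grid_24_2,
    nbsl_angle,
    nbsl_distance,
)


FDR_LEVEL = 0.05


@dataclass
class LocationStatMap:
    """Per-location effect, p, BH-adjusted q, and significance flag."""

    locations: tuple[VFLocation, ...]
    effect: np.ndarray  # dB
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray  # bool, q < alpha
    alpha: float = FDR_LEVEL

    def __post_init__(self) -> None:
        n = len(self.locations)
        if not (len(self.effect) == len(self.p) == len(self.q) == n):
            raise ValueError("field lengths disagree")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h_deg": [p.h_deg for p in self.locations],
                "v_deg": [p.v_deg for p in self.locations],
                "effect_db": self.effect,
                "p": self.p,
                "q": self.q,
                "significant": self.significant.astype(int),
            }
        )


@dataclass
class SplitResult:
    split_variable: Literal["distance", "angle"]
    median_value: float
    group_high: list[VFRecord]  # value >= median
    group_low: list[VFRecord]  # value < median

    @property
    def degenerate(self) -> bool:
        return not self.group_low or not self.group_high


def _transform(rec: VFRecord, variable: str) -> float:
    if variable == "distance":
        return nbsl_distance(rec.nbsl)
    if variable == "angle":
        return nbsl_angle(rec.nbsl)
    raise ValueError(f"unknown split variable {variable!r}")


def median_split(
    records: Sequence[VFRecord], variable: Literal["distance", "angle"]
) -> SplitResult:
    """Split records at the median of blind-spot distance or signed angle.

    The high group takes values greater than *or equal to* the median.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    values = np.array([_transform(r, variable) for r in records])
    med = float(np.median(values))
    high = [r for r, x in zip(records, values) if x >= med]
    low = [r for r, x in zip(records, values) if x < med]
    return SplitResult(variable, med, high, low)


def _pd_matrix(records: Sequence[VFRecord]) -> tuple[np.ndarray, tuple[VFLocation, ...]]:
    locs = location_grid_24_2().analysis_locations
    return np.array([[r.pd_values[p] for p in locs] for r in records]), locs


def _bh_adjust(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def difference_map(
    split: SplitResult,
    *,
    test: Literal["welch", "student"] = "welch",
    alpha: float = FDR_LEVEL,
) -> LocationStatMap:
    """Mean PD difference (high minus low group) per location, with t-tests.

    p-values come from a two-sample t-test at each location (Welch by
    default); q-values adjust the 52 p-values by Benjamini-Hochberg.
    """
    if len(split.group_high) < 2 or len(split.group_low) < 2:
        raise ValueError("both groups need at least 2 records")
    hi, locs = _pd_matrix(split.group_high)
    lo, _ = _pd_matrix(split.group_low)
    effect = hi.mean(axis=0) - lo.mean(axis=0)
    _, p = stats.ttest_ind(hi, lo, axis=0, equal_var=(test == "student"))
    q, reject = _bh_adjust(p, alpha)
    return LocationStatMap(locs, effect, p, q, reject, alpha)


def adsp(stat_map: LocationStatMap, sign: Literal["positive", "negative"]) -> float | None:
    """Average difference over significant points of the requested sign.

    Returns ``None`` when no significant location has that sign.
    """
    mask = stat_map.significant & (
        stat_map.effect > 0 if sign == "positive" else stat_map.effect < 0
    )
    if not mask.any():
        return None
    return float(stat_map.effect[mask].mean())


def regression_map(
    records: Sequence[VFRecord],
    predictor: Literal["distance", "angle"],
    *,
    alpha: float = FDR_LEVEL,
) -> tuple[LocationStatMap, LocationStatMap]:
    """Per-location OLS of PD on the blind-spot predictor and fixation loss.

    PD ~ 1 + predictor + fixation_loss_rate at each of the 52 locations.
    Coefficient p-values for each regressor family are BH-adjusted
    separately across locations.  Returns (predictor map, fixation-loss
    map) whose ``effect`` fields hold the regression coefficients.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for the regression")
    x1 = np.array([_transform(r, predictor) for r in records])
    x2 = np.array([r.fixation_loss_rate for r in records])
    if np.std(x1) == 0 or np.std(x2) == 0 or abs(np.corrcoef(x1, x2)[0, 1]) > 0.9999:
        raise ValueError("predictor and fixation_loss_rate are collinear")
    Y, locs = _pd_matrix(records)
    X = np.column_stack([np.ones_like(x1), x1, x2])
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (3, 52)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # (3, 52)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    maps = []
    for row in (1, 2):
        q, reject = _bh_adjust(pvals[row], alpha)
        maps.append(LocationStatMap(locs, beta[row], pvals[row], q, reject, alpha))
    return maps[0], maps[1]


def se_correlation(records: Sequence[VFRecord]) -> tuple[float, float]:
    """Pearson correlation of blind-spot distance with spherical equivalent."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    d = np.array([nbsl_distance(r.nbsl) for r in records])
    se = np.array([r.se_diopters for r in records])
    if np.std(d) == 0 or np.std(se) == 0:
        raise ValueError("zero variance in distance or spherical equivalent")
    r, p = stats.pearsonr(d, se)
    return float(r), float(p)


def cell_average_map(
    records: Iterable[VFRecord], field: str = "se_diopters"
) -> dict[tuple[int, int], float]:
    """Mean of a per-record field over eyes at each blind-spot cell.

    Cells with no eyes are absent; the default cell (15, -1) is always
    absent because records there are indistinguishable from failed tests.
    """
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for rec in records:
        cell = (rec.nbsl.h_deg, rec.nbsl.v_deg)
        if cell == DEFAULT_NBSL:
            continue
        sums[cell] = sums.get(cell, 0.0) + getattr(rec, field)
        counts[cell] = counts.get(cell, 0) + 1
    return {cell: sums[cell] / counts[cell] for cell in sums}
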