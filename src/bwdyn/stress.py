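"""Recovery from disruptions of steady-state homeostasis.

Phenotyping assays (handling, housing changes, running wheels) knock mice out
of the steady state; the steady-state posterior probability then climbs back
toward 1. A recovery region opens where that probability drops below 0.05 and
closes where it stops monotonically increasing, or crosses 0.95 while still
increasing. For each sufficiently long region (>= ``min_days`` spanned, >= 3
points) the rate of return lambda (1/day) is estimated by least-squares fitting
of the exponential CDF 1 - exp(-lambda * x), x in days from the region start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

LOW_THRESHOLD = 0.05
HIGH_THRESHOLD = 0.95
MIN_DAYS = 30.0
MIN_POINTS = 3
LAMBDA_BOUNDS = (1e-6, 10.0)  # per day
#: Default mid-life/late-life attribution bins (days): (6-18) and (18-30) months.
DEFAULT_AGE_BINS = ((180.0, 540.0), (540.0, 900.0))


@dataclass
class RecoveryRegion:
    animal_id: str
    start_day: float
    end_day: float
    days: np.ndarray          # grid days of the region's points
    steady_probs: np.ndarray  # steady posterior over the region
    lambda_hat: float | None = None
    fit_rss: float | None = None
    assay: str | None = None
    age_bin: str | None = None

    @property
    def n_points(self) -> int:
        return int(self.days.size)


def find_recovery_regions(
    steady_probs: np.ndarray,
    grid_times: np.ndarray,
    animal_id: str = "",
    min_days: float = MIN_DAYS,
    min_points: int = MIN_POINTS,
) -> list[RecoveryRegion]:
    """Scan a steady-posterior series for recovery regions.

    A region opens at the first index with p < 0.05 and tracks the subsequent
    monotone-increasing stretch; it closes at the first index where the
    increase breaks (strictly, any non-increase) or where p exceeds 0.95 while
    increasing. Regions spanning fewer than ``min_days`` days or ``min_points``
    points are discarded. Regions are disjoint by construction.
    """
    p = np.asarray(steady_probs, dtype=float)
    t = np.asarray(grid_times, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("steady probabilities must lie in [0, 1]")
    regions = []
    i, n = 0, p.size
    while i < n:
        if p[i] >= LOW_THRESHOLD:
            i += 1
            continue
        start = i
        j = i
        increasing = False
        while j + 1 < n:
            if p[j + 1] > p[j]:
                increasing = True
                j += 1
                if p[j] > HIGH_THRESHOLD:
                    break
            elif increasing:
                break  # monotone increase stopped
            else:
                j += 1  # still descending toward the trough
        end = j
        if end > start:
            span = t[end] - t[start]
            npts = end - start + 1
            if span >= min_days and npts >= min_points:
                regions.append(RecoveryRegion(
                    animal_id=animal_id,
                    start_day=float(t[start]),
                    end_day=float(t[end]),
                    days=t[start:end + 1].copy(),
                    steady_probs=p[start:end + 1].copy(),
                ))
            else:
                logger.debug("%s: region %s-%s discarded (span %.0f d, %d pts)",
                             animal_id, t[start], t[end], span, npts)
        i = end + 1
    return regions


def fit_recovery_rate(region: RecoveryRegion, xatol: float = 1e-12) -> RecoveryRegion:
    """Estimate lambda by bounded least squares against 1 - exp(-lambda x).

    x is measured in days from the region's first point. Degenerate (constant)
    series are flagged failed with lambda_hat left missing.
    """
    if region.n_points < MIN_POINTS:
        raise ValueError(f"{region.animal_id}: need >= {MIN_POINTS} points to fit lambda")
    x = region.days - region.days[0]
    p = region.steady_probs
    if np.allclose(p, p[0]):
        logger.warning("%s: degenerate recovery series, lambda fit failed", region.animal_id)
        region.lambda_hat = None
        region.fit_rss = None
        return region

    def rss(lam):
        return float(np.sum((p - (1.0 - np.exp(-lam * x))) ** 2))

    # RSS is nearly flat for large lambda (the CDF saturates), so bracket the
    # minimum on a log-spaced grid before the bounded refinement
    grid = np.geomspace(LAMBDA_BOUNDS[0], LAMBDA_BOUNDS[1], 120)
    vals = [rss(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    region.lambda_hat = float(res.x)
    region.fit_rss = float(res.fun)
    return region


def attribute_regions(
    regions: list[RecoveryRegion],
    event_schedule: pd.DataFrame | None,
    age_bins=DEFAULT_AGE_BINS,
    lookback_days: float = 30.0,
) -> list[RecoveryRegion]:
    """Attach an assay and an age bin to each region.

    Each region gets the most recent assay event at or before its start within
    ``lookback_days`` (else 'unattributed'); the age bin is looked up from the
    region's start day ((6-18) and (18-30) months by default, else 'other').
    ``event_schedule`` needs columns ``assay_name`` and ``age_days``.
    """
    for reg in regions:
        reg.assay = "unattributed"
        if event_schedule is not None and len(event_schedule):
            prior = event_schedule[
                (event_schedule["age_days"] <= reg.start_day)
                & (event_schedule["age_days"] >= reg.start_day - lookback_days)
            ]
            if len(prior):
                reg.assay = str(prior.loc[prior["age_days"].idxmax(), "assay_name"])
        reg.age_bin = "other"
        for lo, hi in age_bins:
            if lo <= reg.start_day < hi:
                reg.age_bin = f"{lo / 30:.0f}-{hi / 30:.0f}mo"
                break
    return regions


def regions_table(regions: list[RecoveryRegion]) -> pd.DataFrame:
    """Flatten fitted regions to the long-format output table."""
    return pd.DataFrame([
        {
            "animal_id": r.animal_id, "start_day": r.start_day, "end_day": r.end_day,
            "n_points": r.n_points, "lambda_hat": r.lambda_hat, "fit_rss": r.fit_rss,
            "assay": r.assay, "age_bin": r.age_bin,
        }
        for r in regions
    ])
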