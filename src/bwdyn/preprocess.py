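"""Gridding of longitudinal body-weight records.

Raw body weights are collected every 7-10 days over a mouse's lifespan. Downstream
state-space modelling requires a uniform sampling interval, so raw measurement times
are rounded to the nearest multiple of 10 days, collisions are averaged, and interior
gaps are filled by linear interpolation (flagged, never extrapolated). Animals with
fewer than ``min_measurements`` raw measurements are excluded before gridding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Dietary intervention groups: ad libitum, 1-day fast/week, 2-day fast/week,
#: 20% and 40% calorie restriction.
DIETS = ("AL", "1D", "2D", "20", "40")

GRID_STEP = 10  # days
DEFAULT_INTERVENTION_DAY = 180  # 6 months at 30 days/month


class TraceError(ValueError):
    """A trace violates a precondition (too few points, degenerate times)."""


@dataclass
class RawTrace:
    """One animal's raw, irregularly sampled weight series.

    ``death_day`` is the age at death in days, or ``None`` for a censored animal.
    ``event_days`` lists the ages (days) at which phenotyping assays were run.
    """

    animal_id: str
    times: np.ndarray
    weights: np.ndarray
    diet: str = "AL"
    cohort: str = "C1"
    death_day: float | None = None
    event_days: tuple = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.times.shape != self.weights.shape:
            raise TraceError(f"{self.animal_id}: times and weights differ in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise TraceError(f"{self.animal_id}: times must be strictly increasing")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise TraceError(f"{self.animal_id}: weights must be finite and positive")

    @property
    def n_measurements(self) -> int:
        return int(self.times.size)


@dataclass
class GriddedTrace:
    """One animal's weight series on a consecutive 10-day grid.

    ``interpolated_mask[i]`` is True where ``weights[i]`` was filled in rather than
    assigned from a raw measurement. Grid endpoints are always observed.
    """

    animal_id: str
    grid_times: np.ndarray
    weights: np.ndarray
    interpolated_mask: np.ndarray
    diet: str = "AL"
    cohort: str = "C1"
    intervention_day: float = DEFAULT_INTERVENTION_DAY
    death_day: float | None = None
    event_days: tuple = ()

    def __post_init__(self):
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if not (self.grid_times.shape == self.weights.shape == self.interpolated_mask.shape):
            raise TraceError(f"{self.animal_id}: gridded field lengths differ")
        if self.grid_times.size > 1 and np.any(np.diff(self.grid_times) != GRID_STEP):
            raise TraceError(f"{self.animal_id}: grid must be consecutive {GRID_STEP}-day steps")
        if np.any(~np.isfinite(self.weights)):
            raise TraceError(f"{self.animal_id}: missing values after interpolation")

    def __len__(self) -> int:
        return int(self.grid_times.size)


def round_to_grid(t: float, step: int = GRID_STEP) -> int:
    """Round an age in days to the nearest grid multiple, ties rounding half up."""
    return int(np.floor(t / step + 0.5)) * step


def grid_trace(raw: RawTrace, intervention_day: float = DEFAULT_INTERVENTION_DAY) -> GriddedTrace:
    """Snap a raw trace onto the uniform 10-day grid.

    Each raw time is assigned to its nearest multiple of 10 days (ties half-up);
    measurements colliding on a grid point are averaged; interior grid points with
    no assignment are linearly interpolated between the nearest flanking observed
    grid points and flagged in ``interpolated_mask``. The grid spans the first to
    last assigned point only - no extrapolation.
    """
    if raw.n_measurements < 2:
        raise TraceError(f"{raw.animal_id}: need at least 2 measurements to grid")

    snapped = np.array([round_to_grid(t) for t in raw.times])
    ties = raw.times % GRID_STEP == GRID_STEP / 2
    if np.any(ties):
        logger.info("%s: %d rounding ties resolved half-up", raw.animal_id, int(ties.sum()))

    occupied = np.unique(snapped)
    if occupied.size < 2:
        raise TraceError(f"{raw.animal_id}: all times identical after rounding")

    means = np.array([raw.weights[snapped == g].mean() for g in occupied])
    grid = np.arange(occupied[0], occupied[-1] + GRID_STEP, GRID_STEP, dtype=float)
    weights = np.interp(grid, occupied.astype(float), means)
    mask = ~np.isin(grid, occupied)
    return GriddedTrace(
        animal_id=raw.animal_id,
        grid_times=grid,
        weights=weights,
        interpolated_mask=mask,
        diet=raw.diet,
        cohort=raw.cohort,
        intervention_day=intervention_day,
        death_day=raw.death_day,
        event_days=tuple(raw.event_days),
    )


def filter_cohort(traces: list[RawTrace], min_measurements: int = 7) -> list[RawTrace]:
    """Drop animals with fewer than ``min_measurements`` raw measurements.

    The boundary is inclusive: an animal with exactly ``min_measurements`` is kept.
    Ordering is preserved and removals are logged.
    """
    kept, removed = [], []
    for tr in traces:
        (kept if tr.n_measurements >= min_measurements else removed).append(tr)
    if removed:
        logger.info(
            "excluded %d animals with < %d measurements: %s",
            len(removed), min_measurements, [t.animal_id for t in removed],
        )
    return kept


def split_phases(trace: GriddedTrace) -> tuple[GriddedTrace, GriddedTrace]:
    """Partition a gridded trace at the dietary-intervention boundary.

    The pre phase holds grid points with ``time < intervention_day``; the post
    phase holds ``time >= intervention_day``. Either side may be an empty slice
    (flagged by a warning), and concatenating the two reproduces the input.
    """
    cut = int(np.searchsorted(trace.grid_times, trace.intervention_day, side="left"))

    def _slice(sl: slice) -> GriddedTrace:
        return replace(
            trace,
            grid_times=trace.grid_times[sl],
            weights=trace.weights[sl],
            interpolated_mask=trace.interpolated_mask[sl],
        )

    pre, post = _slice(slice(0, cut)), _slice(slice(cut, None))
    if len(pre) == 0:
        logger.warning("%s: empty pre-intervention phase", trace.animal_id)
    if len(post) == 0:
        logger.warning("%s: empty post-intervention phase", trace.animal_id)
    return pre, post


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_traces(path, events_path=None, sep=",") -> list[RawTrace]:
    """Read raw traces from a tidy CSV/TSV.

    Expected columns: animal_id, age_days, weight_g, diet, cohort, death_day,
    censored. The optional events file has columns animal_id, assay_name, age_days.
    """
    df = pd.read_csv(path, sep=sep)
    events = None
    if events_path is not None:
        events = pd.read_csv(events_path, sep=sep)
    out = []
    for aid, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("age_days")
        death = None
        if "death_day" in grp and not bool(grp["censored"].iloc[0]):
            death = float(grp["death_day"].iloc[0])
        ev = ()
        if events is not None:
            ev = tuple(events.loc[events["animal_id"] == aid, "age_days"].astype(float))
        out.append(RawTrace(
            animal_id=str(aid),
            times=grp["age_days"].to_numpy(float),
            weights=grp["weight_g"].to_numpy(float),
            diet=str(grp["diet"].iloc[0]),
            cohort=str(grp["cohort"].iloc[0]),
            death_day=death,
            event_days=ev,
        ))
    return out


def write_gridded(traces: list[GriddedTrace], csv_path, meta_path=None) -> None:
    """Write gridded traces as tidy CSV plus an optional JSON metadata sidecar."""
    rows = [
        {"animal_id": tr.animal_id, "grid_day": int(t), "weight_g": w, "interpolated": bool(m)}
        for tr in traces
        for t, w, m in zip(tr.grid_times, tr.weights, tr.interpolated_mask)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            tr.animal_id: {
                "diet": tr.diet,
                "cohort": tr.cohort,
                "intervention_day": tr.intervention_day,
                "death_day": tr.death_day,
                "event_days": list(map(float, tr.event_days)),
            }
            for tr in traces
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)
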