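"""Per-animal trait catalog derived from decoded state posteriors.

Occupancies and transition frequencies are posterior-weighted (the smoothing
marginals gamma and pairwise marginals xi act as soft counts); bout lengths and
maximum rates of change are computed on the MAP state path. Traits are reported
per phase (pre-/post-intervention) and, for the homeostasis summaries, per age
bin (6-month calendar bins or deciles of the fraction of life lived).

Rates convert 10-day grid steps to grams/week (factor 7/10); the normalized
variants divide by the body weight measured at the step where the maximum rate
occurred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arhmm import ARHMMParams, PosteriorStates, decode, label_states
from .preprocess import GriddedTrace

logger = logging.getLogger(__name__)

STATES = ("growth", "steady", "decline")

WEEK_PER_STEP = 7.0 / 10.0  # grams per 10-day step -> grams per week
MONTH_DAYS = 30.0
MAX_AGE_DAYS = 1260.0  # 42 months


def _window_index(times: np.ndarray, window) -> np.ndarray:
    """Boolean index of time points inside the closed-open window [a, b)."""
    a, b = window
    return (times >= a) & (times < b)


def occupancy(posterior: PosteriorStates, window=None) -> np.ndarray:
    """Posterior-weighted fraction of time in each state over a window.

    occupancy[s] = mean of gamma[t, s] over grid points in the window; returns
    all-NaN if the window does not overlap the trace.
    """
    gamma = posterior.gamma
    if window is not None:
        sel = _window_index(posterior.times, window)
        gamma = gamma[sel]
    if gamma.shape[0] == 0:
        return np.full(posterior.gamma.shape[1], np.nan)
    return gamma.mean(axis=0)


def transition_frequencies(posterior: PosteriorStates, window=None) -> np.ndarray:
    """Posterior-weighted empirical transition matrix over a window.

    Entry (i, j) = sum_t xi[t, i, j] / sum_t gamma[t, i], summing over steps
    whose left endpoint lies in the window; rows for never-occupied states are
    NaN.
    """
    K = posterior.gamma.shape[1]
    xi, gamma = posterior.xi, posterior.gamma
    if window is not None:
        sel = _window_index(posterior.times[:-1], window)
        xi = xi[sel]
        gamma = gamma[:-1][sel]
    else:
        gamma = gamma[:-1]
    if xi.shape[0] == 0:
        return np.full((K, K), np.nan)
    num = xi.sum(axis=0)
    den = gamma.sum(axis=0)
    out = np.full((K, K), np.nan)
    occupied = den > 0
    out[occupied] = num[occupied] / den[occupied, None]
    return out


def hard_transition_frequencies(map_path: np.ndarray, K: int = 3) -> np.ndarray:
    """Count-based transition matrix from the MAP path (unweighted variant)."""
    out = np.full((K, K), np.nan)
    counts = np.zeros((K, K))
    for a, b in zip(map_path[:-1], map_path[1:]):
        counts[a, b] += 1
    rows = counts.sum(axis=1)
    for i in range(K):
        if rows[i] > 0:
            out[i] = counts[i] / rows[i]
    return out


def longest_bout(map_path: np.ndarray, times: np.ndarray, state: int,
                 step: float = 10.0) -> tuple[float, float]:
    """Longest continuous run of a state: (duration in days, start day).

    Duration is run length x grid step; ties resolve to the earliest run.
    A state absent from the path returns (0.0, NaN).
    """
    best_len, best_start = 0, np.nan
    run, start = 0, None
    for i, s in enumerate(np.append(map_path, -1)):  # sentinel flushes last run
        if s == state:
            if run == 0:
                start = i
            run += 1
        else:
            if run > best_len:
                best_len, best_start = run, times[start]
            run = 0
    if best_len == 0:
        return 0.0, np.nan
    return best_len * step, float(best_start)


def max_rate(trace: GriddedTrace, posterior: PosteriorStates, state: int,
             normalize: bool = False) -> tuple[float, float]:
    """Maximum absolute weekly rate of weight change while in a state.

    Steps are attributed to the state decoded at the step's right endpoint.
    Returns (rate, grid day of the maximizing step); the normalized variant
    divides by the body weight at that endpoint, giving fraction of body weight
    per week. A state never visited returns (NaN, NaN).
    """
    dy = np.abs(np.diff(trace.weights))
    sel = posterior.map_path == state
    if not np.any(sel):
        return np.nan, np.nan
    rates = dy * WEEK_PER_STEP
    if normalize:
        rates = rates / trace.weights[1:]
    masked = np.where(sel, rates, -np.inf)
    i = int(np.argmax(masked))
    return float(masked[i]), float(trace.grid_times[1:][i])


@dataclass
class BinnedHomeostasis:
    """Long-format per-bin occupancy and stability for one animal."""

    animal_id: str
    bin_mode: str  # 'age_6mo' or 'life_decile'
    table: pd.DataFrame  # columns: bin_index, state, occupancy, stability


def _age_bins(max_age: float = MAX_AGE_DAYS, width: float = 6 * MONTH_DAYS):
    edges = np.arange(0.0, max_age + width, width)
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def binned_homeostasis(posterior: PosteriorStates, trace: GriddedTrace,
                       mode: str = "age_6mo") -> BinnedHomeostasis:
    """Per-age-bin occupancy and steady-type stability.

    ``age_6mo`` bins are [0, 180), [180, 360), ... up to 1260 days; ``life_decile``
    splits [0, death_day) into ten equal bins (censored animals are skipped with
    a warning). stability[s] in a bin is sum_t xi[t, s, s] / sum_t gamma[t, s]
    over steps starting in the bin: the empirical probability of not leaving the
    state. Bins without data carry NaN, never zero.
    """
    if mode == "age_6mo":
        bins = _age_bins()
    elif mode == "life_decile":
        if trace.death_day is None:
            raise ValueError(f"{trace.animal_id}: life_decile bins need a death day")
        edges = np.linspace(0.0, float(trace.death_day), 11)
        bins = [(edges[i], edges[i + 1]) for i in range(10)]
    else:
        raise ValueError(f"unknown bin mode {mode!r}")

    K = posterior.gamma.shape[1]
    rows = []
    for b, window in enumerate(bins):
        occ = occupancy(posterior, window)
        tf = transition_frequencies(posterior, window)
        for s in range(K):
            rows.append({
                "bin_index": b, "state": s,
                "occupancy": occ[s] if occ is not None else np.nan,
                "stability": tf[s, s],
            })
    return BinnedHomeostasis(animal_id=trace.animal_id, bin_mode=mode,
                             table=pd.DataFrame(rows))


def phase_traits(trace: GriddedTrace, posterior: PosteriorStates,
                 phase_window, lifespan: float | None) -> dict:
    """The full per-phase catalog: 3 occupancies, 9 transition frequencies,
    3 longest-bout durations, 3 bout onsets, 2 max rates (20 traits), plus
    normalized auxiliary variants."""
    K = posterior.gamma.shape[1]
    out = {}
    sel = _window_index(posterior.times, phase_window)
    n_pts = int(sel.sum())
    occ = occupancy(posterior, phase_window)
    tf = transition_frequencies(posterior, phase_window)
    if n_pts < 3:
        occ = np.full(K, np.nan)
        tf = np.full((K, K), np.nan)
    for s, name in enumerate(STATES[:K]):
        out[f"occupancy_{name}"] = occ[s]
    for i, a in enumerate(STATES[:K]):
        for j, b in enumerate(STATES[:K]):
            out[f"trans_{a}_to_{b}"] = tf[i, j]

    phase_duration = max(n_pts - 1, 0) * 10.0
    times = posterior.times[sel]
    path = posterior.map_path[sel]
    for s, name in enumerate(STATES[:K]):
        if n_pts < 3:
            dur, start = np.nan, np.nan
        else:
            dur, start = longest_bout(path, times, s)
        out[f"longest_bout_{name}"] = dur
        out[f"longest_bout_{name}_frac"] = (
            dur / phase_duration if phase_duration > 0 and np.isfinite(dur) else np.nan
        )
        out[f"bout_start_{name}"] = start
        out[f"bout_start_{name}_norm"] = (
            start / lifespan if lifespan and np.isfinite(start) else np.nan
        )

    # max rates over steps whose right endpoint falls in the phase window
    dy = np.abs(np.diff(trace.weights))[sel]
    end_weights = trace.weights[1:][sel]
    for name, s in (("growth", STATES.index("growth")), ("decline", STATES.index("decline"))):
        in_state = path == s
        if n_pts < 3 or not np.any(in_state):
            rate = day = nrate = np.nan
        else:
            rates = np.where(in_state, dy * WEEK_PER_STEP, -np.inf)
            i = int(np.argmax(rates))
            rate, day = float(rates[i]), float(times[i])
            nrate = rate / float(end_weights[i])
        out[f"max_rate_{name}"] = rate
        out[f"max_rate_{name}_norm"] = nrate
        out[f"rate_time_{name}"] = day
    return out


#: The 20 primary trait columns (auxiliary normalized variants excluded).
PRIMARY_TRAITS = tuple(
    [f"occupancy_{s}" for s in STATES]
    + [f"trans_{a}_to_{b}" for a in STATES for b in STATES]
    + [f"longest_bout_{s}" for s in STATES]
    + [f"bout_start_{s}" for s in STATES]
    + ["max_rate_growth", "max_rate_decline"]
)


def trait_table(traces, params: ARHMMParams, drop: tuple = ()) -> pd.DataFrame:
    """One row per animal x phase with the full trait catalog.

    ``drop`` removes named columns (e.g. to match a 19-trait subset). Phases
    with fewer than 3 grid points yield rows of missing values.
    """
    from .arhmm import relabel_params

    params, _ = relabel_params(params)  # canonical (growth, steady, decline) order
    rows = []
    for tr in traces:
        post = decode(params, tr)
        lifespan = tr.death_day if tr.death_day is not None else float(tr.grid_times[-1])
        for phase, window in (
            ("pre", (-np.inf, tr.intervention_day)),
            ("post", (tr.intervention_day, np.inf)),
        ):
            row = {"animal_id": tr.animal_id, "phase": phase, "diet": tr.diet,
                   "cohort": tr.cohort}
            row.update(phase_traits(tr, post, window, lifespan))
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.drop(columns=[c for c in drop if c in df.columns])


def semantic_order(params: ARHMMParams) -> list[int]:
    """State indices ordered (growth, steady, decline) via label_states."""
    lab = label_states(params)
    inv = {v: k for k, v in lab.items()}
    return [inv[s] for s in STATES]
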