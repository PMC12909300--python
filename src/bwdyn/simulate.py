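"""Synthetic cohorts with full ground truth.

The generator emulates the study structure every pipeline stage assumes: mice
enter at day 60 weighing ~20 g, are weighed on a 10-day grid, switch among
growth/steady/decline drift states driven by a Markov chain whose transition
matrix changes at the 6-month dietary intervention (and differs by diet
afterwards), experience annual phenotyping events that force decline bouts
followed by steady recovery, die at occupancy-dependent piecewise-exponential
times, and carry 8-founder genotype dosages with an optional planted trait
effect.

Default dynamics echo the fitted scale of the real cohort: steady drift ~0,
growth ~ +0.5 g per 10-day step, decline ~ -0.8 g per 10-day step, with states
well separated relative to the step noise. These are simulation defaults, not
estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .arhmm import ARHMMParams
from .genetics import FOUNDERS, FounderDosage
from .preprocess import DIETS, GriddedTrace

logger = logging.getLogger(__name__)

#: semantic order used throughout: 0=growth, 1=steady, 2=decline
GROWTH, STEADY, DECLINE = 0, 1, 2


def _sticky(diag, off):
    A = np.array(off, dtype=float)
    np.fill_diagonal(A, 0.0)
    A = A / A.sum(axis=1, keepdims=True) * (1 - np.asarray(diag))[:, None]
    np.fill_diagonal(A, diag)
    return A


def default_pre_transitions() -> np.ndarray:
    """Young, ad-libitum dynamics: growth-dominant, occasional steady spells."""
    return np.array([
        [0.88, 0.10, 0.02],
        [0.25, 0.70, 0.05],
        [0.15, 0.35, 0.50],
    ])


def default_post_transitions() -> dict:
    """Post-intervention transition matrices per diet.

    Restricted diets are steadier (higher steady self-transition, less decline
    occupancy); ad libitum keeps more growth and, late in life, decline.
    """
    al = np.array([
        [0.80, 0.17, 0.03],
        [0.06, 0.87, 0.07],
        [0.05, 0.30, 0.65],
    ])
    fast = np.array([
        [0.72, 0.25, 0.03],
        [0.05, 0.90, 0.05],
        [0.05, 0.37, 0.58],
    ])
    cr20 = np.array([
        [0.60, 0.37, 0.03],
        [0.03, 0.93, 0.04],
        [0.04, 0.46, 0.50],
    ])
    cr40 = np.array([
        [0.50, 0.48, 0.02],
        [0.02, 0.95, 0.03],
        [0.04, 0.56, 0.40],
    ])
    return {"AL": al, "1D": fast, "2D": fast, "20": cr20, "40": cr40}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_animals: int = 200
    diets: tuple = DIETS
    diet_proportions: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    grid_step: float = 10.0
    start_day: float = 60.0
    intervention_day: float = 180.0
    max_age: float = 1260.0
    init_weight_mean: float = 20.0
    init_weight_sd: float = 2.0
    # state drift (g per 10-day step), intercept spread and step noise sd (g)
    eta0: tuple = (0.5, 0.0, -0.8)
    sigma0: tuple = (0.05, 0.05, 0.05)
    sigma: tuple = (0.25, 0.25, 0.25)
    #: 'per_mouse' draws one intercept per animal per state (the random-intercept
    #: generative model); 'per_step' redraws it every step (the collapsed model).
    intercept_mode: str = "per_mouse"
    pi0: tuple = (0.9, 0.1, 0.0)
    pre_transitions: np.ndarray = field(default_factory=default_pre_transitions)
    post_transitions: dict = field(default_factory=default_post_transitions)
    # annual month-long phenotyping blocks at 10, 22 and 34 months
    event_days: tuple = (300.0, 660.0, 1020.0)
    event_decline_continue: float = 0.6   # geometric continuation, mean 2.5 steps
    event_recovery_steps: int = 5         # forced steady steps after the bout
    # survival: piecewise-exponential with log-hazard on per-bin decline occupancy (%)
    baseline_hazard: float = 2e-4         # deaths per day
    hazard_coefs: dict = field(default_factory=lambda: {"decline_occupancy_pct": 0.065})
    hazard_bin_days: float = 180.0
    # genetics
    n_markers: int = 50
    planted_marker: int = 0
    planted_founder: int = FOUNDERS.index("WSB")
    planted_effect: float = 0.0

    def __post_init__(self):
        if abs(sum(self.diet_proportions) - 1.0) > 1e-9:
            raise ValueError("diet proportions must sum to 1")
        if any(s < 0 for s in self.sigma0) or any(s <= 0 for s in self.sigma):
            raise ValueError("noise scales must be positive")

    def true_params(self, diet: str = "AL", phase: str = "post") -> ARHMMParams:
        """The generating model as an ARHMMParams (for recovery checks)."""
        A = self.pre_transitions if phase == "pre" else self.post_transitions[diet]
        return ARHMMParams(
            K=3, pi0=np.asarray(self.pi0, float), A=np.asarray(A, float),
            eta0=np.asarray(self.eta0, float),
            sigma0_sq=np.asarray(self.sigma0, float) ** 2,
            sigma_sq=np.asarray(self.sigma, float) ** 2,
        )


@dataclass
class GroundTruth:
    """Per-cohort generating truth for tests."""

    state_paths: dict
    config: SimConfig
    death_days: dict
    decline_occupancy: dict  # per animal, per hazard bin, percentage points
    planted_marker_id: str | None = None
    planted_effect: float = 0.0


def _sample_state(rng, probs):
    return int(rng.choice(len(probs), p=probs))


def simulate_trace(config: SimConfig, animal_id: str, diet: str,
                   seed: int) -> tuple[GriddedTrace, np.ndarray]:
    """One animal's full-length trace (to max_age) and its true state path.

    States follow the pre-intervention chain before the intervention day and
    the diet-specific chain after; each phenotyping event forces a decline bout
    of geometric length followed by a stretch of forced steady (the recovery
    the stress stage is meant to detect). Weight increments are
    eta0_s + per-animal intercept noise + step noise.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(config.start_day, config.max_age + config.grid_step,
                     config.grid_step)
    T = grid.size
    intercepts = np.asarray(config.eta0) + rng.normal(size=3) * np.asarray(config.sigma0)

    # pre-plan forced segments from the event schedule
    forced = np.full(T, -1, dtype=int)
    for ev in config.event_days:
        i = int(np.searchsorted(grid, ev, side="left"))
        if i >= T:
            continue
        n_decline = 1 + rng.geometric(1.0 - config.event_decline_continue)
        for k in range(n_decline):
            if i + k < T:
                forced[i + k] = DECLINE
        for k in range(config.event_recovery_steps):
            j = i + n_decline + k
            if j < T:
                forced[j] = STEADY

    states = np.empty(T, dtype=int)
    states[0] = forced[0] if forced[0] >= 0 else _sample_state(rng, np.asarray(config.pi0))
    for t in range(1, T):
        if forced[t] >= 0:
            states[t] = forced[t]
        else:
            A = (config.pre_transitions if grid[t] < config.intervention_day
                 else config.post_transitions[diet])
            states[t] = _sample_state(rng, A[states[t - 1]])

    weights = np.empty(T)
    weights[0] = max(rng.normal(config.init_weight_mean, config.init_weight_sd), 5.0)
    sig = np.asarray(config.sigma)
    sig0 = np.asarray(config.sigma0)
    per_step = config.intercept_mode == "per_step"
    for t in range(1, T):
        s = states[t]
        phi0 = (config.eta0[s] + rng.normal() * sig0[s]) if per_step else intercepts[s]
        weights[t] = max(weights[t - 1] + phi0 + rng.normal() * sig[s], 1.0)

    trace = GriddedTrace(
        animal_id=animal_id, grid_times=grid, weights=weights,
        interpolated_mask=np.zeros(T, dtype=bool), diet=diet,
        intervention_day=config.intervention_day,
        event_days=tuple(config.event_days),
    )
    return trace, states


def _bin_decline_occupancy(states: np.ndarray, grid: np.ndarray,
                           config: SimConfig) -> dict:
    """True decline occupancy (percentage points) per hazard bin."""
    edges = np.arange(config.start_day, config.max_age + config.hazard_bin_days,
                      config.hazard_bin_days)
    out = {}
    for j in range(len(edges) - 1):
        sel = (grid >= edges[j]) & (grid < edges[j + 1])
        if sel.any():
            out[j] = 100.0 * float(np.mean(states[sel] == DECLINE))
    return out


def simulate_survival(bin_features: dict, config: SimConfig, seed: int,
                      feature_name: str = "decline_occupancy_pct") -> float | None:
    """Piecewise-exponential death time from per-bin features.

    Within hazard bin j the rate is baseline * exp(coef * feature_j); the death
    day is drawn sequentially bin by bin. Returns None when the animal survives
    to administrative censoring at max_age.
    """
    rng = np.random.default_rng(seed)
    coef = config.hazard_coefs.get(feature_name, 0.0)
    edges = np.arange(config.start_day, config.max_age + config.hazard_bin_days,
                      config.hazard_bin_days)
    for j in range(len(edges) - 1):
        lo, hi = edges[j], min(edges[j + 1], config.max_age)
        rate = config.baseline_hazard * np.exp(coef * bin_features.get(j, 0.0))
        e = rng.exponential()
        if e < rate * (hi - lo):
            return float(lo + e / rate)
    return None


def simulate_cohort(config: SimConfig, seed: int = 0,
                    truncate_at_death: bool = True) -> tuple[list, GroundTruth]:
    """A full cohort: traces (truncated at death), state paths, death days."""
    rng = np.random.default_rng(seed)
    n_per = np.floor(np.asarray(config.diet_proportions) * config.n_animals).astype(int)
    while n_per.sum() < config.n_animals:
        n_per[int(rng.integers(len(config.diets)))] += 1
    assignments = [d for d, k in zip(config.diets, n_per) for _ in range(k)]

    traces, paths, deaths, occs = [], {}, {}, {}
    for i, diet in enumerate(assignments):
        aid = f"M{i:04d}"
        trace, states = simulate_trace(config, aid, diet, seed=seed * 100003 + i)
        occ = _bin_decline_occupancy(states, trace.grid_times, config)
        death = simulate_survival(occ, config, seed=seed * 100003 + i + 50000)
        if truncate_at_death and death is not None:
            keep = trace.grid_times <= death
            if keep.sum() < 3:
                keep = np.zeros(len(trace), dtype=bool)
                keep[:3] = True
            trace = GriddedTrace(
                animal_id=aid, grid_times=trace.grid_times[keep],
                weights=trace.weights[keep],
                interpolated_mask=trace.interpolated_mask[keep], diet=diet,
                intervention_day=config.intervention_day, death_day=death,
                event_days=trace.event_days,
            )
            states = states[keep]
        else:
            trace.death_day = death
        traces.append(trace)
        paths[aid] = states
        deaths[aid] = death
        occs[aid] = occ
    truth = GroundTruth(state_paths=paths, config=config, death_days=deaths,
                        decline_occupancy=occs)
    return traces, truth


def simulate_founder_genotypes(n_animals: int, n_markers: int,
                               seed: int = 0) -> list[FounderDosage]:
    """Founder-dosage matrices: two founder draws per animal per marker from a
    Dirichlet-perturbed frequency vector, rows summing to 2 exactly."""
    rng = np.random.default_rng(seed)
    out = []
    for m in range(n_markers):
        freq = rng.dirichlet(np.ones(len(FOUNDERS)) * 2.0)
        draws = rng.choice(len(FOUNDERS), size=(n_animals, 2), p=freq)
        dos = np.zeros((n_animals, len(FOUNDERS)))
        for a in range(n_animals):
            dos[a, draws[a, 0]] += 1
            dos[a, draws[a, 1]] += 1
        out.append(FounderDosage(
            marker_id=f"mk{m:04d}", chrom="1", pos_bp=1 + m * 100_000, dosages=dos,
        ))
    return out


def apply_planted_effect(trait: np.ndarray, marker: FounderDosage,
                         founder: int, effect: float) -> np.ndarray:
    """Add effect x founder dosage at a planted marker to a trait vector."""
    return np.asarray(trait, float) + effect * marker.dosages[:, founder]
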