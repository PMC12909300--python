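import numpy as np
import pandas as pd
import pytest

from bwdyn import arhmm, simulate
from bwdyn.preprocess import GriddedTrace


def exact_model_config(**kw):
    """Generator configuration matching the fitted collapsed model exactly:
    homogeneous transition chain, per-step intercept redraw, no event forcing."""
    post = simulate.default_post_transitions()["AL"]
    kw.setdefault("n_animals", 60)
    return simulate.SimConfig(
        event_days=(), intercept_mode="per_step", diets=("AL",),
        diet_proportions=(1.0,), pre_transitions=post, **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """50 full-length synthetic traces with ground-truth state paths."""
    cfg = simulate.SimConfig(n_animals=50)
    traces, truth = simulate.simulate_cohort(cfg, seed=7, truncate_at_death=False)
    return cfg, traces, truth


@pytest.fixture(scope="session")
def fitted_collapsed(small_cohort):
    cfg, traces, truth = small_cohort
    fit = arhmm.fit_arhmm(traces, K=3, n_init=3, seed=0, mode="collapsed")
    return fit


@pytest.fixture()
def random_params():
    rng = np.random.default_rng(3)
    K = 3
    return arhmm.ARHMMParams(
        K=K,
        pi0=rng.dirichlet(np.ones(K)),
        A=rng.dirichlet(np.ones(K), size=K),
        eta0=rng.normal(size=K),
        sigma0_sq=np.abs(rng.normal(size=K)) * 0.1,
        sigma_sq=np.abs(rng.normal(size=K)) + 0.3,
    )


def make_trace(weights, start_day=60.0, **kw):
    weights = np.asarray(weights, float)
    grid = start_day + 10.0 * np.arange(weights.size)
    kw.setdefault("animal_id", "T1")
    return GriddedTrace(
        grid_times=grid, weights=weights,
        interpolated_mask=np.zeros(weights.size, dtype=bool), **kw,
    )


@pytest.fixture()
def trace_factory():
    return make_trace


def two_bin_cohort(n=120, seed=0, beta=0.065, feat_sd=10.0, baseline=4e-4):
    """Animals with a per-bin gated covariate and piecewise-exponential deaths."""
    rng = np.random.default_rng(seed)
    cfg = simulate.SimConfig(baseline_hazard=baseline, hazard_coefs={"x": beta},
                             hazard_bin_days=360.0, max_age=780.0, start_day=60.0)
    traces, feats = [], {}
    for i in range(n):
        aid = f"M{i:03d}"
        x = {0: rng.normal(0, feat_sd), 1: rng.normal(0, feat_sd)}
        death = simulate.simulate_survival(x, cfg, seed=seed * 7919 + i,
                                           feature_name="x")
        end = death if death is not None else cfg.max_age
        grid = np.arange(60.0, end + 10.0, 10.0)
        grid = grid[grid <= end]
        w = 30.0 + rng.normal(0, 0.5, grid.size).cumsum() * 0.1
        traces.append(make_trace(w, start_day=60.0, animal_id=aid, death_day=death))
        feats[aid] = x
    bin_traits = pd.DataFrame([
        {"animal_id": a, "bin_index": j, "value": v}
        for a, x in feats.items() for j, v in x.items()
    ])
    return traces, bin_traits, feats
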