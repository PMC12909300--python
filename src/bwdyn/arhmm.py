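"""Constrained lag-1 autoregressive hidden Markov model for body-weight traces.

The model: y_t = phi0^{s_t} + y_{t-1} + eps_t^{s_t}, where s_t follows a K-state
Markov chain, the unit autoregressive coefficient is fixed (weight is a random
walk with state-dependent drift), the state intercept phi0^s is drawn from
N(eta0_s, sigma0_sq_s), and eps is N(0, sigma_sq_s). Working on first
differences dy_t = y_t - y_{t-1} turns this into a Gaussian HMM over the T-1
increments.

Two inference variants are provided:

* ``collapsed`` - the intercept is treated as redrawn independently at every
  step; marginalizing it gives an exact HMM on dy with emission
  N(eta0_s, sigma0_sq_s + sigma_sq_s), fitted by exact EM. This is the
  reference implementation used by oracles.
* ``random_intercept`` - one intercept per animal per state, fitted by
  mean-field variational EM with a Gaussian posterior q(phi0_{m,s}); restarts
  are compared by the final ELBO.

States of a K=3 fit are mapped to semantic labels by the sign and magnitude of
eta0: largest drift -> growth, smallest -> decline, remaining -> steady.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .preprocess import GriddedTrace

logger = logging.getLogger(__name__)

STATE_LABELS = ("growth", "steady", "decline")

_VAR_FLOOR = 1e-6  # grams^2, prevents emission-variance collapse
_SIMPLEX_TOL = 1e-10


class ARHMMError(ValueError):
    pass


@dataclass
class ARHMMParams:
    """Parameters of the K-state drift model (phi1 is fixed at 1).

    eta0 is the per-state mean drift in grams per 10-day step; sigma0_sq the
    variance of the state intercept across draws; sigma_sq the observation
    noise variance.
    """

    K: int
    pi0: np.ndarray
    A: np.ndarray
    eta0: np.ndarray
    sigma0_sq: np.ndarray
    sigma_sq: np.ndarray

    def __post_init__(self):
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.eta0 = np.asarray(self.eta0, dtype=float)
        self.sigma0_sq = np.asarray(self.sigma0_sq, dtype=float)
        self.sigma_sq = np.asarray(self.sigma_sq, dtype=float)
        self.validate()

    def validate(self):
        K = self.K
        if self.pi0.shape != (K,) or self.A.shape != (K, K):
            raise ARHMMError("pi0/A shape mismatch")
        if abs(self.pi0.sum() - 1) > _SIMPLEX_TOL or np.any(self.pi0 < -_SIMPLEX_TOL):
            raise ARHMMError("pi0 is not a probability simplex")
        if np.any(np.abs(self.A.sum(axis=1) - 1) > _SIMPLEX_TOL) or np.any(self.A < -_SIMPLEX_TOL):
            raise ARHMMError("rows of A must be probability simplexes")
        if np.any(self.sigma0_sq < 0):
            raise ARHMMError("sigma0_sq must be non-negative")
        if np.any(self.sigma_sq <= 0):
            raise ARHMMError("sigma_sq must be positive")

    @property
    def total_var(self) -> np.ndarray:
        """Marginal per-step emission variance sigma0_sq + sigma_sq."""
        return self.sigma0_sq + self.sigma_sq


@dataclass
class PosteriorStates:
    """Smoothing posteriors for one trace.

    gamma[t, s] is the marginal probability of state s at increment t (the step
    ending at ``times[t]``); xi[t] the pairwise marginal between increments t
    and t+1; loglik the marginal log-likelihood (collapsed variant) or ELBO.
    """

    gamma: np.ndarray
    xi: np.ndarray
    loglik: float
    map_path: np.ndarray
    times: np.ndarray | None = None


@dataclass
class FitResult:
    params: ARHMMParams
    elbo_trace: np.ndarray
    seed: int
    n_iter: int
    converged: bool
    state_labels: tuple | None = None
    mode: str = "collapsed"
    # effective per-state counts sum_t gamma_t(s) over training traces
    state_counts: np.ndarray | None = None


def _diffs(trace) -> np.ndarray:
    y = trace.weights if isinstance(trace, GriddedTrace) else np.asarray(trace, float)
    if y.size < 2:
        raise ARHMMError("need T >= 2 grid points to form differences")
    return np.diff(y)


def emission_stats(params: ARHMMParams, trace) -> np.ndarray:
    """(T-1) x K log densities of dy_t under each state's marginal emission.

    Entry (t, s) = log N(dy_t; eta0_s, sigma0_sq_s + sigma_sq_s), the collapsed
    per-step-intercept form.
    """
    dy = _diffs(trace)
    var = params.total_var
    if np.any(var <= 0):
        raise ARHMMError("non-positive total emission variance")
    resid = dy[:, None] - params.eta0[None, :]
    return -0.5 * (np.log(2 * np.pi * var)[None, :] + resid**2 / var[None, :])


def _forward_backward_single(log_emis, log_pi0, log_A):
    Tm1, K = log_emis.shape
    la = np.empty((Tm1, K))
    la[0] = log_pi0 + log_emis[0]
    for t in range(1, Tm1):
        la[t] = log_emis[t] + logsumexp(la[t - 1][:, None] + log_A, axis=0)
    lb = np.zeros((Tm1, K))
    for t in range(Tm1 - 2, -1, -1):
        lb[t] = logsumexp(log_A + (log_emis[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = float(logsumexp(la[-1]))
    gamma = np.exp(la + lb - ll)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.empty((Tm1 - 1, K, K))
    for t in range(Tm1 - 1):
        lx = la[t][:, None] + log_A + (log_emis[t + 1] + lb[t + 1])[None, :] - ll
        x = np.exp(lx)
        xi[t] = x / x.sum()
    return gamma, xi, ll


def _forward_backward_batch(log_emis, log_pi0, log_A):
    """Forward-backward over a stack of equal-length emission matrices.

    log_emis has shape (n, T-1, K); returns gamma (n, T-1, K), xi
    (n, T-2, K, K) and per-trace log-likelihoods (n,).
    """
    n, Tm1, K = log_emis.shape
    la = np.empty((n, Tm1, K))
    la[:, 0] = log_pi0[None, :] + log_emis[:, 0]
    for t in range(1, Tm1):
        la[:, t] = log_emis[:, t] + logsumexp(
            la[:, t - 1][:, :, None] + log_A[None, :, :], axis=1
        )
    lb = np.zeros((n, Tm1, K))
    for t in range(Tm1 - 2, -1, -1):
        lb[:, t] = logsumexp(
            log_A[None, :, :] + (log_emis[:, t + 1] + lb[:, t + 1])[:, None, :], axis=2
        )
    ll = logsumexp(la[:, -1], axis=1)
    gamma = np.exp(la + lb - ll[:, None, None])
    gamma /= gamma.sum(axis=2, keepdims=True)
    xi = np.empty((n, Tm1 - 1, K, K))
    for t in range(Tm1 - 1):
        lx = (
            la[:, t][:, :, None]
            + log_A[None, :, :]
            + (log_emis[:, t + 1] + lb[:, t + 1])[:, None, :]
            - ll[:, None, None]
        )
        x = np.exp(lx)
        xi[:, t] = x / x.sum(axis=(1, 2), keepdims=True)
    return gamma, xi, ll


def forward_backward(params: ARHMMParams, trace) -> PosteriorStates:
    """Exact smoothing marginals and log-likelihood under the collapsed model."""
    log_emis = emission_stats(params, trace)
    with np.errstate(divide="ignore"):
        log_pi0 = np.log(params.pi0)
        log_A = np.log(params.A)
    gamma, xi, ll = _forward_backward_single(log_emis, log_pi0, log_A)
    times = trace.grid_times[1:] if isinstance(trace, GriddedTrace) else None
    return PosteriorStates(
        gamma=gamma, xi=xi, loglik=ll, map_path=np.argmax(gamma, axis=1), times=times
    )


def decode(params: ARHMMParams, trace) -> PosteriorStates:
    """Posterior decoding: per-time argmax of smoothing marginals (not Viterbi).

    Exact ties in a gamma row resolve to the lowest state index (numpy argmax),
    matching the documented tie rule.
    """
    return forward_backward(params, trace)


def label_states(params: ARHMMParams) -> dict:
    """Map state indices to semantic labels by drift: largest eta0 -> growth,
    smallest -> decline, remaining -> steady.

    Exact eta0 ties are broken by assigning the state with the smaller noise
    variance to steady (logged). For K != 3 the mapping is withheld and ordinal
    rank labels are returned instead.
    """
    if params.K != 3:
        order = np.argsort(-params.eta0, kind="stable")
        return {int(s): f"rank{r}" for r, s in enumerate(order)}
    idx = sorted(range(3), key=lambda s: (-params.eta0[s], params.sigma_sq[s]))
    eta = params.eta0
    if eta[idx[0]] == eta[idx[1]] or eta[idx[1]] == eta[idx[2]]:
        # tied drifts: steady slot goes to the smaller-sigma state of the tied pair
        if eta[idx[0]] == eta[idx[1]]:
            pair = sorted(idx[:2], key=lambda s: params.sigma_sq[s])
            idx = [pair[1], pair[0], idx[2]]
        else:
            pair = sorted(idx[1:], key=lambda s: params.sigma_sq[s])
            idx = [idx[0], pair[0], pair[1]]
        logger.info("tied eta0 values: smaller sigma_sq state assigned steady")
    return {idx[0]: "growth", idx[1]: "steady", idx[2]: "decline"}


def relabel_params(params: ARHMMParams) -> tuple[ARHMMParams, np.ndarray]:
    """Permute states into decreasing-eta0 order; returns (params, permutation)
    with ``perm[new_index] = old_index``."""
    perm = np.array(sorted(range(params.K), key=lambda s: (-params.eta0[s], params.sigma_sq[s])))
    out = ARHMMParams(
        K=params.K,
        pi0=params.pi0[perm],
        A=params.A[np.ix_(perm, perm)],
        eta0=params.eta0[perm],
        sigma0_sq=params.sigma0_sq[perm],
        sigma_sq=params.sigma_sq[perm],
    )
    return out, perm


# ---------------------------------------------------------------------------
# fitting


def _init_params(dys, K, rng) -> ARHMMParams:
    """k-means on pooled increments for eta0; sticky transition matrix."""
    pooled = np.concatenate(dys)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    lab = km.fit_predict(pooled[:, None])
    eta0 = km.cluster_centers_.ravel().copy()
    var = np.array([
        max(pooled[lab == s].var(), _VAR_FLOOR) if np.any(lab == s) else pooled.var() + _VAR_FLOOR
        for s in range(K)
    ])
    eta0 += rng.normal(scale=0.05 * (pooled.std() + 1e-12), size=K)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    if K == 1:
        A = np.ones((1, 1))
    return ARHMMParams(
        K=K,
        pi0=np.full(K, 1.0 / K),
        A=A,
        eta0=eta0,
        sigma0_sq=np.zeros(K),
        sigma_sq=var,
    )


def _group_by_length(dys):
    groups = {}
    for i, dy in enumerate(dys):
        groups.setdefault(dy.size, []).append(i)
    return groups


def _e_step_collapsed(params, dys, groups):
    """Batched E-step; returns per-trace (gamma, xi) and total loglik."""
    with np.errstate(divide="ignore"):
        log_pi0 = np.log(params.pi0)
        log_A = np.log(params.A)
    var = params.total_var
    gammas = [None] * len(dys)
    xis = [None] * len(dys)
    total_ll = 0.0
    for size, idxs in groups.items():
        stack = np.stack([dys[i] for i in idxs])  # (n, T-1)
        resid = stack[:, :, None] - params.eta0[None, None, :]
        log_emis = -0.5 * (np.log(2 * np.pi * var)[None, None, :] + resid**2 / var[None, None, :])
        g, x, ll = _forward_backward_batch(log_emis, log_pi0, log_A)
        for j, i in enumerate(idxs):
            gammas[i], xis[i] = g[j], x[j]
        total_ll += float(ll.sum())
    return gammas, xis, total_ll


def _fit_collapsed(dys, K, params, max_iter, tol):
    groups = _group_by_length(dys)
    ll_trace = []
    converged = False
    gammas = xis = None
    for it in range(max_iter):
        gammas, xis, ll = _e_step_collapsed(params, dys, groups)
        ll_trace.append(ll)
        if it > 0 and abs(ll - ll_trace[-2]) <= tol * (abs(ll_trace[-2]) + 1e-12):
            converged = True
            break
        # M-step
        pi0 = np.mean([g[0] for g in gammas], axis=0)
        trans = np.sum([x.sum(axis=0) for x in xis if x.size], axis=0)
        if np.ndim(trans) != 2:
            trans = np.zeros((K, K))
        rowsum = trans.sum(axis=1, keepdims=True)
        A = np.where(rowsum > 0, trans / np.where(rowsum == 0, 1, rowsum), 1.0 / K)
        sg = np.zeros(K)
        sgy = np.zeros(K)
        sgy2 = np.zeros(K)
        for g, dy in zip(gammas, dys):
            sg += g.sum(axis=0)
            sgy += g.T @ dy
            sgy2 += g.T @ (dy**2)
        eta0 = np.where(sg > 0, sgy / np.where(sg == 0, 1, sg), params.eta0)
        var = np.where(sg > 0, sgy2 / np.where(sg == 0, 1, sg) - eta0**2, params.sigma_sq)
        var = np.maximum(var, _VAR_FLOOR)
        params = ARHMMParams(K=K, pi0=pi0 / pi0.sum(), A=A, eta0=eta0,
                             sigma0_sq=np.zeros(K), sigma_sq=var)
    counts = np.sum([g.sum(axis=0) for g in gammas], axis=0)
    return params, np.array(ll_trace), converged, counts


def _fit_random_intercept(dys, K, params, max_iter, tol, fix_sigma0=None):
    """Mean-field VB: q(s_{1:T}) x q(phi0_{m,s}) with Gaussian intercept posteriors.

    Forward-backward is batched over traces of equal length; the recorded ELBO
    is evaluated at the q(phi0) that produced the expected emissions, so the
    per-iteration sequence is non-decreasing up to the convergence tolerance.
    """
    M = len(dys)
    sigma0 = np.full(K, 0.01) if fix_sigma0 is None else np.full(K, fix_sigma0)
    params = ARHMMParams(K=K, pi0=params.pi0, A=params.A, eta0=params.eta0,
                         sigma0_sq=sigma0, sigma_sq=params.sigma_sq)
    mu = np.tile(params.eta0, (M, 1))
    v = np.tile(params.sigma0_sq, (M, 1))
    groups = _group_by_length(dys)
    stacks = {size: np.stack([dys[i] for i in idxs]) for size, idxs in groups.items()}
    elbo_trace = []
    converged = False
    ng_all = np.zeros((M, K))
    gdy_all = np.zeros((M, K))
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            log_pi0 = np.log(params.pi0)
            log_A = np.log(params.A)
        sig = params.sigma_sq
        sig0 = np.maximum(params.sigma0_sq, 1e-12)
        elbo = 0.0
        gamma0_sum = np.zeros(K)
        trans = np.zeros((K, K))
        gammas_by_group = {}
        for size, idxs in groups.items():
            dy = stacks[size]                      # (n, Tm1)
            mu_g, v_g = mu[idxs], v[idxs]          # (n, K)
            resid2 = (dy[:, :, None] - mu_g[:, None, :]) ** 2 + v_g[:, None, :]
            log_emis = -0.5 * (np.log(2 * np.pi * sig)[None, None, :]
                               + resid2 / sig[None, None, :])
            g, x, ll = _forward_backward_batch(log_emis, log_pi0, log_A)
            kl = 0.5 * np.sum(
                np.log(sig0[None, :] / v_g) + (v_g + (mu_g - params.eta0) ** 2) / sig0,
                axis=1,
            ) - 0.5 * K
            elbo += float(ll.sum() - kl.sum())
            gamma0_sum += g[:, 0].sum(axis=0)
            if x.size:
                trans += x.sum(axis=(0, 1))
            ng_all[idxs] = g.sum(axis=1)            # (n, K)
            gdy_all[idxs] = np.einsum("ntk,nt->nk", g, dy)
            gammas_by_group[size] = g
        elbo_trace.append(elbo)
        if it > 0 and abs(elbo - elbo_trace[-2]) <= tol * (abs(elbo_trace[-2]) + 1e-12):
            converged = True
            break
        # M-step. eta0 maximizes the ELBO profiled over q(phi0): marginally,
        # the gamma-weighted trace mean ybar_ms ~ N(eta0_s, sigma0_sq + sig/n_ms),
        # so eta0 is the precision-weighted mean of the ybar; this reduces to the
        # pooled collapsed-EM update as sigma0_sq -> 0.
        visited = ng_all > 1e-12
        ybar = np.where(visited, gdy_all / np.where(visited, ng_all, 1.0), 0.0)
        tau = np.where(visited, 1.0 / (sig0[None, :] + sig[None, :] /
                                       np.where(visited, ng_all, 1.0)), 0.0)
        tausum = tau.sum(axis=0)
        eta0 = np.where(tausum > 0, (tau * ybar).sum(axis=0) /
                        np.where(tausum > 0, tausum, 1.0), params.eta0)
        # exact conditional q(phi0 | gamma, eta0)
        prec = 1.0 / sig0[None, :] + ng_all / sig[None, :]
        mu = (eta0[None, :] / sig0[None, :] + gdy_all / sig[None, :]) / prec
        v = 1.0 / prec
        pi0 = gamma0_sum / gamma0_sum.sum()
        rowsum = trans.sum(axis=1, keepdims=True)
        A = np.where(rowsum > 0, trans / np.where(rowsum == 0, 1, rowsum), 1.0 / K)
        if fix_sigma0 is None:
            sigma0_new = np.maximum(((mu - eta0) ** 2 + v).mean(axis=0), 1e-8)
        else:
            sigma0_new = np.full(K, fix_sigma0)
        sg = np.zeros(K)
        sres = np.zeros(K)
        for size, idxs in groups.items():
            dy = stacks[size]
            g = gammas_by_group[size]
            sg += g.sum(axis=(0, 1))
            resid2_new = (dy[:, :, None] - mu[idxs][:, None, :]) ** 2 + v[idxs][:, None, :]
            sres += np.einsum("ntk,ntk->k", g, resid2_new)
        sig_new = np.maximum(
            np.where(sg > 0, sres / np.where(sg == 0, 1, sg), params.sigma_sq), _VAR_FLOOR
        )
        params = ARHMMParams(K=K, pi0=pi0, A=A, eta0=eta0,
                             sigma0_sq=sigma0_new, sigma_sq=sig_new)
    counts = ng_all.sum(axis=0)
    return params, np.array(elbo_trace), converged, counts


def fit_arhmm(
    traces,
    K: int,
    n_init: int = 10,
    seed: int = 0,
    mode: str = "random_intercept",
    max_iter: int = 500,
    tol: float = 1e-8,
    fix_sigma0: float | None = None,
) -> FitResult:
    """Fit the K-state drift model, best of ``n_init`` restarts by final objective.

    ``mode='collapsed'`` runs exact EM on first differences (the objective is
    the exact marginal log-likelihood); ``mode='random_intercept'`` runs
    variational EM with a per-animal, per-state intercept posterior (the
    objective is the ELBO). States are relabeled in decreasing eta0 order and,
    for K=3, mapped to (growth, steady, decline).
    """
    if K < 1:
        raise ARHMMError("K must be >= 1")
    dys = []
    for tr in traces:
        y = tr.weights if isinstance(tr, GriddedTrace) else np.asarray(tr, float)
        if y.size >= 3:
            dys.append(np.diff(y))
    if not dys:
        raise ARHMMError("no traces with T >= 3 grid points")
    if mode not in ("collapsed", "random_intercept"):
        raise ARHMMError(f"unknown mode {mode!r}")

    best = None
    for i in range(n_init):
        rng = np.random.default_rng(seed + i)
        init = _init_params(dys, K, rng)
        if mode == "collapsed":
            params, obj, conv, counts = _fit_collapsed(dys, K, init, max_iter, tol)
        else:
            params, obj, conv, counts = _fit_random_intercept(
                dys, K, init, max_iter, tol, fix_sigma0=fix_sigma0
            )
        if best is None or obj[-1] > best[1][-1]:
            best = (params, obj, conv, counts, seed + i)
    params, obj, conv, counts, used_seed = best
    if not conv:
        logger.warning("ARHMM fit (K=%d, mode=%s) did not converge in %d iterations",
                       K, mode, max_iter)
    params, perm = relabel_params(params)
    labels = None
    if K == 3:
        lab_map = label_states(params)
        labels = tuple(lab_map[s] for s in range(3))
    return FitResult(
        params=params,
        elbo_trace=obj,
        seed=used_seed,
        n_iter=len(obj),
        converged=conv,
        state_labels=labels,
        mode=mode,
        state_counts=counts[perm],
    )


# ---------------------------------------------------------------------------
# model-order selection


def heldout_loglik(params: ARHMMParams, traces) -> float:
    total = 0.0
    for tr in traces:
        total += forward_backward(params, tr).loglik
    return total


def select_model_order(
    train,
    heldout,
    K_range,
    n_init: int = 3,
    seed: int = 0,
    mode: str = "collapsed",
    n_dic_samples: int = 20,
    max_iter: int = 300,
) -> tuple[int, dict]:
    """Pick the number of states by held-out deviance information criterion.

    For each K the model is fitted on ``train`` and scored on ``heldout`` with
    DIC = 2 * E[D(theta)] - D(theta_hat), D = -2 log p(heldout | theta). The
    parameter posterior is approximated by Gaussian uncertainty on each state
    drift, Var(eta0_s) = total_var_s / N_s with N_s the effective state count
    from the fit; states barely used by the data inflate the expected deviance
    and are thereby penalized. Ties resolve to the smaller K.
    """
    K_range = list(K_range)
    if not K_range:
        raise ARHMMError("K_range must be non-empty")
    rng = np.random.default_rng(seed)
    dic = {}
    for K in K_range:
        fit = fit_arhmm(train, K=K, n_init=n_init, seed=seed + 1000 * K,
                        mode=mode, max_iter=max_iter, tol=1e-6)
        p = fit.params
        d_hat = -2.0 * heldout_loglik(p, heldout)
        counts = np.maximum(fit.state_counts, 1.0)
        se = np.sqrt(p.total_var / counts)
        d_bar = 0.0
        for _ in range(n_dic_samples):
            eta = p.eta0 + rng.normal(size=K) * se
            pert = ARHMMParams(K=K, pi0=p.pi0, A=p.A, eta0=eta,
                               sigma0_sq=p.sigma0_sq, sigma_sq=p.sigma_sq)
            d_bar += -2.0 * heldout_loglik(pert, heldout)
        d_bar /= n_dic_samples
        dic[K] = 2.0 * d_bar - d_hat
    best_K = min(sorted(K_range), key=lambda k: dic[k])
    return best_K, dic


def train_test_split_traces(traces, train_frac: float = 0.7, seed: int = 0):
    """Split traces into train/held-out sets, stratified by diet."""
    rng = np.random.default_rng(seed)
    by_diet = {}
    for tr in traces:
        by_diet.setdefault(tr.diet, []).append(tr)
    train, heldout = [], []
    for diet in sorted(by_diet):
        grp = by_diet[diet]
        idx = rng.permutation(len(grp))
        n_train = int(round(train_frac * len(grp)))
        train += [grp[i] for i in idx[:n_train]]
        heldout += [grp[i] for i in idx[n_train:]]
    return train, heldout


# ---------------------------------------------------------------------------
# serialization


def params_to_dict(fit: FitResult) -> dict:
    p = fit.params
    return {
        "K": p.K,
        "pi0": p.pi0.tolist(),
        "A": p.A.tolist(),
        "eta0": p.eta0.tolist(),
        "sigma0_sq": p.sigma0_sq.tolist(),
        "sigma_sq": p.sigma_sq.tolist(),
        "seed": fit.seed,
        "mode": fit.mode,
        "converged": fit.converged,
        "state_labels": list(fit.state_labels) if fit.state_labels else None,
        "elbo_trace": np.asarray(fit.elbo_trace).tolist(),
    }


def params_from_dict(d: dict) -> ARHMMParams:
    return ARHMMParams(
        K=int(d["K"]), pi0=d["pi0"], A=d["A"], eta0=d["eta0"],
        sigma0_sq=d["sigma0_sq"], sigma_sq=d["sigma_sq"],
    )
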