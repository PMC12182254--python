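"""Likelihoods, Gibbs sampler and convergence diagnostics for the joint model.

The joint posterior factorizes into conjugate blocks because the rank-1
edge term gamma_x * gamma_y is bilinear: holding all other node positions
fixed, each node column of Gamma has a Gaussian full conditional, as do
kappa, the intercepts d and e; tau2 and sigma2 are inverse-gamma and the
latent covariance Sigma is inverse-Wishart.  A per-subject sign-flip
Metropolis move (Gamma_j -> -Gamma_j, which leaves the edge likelihood
invariant) is interleaved every sweep so chains can cross the two sign
modes of the latent positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import invwishart

from .datatypes import (
    SPD_JITTER,
    BehaviorTable,
    ConnectomeSet,
    LatentState,
    McmcConfig,
    ModelParameters,
    PosteriorSummary,
    PriorSpec,
    check_spd,
)

__all__ = [
    "connectivity_loglik",
    "behavior_loglik",
    "latent_logprior",
    "gibbs_sweep",
    "run_mcmc",
    "gelman_rubin",
    "split_rhat",
    "McmcDraws",
    "geweke_chains",
]

LOG_2PI = math.log(2.0 * math.pi)


def _as_connectome_values(C) -> np.ndarray:
    if isinstance(C, ConnectomeSet):
        return C.values
    return np.asarray(C, dtype=float)


def _as_behavior_values(B) -> np.ndarray:
    if isinstance(B, BehaviorTable):
        return B.values
    return np.asarray(B, dtype=float)


def connectivity_loglik(C, d, Gamma, tau2) -> float:
    """Gaussian log-likelihood of the edges given latent node positions.

    Sums log N(c_{x,y,j} | d_j + gamma_{x,j} gamma_{y,j}, tau2) over
    subjects j and unordered node pairs x < y (diagonal excluded).
    """
    vals = _as_connectome_values(C)
    d = np.asarray(d, dtype=float).ravel()
    Gamma = np.asarray(Gamma, dtype=float)
    tau2 = float(tau2)
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    n, v = Gamma.shape
    if vals.shape != (n, v, v):
        raise ValueError("connectome / Gamma shape mismatch")
    iu = np.triu_indices(v, k=1)
    cu = vals[:, iu[0], iu[1]]
    if not (np.all(np.isfinite(cu)) and np.all(np.isfinite(Gamma))
            and np.all(np.isfinite(d))):
        raise ValueError("non-finite inputs to connectivity_loglik")
    resid = cu - d[:, None] - Gamma[:, iu[0]] * Gamma[:, iu[1]]
    m = cu.size
    return float(-0.5 * m * (LOG_2PI + math.log(tau2))
                 - 0.5 * np.sum(resid ** 2) / tau2)


def behavior_loglik(B, e, kappa, sigma2) -> float:
    """Gaussian log-likelihood of observed behavior cells; missing cells
    (NaN) contribute nothing."""
    vals = _as_behavior_values(B)
    e = np.asarray(e, dtype=float).ravel()
    kappa = np.asarray(kappa, dtype=float).ravel()
    sigma2 = float(sigma2)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    obs = np.isfinite(vals)
    n_obs = int(obs.sum())
    if n_obs == 0:
        return 0.0
    resid = np.where(obs, vals - e[None, :] - kappa[:, None], 0.0)
    return float(-0.5 * n_obs * (LOG_2PI + math.log(sigma2))
                 - 0.5 * np.sum(resid ** 2) / sigma2)


def latent_logprior(Gamma, kappa, Sigma, mu=None) -> float:
    """Log density of the iid MVN prior on (gamma_j, kappa_j).

    The mean is (mu, 0) — the shared population connectivity pattern for
    the node positions and 0 for the latent behavior score (whose location
    is absorbed by the indicator intercepts).
    """
    Gamma = np.asarray(Gamma, dtype=float)
    kappa = np.asarray(kappa, dtype=float).ravel()
    Sigma = check_spd(Sigma)
    n, v = Gamma.shape
    if Sigma.shape[0] != v + 1:
        raise ValueError("Sigma must be (V+1) x (V+1)")
    if mu is not None:
        Gamma = Gamma - np.asarray(mu, dtype=float).ravel()[None, :]
    g = np.concatenate([Gamma, kappa[:, None]], axis=1)
    cf = cho_factor(Sigma + SPD_JITTER * np.eye(v + 1), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = np.sum(g * cho_solve(cf, g.T).T)
    return float(-0.5 * (n * ((v + 1) * LOG_2PI + logdet) + quad))


# ---------------------------------------------------------------------------
# Gibbs sampler internals


@dataclass
class _Workspace:
    """Precomputed index structures shared across sweeps."""

    iu0: np.ndarray
    iu1: np.ndarray
    cu: np.ndarray          # N x M upper-triangle edge values
    b0: np.ndarray          # behavior values with NaN -> 0
    obs: np.ndarray         # N x P observation mask
    nobs_row: np.ndarray    # per-subject observed indicator count
    nobs_col: np.ndarray    # per-indicator observed subject count

    @classmethod
    def build(cls, C: ConnectomeSet, B: BehaviorTable) -> "_Workspace":
        v = C.n_nodes
        iu0, iu1 = np.triu_indices(v, k=1)
        cu = C.values[:, iu0, iu1]
        obs = np.isfinite(B.values)
        b0 = np.where(obs, B.values, 0.0)
        return cls(iu0, iu1, cu, b0, obs,
                   obs.sum(axis=1).astype(float),
                   obs.sum(axis=0).astype(float))


def _inv_gamma_draw(shape: float, scale: float, rng: np.random.Generator) -> float:
    return scale / rng.gamma(shape)


def _check_prec(prec: np.ndarray, block: str) -> None:
    if not np.all(np.isfinite(prec)) or np.any(prec <= 0):
        raise RuntimeError(
            f"singular conditional covariance in block '{block}'"
        )


def gibbs_sweep(state: LatentState, params: ModelParameters,
                C: ConnectomeSet, B: BehaviorTable, priors: PriorSpec,
                rng: np.random.Generator,
                work: _Workspace | None = None
                ) -> tuple[LatentState, ModelParameters]:
    """One full blocked-Gibbs update of all latent variables and parameters.

    Each block is drawn from its exact full conditional, so a sweep leaves
    the joint posterior invariant.  Subjects whose behavior row is entirely
    missing receive kappa draws from the Gamma-conditional prior alone —
    this is what makes transductive prediction possible.
    """
    if work is None:
        work = _Workspace.build(C, B)
    n, v = state.Gamma.shape
    m = work.cu.shape[1]
    Gamma = state.Gamma.copy()
    kappa = state.kappa.copy()
    d = params.d.copy()
    e = params.e.copy()
    tau2 = params.tau2
    sigma2 = params.sigma2
    Sigma = params.Sigma
    mu = params.mu.copy()

    jit = SPD_JITTER * np.eye(v + 1)
    Q = np.linalg.inv(Sigma + jit)

    # --- Gamma, one node column at a time (sequential scan) ---------------
    rowsum = Gamma.sum(axis=1)
    sqnorm = np.sum(Gamma ** 2, axis=1)
    vals = C.values
    for node in range(v):
        g_v = Gamma[:, node]
        t = np.einsum("nu,nu->n", vals[:, node, :], Gamma)
        t -= d * (rowsum - g_v)
        s = sqnorm - g_v ** 2
        # prior conditional of gamma_v given the rest, from the precision Q
        full = (Gamma - mu[None, :]) @ Q[node, :v] + kappa * Q[node, v]
        prec = Q[node, node] + s / tau2
        _check_prec(prec, f"Gamma[:, {node}]")
        cond_mean = mu[node] - (full - Q[node, node] * (g_v - mu[node])) \
            / Q[node, node]
        mean = (Q[node, node] * cond_mean + t / tau2) / prec
        new = mean + rng.standard_normal(n) / np.sqrt(prec)
        rowsum += new - g_v
        sqnorm += new ** 2 - g_v ** 2
        Gamma[:, node] = new

    # --- per-subject sign-flip Metropolis (edge likelihood is invariant) --
    q_cross = Q[:v, v]
    u_mat = (Gamma - mu[None, :]) @ Q[:v, :v] + kappa[:, None] * q_cross
    term1 = np.sum(Gamma * u_mat, axis=1)
    term2 = np.sum(Gamma * (Gamma @ Q[:v, :v]), axis=1)
    log_ratio = 2.0 * (term1 - term2)
    flip = np.log(rng.uniform(size=n)) < log_ratio
    Gamma[flip] *= -1.0

    # --- kappa -------------------------------------------------------------
    qk = Q[v, v]
    prior_mean = -((Gamma - mu[None, :]) @ q_cross) / qk
    s_beh = np.sum((work.b0 - e[None, :]) * work.obs, axis=1)
    prec = qk + work.nobs_row / sigma2
    _check_prec(prec, "kappa")
    mean = (qk * prior_mean + s_beh / sigma2) / prec
    kappa = mean + rng.standard_normal(n) / np.sqrt(prec)

    # --- intercepts ---------------------------------------------------------
    prod = Gamma[:, work.iu0] * Gamma[:, work.iu1]
    resid_sum = np.sum(work.cu - prod, axis=1)
    prec_d = m / tau2 + 1.0 / priors.d_var
    d = (resid_sum / tau2 / prec_d
         + rng.standard_normal(n) / np.sqrt(prec_d))

    s_e = np.sum((work.b0 - kappa[:, None]) * work.obs, axis=0)
    prec_e = work.nobs_col / sigma2 + 1.0 / priors.e_var
    e = (s_e / sigma2 / prec_e
         + rng.standard_normal(e.shape[0]) / np.sqrt(prec_e))

    # --- noise variances ----------------------------------------------------
    sse = np.sum((work.cu - d[:, None] - prod) ** 2)
    tau2 = _inv_gamma_draw(priors.tau2_shape + 0.5 * n * m,
                           priors.tau2_scale + 0.5 * sse, rng)
    n_obs = work.obs.sum()
    if n_obs > 0:
        sse_b = np.sum(((work.b0 - e[None, :] - kappa[:, None])
                        * work.obs) ** 2)
        sigma2 = _inv_gamma_draw(priors.sigma2_shape + 0.5 * n_obs,
                                 priors.sigma2_scale + 0.5 * sse_b, rng)
    else:
        sigma2 = _inv_gamma_draw(priors.sigma2_shape,
                                 priors.sigma2_scale, rng)

    # --- latent position mean (shared population pattern) -------------------
    b_mu = Q[:v, :v] @ Gamma.sum(axis=0) + Q[:v, v] * kappa.sum()
    prec_mu = n * Q[:v, :v] + np.eye(v) / priors.mu_var
    chol_mu = np.linalg.cholesky(prec_mu)
    mean_mu = cho_solve((chol_mu, True), b_mu)
    mu = mean_mu + np.linalg.solve(chol_mu.T, rng.standard_normal(v))

    # --- latent covariance --------------------------------------------------
    g = np.concatenate([Gamma - mu[None, :], kappa[:, None]], axis=1)
    scale = priors.sigma_scale + g.T @ g
    Sigma = invwishart.rvs(df=priors.sigma_df + n, scale=scale,
                           random_state=rng)
    Sigma = np.asarray(Sigma, dtype=float)

    new_state = LatentState(Gamma, kappa)
    new_params = ModelParameters(d, e, tau2, sigma2, Sigma, mu)
    return new_state, new_params


@dataclass
class McmcDraws:
    """Retained traces from one run (post burn-in, thinned)."""

    node_cov: np.ndarray      # S x V, Sigma[v, V] per draw
    tau2: np.ndarray          # S
    sigma2: np.ndarray        # S
    kappa: np.ndarray         # S x N
    e: np.ndarray             # S x P
    loglik: np.ndarray        # S
    kappa_var: np.ndarray     # S, Sigma[V, V] per draw


def _init_state(C: ConnectomeSet, B: BehaviorTable, work: _Workspace,
                rng: np.random.Generator, jitter: float = 0.1
                ) -> tuple[LatentState, ModelParameters]:
    """Spectral initialization with behavior-guided sign alignment.

    Each subject's latent vector starts at the rank-1 (leading eigenpair)
    fit of their centered connectome.  Per-subject eigenvector signs are
    free, and a disordered sign assignment is a deep local mode of the
    posterior, so signs are aligned to the shared population pattern by a
    few power-iteration passes.  Seeded jitter keeps independent
    initializations distinct.
    """
    n, v = C.n_subjects, C.n_nodes
    with np.errstate(invalid="ignore"):
        e0 = np.where(work.nobs_col > 0,
                      np.sum(work.b0, axis=0)
                      / np.maximum(work.nobs_col, 1.0), 0.0)
    # crude latent behavior score: mean observed indicator residual
    with np.errstate(invalid="ignore"):
        kappa0 = (np.sum((work.b0 - e0[None, :]) * work.obs, axis=1)
                  / np.maximum(work.nobs_row, 1.0))

    # per-subject rank-1 fit c = d_j + gamma gamma^T: the intercept is
    # confounded with the latent scale, so alternate eigen extraction
    # (with diagonal imputation) and intercept refinement
    gam = np.empty((n, v))
    d0 = np.zeros(n)
    for j in range(n):
        mat = C.values[j].copy()
        w, u = np.linalg.eigh(mat)
        lead = np.argmax(np.abs(w))
        g = np.sqrt(max(abs(w[lead]), 1e-6)) * u[:, lead]
        dj = 0.0
        for _ in range(8):
            m2 = C.values[j] - dj
            np.fill_diagonal(m2, g ** 2)
            w, u = np.linalg.eigh(m2)
            lead = np.argmax(w)
            g = np.sqrt(max(w[lead], 1e-6)) * u[:, lead]
            dj = float(np.mean(work.cu[j]
                               - g[work.iu0] * g[work.iu1]))
        gam[j] = g
        d0[j] = dj

    # per-subject eigenvector signs are arbitrary; choosing them to share a
    # common population direction is a Z2-synchronization problem, solved
    # spectrally via the leading eigenvector of the subject Gram matrix
    gram = gam @ gam.T
    w, u = np.linalg.eigh(gram)
    s = np.where(u[:, -1] >= 0.0, 1.0, -1.0)
    gam *= s[:, None]
    mu0 = gam.mean(axis=0)

    gam += jitter * rng.standard_normal((n, v))
    kappa0 = kappa0 + jitter * rng.standard_normal(n)
    g = np.concatenate([gam - mu0[None, :], kappa0[:, None]], axis=1)
    sigma0 = g.T @ g / max(n, 2) + 0.1 * np.eye(v + 1)
    state = LatentState(gam, kappa0)
    params = ModelParameters(d0, e0, 1.0, 1.0, sigma0, mu0)
    return state, params


def run_mcmc(C: ConnectomeSet, B: BehaviorTable, config: McmcConfig,
             priors: PriorSpec | None = None,
             init: tuple[LatentState, ModelParameters] | None = None
             ) -> tuple[PosteriorSummary, McmcDraws]:
    """Run the Gibbs sampler: burn-in, then retain thinned draws.

    Reproducible bit-for-bit for a fixed ``config.seed``.  The summary's
    ``node_covariances`` are the posterior means of Sigma[v, V] — the
    node-behavior covariances used downstream as biomarker strengths.
    """
    if B.n_subjects != C.n_subjects:
        raise ValueError("connectome and behavior subject counts differ")
    v = C.n_nodes
    n = C.n_subjects
    p = B.n_indicators
    priors = (priors or PriorSpec()).resolve(v)
    rng = np.random.default_rng(config.seed)
    work = _Workspace.build(C, B)
    state, params = init if init is not None else _init_state(C, B, work, rng)

    for it in range(config.n_burn):
        state, params = gibbs_sweep(state, params, C, B, priors, rng, work)

    s_keep = config.n_samples
    draws = McmcDraws(
        node_cov=np.empty((s_keep, v)),
        tau2=np.empty(s_keep),
        sigma2=np.empty(s_keep),
        kappa=np.empty((s_keep, n)),
        e=np.empty((s_keep, p)),
        loglik=np.empty(s_keep),
        kappa_var=np.empty(s_keep),
    )
    d_sum = np.zeros(n)
    d_sumsq = np.zeros(n)
    sigma_sum = np.zeros((v + 1, v + 1))
    sigma_sumsq = np.zeros((v + 1, v + 1))
    cross_ref = np.zeros(v)

    kept = 0
    for it in range(s_keep * config.thin):
        state, params = gibbs_sweep(state, params, C, B, priors, rng, work)
        if (it + 1) % config.thin:
            continue
        if not (np.isfinite(params.tau2) and np.isfinite(params.sigma2)):
            raise RuntimeError(
                f"numerical overflow at post-burn iteration {it}"
            )
        cross = params.Sigma[:v, v]
        # reflection alignment: (Gamma, cross) -> (-Gamma, -cross) is an
        # exact model symmetry, so draws are oriented to a running
        # reference to stop the two modes cancelling in the average
        if kept > 0 and float(cross @ cross_ref) < 0.0:
            cross = -cross
            cross_sign = -1.0
        else:
            cross_sign = 1.0
        cross_ref += cross
        draws.node_cov[kept] = cross
        draws.tau2[kept] = params.tau2
        draws.sigma2[kept] = params.sigma2
        draws.kappa[kept] = state.kappa
        draws.e[kept] = params.e
        draws.kappa_var[kept] = params.Sigma[v, v]
        draws.loglik[kept] = (
            connectivity_loglik(C, params.d, state.Gamma, params.tau2)
            + behavior_loglik(B, params.e, state.kappa, params.sigma2)
        )
        d_sum += params.d
        d_sumsq += params.d ** 2
        sig = params.Sigma.copy()
        sig[:v, v] *= cross_sign
        sig[v, :v] *= cross_sign
        sigma_sum += sig
        sigma_sumsq += sig ** 2
        kept += 1

    # deterministic global orientation: net node-behavior covariance >= 0
    if float(draws.node_cov.sum()) < 0.0:
        draws.node_cov *= -1.0
        sigma_flip = np.ones((v + 1, v + 1))
        sigma_flip[:v, v] = -1.0
        sigma_flip[v, :v] = -1.0
        sigma_sum *= sigma_flip

    node_cov_mean = draws.node_cov.mean(axis=0)
    s = float(kept)
    d_mean = d_sum / s
    sigma_mean = sigma_sum / s

    def _sd(sumsq, mean):
        return np.sqrt(np.maximum(sumsq / s - mean ** 2, 0.0))

    nsplit = config.n_chains_for_rhat

    def _safe_rhat(trace):
        try:
            return split_rhat(trace, nsplit)
        except ValueError:       # trace too short to split
            return float("nan")

    rhat = {
        "tau2": _safe_rhat(draws.tau2),
        "sigma2": _safe_rhat(draws.sigma2),
        "node_covariances": np.array(
            [_safe_rhat(draws.node_cov[:, j]) for j in range(v)]
        ),
    }
    rhat["mean_node_cov"] = float(np.mean(rhat["node_covariances"]))

    summary = PosteriorSummary(
        node_covariances=node_cov_mean,
        param_means={
            "d": d_mean,
            "e": draws.e.mean(axis=0),
            "tau2": float(draws.tau2.mean()),
            "sigma2": float(draws.sigma2.mean()),
            "Sigma": sigma_mean,
            "kappa": draws.kappa.mean(axis=0),
        },
        param_sds={
            "d": _sd(d_sumsq, d_mean),
            "e": draws.e.std(axis=0),
            "tau2": float(draws.tau2.std()),
            "sigma2": float(draws.sigma2.std()),
            "Sigma": _sd(sigma_sumsq, sigma_mean),
        },
        rhat=rhat,
        loglik_trace=draws.loglik,
        node_ids=list(C.node_ids),
    )
    return summary, draws


# ---------------------------------------------------------------------------
# Convergence diagnostics


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor (R-hat) for >= 2 equal-length chains.

    Returns 1.0 when the total variance is exactly zero (all chains constant
    and equal).
    """
    chains = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    length = len(chains[0])
    if any(len(c) != length for c in chains):
        raise ValueError("chains must have equal lengths")
    if length < 10:
        raise ValueError("chains must have length >= 10")
    arr = np.stack(chains)
    w = arr.var(axis=1, ddof=1).mean()
    b_over_n = arr.mean(axis=1).var(ddof=1)
    if w == 0.0 and b_over_n == 0.0:
        return 1.0
    if w == 0.0:
        return float("inf")
    var_hat = (length - 1) / length * w + b_over_n
    return float(np.sqrt(var_hat / w))


def split_rhat(trace, n_split: int = 2) -> float:
    """Split one trace into ``n_split`` consecutive segments and apply the
    Gelman-Rubin statistic — the single-chain variant of R-hat."""
    trace = np.asarray(trace, dtype=float).ravel()
    seg = len(trace) // n_split
    if seg < 10:
        raise ValueError("trace too short to split")
    chains = [trace[i * seg:(i + 1) * seg] for i in range(n_split)]
    return gelman_rubin(chains)


# ---------------------------------------------------------------------------
# Sampler validation (Geweke-style joint-distribution test)


def _draw_from_prior(n: int, v: int, p: int, priors: PriorSpec,
                     rng: np.random.Generator
                     ) -> tuple[LatentState, ModelParameters]:
    tau2 = _inv_gamma_draw(priors.tau2_shape, priors.tau2_scale, rng)
    sigma2 = _inv_gamma_draw(priors.sigma2_shape, priors.sigma2_scale, rng)
    Sigma = np.asarray(invwishart.rvs(df=priors.sigma_df,
                                      scale=priors.sigma_scale,
                                      random_state=rng), dtype=float)
    d = rng.normal(0.0, math.sqrt(priors.d_var), size=n)
    e = rng.normal(0.0, math.sqrt(priors.e_var), size=p)
    mu = rng.normal(0.0, math.sqrt(priors.mu_var), size=v)
    chol = np.linalg.cholesky(Sigma + SPD_JITTER * np.eye(v + 1))
    g = rng.standard_normal((n, v + 1)) @ chol.T
    g[:, :v] += mu[None, :]
    return (LatentState(g[:, :v], g[:, v]),
            ModelParameters(d, e, tau2, sigma2, Sigma, mu))


def _draw_data(state: LatentState, params: ModelParameters, p: int,
               rng: np.random.Generator
               ) -> tuple[ConnectomeSet, BehaviorTable]:
    n, v = state.Gamma.shape
    iu0, iu1 = np.triu_indices(v, k=1)
    mean = (params.d[:, None]
            + state.Gamma[:, iu0] * state.Gamma[:, iu1])
    cu = mean + math.sqrt(params.tau2) * rng.standard_normal(mean.shape)
    mats = np.zeros((n, v, v))
    mats[:, iu0, iu1] = cu
    mats += mats.transpose(0, 2, 1)
    b = (params.e[None, :] + state.kappa[:, None]
         + math.sqrt(params.sigma2) * rng.standard_normal((n, p)))
    return ConnectomeSet(mats), BehaviorTable(b)


def _geweke_stats(params: ModelParameters, v: int
                  ) -> tuple[float, float, float, float]:
    corr = params.Sigma[0, v] / math.sqrt(params.Sigma[0, 0]
                                          * params.Sigma[v, v])
    return (math.log(params.tau2), math.log(params.sigma2), corr,
            float(params.mu[0]))


def geweke_chains(v: int = 4, n: int = 8, p: int = 2, n_iter: int = 20000,
                  priors: PriorSpec | None = None, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Joint-distribution validation of the Gibbs transition kernel.

    Two ways of sampling the prior-predictive joint distribution must agree:
    the *marginal-conditional* sampler draws parameters directly from the
    prior, while the *successive-conditional* sampler alternates drawing
    data given parameters with one Gibbs sweep given the data.  Returns two
    ``n_iter x 4`` statistic arrays (log tau2, log sigma2, node-behavior
    latent correlation, first latent-mean coordinate); a bug in any full conditional shifts the second
    relative to the first.

    Statistics are reported on transformed scales with finite prior
    variance, so their Monte-Carlo means are well-behaved.
    """
    priors = (priors or PriorSpec()).resolve(v)
    rng = np.random.default_rng(seed)

    stats_m = np.empty((n_iter, 4))
    for i in range(n_iter):
        _, params = _draw_from_prior(n, v, p, priors, rng)
        stats_m[i] = _geweke_stats(params, v)

    rng2 = np.random.default_rng(seed + 1)
    state, params = _draw_from_prior(n, v, p, priors, rng2)
    stats_s = np.empty((n_iter, 4))
    for i in range(n_iter):
        C, B = _draw_data(state, params, p, rng2)
        state, params = gibbs_sweep(state, params, C, B, priors, rng2)
        stats_s[i] = _geweke_stats(params, v)
    return stats_m, stats_s
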