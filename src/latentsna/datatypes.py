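"""Core data containers for the joint connectome-behavior model.

The model couples, for each subject j, a symmetric V x V functional
connectivity matrix (Fisher-z of Pearson correlations between node time
series) with P behavioral indicators measuring one unidimensional
construct.  Edge weights are generated by a rank-1 latent eigenmodel

    c_{x,y,j} = d_j + gamma_{x,j} * gamma_{y,j} + eps,   eps ~ N(0, tau2)

for unordered node pairs x < y, behaviors by

    b_{j,p} = e_p + kappa_j + nu,                        nu ~ N(0, sigma2)

and the per-subject latent vector (gamma_{1..V,j}, kappa_j) is drawn iid
from MVN(0, Sigma) with Sigma a (V+1) x (V+1) covariance whose last
row/column couples node positions to the latent behavior score kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConnectomeSet",
    "BehaviorTable",
    "ModelParameters",
    "LatentState",
    "McmcConfig",
    "PriorSpec",
    "PosteriorSummary",
    "check_spd",
]

#: relative eigenvalue tolerance for symmetric positive-definite checks
SPD_RTOL = 1e-8
#: jitter added to diagonals before Cholesky factorization
SPD_JITTER = 1e-8


def check_spd(Sigma: np.ndarray, name: str = "Sigma") -> np.ndarray:
    """Validate that ``Sigma`` is symmetric positive-definite within tolerance.

    Returns the symmetrized matrix.  Raises ``ValueError`` otherwise.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
        raise ValueError(f"{name} must be square, got shape {Sigma.shape}")
    if not np.allclose(Sigma, Sigma.T, atol=1e-8, rtol=1e-6):
        raise ValueError(f"{name} is not symmetric")
    Sigma = 0.5 * (Sigma + Sigma.T)
    w = np.linalg.eigvalsh(Sigma)
    if w[0] <= -SPD_RTOL * max(w[-1], 1.0):
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {w[0]:.3g})"
        )
    return Sigma


@dataclass
class ConnectomeSet:
    """Stack of N symmetric V x V Fisher-z connectivity matrices, one condition.

    Diagonals carry no information under the edge model (only pairs x < y
    enter the likelihood) and are stored as 0 by convention.
    """

    values: np.ndarray
    node_ids: Sequence[str] | None = None
    subject_ids: Sequence[str] | None = None
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(
                f"values must be N x V x V, got shape {self.values.shape}"
            )
        n, v = self.values.shape[:2]
        if v < 3:
            raise ValueError(f"need V >= 3 nodes, got V={v}")
        off = self.values[:, ~np.eye(v, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("non-finite off-diagonal connectivity values")
        if not np.allclose(self.values, self.values.transpose(0, 2, 1),
                           atol=1e-6, rtol=0.0):
            raise ValueError("connectivity matrices must be symmetric")
        self.values = 0.5 * (self.values + self.values.transpose(0, 2, 1))
        self.values[:, np.arange(v), np.arange(v)] = 0.0
        if self.node_ids is None:
            self.node_ids = [str(i + 1) for i in range(v)]
        if self.subject_ids is None:
            self.subject_ids = [f"s{j + 1}" for j in range(n)]
        self.node_ids = list(map(str, self.node_ids))
        self.subject_ids = list(map(str, self.subject_ids))
        if len(self.node_ids) != v:
            raise ValueError("node_ids length does not match V")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match N")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class BehaviorTable:
    """N x P indicator matrix for one behavioral category; NaN marks missing."""

    values: np.ndarray
    indicator_names: Sequence[str] | None = None
    category: str = "behavior"
    subject_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("behavior values must be N x P")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("need at least one indicator")
        if self.indicator_names is None:
            self.indicator_names = [f"ind{k + 1}" for k in range(p)]
        if self.subject_ids is None:
            self.subject_ids = [f"s{j + 1}" for j in range(n)]
        self.indicator_names = list(map(str, self.indicator_names))
        self.subject_ids = list(map(str, self.subject_ids))
        if len(self.indicator_names) != p:
            raise ValueError("indicator_names length does not match P")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match N")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def mask_subjects(self, subject_ids: Sequence[str]) -> "BehaviorTable":
        """Return a copy with the given subjects' rows set to missing."""
        idx = [self.subject_ids.index(str(s)) for s in subject_ids]
        vals = self.values.copy()
        vals[idx, :] = np.nan
        return BehaviorTable(vals, self.indicator_names, self.category,
                             self.subject_ids)


@dataclass
class ModelParameters:
    """Global parameters: intercepts, noise variances and latent covariance.

    ``mu`` is the mean of the latent node positions — the shared population
    connectivity pattern; the latent behavior score kappa is centered at 0
    (its location is absorbed by the indicator intercepts e).
    """

    d: np.ndarray       # per-subject connectivity intercept, length N
    e: np.ndarray       # per-indicator behavior intercept, length P
    tau2: float         # edge noise variance
    sigma2: float       # behavior noise variance
    Sigma: np.ndarray   # (V+1) x (V+1) latent covariance
    mu: np.ndarray | None = None   # latent position mean, length V

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float).ravel()
        self.e = np.asarray(self.e, dtype=float).ravel()
        self.tau2 = float(self.tau2)
        self.sigma2 = float(self.sigma2)
        if self.tau2 <= 0 or self.sigma2 <= 0:
            raise ValueError("tau2 and sigma2 must be positive")
        self.Sigma = check_spd(self.Sigma)
        v = self.Sigma.shape[0] - 1
        if self.mu is None:
            self.mu = np.zeros(v)
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        if self.mu.shape[0] != v:
            raise ValueError("mu length must equal the node count V")


@dataclass
class LatentState:
    """Latent node positions Gamma (N x V) and behavior scores kappa (N,)."""

    Gamma: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float).ravel()
        if self.Gamma.ndim != 2:
            raise ValueError("Gamma must be N x V")
        if self.kappa.shape[0] != self.Gamma.shape[0]:
            raise ValueError("kappa length must match Gamma rows")
        if not (np.all(np.isfinite(self.Gamma))
                and np.all(np.isfinite(self.kappa))):
            raise ValueError("latent state must be finite")


@dataclass
class McmcConfig:
    """Sampler run lengths and seeding.

    Defaults follow the study protocol: 5000 burn-in sweeps, 15,000 retained
    samples, 10 random initializations.
    """

    n_burn: int = 5000
    n_samples: int = 15000
    thin: int = 1
    n_inits: int = 10
    seed: int = 0
    n_chains_for_rhat: int = 2

    def __post_init__(self) -> None:
        if self.n_burn < 0:
            raise ValueError("n_burn must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_inits < 1:
            raise ValueError("n_inits must be >= 1")
        if self.n_chains_for_rhat < 2:
            raise ValueError("n_chains_for_rhat must be >= 2")

    def replace(self, **kw) -> "McmcConfig":
        from dataclasses import replace
        return replace(self, **kw)


@dataclass
class PriorSpec:
    """Weakly informative conjugate priors enabling a pure Gibbs sampler.

    d_j ~ N(0, d_var), e_p ~ N(0, e_var), mu_v ~ N(0, mu_var), tau2 and
    sigma2 ~ InvGamma(shape, scale), Sigma ~ InvWishart(sigma_df,
    sigma_scale).  When ``sigma_df`` or
    ``sigma_scale`` is None they default to V+3 and the identity, the
    smallest proper choice keeping the prior diffuse.
    """

    d_var: float = 100.0
    e_var: float = 100.0
    mu_var: float = 100.0
    tau2_shape: float = 2.0
    tau2_scale: float = 1.0
    sigma2_shape: float = 2.0
    sigma2_scale: float = 1.0
    sigma_df: float | None = None
    sigma_scale: np.ndarray | None = None

    def resolve(self, v: int) -> "PriorSpec":
        """Fill dimension-dependent defaults for a V-node problem."""
        df = self.sigma_df if self.sigma_df is not None else v + 3
        scale = (np.asarray(self.sigma_scale, dtype=float)
                 if self.sigma_scale is not None else np.eye(v + 1))
        if df <= v:
            raise ValueError("sigma_df must exceed the latent dimension")
        if scale.shape != (v + 1, v + 1):
            raise ValueError("sigma_scale must be (V+1) x (V+1)")
        return PriorSpec(self.d_var, self.e_var, self.mu_var,
                         self.tau2_shape, self.tau2_scale,
                         self.sigma2_shape, self.sigma2_scale, df, scale)


@dataclass
class PosteriorSummary:
    """Posterior summaries of one MCMC run.

    ``node_covariances`` is the posterior mean of Sigma[v, V] for each node
    v — the node-behavior covariance that serves as the biomarker-strength
    estimate.
    """

    node_covariances: np.ndarray
    param_means: dict = field(default_factory=dict)
    param_sds: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    loglik_trace: np.ndarray | None = None
    node_ids: Sequence[str] | None = None
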