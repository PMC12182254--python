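"""Forward simulation of connectome + behavior datasets under the joint model.

The generator runs the generative equations forward: latent vectors
(gamma_j, kappa_j) ~ MVN(0, Sigma), edges from the rank-1 eigenmodel with
Gaussian noise tau2, behavior indicators from the latent score kappa with
noise sigma2.  The cross-covariance block of Sigma is planted on a chosen
set of "biomarker" nodes, which is what makes behavior predictable from
connectivity — and recoverable by the sampler.

Defaults mirror the planted-recovery study conditions: V=30 nodes, N=150
subjects, P=4 indicators, 10 biomarker nodes with cross-covariance 0.3 and
noise variances tau2 = sigma2 = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import BehaviorTable, ConnectomeSet, LatentState, \
    ModelParameters, check_spd

__all__ = [
    "SimulationDesign",
    "MultiConditionDesign",
    "GroundTruth",
    "build_sigma",
    "simulate_dataset",
    "simulate_conditions",
    "theoretical_ceiling",
    "make_atlas",
    "simulate_timeseries",
    "SHEN_SYSTEMS",
]

#: the ten functional-system labels of the Shen-268 style parcellation
SHEN_SYSTEMS = (
    "MedialFrontal", "Frontoparietal", "DefaultMode", "Motor",
    "VisualI", "VisualII", "VisualAssociation", "Limbic",
    "BasalGanglia", "Cerebellum",
)


@dataclass
class SimulationDesign:
    """Parameters of one simulated condition.

    ``cross_cov`` is the Sigma[v, V] entry for every node in
    ``biomarker_nodes`` (0-based indices); all other node-behavior
    covariances are zero.  ``gamma_mean`` is the shared population
    connectivity pattern (every node position centered there), which is
    what anchors the per-subject latent sign and makes behavior
    predictable from a new subject's connectome.  ``d_spread`` /
    ``e_spread`` are the standard deviations of the subject and indicator
    intercepts.
    """

    V: int = 30
    N: int = 150
    P: int = 4
    biomarker_nodes: Sequence[int] = field(default_factory=lambda: range(10))
    cross_cov: float = 0.3
    gamma_mean: float = 1.0
    gamma_var: float = 1.0
    kappa_var: float = 1.0
    tau2: float = 0.5
    sigma2: float = 0.5
    d_spread: float = 0.5
    e_spread: float = 0.5
    seed: int = 0
    condition: str = "sim"
    dense_sigma: bool = False

    def __post_init__(self) -> None:
        self.biomarker_nodes = sorted(int(b) for b in self.biomarker_nodes)
        if self.biomarker_nodes and (self.biomarker_nodes[0] < 0
                                     or self.biomarker_nodes[-1] >= self.V):
            raise ValueError("biomarker node indices out of range")
        for name in ("gamma_var", "kappa_var", "tau2", "sigma2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MultiConditionDesign:
    """Several conditions sharing subjects, behaviors and the latent score.

    All designs must agree on N, P, kappa_var and sigma2 so a single
    (kappa, behavior) draw is valid across conditions; only the connectome
    side (biomarker sets, cross-covariance, edge noise) may differ.
    """

    conditions: Sequence[tuple[str, SimulationDesign]]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("need at least one condition")
        ref = self.conditions[0][1]
        for label, des in self.conditions:
            if (des.N, des.P) != (ref.N, ref.P):
                raise ValueError(f"condition '{label}': N/P misaligned")
            if not math.isclose(des.kappa_var, ref.kappa_var):
                raise ValueError(f"condition '{label}': kappa_var differs")
            if not math.isclose(des.sigma2, ref.sigma2):
                raise ValueError(f"condition '{label}': sigma2 differs")


@dataclass
class GroundTruth:
    """Generating quantities saved alongside a simulated dataset."""

    state: LatentState
    params: ModelParameters
    design: SimulationDesign

    @property
    def node_covariances(self) -> np.ndarray:
        v = self.design.V
        return self.params.Sigma[:v, v]


def build_sigma(design: SimulationDesign) -> np.ndarray:
    """Latent covariance with the planted cross block; validated SPD.

    With diagonal node block, SPD requires
    |cross_cov| < sqrt(gamma_var * kappa_var / n_biomarkers).
    """
    v = design.V
    sigma = np.zeros((v + 1, v + 1))
    np.fill_diagonal(sigma, design.gamma_var)
    sigma[v, v] = design.kappa_var
    bio = list(design.biomarker_nodes)
    sigma[bio, v] = design.cross_cov
    sigma[v, bio] = design.cross_cov
    if design.dense_sigma:
        # random SPD node block with the same controlled cross block
        rng = np.random.default_rng(design.seed + 7)
        a = rng.standard_normal((v, v)) / math.sqrt(v)
        sigma[:v, :v] += 0.3 * (a @ a.T)
    try:
        return check_spd(sigma, "simulated Sigma")
    except ValueError as exc:
        nb = max(len(bio), 1)
        bound = math.sqrt(design.gamma_var * design.kappa_var / nb)
        raise ValueError(
            f"cross_cov {design.cross_cov} too large for SPD Sigma: "
            f"feasible bound is |cross_cov| < {bound:.4g} with "
            f"{len(bio)} biomarker nodes"
        ) from exc


def theoretical_ceiling(design: SimulationDesign) -> float:
    """Maximum predicted-vs-observed correlation attainable for one indicator.

    In the noiseless-connectome limit the best Gamma-based predictor of a
    behavior indicator is E[kappa | gamma]; its correlation with
    b = e + kappa + noise is

        sqrt(S_kg S_gg^{-1} S_gk) / sqrt(S_kk + sigma2)

    in terms of the blocks of the latent covariance.
    """
    sigma = build_sigma(design)
    v = design.V
    s_gg = sigma[:v, :v]
    s_gk = sigma[:v, v]
    explained = float(s_gk @ np.linalg.solve(s_gg, s_gk))
    return math.sqrt(explained) / math.sqrt(sigma[v, v] + design.sigma2)


def _edges_from_latents(Gamma: np.ndarray, d: np.ndarray, tau2: float,
                        rng: np.random.Generator) -> np.ndarray:
    n, v = Gamma.shape
    iu0, iu1 = np.triu_indices(v, k=1)
    mean = d[:, None] + Gamma[:, iu0] * Gamma[:, iu1]
    cu = mean + math.sqrt(tau2) * rng.standard_normal(mean.shape)
    mats = np.zeros((n, v, v))
    mats[:, iu0, iu1] = cu
    mats += mats.transpose(0, 2, 1)
    return mats


def simulate_dataset(design: SimulationDesign
                     ) -> tuple[ConnectomeSet, BehaviorTable, GroundTruth]:
    """Run the generative equations forward for one condition."""
    sigma = build_sigma(design)
    v, n, p = design.V, design.N, design.P
    rng = np.random.default_rng(design.seed)
    chol = np.linalg.cholesky(sigma)
    g = rng.standard_normal((n, v + 1)) @ chol.T
    mu = np.full(v, design.gamma_mean)
    Gamma, kappa = g[:, :v] + mu[None, :], g[:, v]
    d = rng.normal(0.0, design.d_spread, size=n)
    e = rng.normal(0.0, design.e_spread, size=p)
    mats = _edges_from_latents(Gamma, d, design.tau2, rng)
    b = (e[None, :] + kappa[:, None]
         + math.sqrt(design.sigma2) * rng.standard_normal((n, p)))
    C = ConnectomeSet(mats, condition=design.condition)
    B = BehaviorTable(b, category="sim_category",
                      subject_ids=C.subject_ids)
    truth = GroundTruth(LatentState(Gamma, kappa),
                        ModelParameters(d, e, design.tau2, design.sigma2,
                                        sigma, mu),
                        design)
    return C, B, truth


def simulate_conditions(multi: MultiConditionDesign
                        ) -> tuple[dict[str, ConnectomeSet], BehaviorTable,
                                   dict[str, GroundTruth]]:
    """Simulate several conditions with a single shared kappa/behavior draw.

    kappa is drawn once; each condition's node positions are drawn from the
    conditional MVN of gamma given kappa under that condition's Sigma, so
    the same latent score expresses itself through different (possibly
    disjoint) biomarker sets across conditions.
    """
    ref = multi.conditions[0][1]
    n, p = ref.N, ref.P
    rng = np.random.default_rng(multi.seed)
    kappa = rng.normal(0.0, math.sqrt(ref.kappa_var), size=n)
    e = rng.normal(0.0, ref.e_spread, size=p)
    b = (e[None, :] + kappa[:, None]
         + math.sqrt(ref.sigma2) * rng.standard_normal((n, p)))

    connectomes: dict[str, ConnectomeSet] = {}
    truths: dict[str, GroundTruth] = {}
    behavior: BehaviorTable | None = None
    for label, design in multi.conditions:
        sigma = build_sigma(design)
        v = design.V
        s_gg, s_gk, s_kk = sigma[:v, :v], sigma[:v, v], sigma[v, v]
        mu = np.full(v, design.gamma_mean)
        cond_mean = mu[None, :] + np.outer(kappa, s_gk) / s_kk
        cond_cov = s_gg - np.outer(s_gk, s_gk) / s_kk
        chol = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(v))
        Gamma = cond_mean + rng.standard_normal((n, v)) @ chol.T
        d = rng.normal(0.0, design.d_spread, size=n)
        mats = _edges_from_latents(Gamma, d, design.tau2, rng)
        C = ConnectomeSet(mats, condition=label)
        if behavior is None:
            behavior = BehaviorTable(b, category="sim_category",
                                     subject_ids=C.subject_ids)
        connectomes[label] = C
        truths[label] = GroundTruth(
            LatentState(Gamma, kappa),
            ModelParameters(d, e, design.tau2, design.sigma2, sigma, mu),
            design)
    assert behavior is not None
    return connectomes, behavior, truths


def make_atlas(v: int, systems: Sequence[str] = SHEN_SYSTEMS,
               seed: int | None = None) -> pd.DataFrame:
    """Synthetic node -> functional-system table for a V-node parcellation.

    Nodes are assigned to the given systems in round-robin order (or
    shuffled when ``seed`` is given), with synthetic unit-sphere coordinates
    for plotting.  1-based node ids matching connectome node order.
    """
    labels = [systems[i % len(systems)] for i in range(v)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        labels = list(rng.permutation(labels))
    theta = 2.0 * np.pi * np.arange(v) / v
    return pd.DataFrame({
        "node_id": np.arange(1, v + 1),
        "system": labels,
        "x": np.cos(theta),
        "y": np.sin(theta),
        "z": np.linspace(-1.0, 1.0, v),
    })


def simulate_timeseries(t: int, v: int, seed: int = 0,
                        correlation: np.ndarray | None = None) -> np.ndarray:
    """Minimal white-noise node time series (T x V) to exercise the
    correlation/Fisher-z constructor; optionally with a target correlation."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((t, v))
    if correlation is None:
        return z
    corr = check_spd(correlation, "correlation")
    return z @ np.linalg.cholesky(corr).T
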