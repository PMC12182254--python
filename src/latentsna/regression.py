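"""Dummy-variable OLS comparisons of accuracy across fMRI conditions and of
covariance magnitude across functional systems.

With condition dummies as the only regressors, the intercept equals the
reference condition's mean accuracy and each coefficient equals that
condition's mean minus the reference mean; both regressions are reported
descriptively (coefficients and R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ConditionRegressionResult",
    "SystemRegressionResult",
    "fit_condition_regression",
    "network_covariance_regression",
]


@dataclass
class ConditionRegressionResult:
    """Accuracy ~ condition dummies, one behavioral category."""

    reference_condition: str
    beta0: float
    betas: dict = field(default_factory=dict)   # condition -> coefficient
    r2: float = 0.0
    n_obs: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("(intercept)", self.beta0)]
        rows += sorted(self.betas.items())
        df = pd.DataFrame(rows, columns=["term", "coefficient"])
        df["reference"] = self.reference_condition
        df["r2"] = self.r2
        df["n_obs"] = self.n_obs
        return df


@dataclass
class SystemRegressionResult:
    """|node covariance| ~ functional-system dummies."""

    reference_system: str
    intercept: float
    coefficients: dict = field(default_factory=dict)
    r2: float = 0.0
    n_obs: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("(intercept)", self.intercept)]
        rows += sorted(self.coefficients.items())
        df = pd.DataFrame(rows, columns=["term", "coefficient"])
        df["reference"] = self.reference_system
        df["r2"] = self.r2
        return df


def _dummy_ols(y: np.ndarray, groups: pd.Series, reference: str
               ) -> tuple[float, dict, float]:
    levels = [g for g in pd.unique(groups) if g != reference]
    dummies = pd.DataFrame(
        {g: (groups == g).astype(float).to_numpy() for g in levels})
    x = sm.add_constant(dummies, has_constant="add")
    fit = sm.OLS(y, x).fit()
    beta0 = float(fit.params["const"])
    betas = {g: float(fit.params[g]) for g in levels}
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):        # zero total sum of squares
        r2 = 0.0
    return beta0, betas, r2


def fit_condition_regression(table: pd.DataFrame, category: str,
                             reference: str = "Rest1"
                             ) -> ConditionRegressionResult:
    """OLS of prediction accuracy on fMRI-condition dummy indicators.

    ``table`` is a long-format accuracy table with columns (condition,
    category, indicator, repeat, accuracy); every accuracy record of the
    category (one per indicator x repeat x condition) is an observation.
    Undefined accuracies (NaN) are excluded.
    """
    sub = table[table["category"] == category]
    if sub.empty:
        raise ValueError(f"category '{category}' not present in the table")
    sub = sub[np.isfinite(sub["accuracy"].to_numpy(dtype=float))]
    conditions = pd.unique(sub["condition"])
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to regress on")
    if reference not in set(conditions):
        raise ValueError(f"reference condition '{reference}' absent")
    y = sub["accuracy"].to_numpy(dtype=float)
    beta0, betas, r2 = _dummy_ols(y, sub["condition"].reset_index(drop=True),
                                  reference)
    return ConditionRegressionResult(reference, beta0, betas, r2, len(sub))


def network_covariance_regression(node_covariances, atlas
                                  ) -> SystemRegressionResult:
    """OLS of |node-behavior covariance| on functional-system dummies.

    ``atlas`` maps every node to a system (an AtlasMap or a node-ordered
    sequence of system labels).  Reference system = first alphabetically.
    """
    cov = np.abs(np.asarray(node_covariances, dtype=float).ravel())
    labels = _systems_in_node_order(atlas, len(cov))
    groups = pd.Series(labels)
    reference = sorted(groups.unique())[0]
    intercept, coefs, r2 = _dummy_ols(cov, groups, reference)
    return SystemRegressionResult(reference, intercept, coefs, r2, len(cov))


def _systems_in_node_order(atlas, v: int) -> list[str]:
    from .biomarkers import AtlasMap
    if isinstance(atlas, AtlasMap):
        missing = [i + 1 for i in range(v)
                   if str(i + 1) not in atlas.systems]
        if missing:
            raise ValueError(f"nodes without a system mapping: {missing}")
        return [atlas.systems[str(i + 1)] for i in range(v)]
    labels = list(atlas)
    if len(labels) != v:
        raise ValueError("system labels do not cover every node")
    return [str(s) for s in labels]
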