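"""Transductive prediction protocol: repeated 90/10 splits, multi-init
selection, accuracy as correlation, and the Average condition.

Prediction is transductive: the model is fitted on the connectomes of ALL
subjects while the test subjects' behavior rows are masked to missing.
Their latent scores kappa are then sampled from the Gamma-conditional
alone, and the prediction for (subject j, indicator p) is the posterior
mean of e_p + kappa_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import BehaviorTable, ConnectomeSet, McmcConfig, PriorSpec
from .model import McmcDraws, PosteriorSummary, run_mcmc

__all__ = [
    "SplitPlan",
    "FittedRun",
    "make_split",
    "fit_predict",
    "select_best_init",
    "accuracy",
    "crossval",
    "average_connectomes",
    "ACCURACY_COLUMNS",
]

ACCURACY_COLUMNS = ["condition", "category", "indicator", "repeat", "accuracy"]


@dataclass
class SplitPlan:
    """One train/test partition of the subject ids."""

    train_ids: list[str]
    test_ids: list[str]
    fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def make_split(subject_ids: Sequence[str], fraction: float = 0.9,
               seed: int = 0) -> SplitPlan:
    """Random train/test split; |train| = round-half-up(fraction * N)."""
    ids = list(map(str, subject_ids))
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 subjects to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return SplitPlan(train, test, fraction, seed)


@dataclass
class FittedRun:
    """One MCMC fit plus its test-sample predictions and selection criterion."""

    predictions: pd.DataFrame        # test subjects x indicators
    criterion: float                 # held-out predictive correlation
    summary: PosteriorSummary
    draws: McmcDraws
    seed: int


def accuracy(predicted, observed) -> float:
    """Prediction accuracy = sample Pearson correlation.

    Returns NaN (the undefined-accuracy flag, excluded from averages) when
    either vector is constant.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(predicted) & np.isfinite(observed)
    predicted, observed = predicted[keep], observed[keep]
    if predicted.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(predicted) == 0.0 or np.ptp(observed) == 0.0:
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def _predict_from_draws(draws: McmcDraws, test_idx: Sequence[int],
                        test_ids: Sequence[str],
                        indicator_names: Sequence[str]) -> pd.DataFrame:
    kappa_mean = draws.kappa[:, list(test_idx)].mean(axis=0)
    e_mean = draws.e.mean(axis=0)
    pred = kappa_mean[:, None] + e_mean[None, :]
    return pd.DataFrame(pred, index=list(test_ids),
                        columns=list(indicator_names))


def _run_criterion(pred: pd.DataFrame, observed: pd.DataFrame) -> float:
    """Mean held-out correlation across indicators (NaNs excluded)."""
    accs = []
    for col in pred.columns:
        try:
            a = accuracy(pred[col].to_numpy(), observed[col].to_numpy())
        except ValueError:
            a = float("nan")
        accs.append(a)
    accs = np.asarray(accs, dtype=float)
    return float(np.nanmean(accs)) if np.any(np.isfinite(accs)) else -np.inf


def select_best_init(fits: Sequence[FittedRun]) -> FittedRun:
    """Pick the run with the best held-out predictive correlation.

    Ties are broken by lower run index, so selection is deterministic.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fitted runs to select from")
    crit = np.array([(-np.inf if not np.isfinite(f.criterion)
                      else f.criterion) for f in fits])
    return fits[int(np.argmax(crit))]


def fit_predict(C: ConnectomeSet, B: BehaviorTable, plan: SplitPlan,
                config: McmcConfig, priors: PriorSpec | None = None,
                return_all: bool = False):
    """Fit transductively and predict the test subjects' behavior scores.

    Behavior rows of the test subjects are masked to missing before the
    fit; all connectomes stay in.  ``config.n_inits`` independent random
    initializations are run (seeds ``config.seed + i``) and the run with
    the best test-sample predictive correlation is kept, mirroring the
    multi-start selection protocol.
    """
    ids = list(B.subject_ids)
    if set(plan.train_ids) | set(plan.test_ids) != set(ids):
        raise ValueError("split plan does not cover the subject ids")
    if list(C.subject_ids) != ids:
        raise ValueError("connectome and behavior subject order differ")
    test_idx = [ids.index(s) for s in plan.test_ids]
    observed = pd.DataFrame(B.values[test_idx, :], index=plan.test_ids,
                            columns=B.indicator_names)
    masked = B.mask_subjects(plan.test_ids)

    fits: list[FittedRun] = []
    for i in range(config.n_inits):
        sub = config.replace(seed=config.seed + i, n_inits=1)
        summary, draws = run_mcmc(C, masked, sub, priors)
        pred = _predict_from_draws(draws, test_idx, plan.test_ids,
                                   B.indicator_names)
        fits.append(FittedRun(pred, _run_criterion(pred, observed),
                              summary, draws, sub.seed))
    best = select_best_init(fits)
    if return_all:
        return best, fits
    return best


def crossval(C: ConnectomeSet, B: BehaviorTable, config: McmcConfig,
             n_repeats: int = 5, fraction: float = 0.9,
             priors: PriorSpec | None = None,
             collect_covariances: bool = False):
    """Repeated random-split validation: the accuracy substrate.

    Each repeat draws an independent 90/10 split (seed = base seed +
    repeat index), fits transductively, and records one accuracy per
    indicator.  Returns a long-format accuracy table and the per-indicator
    mean across repeats; optionally also the per-fold node-covariance
    vectors for biomarker averaging.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    records = []
    fold_covs = []
    for r in range(n_repeats):
        plan = make_split(B.subject_ids, fraction, seed=config.seed + r)
        best = fit_predict(C, B, plan, config.replace(seed=config.seed
                                                      + 1000 * (r + 1)),
                           priors)
        ids = list(B.subject_ids)
        test_idx = [ids.index(s) for s in plan.test_ids]
        for k, name in enumerate(B.indicator_names):
            try:
                acc = accuracy(best.predictions[name].to_numpy(),
                               B.values[test_idx, k])
            except ValueError:
                acc = float("nan")
            records.append((C.condition, B.category, name, r, acc))
        fold_covs.append(best.summary.node_covariances)
    table = pd.DataFrame.from_records(records, columns=ACCURACY_COLUMNS)
    means = table.groupby("indicator", sort=False)["accuracy"].mean()
    if collect_covariances:
        return table, means, fold_covs
    return table, means


def average_connectomes(sets: Sequence[ConnectomeSet]) -> ConnectomeSet:
    """Entrywise mean across conditions -> the "Average" condition."""
    sets = list(sets)
    if not sets:
        raise ValueError("no connectome sets to average")
    ref = sets[0]
    for s in sets[1:]:
        if s.values.shape != ref.values.shape:
            raise ValueError("mismatched connectome dimensions")
        if list(s.subject_ids) != list(ref.subject_ids):
            raise ValueError("mismatched subject ids")
        if list(s.node_ids) != list(ref.node_ids):
            raise ValueError("mismatched node ids")
    mean = np.mean([s.values for s in sets], axis=0)
    return ConnectomeSet(mean, node_ids=list(ref.node_ids),
                         subject_ids=list(ref.subject_ids),
                         condition="Average")
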