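"""Basic plots for biomarker profiles and condition accuracies.

These reduce the study's spider/bar/brain visualizations to simple
matplotlib figures driven by the tidy tables the pipeline writes; surface
rendering of brain anatomy is out of scope.
"""

from __future__ import annotations

import numpy as np

from .biomarkers import NetworkCountProfile

__all__ = ["spider_plot", "accuracy_barplot"]


def spider_plot(profile: NetworkCountProfile, ax=None, label=None):
    """Radar chart of per-system biomarker counts (fixed axes, zero counts
    included)."""
    import matplotlib.pyplot as plt

    systems = sorted(profile.counts)
    counts = [profile.counts[s] for s in systems]
    angles = np.linspace(0, 2 * np.pi, len(systems), endpoint=False)
    angles = np.concatenate([angles, angles[:1]])
    vals = np.array(counts + counts[:1], dtype=float)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles, vals, label=label)
    ax.fill(angles, vals, alpha=0.15)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(systems, fontsize=7)
    return ax


def accuracy_barplot(table, ax=None):
    """Mean accuracy per condition with interquartile bars."""
    import matplotlib.pyplot as plt

    grouped = table.groupby("condition")["accuracy"]
    means = grouped.mean()
    q1 = grouped.quantile(0.25)
    q3 = grouped.quantile(0.75)
    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(means))
    ax.bar(x, means.to_numpy(),
           yerr=np.vstack([(means - q1).to_numpy(),
                           (q3 - means).to_numpy()]),
           capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(means.index, rotation=45, ha="right")
    ax.set_ylabel("prediction accuracy (r)")
    return ax
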