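"""Biomarker detection: fold-averaged node covariances, top-node selection,
functional-system profiling and edge highlights.

The node-behavior covariance Sigma[v, V] estimated by the sampler is the
biomarker-strength measure: after averaging over cross-validation folds,
the top 10 positive and top 10 negative nodes form the "top 20" biomarker
set, which is then profiled by functional system (spider-plot input) and
reduced to within-group edge lists (circle-plot input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtlasMap",
    "BiomarkerSelection",
    "NetworkCountProfile",
    "EdgeHighlight",
    "average_covariances",
    "select_top_nodes",
    "count_by_system",
    "top_edges",
]


@dataclass
class AtlasMap:
    """node_id -> functional system (plus optional plotting coordinates).

    ``labels`` declares the finite system set so that zero-count systems
    keep their axes in downstream profiles.
    """

    systems: Mapping[str, str]
    labels: Sequence[str] | None = None
    coords: Mapping[str, tuple] | None = None

    def __post_init__(self) -> None:
        self.systems = {str(k): str(v) for k, v in self.systems.items()}
        if self.labels is None:
            self.labels = sorted(set(self.systems.values()))
        self.labels = list(self.labels)
        unknown = set(self.systems.values()) - set(self.labels)
        if unknown:
            raise ValueError(f"systems outside the declared label set: "
                             f"{sorted(unknown)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   labels: Sequence[str] | None = None) -> "AtlasMap":
        systems = {str(r.node_id): str(r.system) for r in df.itertuples()}
        coords = None
        if {"x", "y", "z"} <= set(df.columns):
            coords = {str(r.node_id): (float(r.x), float(r.y), float(r.z))
                      for r in df.itertuples()}
        return cls(systems, labels, coords)


@dataclass
class BiomarkerSelection:
    """Top nodes by signed covariance.

    ``positive_nodes`` sorted descending by covariance, ``negative_nodes``
    ascending (most negative first); each entry is (node_id, covariance).
    """

    positive_nodes: list = field(default_factory=list)
    negative_nodes: list = field(default_factory=list)

    @property
    def node_ids(self) -> list[str]:
        return ([n for n, _ in self.positive_nodes]
                + [n for n, _ in self.negative_nodes])

    def __len__(self) -> int:
        return len(self.positive_nodes) + len(self.negative_nodes)

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, c, "positive") for n, c in self.positive_nodes]
        rows += [(n, c, "negative") for n, c in self.negative_nodes]
        return pd.DataFrame(rows, columns=["node_id", "covariance", "sign"])


@dataclass
class NetworkCountProfile:
    """Per-functional-system counts of selected nodes (spider-plot input)."""

    counts: dict
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.counts.items()),
                            columns=["system", "count"])


@dataclass
class EdgeHighlight:
    """Within-group edges of the top signed covariance nodes."""

    positive_nodes: list
    negative_nodes: list
    positive_edges: list          # (node_x, node_y, weight)
    negative_edges: list
    truncated: bool = False       # fewer than k signed nodes available
    coords: dict | None = None


def average_covariances(fold_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Entrywise mean of per-fold node-covariance vectors."""
    vecs = [np.asarray(v, dtype=float).ravel() for v in fold_vectors]
    if not vecs:
        raise ValueError("no fold vectors to average")
    length = vecs[0].size
    if any(v.size != length for v in vecs):
        raise ValueError("fold vectors have unequal lengths")
    return np.mean(vecs, axis=0)


def _signed_order(cov: np.ndarray, sign: int) -> list[int]:
    """Indices of strictly signed entries, strongest first, ties by lower
    node index."""
    idx = np.nonzero(sign * cov > 0)[0]
    # stable sort on -|cov| keeps lower indices first among ties
    order = idx[np.argsort(-sign * cov[idx], kind="stable")]
    return list(order)


def select_top_nodes(cov, k_pos: int = 10, k_neg: int = 10,
                     node_ids: Sequence[str] | None = None
                     ) -> BiomarkerSelection:
    """Top-k positive and top-k negative covariance nodes.

    Zero covariances belong to neither list; when fewer than k strictly
    signed entries exist, the available ones are returned.
    """
    cov = np.asarray(cov, dtype=float).ravel()
    if cov.size < 1:
        raise ValueError("empty covariance vector")
    if node_ids is None:
        node_ids = [str(i + 1) for i in range(cov.size)]
    pos = [(str(node_ids[i]), float(cov[i]))
           for i in _signed_order(cov, +1)[:k_pos]]
    neg = [(str(node_ids[i]), float(cov[i]))
           for i in _signed_order(cov, -1)[:k_neg]]
    return BiomarkerSelection(pos, neg)


def count_by_system(selection: BiomarkerSelection, atlas: AtlasMap
                    ) -> NetworkCountProfile:
    """Count selected nodes per functional system (zero counts kept)."""
    counts = {label: 0 for label in atlas.labels}
    unmapped = [n for n in selection.node_ids if n not in atlas.systems]
    if unmapped:
        raise ValueError(f"selected nodes without atlas mapping: {unmapped}")
    for node in selection.node_ids:
        counts[atlas.systems[node]] += 1
    return NetworkCountProfile(counts, total=len(selection))


def top_edges(cov, group_mean_connectome, k: int = 5,
              node_ids: Sequence[str] | None = None,
              atlas: AtlasMap | None = None) -> EdgeHighlight:
    """Top-k positive and top-k negative covariance nodes with the edges
    among each group taken from the group-mean connectome.

    The highlighted elements are node groups; the returned edges are all
    unordered pairs within each signed group (a subset of the complete
    graph on the group), weighted by the group-mean connectivity.
    """
    cov = np.asarray(cov, dtype=float).ravel()
    mat = np.asarray(group_mean_connectome, dtype=float)
    if mat.shape != (cov.size, cov.size):
        raise ValueError("group-mean connectome shape mismatch")
    if node_ids is None:
        node_ids = [str(i + 1) for i in range(cov.size)]
    pos_idx = _signed_order(cov, +1)[:k]
    neg_idx = _signed_order(cov, -1)[:k]
    truncated = len(pos_idx) < k or len(neg_idx) < k

    def edges(group: list[int]) -> list:
        out = []
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                x, y = sorted((group[a], group[b]))
                out.append((str(node_ids[x]), str(node_ids[y]),
                            float(mat[x, y])))
        return out

    coords = None
    if atlas is not None and atlas.coords is not None:
        coords = {str(node_ids[i]): atlas.coords.get(str(node_ids[i]))
                  for i in pos_idx + neg_idx}
    return EdgeHighlight(
        positive_nodes=[(str(node_ids[i]), float(cov[i])) for i in pos_idx],
        negative_nodes=[(str(node_ids[i]), float(cov[i])) for i in neg_idx],
        positive_edges=edges(pos_idx),
        negative_edges=edges(neg_idx),
        truncated=truncated,
        coords=coords,
    )
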