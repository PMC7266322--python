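"""Opinion-based-group statistics.

The headline statistic is the *non-spatial* cluster count: clusters are
equivalence classes of identical length-F culture vectors over all N
agents, regardless of lattice position (isolates count as clusters of
size 1, so cluster sizes always sum to N).  Classic spatial cultural
regions — lattice-connected components of identical culture — are
provided for comparison, as is a relaxed variant where agents are
grouped when they disagree on at most ``m`` features.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import LatticeTopology
from .state import CultureState


@dataclass(frozen=True)
class ClusterSummary:
    """Cluster count and size distribution; sizes sum to N."""

    n_clusters: int
    sizes: tuple[int, ...]  # descending

    @classmethod
    def from_sizes(cls, sizes) -> "ClusterSummary":
        sizes = tuple(sorted((int(s) for s in sizes), reverse=True))
        return cls(n_clusters=len(sizes), sizes=sizes)

    @property
    def n_isolates(self) -> int:
        return sum(1 for s in self.sizes if s == 1)

    @property
    def largest(self) -> int:
        return self.sizes[0] if self.sizes else 0

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.sizes else 0.0

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "sizes": list(self.sizes),
            "n_isolates": self.n_isolates,
            "largest": self.largest,
            "mean_size": self.mean_size,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def size_distribution(self) -> pd.DataFrame:
        """Tidy (size, count) table of the cluster-size multiset."""
        counts = Counter(self.sizes)
        return pd.DataFrame(
            sorted(counts.items()), columns=["size", "count"]
        )


def count_clusters(state: CultureState) -> ClusterSummary:
    """Opinion-based groups: agents with identical culture vectors."""
    _, counts = np.unique(state.traits, axis=0, return_counts=True)
    return ClusterSummary.from_sizes(counts)


def _component_summary(n: int, rows, cols) -> ClusterSummary:
    adj = coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    return ClusterSummary.from_sizes(np.bincount(labels, minlength=n_comp))


def relaxed_components(state: CultureState, max_disagreement: int) -> ClusterSummary:
    """Components of the agent graph linked at >= F - m shared features.

    ``m = 0`` reduces exactly to :func:`count_clusters`; growing ``m``
    can only merge components.
    """
    m = max_disagreement
    if not (0 <= m < state.F):
        raise ValueError(f"max_disagreement must be in [0, F-1], got {m}")
    shared = np.count_nonzero(
        state.traits[:, None, :] == state.traits[None, :, :], axis=2
    )
    rows, cols = np.nonzero(np.triu(shared >= state.F - m, k=1))
    return _component_summary(state.N, rows, cols)


def spatial_regions(state: CultureState, topology: LatticeTopology) -> ClusterSummary:
    """Classic cultural regions: lattice components of identical culture."""
    same = np.all(
        state.traits[topology.edge_u] == state.traits[topology.edge_v], axis=1
    )
    return _component_summary(
        state.N, topology.edge_u[same], topology.edge_v[same]
    )
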