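"""Non-periodic square-lattice topology.

Agents sit on an ``L x L`` grid without periodic boundaries, numbered in
row-major order (site ``(r, c)`` is agent ``r * L + c``).  The default
von Neumann neighborhood links each site to its 4 orthogonal neighbors
(corner degree 2, border degree 3, interior degree 4); the Moore option
adds the diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

_OFFSETS = {
    "von_neumann": ((-1, 0), (1, 0), (0, -1), (0, 1)),
    "moore": (
        (-1, -1), (-1, 0), (-1, 1),
        (0, -1), (0, 1),
        (1, -1), (1, 0), (1, 1),
    ),
}


@dataclass(frozen=True)
class LatticeTopology:
    """Neighbor structure of the non-periodic grid, in CSR form.

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbors of agent ``i``;
    ``edge_u``/``edge_v`` list each undirected edge once with ``u < v``.
    """

    L: int
    neighborhood: str = "von_neumann"
    indptr: np.ndarray = field(repr=False, compare=False, default=None)
    indices: np.ndarray = field(repr=False, compare=False, default=None)
    edge_u: np.ndarray = field(repr=False, compare=False, default=None)
    edge_v: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def N(self) -> int:
        return self.L * self.L

    @classmethod
    def build(cls, L: int, neighborhood: str = "von_neumann") -> "LatticeTopology":
        if L < 2:
            raise ValueError(f"L must be >= 2, got {L}")
        if neighborhood not in _OFFSETS:
            raise ValueError(f"unknown neighborhood {neighborhood!r}")
        offsets = _OFFSETS[neighborhood]
        nbrs: list[list[int]] = []
        for r in range(L):
            for c in range(L):
                cur = []
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < L and 0 <= cc < L:
                        cur.append(rr * L + cc)
                nbrs.append(sorted(cur))
        indptr = np.zeros(L * L + 1, dtype=np.int64)
        for i, cur in enumerate(nbrs):
            indptr[i + 1] = indptr[i] + len(cur)
        indices = np.fromiter(
            (j for cur in nbrs for j in cur), dtype=np.int64, count=indptr[-1]
        )
        eu, ev = [], []
        for i, cur in enumerate(nbrs):
            for j in cur:
                if i < j:
                    eu.append(i)
                    ev.append(j)
        return cls(
            L=L,
            neighborhood=neighborhood,
            indptr=indptr,
            indices=indices,
            edge_u=np.asarray(eu, dtype=np.int64),
            edge_v=np.asarray(ev, dtype=np.int64),
        )

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def degree(self, i: int) -> int:
        return int(self.indptr[i + 1] - self.indptr[i])

    @property
    def n_edges(self) -> int:
        return len(self.edge_u)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(zip(self.edge_u.tolist(), self.edge_v.tolist()))
        return g

    def position(self, i: int) -> tuple[int, int]:
        """Row-major grid coordinates (row, col) of agent ``i``."""
        return divmod(i, self.L)
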