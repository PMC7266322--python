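"""Culture state: the N x F matrix of trait indices.

Rows are agents in row-major lattice order, columns are features; each
entry is the trait (0-based, ``0..q-1``) the agent holds on that feature.
The matrix plus the elapsed event count is the entire dynamical state.
States round-trip through a CSV file (the matrix) and a JSON sidecar
(config echo and step count), and a survey-style N x F CSV can be loaded
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig


@dataclass
class CultureState:
    """Trait matrix of shape (N, F) plus the elapsed event count."""

    traits: np.ndarray
    step_count: int = 0
    q: int | None = None  # trait range, when known

    def __post_init__(self) -> None:
        self.traits = np.ascontiguousarray(self.traits, dtype=np.int64)
        if self.traits.ndim != 2:
            raise ValueError("traits must be a 2-D (N, F) matrix")
        if self.traits.size and self.traits.min() < 0:
            raise ValueError("traits must be non-negative integers")
        if self.q is not None and self.traits.size and self.traits.max() >= self.q:
            raise ValueError(f"traits must lie in [0, {self.q - 1}]")
        if self.step_count < 0:
            raise ValueError("step_count must be >= 0")

    @property
    def N(self) -> int:
        return self.traits.shape[0]

    @property
    def F(self) -> int:
        return self.traits.shape[1]

    def copy(self) -> "CultureState":
        return CultureState(self.traits.copy(), self.step_count, self.q)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path, config: ModelConfig | None = None) -> None:
        """Write the matrix as CSV plus a JSON sidecar (<path>.json)."""
        path = Path(path)
        df = pd.DataFrame(
            self.traits, columns=[f"f{k}" for k in range(self.F)]
        )
        df.to_csv(path, index=False)
        sidecar = {
            "step_count": int(self.step_count),
            "q": None if self.q is None else int(self.q),
            "config": None if config is None else config.to_dict(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path, q: int | None = None) -> "CultureState":
        """Load an N x F integer matrix from CSV (survey-style input).

        If a JSON sidecar written by :meth:`to_csv` sits next to the file
        its step count and trait range are restored; otherwise the state
        starts at step 0 with range inferred from ``q`` (or left unknown).
        """
        path = Path(path)
        df = pd.read_csv(path)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.issubdtype(arr.dtype, np.number) or np.any(arr != arr.astype(np.int64)):
                raise ValueError(f"{path}: state matrix must be integer-valued")
            arr = arr.astype(np.int64)
        step_count = 0
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            step_count = int(meta.get("step_count", 0))
            if q is None:
                q = meta.get("q")
        return cls(arr, step_count=step_count, q=q)


def init_random(config: ModelConfig, rng: np.random.Generator) -> CultureState:
    """Draw an initial state: entries i.i.d. uniform on ``{0, .., q-1}``."""
    traits = rng.integers(0, config.q, size=(config.N, config.F), dtype=np.int64)
    return CultureState(traits, step_count=0, q=config.q)
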