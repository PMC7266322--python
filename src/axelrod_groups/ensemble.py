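"""Ensemble campaigns: sweeps over (L, q, F, a) with reproducible seeding.

A sweep runs ``n_runs`` independent realisations per grid cell.  Each
(cell, run) gets its own seed derived from the master seed through a
``numpy.random.SeedSequence`` spawn key ``(cell_index, run_index)`` in
lexicographic cell order, so any single row of the results table can be
re-run to the identical outcome without re-running the ensemble, and
parallel execution gives results identical to sequential.

Outputs are a long-form per-run table (one row per realisation) and a
per-cell summary (mean and standard error of the cluster count).  Runs
that hit the step cap are kept with ``absorbed=False`` and counted in the
summary's ``n_not_absorbed`` — dropping them silently would bias means.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .clusters import count_clusters
from .config import ModelConfig
from .dynamics import run_to_absorption
from .lattice import LatticeTopology

RUN_COLUMNS = [
    "F", "q", "a", "L", "mode", "seed",
    "n_clusters", "largest_cluster", "mean_cluster_size", "steps", "absorbed",
]
CELL_KEYS = ["L", "q", "F", "a"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Grid of run configurations plus the run count and master seed."""

    base: ModelConfig
    F_values: tuple[int, ...] = ()
    a_values: tuple[int | None, ...] = ()
    q_values: tuple[int, ...] = ()
    L_values: tuple[int, ...] = ()
    n_runs: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "F_values",
                           tuple(self.F_values) or (self.base.F,))
        object.__setattr__(self, "a_values",
                           tuple(self.a_values) or (self.base.a,))
        object.__setattr__(self, "q_values",
                           tuple(self.q_values) or (self.base.q,))
        object.__setattr__(self, "L_values",
                           tuple(self.L_values) or (self.base.L,))
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for cfg in self.cells():  # validates every cell
            pass

    def cells(self):
        """Cell configs in lexicographic (L, q, F, a) order."""
        for L, q, F, a in itertools.product(
            self.L_values, self.q_values, self.F_values, self.a_values
        ):
            yield self.base.replace(L=L, q=q, F=F, a=a, seed=None)

    def run_seed(self, cell_index: int, run_index: int) -> int:
        ss = np.random.SeedSequence(
            self.master_seed, spawn_key=(cell_index, run_index)
        )
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base"] = self.base.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSpec":
        d = dict(d)
        d["base"] = ModelConfig.from_dict(d["base"])
        for key in ("F_values", "a_values", "q_values", "L_values"):
            d[key] = tuple(d.get(key) or ())
        return cls(**d)


@dataclass
class EnsembleResult:
    """Per-run rows plus per-cell summaries for one sweep."""

    spec: EnsembleSpec
    runs: pd.DataFrame
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.summary is None:
            self.summary = summarize_runs(self.runs, self.spec.n_runs)

    def cell_runs(self, **cell) -> pd.DataFrame:
        """Rows of one grid cell, selected by any of L, q, F, a."""
        mask = np.ones(len(self.runs), dtype=bool)
        for key, val in cell.items():
            if key not in CELL_KEYS:
                raise KeyError(f"unknown cell key {key!r}")
            col = self.runs[key]
            mask &= col.isna() if val is None else (col == val)
        out = self.runs[mask]
        if out.empty:
            raise KeyError(f"no runs match cell {cell!r}")
        return out


def _one_run(config: ModelConfig, topology: LatticeTopology) -> dict:
    res = run_to_absorption(config, topology=topology)
    summ = count_clusters(res.final_state)
    return {
        "F": config.F,
        "q": config.q,
        "a": config.a,
        "L": config.L,
        "mode": config.mode,
        "seed": res.seed,
        "n_clusters": summ.n_clusters,
        "largest_cluster": summ.largest,
        "mean_cluster_size": summ.mean_size,
        "steps": res.steps,
        "absorbed": res.absorbed,
    }


def run_ensemble(spec: EnsembleSpec, n_jobs: int = 1) -> EnsembleResult:
    """Execute every (cell, run); deterministic given the master seed.

    Cells and runs are independent; with ``n_jobs > 1`` they run in
    parallel with results identical to sequential execution (seeds are
    fixed per (cell, run), and rows are emitted in sweep order).
    """
    jobs = []
    for cell_index, cfg in enumerate(spec.cells()):
        topo = LatticeTopology.build(cfg.L, cfg.neighborhood)
        for run_index in range(spec.n_runs):
            seeded = cfg.replace(seed=spec.run_seed(cell_index, run_index))
            jobs.append((seeded, topo))
    if n_jobs == 1:
        rows = [_one_run(cfg, topo) for cfg, topo in jobs]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_run)(cfg, topo) for cfg, topo in jobs
        )
    runs = pd.DataFrame(rows, columns=RUN_COLUMNS)
    return EnsembleResult(spec=spec, runs=runs)


def summarize_runs(runs: pd.DataFrame, n_runs: int | None = None) -> pd.DataFrame:
    """Per-cell mean and standard error of the cluster count."""
    grouped = runs.groupby(CELL_KEYS, dropna=False, sort=True)
    out = grouped.agg(
        mode=("mode", "first"),
        mean_clusters=("n_clusters", "mean"),
        sd_clusters=("n_clusters", "std"),
        mean_largest=("largest_cluster", "mean"),
        mean_size=("mean_cluster_size", "mean"),
        mean_steps=("steps", "mean"),
        n_runs=("n_clusters", "size"),
        n_not_absorbed=("absorbed", lambda s: int((~s).sum())),
    ).reset_index()
    out["se_clusters"] = out["sd_clusters"] / np.sqrt(out["n_runs"])
    if n_runs is not None:
        assert (out["n_runs"] == n_runs).all(), "missing rows in some cell"
    return out


def mean_clusters_table(result: EnsembleResult) -> pd.DataFrame:
    """(F, a) table of mean cluster count with its standard error."""
    return result.summary[
        CELL_KEYS + ["mean_clusters", "se_clusters", "n_runs"]
    ].copy()


def cluster_density(result: EnsembleResult, **cell) -> pd.Series:
    """Discrete probability density of the cluster count in one cell.

    Exact normalised frequencies over the observed counts (the count is
    an integer; no smoothing).  The returned series sums to 1.
    """
    rows = result.cell_runs(**cell)
    dens = rows["n_clusters"].value_counts(normalize=True).sort_index()
    dens.name = "density"
    return dens


# --------------------------------------------------------------- file I/O


def write_results(result: EnsembleResult, out_dir: str | Path) -> dict[str, Path]:
    """Write runs.csv, summary.csv and spec.json under ``out_dir``."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "runs": out / "runs.csv",
            "summary": out / "summary.csv",
            "spec": out / "spec.json",
        }
        result.runs.to_csv(paths["runs"], index=False)
        result.summary.to_csv(paths["summary"], index=False)
        meta = result.spec.to_dict()
        meta["version"] = __version__
        paths["spec"].write_text(json.dumps(meta, indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing ensemble results under {out}: {exc}") from exc
    return paths


def read_results(out_dir: str | Path) -> EnsembleResult:
    out = Path(out_dir)
    meta = json.loads((out / "spec.json").read_text())
    meta.pop("version", None)
    spec = EnsembleSpec.from_dict(meta)
    runs = pd.read_csv(out / "runs.csv")
    # a is nullable (standard mode): keep pandas' float NaN representation
    summary = pd.read_csv(out / "summary.csv")
    return EnsembleResult(spec=spec, runs=runs, summary=summary)
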