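"""The dynamical engine: one-event updates and runs to absorption.

One elementary event (one time step, whether or not anything changes):
pick agent ``i`` uniformly, pick ``j`` uniformly among its lattice
neighbors, interact with a probability set by cultural similarity, and on
interaction copy one candidate feature's trait from ``j`` to ``i``.

Standard mode is the classic homophily rule: the interaction probability
is the fraction of features on which the pair already agree, and the
copied feature is drawn among the disagreeing ones.  Threshold mode
implements bounded confidence on the ordered traits: features whose trait
distance ``|Δ|`` is within the agreement threshold ``a`` (including
``Δ = 0``) count toward the interaction probability, and only disagreeing
features within the threshold can be copied.  With ``a = q - 1`` every
pair interacts; with ``a = 0`` nothing can ever be copied and the initial
state is frozen.

The event-level functions here are plain Python/numpy and serve as the
reference semantics; :func:`run_to_absorption` delegates to a compiled
kernel by default (``engine="numba"``) with the pure-Python loop
available as ``engine="python"``.  Both are deterministic given a seed
but use distinct RNG streams, so trajectories differ between engines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .lattice import LatticeTopology
from .state import CultureState, init_random

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- pair algebra


def shared_feature_count(vec_i: np.ndarray, vec_j: np.ndarray) -> int:
    """Number of features on which two culture vectors agree."""
    vec_i = np.asarray(vec_i)
    vec_j = np.asarray(vec_j)
    if vec_i.shape != vec_j.shape or vec_i.ndim != 1:
        raise ValueError("culture vectors must be 1-D and of equal length")
    return int(np.count_nonzero(vec_i == vec_j))


def eligible_features(
    vec_i: np.ndarray, vec_j: np.ndarray, config: ModelConfig
) -> set[int]:
    """Features that may be drawn as the copy candidate for this pair."""
    vec_i = np.asarray(vec_i)
    vec_j = np.asarray(vec_j)
    if vec_i.shape != vec_j.shape or vec_i.ndim != 1:
        raise ValueError("culture vectors must be 1-D and of equal length")
    diff = vec_i != vec_j
    if config.mode == "standard" or config.selection_rule == "literal_two_stage":
        return set(np.flatnonzero(diff).tolist())
    dist = np.abs(vec_i - vec_j)
    return set(np.flatnonzero(diff & (dist <= config.a)).tolist())


def interaction_probability(
    vec_i: np.ndarray, vec_j: np.ndarray, config: ModelConfig
) -> float:
    """Probability the pair interacts in an event that selected it.

    Standard mode: shared features over F.  Threshold mode: features with
    trait distance ``|Δ| <= a`` over F (distance 0 counts, so the
    threshold-mode probability is never below the standard one).
    """
    vec_i = np.asarray(vec_i)
    vec_j = np.asarray(vec_j)
    F = config.F
    if config.mode == "standard":
        return shared_feature_count(vec_i, vec_j) / F
    within = int(np.count_nonzero(np.abs(vec_i - vec_j) <= config.a))
    return within / F


def is_pair_active(
    vec_i: np.ndarray, vec_j: np.ndarray, config: ModelConfig
) -> bool:
    """True iff some future event between this pair could change a trait."""
    vec_i = np.asarray(vec_i)
    vec_j = np.asarray(vec_j)
    if config.mode == "standard":
        s = shared_feature_count(vec_i, vec_j)
        return 0 < s < config.F
    dist = np.abs(vec_i - vec_j)
    return bool(np.any((dist > 0) & (dist <= config.a)))


# ------------------------------------------------------------ single events


@dataclass(frozen=True)
class InteractionEvent:
    """Record of one elementary event."""

    i: int
    j: int
    interacted: bool
    copied_feature: int | None


def attempt_interaction(
    state: CultureState,
    topology: LatticeTopology,
    config: ModelConfig,
    rng: np.random.Generator,
) -> InteractionEvent:
    """Execute one elementary event in place.

    Draws ``i`` uniformly and ``j`` uniformly among its neighbors; with
    probability :func:`interaction_probability` the pair interacts; on
    interaction one candidate feature is drawn uniformly from
    :func:`eligible_features` and copied (under ``literal_two_stage`` the
    copy is additionally rejected when ``|Δ| > a``).  The step count
    increments by exactly one whatever the outcome, and at most one
    matrix entry changes.
    """
    i = int(rng.integers(0, state.N))
    nbrs = topology.neighbors(i)
    j = int(nbrs[rng.integers(0, len(nbrs))])
    state.step_count += 1

    vec_i = state.traits[i]
    vec_j = state.traits[j]
    p = interaction_probability(vec_i, vec_j, config)
    if p == 0.0 or (p < 1.0 and rng.random() >= p):
        return InteractionEvent(i, j, False, None)
    elig = eligible_features(vec_i, vec_j, config)
    if not elig:
        return InteractionEvent(i, j, True, None)
    candidates = sorted(elig)
    k = candidates[int(rng.integers(0, len(candidates)))]
    if config.mode == "threshold" and config.selection_rule == "literal_two_stage":
        if abs(int(vec_i[k]) - int(vec_j[k])) > config.a:
            return InteractionEvent(i, j, True, None)
    state.traits[i, k] = state.traits[j, k]
    return InteractionEvent(i, j, True, k)


# --------------------------------------------------------- absorbing states


def is_absorbing(
    state: CultureState, topology: LatticeTopology, config: ModelConfig
) -> bool:
    """Exhaustive scan: no lattice edge admits a state-changing event."""
    vi = state.traits[topology.edge_u]
    vj = state.traits[topology.edge_v]
    if config.mode == "standard":
        shared = np.count_nonzero(vi == vj, axis=1)
        active = (shared > 0) & (shared < config.F)
    else:
        dist = np.abs(vi - vj)
        active = np.any((dist > 0) & (dist <= config.a), axis=1)
    return not bool(active.any())


# -------------------------------------------------------------- full runs


@dataclass(frozen=True)
class RunResult:
    """Outcome of one run: final state, steps used, absorption flag."""

    final_state: CultureState
    steps: int
    absorbed: bool
    config: ModelConfig
    seed: int

    def to_dict(self) -> dict:
        return {
            "steps": int(self.steps),
            "absorbed": bool(self.absorbed),
            "seed": int(self.seed),
            "config": self.config.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        """Write the final state CSV + sidecar and a run-summary JSON."""
        path = Path(path)
        self.final_state.to_csv(path, config=self.config)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        meta.update(self.to_dict())
        meta["step_count"] = int(self.final_state.step_count)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )


def _mode_flags(config: ModelConfig) -> tuple[int, int, int]:
    mode = 0 if config.mode == "standard" else 1
    rule = 1 if config.selection_rule == "literal_two_stage" else 0
    a = -1 if config.a is None else config.a
    return mode, rule, a


def run_to_absorption(
    config: ModelConfig,
    initial_state: CultureState | None = None,
    topology: LatticeTopology | None = None,
    engine: str = "numba",
) -> RunResult:
    """Run elementary events until the absorbing state or ``max_steps``.

    The absorbing scan runs every ``config.effective_check_every`` events
    (default ``N * F``), including once before the first event, so a
    frozen configuration (threshold ``a = 0``) absorbs immediately with
    its initial matrix intact.  Fully reproducible from ``config.seed``.
    """
    if engine not in ("numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
    rng = np.random.default_rng(seed)
    topo = topology or LatticeTopology.build(config.L, config.neighborhood)
    if initial_state is None:
        state = init_random(config, rng)
    else:
        if initial_state.traits.shape != (config.N, config.F):
            raise ValueError("initial state shape does not match config")
        state = initial_state.copy()
        state.q = config.q
    mode, rule, a = _mode_flags(config)
    check_every = config.effective_check_every

    if engine == "numba":
        from ._kernel import run_kernel

        kernel_seed = int(rng.integers(0, 2**31))
        steps, absorbed = run_kernel(
            state.traits,
            topo.indptr,
            topo.indices,
            topo.edge_u,
            topo.edge_v,
            a,
            mode,
            rule,
            config.max_steps,
            check_every,
            kernel_seed,
        )
        state.step_count += int(steps)
        absorbed = bool(absorbed)
    else:
        start = state.step_count
        absorbed = is_absorbing(state, topo, config)
        while not absorbed and state.step_count - start < config.max_steps:
            block = min(check_every, config.max_steps - (state.step_count - start))
            for _ in range(block):
                attempt_interaction(state, topo, config, rng)
            absorbed = is_absorbing(state, topo, config)

    steps_used = state.step_count
    if not absorbed:
        logger.warning(
            "run hit max_steps=%d without absorbing (L=%d F=%d q=%d mode=%s a=%s)",
            config.max_steps, config.L, config.F, config.q, config.mode, config.a,
        )
    return RunResult(
        final_state=state,
        steps=steps_used,
        absorbed=absorbed,
        config=dataclasses.replace(config, seed=seed),
        seed=seed,
    )
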