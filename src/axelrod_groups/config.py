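"""Run configuration for the lattice dynamics.

A :class:`ModelConfig` fixes every parameter of a single simulation run:
the lattice side ``L`` (``N = L**2`` agents), the number of cultural
features ``F`` (survey items), the number of traits per feature ``q``
(ordered response options, stored 0-based as ``0..q-1``), the interaction
``mode`` and — in threshold mode — the agreement threshold ``a``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

MODES = ("standard", "threshold")
SELECTION_RULES = ("within_threshold", "literal_two_stage")
NEIGHBORHOODS = ("von_neumann", "moore")

DEFAULT_MAX_STEPS = 10_000_000


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one simulation run.

    Parameters
    ----------
    L : int
        Lattice side; the non-periodic grid holds ``N = L**2`` agents.
    F : int
        Number of features (cultural dimensions / survey items), ``>= 1``.
    q : int
        Traits per feature (ordered options), ``>= 2``; traits are
        ``0..q-1``.
    mode : {"standard", "threshold"}
        ``standard`` is the classic homophily rule; ``threshold`` gates
        interaction and copying by the trait distance ``|Δ| <= a``.
    a : int or None
        Agreement threshold, ``0 <= a <= q - 1``.  Required in threshold
        mode; must be omitted (None) in standard mode.
    selection_rule : {"within_threshold", "literal_two_stage"}
        Threshold mode only.  ``within_threshold`` draws the candidate
        feature among differing features already within the threshold;
        ``literal_two_stage`` draws among all differing features and then
        rejects the copy if ``|Δ| > a``.  Absorbing states coincide;
        transient kinetics differ.
    neighborhood : {"von_neumann", "moore"}
        Lattice neighborhood (4- or 8-neighbor).
    max_steps : int
        Cap on elementary events for a run.
    check_every : int or None
        Absorbing-state scan cadence in events; defaults to ``N * F``.
    seed : int or None
        RNG seed; None draws a fresh one at run time.
    """

    L: int
    F: int
    q: int
    mode: str = "standard"
    a: int | None = None
    selection_rule: str = "within_threshold"
    neighborhood: str = "von_neumann"
    max_steps: int = DEFAULT_MAX_STEPS
    check_every: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.L, int) or self.L < 2:
            raise ConfigError(f"L must be an integer >= 2, got {self.L!r}")
        if not isinstance(self.F, int) or self.F < 1:
            raise ConfigError(f"F must be an integer >= 1, got {self.F!r}")
        if not isinstance(self.q, int) or self.q < 2:
            raise ConfigError(f"q must be an integer >= 2, got {self.q!r}")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.selection_rule not in SELECTION_RULES:
            raise ConfigError(
                f"selection_rule must be one of {SELECTION_RULES}, "
                f"got {self.selection_rule!r}"
            )
        if self.neighborhood not in NEIGHBORHOODS:
            raise ConfigError(
                f"neighborhood must be one of {NEIGHBORHOODS}, "
                f"got {self.neighborhood!r}"
            )
        if self.mode == "threshold":
            if self.a is None:
                raise ConfigError("threshold mode requires an agreement threshold a")
            if not isinstance(self.a, int) or not (0 <= self.a <= self.q - 1):
                raise ConfigError(
                    f"a must be an integer in [0, q-1] = [0, {self.q - 1}], "
                    f"got {self.a!r}"
                )
        elif self.a is not None:
            raise ConfigError("a is only meaningful in threshold mode; leave it unset")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")
        if self.check_every is not None and self.check_every < 1:
            raise ConfigError("check_every must be >= 1")
        if self.seed is not None and not (0 <= int(self.seed) < 2**63):
            raise ConfigError("seed must be a non-negative 63-bit integer")

    @property
    def N(self) -> int:
        """Number of agents, ``L**2``."""
        return self.L * self.L

    @property
    def effective_check_every(self) -> int:
        return self.check_every if self.check_every is not None else self.N * self.F

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # a is reported as null outside threshold mode by construction
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "ModelConfig":
        """Load a flat YAML or JSON config file; keyword overrides win."""
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
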