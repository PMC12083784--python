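"""Small integer-distribution specs used by the synthetic cohort generator.

A distribution spec is either a ``Distribution`` instance or a plain dict such
as ``{"kind": "choice", "values": [1, 2, 3], "probs": [0.5, 0.3, 0.2]}`` or
``{"kind": "lognormal", "median": 93, "sigma": 0.7}`` — the latter is
discretized and clipped below at ``minimum``. Dict form round-trips through
YAML config files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Invalid configuration value; the message names the offending field."""


@dataclass(frozen=True)
class Choice:
    """Finite distribution over positive integers."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs) or not self.values:
            raise ConfigurationError("choice distribution needs matching non-empty values/probs")
        if any(int(v) != v or v < 1 for v in self.values):
            raise ConfigurationError("choice distribution values must be positive integers")
        if any(p < 0 for p in self.probs) or not np.isclose(sum(self.probs), 1.0):
            raise ConfigurationError("choice distribution probs must be non-negative and sum to 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        cum = np.cumsum(self.probs)
        idx = np.searchsorted(cum, rng.random(size), side="right")
        idx = np.minimum(idx, len(self.values) - 1)
        return np.asarray(self.values, dtype=np.int64)[idx]

    def to_dict(self) -> dict:
        return {"kind": "choice", "values": list(self.values), "probs": list(self.probs)}


@dataclass(frozen=True)
class Lognormal:
    """Discretized lognormal, parameterized by its median; clipped at ``minimum``."""

    median: float
    sigma: float
    minimum: int = 1

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma < 0 or self.minimum < 1:
            raise ConfigurationError("lognormal distribution needs median>0, sigma>=0, minimum>=1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raw = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=size)
        return np.maximum(np.rint(raw).astype(np.int64), self.minimum)

    def to_dict(self) -> dict:
        return {"kind": "lognormal", "median": self.median, "sigma": self.sigma, "minimum": self.minimum}


Distribution = Choice | Lognormal


def parse_distribution(spec, field: str) -> Distribution:
    """Coerce a config value into a Distribution, naming ``field`` on error."""
    if isinstance(spec, (Choice, Lognormal)):
        return spec
    if isinstance(spec, int):
        return Choice(values=(spec,), probs=(1.0,))
    if isinstance(spec, dict):
        kind = spec.get("kind")
        try:
            if kind == "choice":
                return Choice(values=tuple(spec["values"]), probs=tuple(spec["probs"]))
            if kind == "lognormal":
                return Lognormal(
                    median=spec["median"],
                    sigma=spec["sigma"],
                    minimum=int(spec.get("minimum", 1)),
                )
        except (KeyError, TypeError, ConfigurationError) as exc:
            raise ConfigurationError(f"{field}: invalid distribution spec ({exc})") from exc
        raise ConfigurationError(f"{field}: unknown distribution kind {kind!r}")
    raise ConfigurationError(f"{field}: cannot interpret {spec!r} as a distribution")
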