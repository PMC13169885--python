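"""Small distribution specifications used by the cohort generator.

Every stochastic generator parameter (speech duration, pause fraction,
per-segment amplitude, words per subject, ...) is described by a
:class:`Dist` so that configurations are explicit, serialisable and
checkable.  Three kinds cover what the generator needs:

``point``
    a degenerate distribution; sampling always returns ``value``.
``normal``
    a normal distribution truncated to ``[low, high]`` by rejection.
    Bounds default to ``mean +/- 4 sd``; symmetric bounds keep the mean
    of the truncated law equal to the nominal mean.
``uniform``
    continuous uniform on ``[low, high]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class Dist:
    kind: str
    value: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.value is None:
                raise ConfigurationError("point distribution requires 'value'")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None:
                raise ConfigurationError("normal distribution requires 'mean' and 'sd'")
            if self.sd < 0:
                raise ConfigurationError("sd must be non-negative")
            lo, hi = self.bounds()
            if lo >= hi:
                raise ConfigurationError("normal bounds must satisfy low < high")
        elif self.kind == "uniform":
            if self.low is None or self.high is None:
                raise ConfigurationError("uniform distribution requires 'low' and 'high'")
            if self.low > self.high:
                raise ConfigurationError("uniform requires low <= high")
        else:
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")

    def bounds(self) -> tuple[float, float]:
        if self.kind == "point":
            return (self.value, self.value)
        if self.kind == "uniform":
            return (self.low, self.high)
        lo = self.low if self.low is not None else self.mean - 4.0 * self.sd
        hi = self.high if self.high is not None else self.mean + 4.0 * self.sd
        return (lo, hi)

    def nominal_mean(self) -> float:
        if self.kind == "point":
            return float(self.value)
        if self.kind == "uniform":
            return 0.5 * (self.low + self.high)
        return float(self.mean)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw ``size`` values (scalar when ``size`` is None)."""
        scalar = size is None
        n = 1 if scalar else int(size)
        if self.kind == "point":
            out = np.full(n, float(self.value))
        elif self.kind == "uniform":
            out = rng.uniform(self.low, self.high, size=n)
        else:
            lo, hi = self.bounds()
            out = rng.normal(self.mean, self.sd, size=n)
            bad = (out < lo) | (out > hi)
            # rejection keeps the truncated law exact; sd=0 never rejects
            while bad.any():
                out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
                bad = (out < lo) | (out > hi)
        return float(out[0]) if scalar else out


def point(value: float) -> Dist:
    return Dist("point", value=value)


def normal(mean: float, sd: float, low: Optional[float] = None,
           high: Optional[float] = None) -> Dist:
    return Dist("normal", mean=mean, sd=sd, low=low, high=high)


def uniform(low: float, high: float) -> Dist:
    return Dist("uniform", low=low, high=high)
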