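"""Per-trial resolution of parameter scaling factors for sensitivity runs.

Each parameter under study gets a :class:`PvarSpec` in one of three modes:

``init``
    every trial uses the same fixed factor;
``iter``
    trial *i* uses ``init_value + i * increment`` (an arithmetic sweep);
``random``
    trial *i* draws independently from a normal or lognormal distribution.

Random draws use a counter-based stream keyed on (seed, parameter name,
trial index), so factors are reproducible across runs, identical under
serial or concurrent trial execution, and unaffected for early trials when
the trial count changes.  The lognormal distribution is parameterised by its
natural-scale mean and standard deviation (what a user scaling conductances
around 1.0 intuitively expects), converted internally to log-scale µ, σ.
"""
from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cell_core import ConfigurationError

logger = logging.getLogger(__name__)

MODES = ("init", "iter", "random")
DISTRIBUTIONS = ("normal", "lognormal")


@dataclass(frozen=True)
class PvarSpec:
    """How one model parameter varies across trials."""

    parameter: str
    mode: str
    init_value: float | None = None
    increment: float | None = None
    distribution: str | None = None
    mean: float | None = None
    standard_deviation: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(
                f"pvar mode must be one of {MODES}, got {self.mode!r}"
            )
        if self.mode in ("init", "iter") and self.init_value is None:
            raise ConfigurationError(f"mode {self.mode!r} requires init_value")
        if self.mode == "iter" and self.increment is None:
            raise ConfigurationError("mode 'iter' requires an increment")
        if self.mode == "random":
            if self.distribution not in DISTRIBUTIONS:
                raise ConfigurationError(
                    f"random pvar requires distribution in {DISTRIBUTIONS}, "
                    f"got {self.distribution!r}"
                )
            if self.mean is None or self.standard_deviation is None:
                raise ConfigurationError("random pvar requires mean and standard_deviation")
            if self.standard_deviation <= 0:
                raise ConfigurationError("standard_deviation must be > 0")
            if self.distribution == "lognormal" and self.mean <= 0:
                raise ConfigurationError("lognormal mean must be > 0")


def _trial_rng(seed: int, parameter: str, trial: int) -> np.random.Generator:
    # Counter-based stream: one generator per (seed, parameter, trial) so
    # each draw is independent of every other spec and of numtrials.
    tag = zlib.crc32(parameter.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, trial]))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Natural-scale (mean, sd) → log-scale (µ, σ)."""
    mu = math.log(mean * mean / math.sqrt(mean * mean + sd * sd))
    sigma = math.sqrt(math.log(1.0 + (sd * sd) / (mean * mean)))
    return mu, sigma


def _draw(spec: PvarSpec, seed: int, trial: int) -> float:
    rng = _trial_rng(seed, spec.parameter, trial)
    if spec.distribution == "normal":
        value = spec.mean + spec.standard_deviation * rng.standard_normal()
        if value < 0.0:
            logger.warning(
                "normal draw for %r in trial %d was %.4g < 0; floored at 0 "
                "(negative conductance factors are unphysical)",
                spec.parameter, trial, value,
            )
            value = 0.0
        return value
    mu, sigma = _lognormal_params(spec.mean, spec.standard_deviation)
    return float(rng.lognormal(mean=mu, sigma=sigma))


def resolve_pvars(
    specs: Iterable[PvarSpec], numtrials: int, seed: int
) -> list[dict[str, float]]:
    """Resolve the factor map applied to each of ``numtrials`` trials.

    Returns one ``{parameter: factor}`` dict per trial.  Duplicate parameter
    names across specs are rejected.
    """
    specs = list(specs)
    if numtrials < 1:
        raise ConfigurationError(f"numtrials must be >= 1, got {numtrials}")
    names = [s.parameter for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate parameter in pvars: {sorted(names)}")
    out: list[dict[str, float]] = []
    for i in range(numtrials):
        factors: dict[str, float] = {}
        for spec in specs:
            if spec.mode == "init":
                factors[spec.parameter] = float(spec.init_value)
            elif spec.mode == "iter":
                factors[spec.parameter] = float(spec.init_value) + i * float(spec.increment)
            else:
                factors[spec.parameter] = _draw(spec, seed, i)
        out.append(factors)
    return out


def summarize_draws(factors: Sequence[float]) -> tuple[float, float]:
    """Sample mean and unbiased standard deviation of a list of factors."""
    if len(factors) < 2:
        raise ValueError("need at least 2 values to summarize")
    arr = np.asarray(factors, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
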