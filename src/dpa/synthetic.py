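"""Synthetic latency generators with known structure.

Provides ex-Gaussian baseline samples (the standard positively skewed model
for response latencies), null condition pairs with no true divergence, and
populations carrying artificially injected divergence points: latencies
below a participant's divergence value are shared verbatim between
conditions, while a random half of the latencies at or above it are
lengthened by a fixed amount in the slow condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .survival import FAST, SLOW, InvalidInputError, LatencyTable

__all__ = [
    "ExGaussianParams",
    "ArtificialEffectSpec",
    "sample_exgaussian",
    "make_artificial_slow",
    "generate_simulation2_population",
    "generate_null_population",
    "DEFAULT_DIVERGENCE_VALUES",
]

#: Default injected divergence values: 110..210 ms inclusive in 4-ms steps
#: (26 distinct values; mean 160 ms).
DEFAULT_DIVERGENCE_VALUES: tuple[float, ...] = tuple(float(v) for v in range(110, 211, 4))


@dataclass(frozen=True)
class ExGaussianParams:
    """Gaussian-plus-exponential latency model.

    Distribution mean is ``mu + tau`` and variance ``sigma**2 + tau**2``.
    Defaults emulate a fast-condition fixation-duration distribution: mean
    ~203 ms with a clear rightward skew and a left tail that, like empirical
    fixation-duration pools, carries some mass down to ~110 ms.
    """

    mu: float = 176.0
    sigma: float = 24.0
    tau: float = 27.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidInputError("sigma must be > 0")
        if self.tau < 0:
            raise InvalidInputError("tau must be >= 0")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def sd(self) -> float:
        return float(np.hypot(self.sigma, self.tau))


@dataclass(frozen=True)
class ArtificialEffectSpec:
    """Construction rule for injected divergence effects.

    Each participant receives one value from ``divergence_values``; in their
    slow condition a random ``proportion`` of the latencies at or above that
    value are lengthened by ``delta`` ms.
    """

    divergence_values: tuple[float, ...] = DEFAULT_DIVERGENCE_VALUES
    delta: float = 50.0
    proportion: float = 0.5

    def __post_init__(self) -> None:
        if not self.divergence_values or any(v <= 0 for v in self.divergence_values):
            raise InvalidInputError("divergence values must be positive and non-empty")
        if not (0 < self.proportion <= 1):
            raise InvalidInputError("proportion must be in (0, 1]")
        if self.delta <= 0:
            raise InvalidInputError("delta must be > 0")


def sample_exgaussian(
    n: int, params: ExGaussianParams, rng: np.random.Generator
) -> np.ndarray:
    """``n`` positive draws of Gaussian(mu, sigma) + Exponential(tau).

    Non-positive draws are redrawn rather than clipped, so no point mass
    accumulates at the floor.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    out = np.empty(n, dtype=float)
    remaining = np.arange(n)
    while remaining.size:
        draws = rng.normal(params.mu, params.sigma, size=remaining.size)
        if params.tau > 0:
            draws += rng.exponential(params.tau, size=remaining.size)
        out[remaining] = draws
        remaining = remaining[draws <= 0]
    return out


def make_artificial_slow(
    fast: Sequence[float] | np.ndarray,
    d_sim: float,
    delta: float = 50.0,
    proportion: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Slow-condition counterpart of ``fast`` with a divergence at ``d_sim``.

    Values below ``d_sim`` are copied unchanged; of the values >= ``d_sim``,
    a uniformly random subset of size ``round(proportion * count)``
    (round-half-to-even) is lengthened by ``delta``.  Length and pairing
    order are preserved.
    """
    if rng is None:
        rng = np.random.default_rng()
    fast = np.asarray(fast, dtype=float)
    if fast.size == 0:
        raise InvalidInputError("fast pool must be non-empty")
    slow = fast.copy()
    eligible = np.nonzero(fast >= d_sim)[0]
    k = round(proportion * eligible.size)
    if k > 0:
        chosen = rng.choice(eligible, size=k, replace=False)
        slow[chosen] += delta
    return slow


def generate_simulation2_population(
    n_participants: int = 104,
    per_cell: int = 60,
    base: Optional[ExGaussianParams] = None,
    spec: Optional[ArtificialEffectSpec] = None,
    seed: Optional[int] = None,
) -> tuple[LatencyTable, dict[str, float]]:
    """Population with known injected divergence points.

    Participants are randomly divided into equally sized groups, one group
    per distinct divergence value.  Returns the latency table and the truth
    map ``{participant_id: d_sim}`` for recovery scoring.
    """
    base = base or ExGaussianParams()
    spec = spec or ArtificialEffectSpec()
    n_groups = len(spec.divergence_values)
    if n_participants % n_groups:
        raise InvalidInputError(
            f"n_participants ({n_participants}) must be divisible by the number "
            f"of divergence values ({n_groups})"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_participants))
    pids = [f"p{i + 1:0{width}d}" for i in range(n_participants)]
    # random division into groups: shuffle, then chunk
    order = rng.permutation(n_participants)
    per_group = n_participants // n_groups
    truth: dict[str, float] = {}
    for g, d_sim in enumerate(spec.divergence_values):
        for idx in order[g * per_group : (g + 1) * per_group]:
            truth[pids[idx]] = float(d_sim)
    cells: dict[tuple[str, str], np.ndarray] = {}
    for pid in pids:
        fast = sample_exgaussian(per_cell, base, rng)
        slow = make_artificial_slow(fast, truth[pid], spec.delta, spec.proportion, rng)
        cells[(pid, FAST)] = fast
        cells[(pid, SLOW)] = slow
    return LatencyTable(cells), truth


def generate_null_population(
    n_participants: int = 52,
    per_cell: int = 60,
    base: Optional[ExGaussianParams] = None,
    seed: Optional[int] = None,
) -> LatencyTable:
    """Both conditions drawn independently from one distribution: no true
    divergence exists."""
    if n_participants < 1 or per_cell < 1:
        raise InvalidInputError("participant and cell counts must be >= 1")
    base = base or ExGaussianParams()
    rng = np.random.default_rng(seed)
    width = len(str(n_participants))
    cells: dict[tuple[str, str], np.ndarray] = {}
    for i in range(n_participants):
        pid = f"p{i + 1:0{width}d}"
        cells[(pid, SLOW)] = sample_exgaussian(per_cell, base, rng)
        cells[(pid, FAST)] = sample_exgaussian(per_cell, base, rng)
    return LatencyTable(cells)
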