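"""Individual-participant divergence point procedure.

Within each bootstrap iteration, a fixed number of latencies (default 1200)
is drawn with replacement from each condition's pool, both draws are sorted
ascending, and the two order statistics are paired index-wise.  Bin ``i``
(1-based) carries survival percent ``100 - i/n * 100``; its difference is
``s_i - f_i``.  The divergence value of the iteration is the mean of the
pair opening the first run of ``run_length`` strictly positive differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._util import first_run_starts
from .survival import FAST, SLOW, InvalidInputError, LatencyTable

__all__ = [
    "IndividualConfig",
    "PairedOrderStatistics",
    "ParticipantDivergence",
    "IndividualGroupResult",
    "pair_iteration",
    "iteration_individual_divergence",
    "ip_dpa_participant",
    "ip_dpa_group",
    "compare_individual_estimates",
]

logger = logging.getLogger(__name__)

#: Detection-rate cutoff below which a participant's estimate is unreliable.
RELIABILITY_CUTOFF = 0.5


@dataclass(frozen=True)
class IndividualConfig:
    """Configuration of the individual-participant procedure."""

    n_iterations: int = 1000
    resample_n: int = 1200
    run_length: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise InvalidInputError("n_iterations must be >= 1")
        if self.resample_n < 1:
            raise InvalidInputError("resample_n must be >= 1")
        if not (1 <= self.run_length <= self.resample_n):
            raise InvalidInputError("run_length must satisfy 1 <= run_length <= resample_n")


@dataclass(frozen=True)
class PairedOrderStatistics:
    """Sorted-and-paired resamples from the slow and fast pools."""

    slow_sorted: np.ndarray
    fast_sorted: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.slow_sorted, dtype=float)
        f = np.asarray(self.fast_sorted, dtype=float)
        if s.shape != f.shape or s.ndim != 1:
            raise InvalidInputError("paired resamples must be 1-D and equal length")
        object.__setattr__(self, "slow_sorted", s)
        object.__setattr__(self, "fast_sorted", f)

    @property
    def n(self) -> int:
        return self.slow_sorted.size

    @property
    def diff(self) -> np.ndarray:
        """Per-bin slow-minus-fast duration difference, d_i = s_i - f_i."""
        return self.slow_sorted - self.fast_sorted

    @property
    def survival_percent(self) -> np.ndarray:
        """Survival percent attached to bin i (1-based): 100 - i/n * 100."""
        i = np.arange(1, self.n + 1)
        return 100.0 - i / self.n * 100.0


@dataclass(frozen=True)
class ParticipantDivergence:
    """One participant's estimate plus its reliability status."""

    participant_id: str
    estimate: Optional[float]
    detection_rate: float
    iteration_values: np.ndarray

    @property
    def reliable(self) -> bool:
        return self.detection_rate >= RELIABILITY_CUTOFF


@dataclass(frozen=True)
class IndividualGroupResult:
    """Per-participant estimates and the reliable-only group summary."""

    per_participant: tuple[ParticipantDivergence, ...]
    group_mean: Optional[float]
    group_sd: Optional[float]
    n_excluded: int
    seed: Optional[int]


def pair_iteration(
    slow_pool: Sequence[float] | np.ndarray,
    fast_pool: Sequence[float] | np.ndarray,
    resample_n: int,
    rng: np.random.Generator,
    participant: Optional[str] = None,
) -> PairedOrderStatistics:
    """Draw ``resample_n`` latencies with replacement from each pool and sort.

    The resample size is fixed regardless of how many observations the pools
    contain, so every participant contributes the same survival grid.
    """
    who = f" (participant {participant!r})" if participant else ""
    slow = np.asarray(slow_pool, dtype=float)
    fast = np.asarray(fast_pool, dtype=float)
    if slow.size == 0:
        raise InvalidInputError(f"empty slow pool{who}")
    if fast.size == 0:
        raise InvalidInputError(f"empty fast pool{who}")
    s = np.sort(rng.choice(slow, size=resample_n, replace=True))
    f = np.sort(rng.choice(fast, size=resample_n, replace=True))
    return PairedOrderStatistics(slow_sorted=s, fast_sorted=f)


def iteration_individual_divergence(
    pairs: PairedOrderStatistics, run_length: int = 100
) -> Optional[float]:
    """Mean of the pair opening the first run of ``run_length`` bins with
    strictly positive difference (s_i > f_i); ties break a run."""
    found, start = first_run_starts((pairs.diff > 0.0)[None, :], run_length)
    if not found[0]:
        return None
    i = int(start[0])
    return float((pairs.slow_sorted[i] + pairs.fast_sorted[i]) / 2.0)


def _participant_iteration_values(
    slow: np.ndarray, fast: np.ndarray, config: IndividualConfig, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized per-iteration divergence values for one participant."""
    n_iter, m = config.n_iterations, config.resample_n
    s = np.sort(slow[rng.integers(0, slow.size, size=(n_iter, m))], axis=1)
    f = np.sort(fast[rng.integers(0, fast.size, size=(n_iter, m))], axis=1)
    found, start = first_run_starts(s > f, config.run_length)
    rows = np.nonzero(found)[0]
    return (s[rows, start[rows]] + f[rows, start[rows]]) / 2.0


def ip_dpa_participant(
    slow_pool: Sequence[float] | np.ndarray,
    fast_pool: Sequence[float] | np.ndarray,
    config: Optional[IndividualConfig] = None,
    participant: str = "participant",
    rng: Optional[np.random.Generator] = None,
) -> ParticipantDivergence:
    """Run the individual procedure for one participant.

    Iterations without a detected divergence are discarded; the estimate is
    the median of the remaining values.  Participants detecting in fewer than
    half of the iterations are flagged unreliable, not rejected.
    """
    if config is None:
        config = IndividualConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    slow = np.asarray(slow_pool, dtype=float)
    fast = np.asarray(fast_pool, dtype=float)
    if slow.size == 0 or fast.size == 0:
        role = SLOW if slow.size == 0 else FAST
        raise InvalidInputError(f"empty {role} pool (participant {participant!r})")
    values = _participant_iteration_values(slow, fast, config, rng)
    estimate = float(np.median(values)) if values.size else None
    return ParticipantDivergence(
        participant_id=str(participant),
        estimate=estimate,
        detection_rate=values.size / config.n_iterations,
        iteration_values=values,
    )


def _participant_rng(master_seed: Optional[int], rank: int) -> np.random.Generator:
    # substream keyed by (master seed, participant rank in sorted-id order):
    # results are invariant to input row order and reproducible per participant
    entropy = [rank] if master_seed is None else [master_seed, rank]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def ip_dpa_group(
    table: LatencyTable, config: Optional[IndividualConfig] = None
) -> IndividualGroupResult:
    """Individual procedure across every participant in the table.

    The group mean and SD are computed over reliable participants only;
    unreliable participants are counted in ``n_excluded``.
    """
    if config is None:
        config = IndividualConfig()
    results = []
    for rank, pid in enumerate(table.participants):
        rng = _participant_rng(config.seed, rank)
        results.append(
            ip_dpa_participant(
                table.cell(pid, SLOW),
                table.cell(pid, FAST),
                config,
                participant=pid,
                rng=rng,
            )
        )
    reliable = [r.estimate for r in results if r.reliable and r.estimate is not None]
    n_excluded = len(results) - len(reliable)
    if reliable:
        group_mean = float(np.mean(reliable))
        group_sd = float(np.std(reliable, ddof=1)) if len(reliable) > 1 else 0.0
    else:
        logger.warning("ip_dpa_group: no reliable participant estimates")
        group_mean = None
        group_sd = None
    return IndividualGroupResult(
        per_participant=tuple(results),
        group_mean=group_mean,
        group_sd=group_sd,
        n_excluded=n_excluded,
        seed=config.seed,
    )


def compare_individual_estimates(
    a: Sequence[float] | Mapping[str, float],
    b: Sequence[float] | Mapping[str, float],
    paired: bool = True,
) -> tuple[float, float, float]:
    """t-test between two vectors of per-participant estimates.

    Paired (default) requires matched participants; mappings are aligned on
    their shared keys.  Unpaired uses Welch's correction.  Returns
    ``(t, df, p)``.
    """
    if isinstance(a, Mapping) and isinstance(b, Mapping):
        keys = sorted(set(a) & set(b)) if paired else None
        if paired:
            xs = np.asarray([a[k] for k in keys], dtype=float)
            ys = np.asarray([b[k] for k in keys], dtype=float)
        else:
            xs = np.asarray(sorted(a.values()), dtype=float)
            ys = np.asarray(sorted(b.values()), dtype=float)
    else:
        xs = np.asarray(a, dtype=float)
        ys = np.asarray(b, dtype=float)
    if paired:
        if xs.size != ys.size:
            raise InvalidInputError("paired comparison requires equal-length estimate vectors")
        if xs.size < 2:
            raise InvalidInputError("need at least 2 complete pairs")
        if np.allclose(xs, ys):
            return 0.0, float(xs.size - 1), 1.0
        res = stats.ttest_rel(xs, ys)
        df = float(xs.size - 1)
    else:
        if xs.size < 2 or ys.size < 2:
            raise InvalidInputError("need at least 2 estimates per group")
        res = stats.ttest_ind(xs, ys, equal_var=False)
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)
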