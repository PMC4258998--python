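"""Group-level divergence point procedures.

Two bootstrap procedures over group-average survival curves:

* the original procedure — per-bin ranked confidence intervals of the
  slow-minus-fast difference across iterations, with a divergence declared at
  the first bin opening a run of consecutive significant bins; and
* the confidence-interval (CI) procedure — a divergence point computed within
  every iteration (threshold + run rule), summarized by the median and a
  ranked-value interval over the per-iteration estimates.

Both resample observations with replacement within each (participant,
condition) cell; participants themselves are never resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ._util import first_run_starts, ranked_ci, scaled_ranks
from .survival import (
    DEFAULT_T_MAX,
    FAST,
    ROLES,
    SLOW,
    DifferenceCurve,
    InvalidInputError,
    LatencyTable,
    SurvivalCurve,
    survival_matrix,
)

__all__ = [
    "ProcedureConfig",
    "DivergenceResult",
    "bootstrap_group_curves",
    "original_dpa",
    "iteration_divergence",
    "ci_dpa",
    "compare_ci_overlap",
]

logger = logging.getLogger(__name__)

# Nominal CI coverage fractions implied by the default ranked indices:
# 5/10,000 and 9,995/10,000 for the original per-bin interval (99.9%),
# 25/1,000 and 975/1,000 for the CI procedure (95%).
_ORIGINAL_LOWER_FRAC = 0.0005
_ORIGINAL_UPPER_FRAC = 0.9995
_CI_LOWER_FRAC = 0.025
_CI_UPPER_FRAC = 0.975


@dataclass(frozen=True)
class ProcedureConfig:
    """Knobs shared by the bootstrap procedures.

    ``ci_lower_index`` / ``ci_upper_index`` are 1-based ranks into the
    ascending sorted vector of iteration values, exactly as the ranked-value
    interval is counted.
    """

    n_iterations: int = 1000
    run_length: int = 5
    difference_threshold: float = 1.5
    ci_lower_index: int = 25
    ci_upper_index: int = 975
    t_max: int = DEFAULT_T_MAX
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise InvalidInputError("n_iterations must be >= 1")
        if not (1 <= self.ci_lower_index < self.ci_upper_index <= self.n_iterations):
            raise InvalidInputError(
                "CI ranks must satisfy 1 <= lower < upper <= n_iterations"
            )
        if self.run_length < 1:
            raise InvalidInputError("run_length must be >= 1")
        if self.difference_threshold < 0:
            raise InvalidInputError("difference_threshold must be >= 0")
        if self.t_max < 1:
            raise InvalidInputError("t_max must be >= 1")

    @classmethod
    def original(cls, n_iterations: int = 10_000, **kwargs) -> "ProcedureConfig":
        """Defaults for the original procedure: 10,000 iterations, per-bin
        99.9% ranked interval, significance = lower bound > 0, run of 5."""
        lo = max(1, round(_ORIGINAL_LOWER_FRAC * n_iterations))
        hi = min(n_iterations, round(_ORIGINAL_UPPER_FRAC * n_iterations))
        if hi <= lo:
            hi = lo + 1
        return cls(
            n_iterations=n_iterations,
            run_length=kwargs.pop("run_length", 5),
            difference_threshold=kwargs.pop("difference_threshold", 0.0),
            ci_lower_index=kwargs.pop("ci_lower_index", lo),
            ci_upper_index=kwargs.pop("ci_upper_index", hi),
            **kwargs,
        )

    @classmethod
    def ci(cls, n_iterations: int = 1000, **kwargs) -> "ProcedureConfig":
        """Defaults for the CI procedure: 1,000 iterations, 1.5% threshold,
        run of 5, 95% ranked interval over iteration estimates."""
        lo = max(1, round(_CI_LOWER_FRAC * n_iterations))
        hi = min(n_iterations, round(_CI_UPPER_FRAC * n_iterations))
        if hi <= lo:
            hi = lo + 1
        return cls(
            n_iterations=n_iterations,
            run_length=kwargs.pop("run_length", 5),
            difference_threshold=kwargs.pop("difference_threshold", 1.5),
            ci_lower_index=kwargs.pop("ci_lower_index", lo),
            ci_upper_index=kwargs.pop("ci_upper_index", hi),
            **kwargs,
        )

    def with_seed(self, seed: Optional[int]) -> "ProcedureConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class DivergenceResult:
    """Outcome of a divergence point procedure."""

    procedure: str
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    iteration_estimates: np.ndarray
    detection_rate: float
    n_iterations: int
    seed: Optional[int]
    per_bin_significant: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (
            self.estimate is not None
            and self.ci_low is not None
            and self.ci_high is not None
        ):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise InvalidInputError("estimate must lie within its CI")


def _group_mean_survival_matrices(
    table: LatencyTable, n_iterations: int, t_max: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Bootstrap group-average survival curves for every iteration at once.

    Returns ``{role: matrix}`` with shape ``(n_iterations, t_max + 1)``:
    row ``i`` is the across-participant mean survival curve of iteration
    ``i``.  Each cell is resampled with replacement to its observed size.
    RNG draws follow a fixed order (sorted participants, slow then fast) so
    results are reproducible and independent of input row order.
    """
    participants = table.participants
    sums = {role: np.zeros((n_iterations, t_max + 1)) for role in ROLES}
    for pid in participants:
        for role in ROLES:
            pool = table.cell(pid, role)
            idx = rng.integers(0, pool.size, size=(n_iterations, pool.size))
            sums[role] += survival_matrix(pool[idx], t_max)
    n = len(participants)
    return {role: sums[role] / n for role in ROLES}


def bootstrap_group_curves(
    table: LatencyTable, config: ProcedureConfig, rng: np.random.Generator
) -> tuple[SurvivalCurve, SurvivalCurve]:
    """One bootstrap iteration: resampled group-average slow and fast curves."""
    mats = _group_mean_survival_matrices(table, 1, config.t_max, rng)
    bins = np.arange(config.t_max + 1)
    return (
        SurvivalCurve(bins=bins, survival=mats[SLOW][0]),
        SurvivalCurve(bins=bins.copy(), survival=mats[FAST][0]),
    )


def original_dpa(table: LatencyTable, config: Optional[ProcedureConfig] = None) -> DivergenceResult:
    """Original group procedure.

    A bin is significant when the ranked lower bound of the bootstrap
    distribution of the slow-minus-fast difference at that bin is strictly
    greater than zero; the divergence point is the first significant bin
    beginning a run of ``run_length`` consecutive significant bins.
    """
    if config is None:
        config = ProcedureConfig.original()
    rng = np.random.default_rng(config.seed)
    mats = _group_mean_survival_matrices(table, config.n_iterations, config.t_max, rng)
    diffs = mats[SLOW] - mats[FAST]  # (n_iterations, n_bins)
    # per-bin ranked lower/upper bounds across iterations
    lower = np.partition(diffs, config.ci_lower_index - 1, axis=0)[config.ci_lower_index - 1]
    significant = lower > 0.0
    found, start = first_run_starts(significant[None, :], config.run_length)
    estimate = float(start[0]) if found[0] else None
    return DivergenceResult(
        procedure="original",
        estimate=estimate,
        ci_low=None,
        ci_high=None,
        iteration_estimates=np.asarray([], dtype=float),
        detection_rate=1.0 if found[0] else 0.0,
        n_iterations=config.n_iterations,
        seed=config.seed,
        per_bin_significant=significant,
    )


def iteration_divergence(
    diff: DifferenceCurve | np.ndarray,
    threshold: float,
    run_length: int,
    bins: Optional[np.ndarray] = None,
) -> Optional[float]:
    """First bin opening ``run_length`` consecutive bins with diff >= threshold.

    "At least" the threshold means the comparison is ``>=``.  Returns the bin
    time in ms, or ``None`` when no qualifying run exists.
    """
    if isinstance(diff, DifferenceCurve):
        values, grid = diff.diff, diff.bins
    else:
        values = np.asarray(diff, dtype=float)
        grid = np.arange(values.size) if bins is None else np.asarray(bins)
    found, start = first_run_starts(values >= threshold, run_length)
    return float(grid[start[0]]) if found[0] else None


def ci_dpa(table: LatencyTable, config: Optional[ProcedureConfig] = None) -> DivergenceResult:
    """Confidence-interval procedure.

    Every iteration yields its own divergence point (threshold + run rule on
    the resampled group difference curve); the estimate is the median of the
    detected values and the CI the ranked values at the configured ranks.
    Iterations detecting no divergence are dropped before ranking, with the
    ranks rescaled proportionally to the retained count.
    """
    if config is None:
        config = ProcedureConfig.ci()
    rng = np.random.default_rng(config.seed)
    mats = _group_mean_survival_matrices(table, config.n_iterations, config.t_max, rng)
    diffs = mats[SLOW] - mats[FAST]
    found, start = first_run_starts(diffs >= config.difference_threshold, config.run_length)
    bins = np.arange(config.t_max + 1)
    estimates = bins[start[found]].astype(float)
    detection_rate = estimates.size / config.n_iterations
    if estimates.size == 0:
        logger.warning(
            "ci_dpa: no iteration detected a divergence point (n_iterations=%d)",
            config.n_iterations,
        )
        return DivergenceResult(
            procedure="ci",
            estimate=None,
            ci_low=None,
            ci_high=None,
            iteration_estimates=estimates,
            detection_rate=0.0,
            n_iterations=config.n_iterations,
            seed=config.seed,
        )
    ordered = np.sort(estimates)
    lo_rank, hi_rank = scaled_ranks(
        ordered.size,
        config.ci_lower_index / config.n_iterations,
        config.ci_upper_index / config.n_iterations,
    )
    ci_low, ci_high = ranked_ci(ordered, lo_rank, hi_rank)
    if detection_rate < 1.0:
        logger.info(
            "ci_dpa: divergence detected in %d/%d iterations (rate %.3f)",
            ordered.size,
            config.n_iterations,
            detection_rate,
        )
    return DivergenceResult(
        procedure="ci",
        estimate=float(np.median(ordered)),
        ci_low=ci_low,
        ci_high=ci_high,
        iteration_estimates=estimates,
        detection_rate=detection_rate,
        n_iterations=config.n_iterations,
        seed=config.seed,
    )


def compare_ci_overlap(a: DivergenceResult, b: DivergenceResult) -> bool:
    """True when the two closed CIs are disjoint (a significant difference).

    A shared endpoint counts as overlap, which is conservative for claiming
    that two conditions differ.
    """
    for r in (a, b):
        if r.ci_low is None or r.ci_high is None:
            raise InvalidInputError(
                f"result for procedure {r.procedure!r} has no confidence interval"
            )
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low
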