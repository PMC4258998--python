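"""Empirical survival curves over 1-ms time bins.

The survival percent at time ``t`` is the percentage of latencies strictly
exceeding ``t``.  Curves are evaluated on the integer grid ``0..t_max``;
latencies themselves are kept as (possibly non-integer) milliseconds and are
never rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LatencyTable",
    "SurvivalCurve",
    "DifferenceCurve",
    "compute_survival_curve",
    "group_average_curve",
    "difference_curve",
    "DEFAULT_T_MAX",
]

#: Default upper edge of the evaluation grid, in ms.
DEFAULT_T_MAX = 600

SLOW = "slow"
FAST = "fast"
ROLES = (SLOW, FAST)


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class LatencyTable:
    """Long-format latency observations, keyed by (participant, role).

    ``cells`` maps ``(participant_id, role)`` to a 1-D float array of
    latencies in ms, with ``role`` being ``"slow"`` or ``"fast"``.  Every
    participant must contribute at least one observation to both roles and
    every latency must be finite and strictly positive.
    """

    cells: Mapping[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        normalized: dict[tuple[str, str], np.ndarray] = {}
        participants: dict[str, set[str]] = {}
        for key, values in self.cells.items():
            pid, role = str(key[0]), str(key[1])
            if role not in ROLES:
                raise InvalidInputError(f"unknown condition role {role!r} for participant {pid!r}")
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise InvalidInputError(
                    f"empty latency cell for participant {pid!r}, condition {role!r}"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise InvalidInputError(
                    f"non-finite or non-positive latency in cell ({pid!r}, {role!r})"
                )
            normalized[(pid, role)] = arr
            participants.setdefault(pid, set()).add(role)
        object.__setattr__(self, "cells", normalized)
        if not participants:
            raise InvalidInputError("latency table is empty")
        for pid, roles in participants.items():
            missing = set(ROLES) - roles
            if missing:
                raise InvalidInputError(
                    f"participant {pid!r} is missing condition(s): {sorted(missing)}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[object, str, float]]
    ) -> "LatencyTable":
        """Build a table from ``(participant, role, latency_ms)`` triples."""
        buckets: dict[tuple[str, str], list[float]] = {}
        for pid, role, latency in records:
            buckets.setdefault((str(pid), str(role)), []).append(float(latency))
        return cls({k: np.asarray(v, dtype=float) for k, v in buckets.items()})

    @property
    def participants(self) -> list[str]:
        """Participant ids in stable sorted order."""
        return sorted({pid for pid, _ in self.cells})

    def cell(self, participant: str, role: str) -> np.ndarray:
        return np.asarray(self.cells[(str(participant), role)], dtype=float)

    def n_observations(self) -> int:
        return int(sum(len(v) for v in self.cells.values()))

    def subset(self, participants: Sequence[str]) -> "LatencyTable":
        """Restrict the table to the given participants (order irrelevant)."""
        wanted = {str(p) for p in participants}
        missing = wanted - set(self.participants)
        if missing:
            raise InvalidInputError(f"unknown participant(s): {sorted(missing)}")
        return LatencyTable(
            {k: v for k, v in self.cells.items() if k[0] in wanted}
        )

    def subsample_observations(self, per_cell: int, rng: np.random.Generator) -> "LatencyTable":
        """Sample ``per_cell`` observations per cell without replacement."""
        out: dict[tuple[str, str], np.ndarray] = {}
        for pid in self.participants:
            for role in ROLES:
                pool = self.cell(pid, role)
                if per_cell > pool.size:
                    raise InvalidInputError(
                        f"cannot draw {per_cell} from cell ({pid!r}, {role!r}) "
                        f"of size {pool.size} without replacement"
                    )
                out[(pid, role)] = rng.choice(pool, size=per_cell, replace=False)
        return LatencyTable(out)


@dataclass(frozen=True)
class SurvivalCurve:
    """Percent of latencies strictly exceeding each integer time bin."""

    bins: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=int)
        surv = np.asarray(self.survival, dtype=float)
        if bins.shape != surv.shape:
            raise InvalidInputError("bins and survival must have identical shape")
        object.__setattr__(self, "bins", bins)
        object.__setattr__(self, "survival", surv)

    def at(self, t: int) -> float:
        idx = int(t) - int(self.bins[0])
        return float(self.survival[idx])


@dataclass(frozen=True)
class DifferenceCurve:
    """Slow-minus-fast survival percent per bin."""

    bins: np.ndarray
    diff: np.ndarray

    def at(self, t: int) -> float:
        idx = int(t) - int(self.bins[0])
        return float(self.diff[idx])


def _check_latencies(latencies: np.ndarray, cell: tuple[str, str] | None = None) -> np.ndarray:
    arr = np.asarray(latencies, dtype=float)
    if arr.size == 0:
        where = f" for cell {cell!r}" if cell else ""
        raise InvalidInputError(f"empty latency sequence{where}")
    return arr


def compute_survival_curve(
    latencies: Sequence[float] | np.ndarray,
    t_max: int = DEFAULT_T_MAX,
    cell: tuple[str, str] | None = None,
) -> SurvivalCurve:
    """Survival percent ``100 * #{x > t} / n`` on the grid ``t = 0..t_max``.

    The inequality is strict: a latency exactly equal to ``t`` has ended at
    ``t`` and does not survive it.  Latencies above ``t_max`` are retained in
    the data; the curve is simply not evaluated beyond ``t_max``.
    """
    arr = _check_latencies(latencies, cell)
    if t_max < 1:
        raise InvalidInputError("t_max must be >= 1")
    bins = np.arange(t_max + 1)
    ordered = np.sort(arr)
    # count of values <= t  ==  right-insertion index of t in the sorted data
    n_le = np.searchsorted(ordered, bins, side="right")
    survival = 100.0 * (arr.size - n_le) / arr.size
    return SurvivalCurve(bins=bins, survival=survival)


def _require_same_grid(bins_a: np.ndarray, bins_b: np.ndarray) -> None:
    if bins_a.shape != bins_b.shape or not np.array_equal(bins_a, bins_b):
        raise InvalidInputError("survival curves are defined on mismatched bin grids")


def group_average_curve(curves: Sequence[SurvivalCurve]) -> SurvivalCurve:
    """Unweighted per-bin mean across participants' curves.

    Participants are the sampling unit, so each curve contributes equally
    regardless of how many observations produced it.
    """
    if len(curves) == 0:
        raise InvalidInputError("cannot average zero curves")
    bins = curves[0].bins
    for c in curves[1:]:
        _require_same_grid(bins, c.bins)
    stacked = np.vstack([c.survival for c in curves])
    return SurvivalCurve(bins=bins.copy(), survival=stacked.mean(axis=0))


def difference_curve(slow: SurvivalCurve, fast: SurvivalCurve) -> DifferenceCurve:
    """Element-wise slow-minus-fast difference of two survival curves."""
    _require_same_grid(slow.bins, fast.bins)
    return DifferenceCurve(bins=slow.bins.copy(), diff=slow.survival - fast.survival)


def survival_matrix(samples: np.ndarray, t_max: int) -> np.ndarray:
    """Row-wise survival curves for a matrix of latency resamples.

    ``samples`` has shape ``(n_rows, n_obs)``; the result has shape
    ``(n_rows, t_max + 1)`` with row ``r`` holding the survival percents of
    ``samples[r]`` on the grid ``0..t_max``.  Uses the identity
    ``#{x <= t} = #{ceil(x) <= t}`` for integer ``t`` so each row costs a
    single bincount + cumulative sum rather than a sort.
    """
    samples = np.asarray(samples, dtype=float)
    n_rows, n_obs = samples.shape
    width = t_max + 2  # one slot per bin plus overflow for x > t_max
    levels = np.clip(np.ceil(samples).astype(np.int64), 0, t_max + 1)
    flat = levels + (np.arange(n_rows, dtype=np.int64)[:, None] * width)
    counts = np.bincount(flat.ravel(), minlength=n_rows * width).reshape(n_rows, width)
    n_le = np.cumsum(counts[:, : t_max + 1], axis=1)
    return 100.0 * (n_obs - n_le) / n_obs


def curves_from_table(table: LatencyTable, t_max: int = DEFAULT_T_MAX) -> tuple[SurvivalCurve, SurvivalCurve]:
    """Empirical (non-bootstrap) group-average slow and fast curves."""
    out = []
    for role in ROLES:
        curves = [
            compute_survival_curve(table.cell(pid, role), t_max, cell=(pid, role))
            for pid in table.participants
        ]
        out.append(group_average_curve(curves))
    return out[0], out[1]
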