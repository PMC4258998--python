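"""End-to-end simulation designs for evaluating the procedures.

Design 1 subsamples participants from a parent population and summarizes
how each procedure's estimate degrades as the sample shrinks.  Design 2
injects known divergence points, subsamples observations per condition, and
scores recovery by the correlation between injected and estimated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .group import ProcedureConfig, ci_dpa, original_dpa
from .individual import IndividualConfig, ip_dpa_group
from .survival import InvalidInputError, LatencyTable
from .synthetic import (
    ArtificialEffectSpec,
    ExGaussianParams,
    generate_simulation2_population,
)

__all__ = [
    "SimulationSummary",
    "simulation1",
    "simulation2",
    "recovery_correlation",
]

PROCEDURES = ("original", "ci", "ip")


@dataclass
class SimulationSummary:
    """Replicate summaries keyed by (procedure, size).

    Each cell holds min/max/mean of the replicate estimates plus bookkeeping
    (how many replicates produced an estimate).  Design-2 cells additionally
    carry min/max/mean of the recovery correlation.  ``criteria`` holds the
    full-population estimate per procedure, used as the bias reference.
    """

    design: int
    cells: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    criteria: dict[str, Optional[float]] = field(default_factory=dict)
    seed: Optional[int] = None

    def cell(self, procedure: str, size: int) -> dict[str, float]:
        return self.cells[(procedure, size)]

    def to_jsonable(self) -> dict:
        return {
            "design": self.design,
            "seed": self.seed,
            "criteria": self.criteria,
            "cells": [
                {"procedure": proc, "size": size, **stats_}
                for (proc, size), stats_ in sorted(self.cells.items())
            ],
        }


def _summarize(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    out: dict[str, float] = {"n_estimates": int(arr.size)}
    if arr.size:
        out.update(min=float(arr.min()), max=float(arr.max()), mean=float(arr.mean()))
    return out


def _run_procedure(
    procedure: str,
    table: LatencyTable,
    seed: int,
    group_config: Optional[ProcedureConfig],
    original_config: Optional[ProcedureConfig],
    individual_config: Optional[IndividualConfig],
) -> Optional[float]:
    if procedure == "original":
        cfg = original_config or ProcedureConfig.original()
        return original_dpa(table, cfg.with_seed(seed)).estimate
    if procedure == "ci":
        cfg = group_config or ProcedureConfig.ci()
        return ci_dpa(table, cfg.with_seed(seed)).estimate
    if procedure == "ip":
        cfg = individual_config or IndividualConfig()
        cfg = IndividualConfig(cfg.n_iterations, cfg.resample_n, cfg.run_length, seed)
        return ip_dpa_group(table, cfg).group_mean
    raise InvalidInputError(f"unknown procedure {procedure!r}")


def simulation1(
    table: LatencyTable,
    sizes: Sequence[int] = (52, 26, 13),
    n_samples: int = 100,
    procedures: Sequence[str] = PROCEDURES,
    seed: Optional[int] = None,
    group_config: Optional[ProcedureConfig] = None,
    original_config: Optional[ProcedureConfig] = None,
    individual_config: Optional[IndividualConfig] = None,
) -> SimulationSummary:
    """Participant-subsampling design.

    For each size, ``n_samples`` independent subsets of participants are
    drawn without replacement and each procedure is run on every subset.
    Full-population estimates are recorded as the bias criteria.
    """
    participants = table.participants
    for size in sizes:
        if size > len(participants):
            raise InvalidInputError(
                f"subset size {size} exceeds population size {len(participants)}"
            )
    master = np.random.SeedSequence(seed)
    sampling_rng = np.random.default_rng(master.spawn(1)[0])
    proc_seeds = {p: int(s.generate_state(1)[0]) for p, s in zip(procedures, master.spawn(len(procedures)))}
    summary = SimulationSummary(design=1, seed=seed)
    for proc in procedures:
        summary.criteria[proc] = _run_procedure(
            proc, table, proc_seeds[proc], group_config, original_config, individual_config
        )
    replicate_seeds = master.generate_state(n_samples * len(sizes) * len(procedures)).reshape(
        len(sizes), n_samples, len(procedures)
    )
    for si, size in enumerate(sizes):
        subsets = [
            sampling_rng.choice(participants, size=size, replace=False) for _ in range(n_samples)
        ]
        for pi, proc in enumerate(procedures):
            estimates = [
                _run_procedure(
                    proc,
                    table.subset(subsets[r]),
                    int(replicate_seeds[si, r, pi]),
                    group_config,
                    original_config,
                    individual_config,
                )
                for r in range(n_samples)
            ]
            summary.cells[(proc, size)] = _summarize(estimates)
    return summary


def recovery_correlation(
    truth: Mapping[str, float], estimates: Mapping[str, Optional[float]]
) -> float:
    """Pearson correlation between injected and estimated divergence points.

    Participants lacking an estimate are excluded pairwise; at least three
    complete pairs are required.
    """
    keys = [k for k in truth if estimates.get(k) is not None]
    if len(keys) < 3:
        raise InvalidInputError(
            f"need >= 3 complete (truth, estimate) pairs, got {len(keys)}"
        )
    x = np.asarray([truth[k] for k in keys], dtype=float)
    y = np.asarray([estimates[k] for k in keys], dtype=float)
    return float(stats.pearsonr(x, y).statistic)


def simulation2(
    base: Optional[ExGaussianParams] = None,
    spec: Optional[ArtificialEffectSpec] = None,
    n_participants: int = 104,
    per_cell: int = 60,
    per_cell_sizes: Sequence[int] = (60, 36, 24, 12),
    n_samples: int = 100,
    seed: Optional[int] = None,
    individual_config: Optional[IndividualConfig] = None,
    fresh_population_per_replicate: bool = False,
) -> SimulationSummary:
    """Observation-count sweep of the individual procedure's recovery.

    A population with injected divergence points is generated once (or per
    replicate when ``fresh_population_per_replicate``); for each per-cell
    size below the full count, observations are repeatedly subsampled
    without replacement and recovery is scored by ``recovery_correlation``.
    At the full count a single run is reported.
    """
    base = base or ExGaussianParams()
    spec = spec or ArtificialEffectSpec()
    cfg = individual_config or IndividualConfig()
    master = np.random.SeedSequence(seed)
    pop_seed, sub_seed, run_seed = master.spawn(3)
    table, truth = generate_simulation2_population(
        n_participants, per_cell, base, spec, seed=int(pop_seed.generate_state(1)[0])
    )
    sub_rng = np.random.default_rng(sub_seed)
    seed_rng = np.random.default_rng(run_seed)

    def next_seed() -> int:
        return int(seed_rng.integers(0, 2**63 - 1))

    def run_ip(tbl: LatencyTable) -> dict[str, Optional[float]]:
        c = IndividualConfig(cfg.n_iterations, cfg.resample_n, cfg.run_length, next_seed())
        res = ip_dpa_group(tbl, c)
        return {p.participant_id: p.estimate for p in res.per_participant}

    summary = SimulationSummary(design=2, seed=seed)
    for size in per_cell_sizes:
        if size > per_cell:
            raise InvalidInputError(f"per-cell size {size} exceeds generated count {per_cell}")
        if size == per_cell:
            est = run_ip(table)
            r = recovery_correlation(truth, est)
            vals = [v for v in est.values() if v is not None]
            summary.cells[("ip", size)] = {
                "n_estimates": len(vals),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "mean": float(np.mean(vals)),
                "r_min": r,
                "r_max": r,
                "r_mean": r,
            }
            continue
        rs, means = [], []
        for _ in range(n_samples):
            if fresh_population_per_replicate:
                tbl_r, truth_r = generate_simulation2_population(
                    n_participants, per_cell, base, spec, seed=next_seed(),
                )
            else:
                tbl_r, truth_r = table, truth
            reduced = tbl_r.subsample_observations(size, sub_rng)
            est = run_ip(reduced)
            rs.append(recovery_correlation(truth_r, est))
            means.append(float(np.mean([v for v in est.values() if v is not None])))
        cell = _summarize(means)
        cell.update(
            r_min=float(np.min(rs)), r_max=float(np.max(rs)), r_mean=float(np.mean(rs))
        )
        summary.cells[("ip", size)] = cell
    return summary
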