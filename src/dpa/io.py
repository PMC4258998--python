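"""Reading, validation, and serialization of tables and results.

The single input dialect is a long/tidy CSV with header
``participant,condition,latency_ms``; which condition label plays the
"slow" role is always supplied explicitly, never guessed from the data.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .group import DivergenceResult, ProcedureConfig
from .individual import IndividualConfig, IndividualGroupResult
from .survival import FAST, SLOW, InvalidInputError, LatencyTable, SurvivalCurve

__all__ = [
    "read_latency_table",
    "write_latency_table",
    "write_survival_curve",
    "write_result",
    "read_result",
    "write_truth_map",
    "read_truth_map",
]

REQUIRED_COLUMNS = ("participant", "condition", "latency_ms")


class ValidationError(InvalidInputError):
    """Input file failed validation; ``errors`` lists every offending row."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def read_latency_table(
    path: Union[str, Path], slow_label: str, fast_label: str
) -> LatencyTable:
    """Load and validate a long-format latency CSV.

    Role assignment follows the supplied labels: rows whose condition equals
    ``slow_label`` become the slow cell and likewise for ``fast_label``.
    Every malformed row is reported (1-based data row numbers, excluding the
    header).
    """
    if slow_label == fast_label:
        raise InvalidInputError("slow and fast labels must differ")
    df = pd.read_csv(path, dtype={"participant": str, "condition": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing required column(s): {', '.join(missing)}"])
    errors: list[str] = []
    role_map = {slow_label: SLOW, fast_label: FAST}
    records: list[tuple[str, str, float]] = []
    latencies = pd.to_numeric(df["latency_ms"], errors="coerce")
    for row_no, (pid, cond, lat) in enumerate(
        zip(df["participant"], df["condition"], latencies), start=1
    ):
        if cond not in role_map:
            errors.append(f"row {row_no}: unknown condition {cond!r}")
            continue
        if pd.isna(lat) or not np.isfinite(lat) or lat <= 0:
            errors.append(f"row {row_no}: latency must be a positive number, got {df['latency_ms'].iloc[row_no - 1]!r}")
            continue
        records.append((str(pid), role_map[cond], float(lat)))
    if errors:
        raise ValidationError(errors)
    try:
        return LatencyTable.from_records(records)
    except InvalidInputError as exc:
        raise ValidationError([str(exc)]) from exc


def write_latency_table(
    table: LatencyTable,
    path: Union[str, Path],
    slow_label: str = SLOW,
    fast_label: str = FAST,
) -> None:
    """Serialize a table back to the long CSV dialect."""
    label = {SLOW: slow_label, FAST: fast_label}
    rows = [
        {"participant": pid, "condition": label[role], "latency_ms": float(v)}
        for (pid, role), values in sorted(table.cells.items())
        for v in values
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def write_survival_curve(curve: SurvivalCurve, path: Union[str, Path]) -> None:
    pd.DataFrame({"t_ms": curve.bins, "survival_pct": curve.survival}).to_csv(
        path, index=False
    )


def _config_echo(config) -> dict:
    return asdict(config)


def write_result(
    result: Union[DivergenceResult, IndividualGroupResult],
    config: Union[ProcedureConfig, IndividualConfig],
    path: Union[str, Path],
    iteration_csv: Optional[Union[str, Path]] = None,
    participant_csv: Optional[Union[str, Path]] = None,
) -> dict:
    """Write the JSON result envelope (and optional CSV side-products).

    Missing estimates serialize as explicit nulls.  The envelope echoes the
    full configuration and seed so any run can be reproduced from its output
    alone.  Returns the envelope dict.
    """
    from . import __version__

    envelope: dict = {
        "tool_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": _config_echo(config),
        "seed": config.seed,
    }
    if isinstance(result, DivergenceResult):
        envelope.update(
            procedure=result.procedure,
            estimate_ms=result.estimate,
            ci_low_ms=result.ci_low,
            ci_high_ms=result.ci_high,
            detection_rate=result.detection_rate,
            n_iterations=result.n_iterations,
        )
        if iteration_csv is not None:
            pd.DataFrame({"divergence_ms": result.iteration_estimates}).to_csv(
                iteration_csv, index=False
            )
    else:
        estimates = {
            p.participant_id: p.estimate for p in result.per_participant
        }
        envelope.update(
            procedure="ip",
            estimate_ms=result.group_mean,
            group_sd_ms=result.group_sd,
            n_excluded=result.n_excluded,
            n_participants=len(result.per_participant),
            participant_estimates=estimates,
            detection_rates={
                p.participant_id: p.detection_rate for p in result.per_participant
            },
        )
        if participant_csv is not None:
            pd.DataFrame(
                [
                    {
                        "participant": p.participant_id,
                        "estimate_ms": p.estimate,
                        "detection_rate": p.detection_rate,
                        "reliable": p.reliable,
                    }
                    for p in result.per_participant
                ]
            ).to_csv(participant_csv, index=False)
    Path(path).write_text(json.dumps(envelope, indent=2))
    return envelope


def read_result(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def write_truth_map(truth: dict[str, float], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"participant": list(truth), "d_sim_ms": list(truth.values())}
    ).to_csv(path, index=False)


def read_truth_map(path: Union[str, Path]) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"participant": str})
    return dict(zip(df["participant"], df["d_sim_ms"].astype(float)))
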