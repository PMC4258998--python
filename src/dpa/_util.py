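"""Shared internals: run detection and ranked-value confidence intervals."""

from __future__ import annotations

import numpy as np


def first_run_starts(qualifies: np.ndarray, run_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per row, the first column index starting ``run_length`` consecutive True.

    ``qualifies`` is a boolean matrix ``(n_rows, n_cols)``.  Returns
    ``(found, start)`` where ``found[r]`` says whether row ``r`` contains a
    qualifying run and ``start[r]`` is its first column (0 where not found).
    Runs truncated by the right edge do not qualify.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    q = np.asarray(qualifies, dtype=bool)
    if q.ndim == 1:
        q = q[None, :]
    n_rows, n_cols = q.shape
    if run_length > n_cols:
        return np.zeros(n_rows, dtype=bool), np.zeros(n_rows, dtype=np.int64)
    # rolling window sum of width run_length via cumulative sums
    cs = np.cumsum(q, axis=1, dtype=np.int64)
    window = cs[:, run_length - 1 :].copy()
    window[:, 1:] -= cs[:, : n_cols - run_length]
    hit = window == run_length
    found = hit.any(axis=1)
    start = hit.argmax(axis=1).astype(np.int64)
    start[~found] = 0
    return found, start


def ranked_ci(sorted_values: np.ndarray, lower_rank: int, upper_rank: int) -> tuple[float, float]:
    """Closed ranked-value interval using 1-based ranks into ascending values."""
    m = len(sorted_values)
    if not (1 <= lower_rank <= upper_rank <= m):
        raise ValueError(
            f"invalid CI ranks ({lower_rank}, {upper_rank}) for {m} values"
        )
    return float(sorted_values[lower_rank - 1]), float(sorted_values[upper_rank - 1])


def scaled_ranks(n_detected: int, lower_frac: float, upper_frac: float) -> tuple[int, int]:
    """Rescale nominal CI rank fractions to ``n_detected`` retained values.

    Ranks are rounded to the nearest integer and floored at 1 / capped at
    ``n_detected`` so degenerate detection counts still yield a valid pair.
    """
    lo = min(max(1, round(lower_frac * n_detected)), n_detected)
    hi = min(max(1, round(upper_frac * n_detected)), n_detected)
    if hi < lo:
        lo, hi = hi, lo
    return lo, hi
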