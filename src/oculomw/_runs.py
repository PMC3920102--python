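"""Run/interval arithmetic on sample indices.

All runs are half-open ``[start, end)`` index pairs stored as an ``(k, 2)``
integer array sorted by start. These primitives back the blink masking,
artifact merging, and interpolation steps.
"""

from __future__ import annotations

import numpy as np


def find_runs(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True in a boolean array as an (k, 2) array of [start, end)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends]).astype(np.int64)


def sort_runs(runs: np.ndarray) -> np.ndarray:
    runs = np.asarray(runs, dtype=np.int64).reshape(-1, 2)
    if runs.shape[0] == 0:
        return runs
    return runs[np.argsort(runs[:, 0], kind="stable")]


def merge_runs(runs: np.ndarray, max_gap: int) -> np.ndarray:
    """Union runs whose inter-run gap is strictly smaller than ``max_gap`` samples.

    ``max_gap=0`` merges only overlapping/abutting-with-overlap runs; ``max_gap=1``
    additionally merges abutting runs. Input order is irrelevant (runs are
    sorted first), which makes the merge order-independent.
    """
    runs = sort_runs(runs)
    if runs.shape[0] == 0:
        return runs
    merged = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] < max_gap or start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(end))
        else:
            merged.append([int(start), int(end)])
    return np.asarray(merged, dtype=np.int64)


def clip_runs(runs: np.ndarray, n: int) -> np.ndarray:
    """Clip runs to [0, n); drop runs that become empty."""
    runs = np.asarray(runs, dtype=np.int64).reshape(-1, 2).copy()
    if runs.shape[0] == 0:
        return runs
    runs[:, 0] = np.clip(runs[:, 0], 0, n)
    runs[:, 1] = np.clip(runs[:, 1], 0, n)
    return runs[runs[:, 1] > runs[:, 0]]


def runs_to_mask(runs: np.ndarray, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, end in np.asarray(runs, dtype=np.int64).reshape(-1, 2):
        mask[max(0, start):min(n, end)] = True
    return mask


def run_gap(a: tuple[int, int] | np.ndarray, b: tuple[int, int] | np.ndarray) -> int:
    """Gap in samples between two runs; 0 when they touch or overlap."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, lo - hi)
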