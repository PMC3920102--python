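"""Per-epoch oculometric features, sliding-window blink statistics, and the
median pupil time-course regression.

Nine variables are computed per 9-s epoch: pupil-size slope (ordinary least
squares of pupil on time, px^2/s), mean and SD of pupil size, blink rate
(epoch blink count scaled by 60/9 to blinks per minute), mean blink duration
(blinks longer than 1.5 s are discarded from duration statistics), and mean
and SD of horizontal and vertical gaze position. A blink belongs to an epoch
when its onset falls inside the window, which prevents double counting
across abutting windows. Epochs without blinks carry NaN for mean blink
duration; the classifier imputes the column mean downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .epochs import Epoch
from .io import FEATURE_COLUMNS
from .preprocess import CleanRecording

#: Blinks longer than this are excluded from duration statistics (s).
MAX_BLINK_DURATION_FOR_STATS = 1.5
#: Exact epoch-count-to-rate conversion; prints as 6.67 at 2 decimals.
BLINK_RATE_FACTOR = 60.0 / 9.0


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a series on time: slope a, intercept, Pearson r, p, n."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class WindowedBlinkStats:
    window_start: float      # s
    blink_rate: float        # blinks/min
    blink_duration_mean: float  # s; NaN when the window holds no blinks


def _epoch_blinks(epoch: Epoch, clean: CleanRecording) -> list:
    start, end = epoch.window
    return [b for b in clean.blinks if start <= b.onset < end]


def _duration_mean(blinks: Sequence) -> float:
    durations = [
        b.duration
        for b in blinks
        if not b.boundary and b.duration <= MAX_BLINK_DURATION_FOR_STATS
    ]
    return float(np.mean(durations)) if durations else float("nan")


def compute_features(epoch: Epoch, clean: CleanRecording) -> dict[str, float]:
    """Fill and return the 9-variable feature vector of one epoch."""
    sl = clean.window_slice(*epoch.window)
    if sl.stop <= sl.start:
        raise ValidationError(f"epoch {epoch.epoch_id}: empty analysis window")
    t = clean.timestamps[sl] - epoch.window[0]
    pupil = clean.pupil[sl]
    gx = clean.gaze_x[sl]
    gy = clean.gaze_y[sl]
    slope, _intercept = np.polyfit(t, pupil, 1) if t.size > 1 else (0.0, pupil[0])
    blinks = _epoch_blinks(epoch, clean)
    window_len = epoch.window[1] - epoch.window[0]
    features = {
        "pupil_size_slope": float(slope),
        "pupil_size_mean": float(np.mean(pupil)),
        "pupil_size_std": float(np.std(pupil, ddof=1)) if pupil.size > 1 else 0.0,
        "blink_rate": len(blinks) * (60.0 / window_len),
        "blink_duration_mean": _duration_mean(blinks),
        "gaze_x_position_mean": float(np.mean(gx)),
        "gaze_x_position_std": float(np.std(gx, ddof=1)) if gx.size > 1 else 0.0,
        "gaze_y_position_mean": float(np.mean(gy)),
        "gaze_y_position_std": float(np.std(gy, ddof=1)) if gy.size > 1 else 0.0,
    }
    assert set(features) == set(FEATURE_COLUMNS)
    epoch.features = features
    return features


def compute_all_features(epochs: Sequence[Epoch], clean: CleanRecording) -> None:
    for ep in epochs:
        compute_features(ep, clean)


# ---------------------------------------------------------------------------
# Continuous-data blink statistics (time-on-task analysis)
# ---------------------------------------------------------------------------

def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or np.ptp(x) == 0:
        return RegressionResult(float("nan"), float("nan"), float("nan"),
                                float("nan"), int(x.size))
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def sliding_blink_stats(
    clean: CleanRecording,
    window_s: float = 60.0,
    step_s: float = 30.0,
    time_offset: float = 0.0,
) -> tuple[list[WindowedBlinkStats], RegressionResult, RegressionResult]:
    """Blink rate and mean duration in 1-min windows advancing by 30 s, plus
    the time-on-task trends (rate and duration regressed on window start).

    ``time_offset`` shifts window-start times, so multi-session analyses can
    express windows in cumulative time spent performing the task.
    """
    duration = clean.duration
    if duration < window_s:
        raise ValidationError(
            f"session of {duration:.1f} s is shorter than one {window_s:.0f}-s window"
        )
    starts = np.arange(0.0, duration - window_s + 1e-9, step_s)
    stats: list[WindowedBlinkStats] = []
    for w0 in starts:
        blinks = [b for b in clean.blinks if w0 <= b.onset < w0 + window_s]
        rate = len(blinks) * (60.0 / window_s)
        stats.append(
            WindowedBlinkStats(
                window_start=float(w0 + time_offset),
                blink_rate=rate,
                blink_duration_mean=_duration_mean(blinks),
            )
        )
    t = np.asarray([w.window_start for w in stats])
    rate_trend = _regress(t, [w.blink_rate for w in stats])
    duration_trend = _regress(t, [w.blink_duration_mean for w in stats])
    return stats, rate_trend, duration_trend


# ---------------------------------------------------------------------------
# Median pupil time course
# ---------------------------------------------------------------------------

def median_pupil_timecourse(
    epochs: Sequence[Epoch], clean: CleanRecording
) -> tuple[np.ndarray, np.ndarray, RegressionResult]:
    """Pointwise median pupil size across same-label epochs and its OLS fit.

    Returns ``(relative_time_s, median_series, regression)``.
    """
    if not epochs:
        raise ValidationError("need at least one epoch")
    labels = {ep.label for ep in epochs}
    if len(labels) > 1:
        raise ValidationError(f"epochs mix labels {sorted(labels)}")
    slices = [clean.window_slice(*ep.window) for ep in epochs]
    lengths = {sl.stop - sl.start for sl in slices}
    if len(lengths) > 1:
        raise ValidationError("epochs have unequal window lengths")
    matrix = np.vstack([clean.pupil[sl] for sl in slices])
    median = np.median(matrix, axis=0)
    rel_t = np.arange(median.size) / clean.sampling_rate
    return rel_t, median, _regress(rel_t, median)
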