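"""Two-step artifact removal and blink identification for pupil traces.

Step 1 builds a conservative blink mask from zero-runs of the pupil channel
(extended 100 ms backward and 300 ms forward), estimates pupil-size change
velocity statistics on the remaining blink-free samples, flags samples whose
velocity leaves mu +/- a*sigma (a = 1.5), merges flagged runs closer than
16 ms, splits them into blink-related (absorbed into their zero-run) and
isolated artifacts, and linearly interpolates the isolated ones on pupil and
both gaze channels.

Step 2 refines each blink's onset and offset with a velocity-threshold walk
(an adaptation of the Engbert-Mergenthaler velocity-threshold event
detector, with a median-based scale estimate and multiplier lambda), merges
refined events separated by less than 100 ms, and interpolates the blinks.

The result is a :class:`CleanRecording` with no zero pupil samples, a
per-sample provenance mask, and a refined blink event list.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._runs import clip_runs, find_runs, merge_runs, run_gap, runs_to_mask, sort_runs
from .errors import DegenerateSignalError, ValidationError
from .io import RawRecording

# Mask codes
VALID, BLINK, ARTIFACT, INTERPOLATED = 0, 1, 2, 3
MASK_LABELS = {VALID: "valid", BLINK: "blink", ARTIFACT: "artifact",
               INTERPOLATED: "interpolated"}


@dataclass
class PreprocessParams:
    """All tunables of the cleaning procedure, at their standard values."""

    a: float = 1.5                 # velocity-threshold coefficient (mu +/- a*sigma)
    pre_pad_s: float = 0.1         # conservative mask extension before a zero-run
    post_pad_s: float = 0.3        # ... and after
    blink_merge_s: float = 0.1     # blinks closer than this are one blink
    artifact_merge_s: float = 0.016  # artifact runs closer than this are merged
    adjacency_s: float = 0.1       # "around zero values": artifact-to-zero-run gap
    lam: float = 6.0               # refinement threshold multiplier (lambda)
    smooth_window: int = 1         # samples; velocity smoothing for refinement


@dataclass(frozen=True)
class VelocityThresholds:
    """Velocity band computed on blink-free samples: [mu - a*sigma, mu + a*sigma]."""

    mu: float
    sigma: float
    a: float

    @property
    def low(self) -> float:
        return self.mu - self.a * self.sigma

    @property
    def high(self) -> float:
        return self.mu + self.a * self.sigma


@dataclass
class BlinkEvent:
    onset: float      # s, first sample of the refined blink
    offset: float     # s, last sample of the refined blink
    n_merged: int = 1
    boundary: bool = False  # clipped at a record edge; excluded from duration stats

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class CleanRecording:
    """Interpolated traces plus per-sample mask, blink list, and provenance."""

    timestamps: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    sampling_rate: float
    mask: np.ndarray                 # int8 codes: VALID/BLINK/ARTIFACT/INTERPOLATED
    blinks: list[BlinkEvent]
    thresholds: VelocityThresholds | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.pupil.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Samples whose time lies in the half-open window [start_s, end_s)."""
        fs = self.sampling_rate
        i0 = max(0, int(np.ceil(start_s * fs - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(end_s * fs - 1e-9)))
        return slice(i0, i1)

    def interpolated_fraction(self, start_s: float | None = None,
                              end_s: float | None = None) -> float:
        sl = slice(None) if start_s is None else self.window_slice(start_s, end_s)
        m = self.mask[sl]
        if m.size == 0:
            return 0.0
        return float(np.mean(m != VALID))


# ---------------------------------------------------------------------------
# Step 1: conservative mask, velocity thresholds, artifact flagging
# ---------------------------------------------------------------------------

def zero_runs(pupil: np.ndarray) -> np.ndarray:
    """Maximal runs of pupil == 0 as [start, end) sample indices."""
    return find_runs(np.asarray(pupil) == 0)


def conservative_blink_mask(
    rec: RawRecording, params: PreprocessParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask plus runs of the conservative (padded) blink intervals.

    Each zero-run is extended ``pre_pad_s`` backward and ``post_pad_s``
    forward (clipped to the record), and extended runs separated by less
    than ``blink_merge_s`` are merged.
    """
    params = params or PreprocessParams()
    fs = rec.sampling_rate
    n = rec.pupil_area.size
    runs = zero_runs(rec.pupil_area)
    if runs.shape[0] == 0:
        return np.zeros(n, dtype=bool), runs
    pre = int(round(params.pre_pad_s * fs))
    post = int(round(params.post_pad_s * fs))
    padded = runs.copy()
    padded[:, 0] -= pre
    padded[:, 1] += post
    padded = clip_runs(padded, n)
    merged = merge_runs(padded, int(round(params.blink_merge_s * fs)))
    return runs_to_mask(merged, n), merged


def pupil_velocity(rec_or_pupil: RawRecording | np.ndarray) -> np.ndarray:
    """Per-sample pupil-size change (first difference), aligned to the later
    sample: ``v[i] = p[i+1] - p[i]`` stored at output index i, length n-1."""
    pupil = (
        rec_or_pupil.pupil_area
        if isinstance(rec_or_pupil, RawRecording)
        else np.asarray(rec_or_pupil, dtype=float)
    )
    if pupil.size < 2:
        raise ValidationError("recording shorter than 2 samples has no velocity")
    return np.diff(pupil)


def compute_velocity_thresholds(
    velocity: np.ndarray, blink_mask: np.ndarray, a: float = 1.5
) -> VelocityThresholds:
    """Mean/SD of velocity over samples outside the conservative blink mask.

    A velocity sample ``v[i] = p[i+1] - p[i]`` is kept only when neither of
    its endpoints is masked.
    """
    velocity = np.asarray(velocity, dtype=float)
    blink_mask = np.asarray(blink_mask, dtype=bool)
    keep = ~(blink_mask[:-1] | blink_mask[1:])
    v = velocity[keep]
    if v.size < 2:
        raise DegenerateSignalError("fewer than 2 blink-free velocity samples")
    mu = float(np.mean(v))
    sigma = float(np.std(v, ddof=1))
    if sigma == 0.0:
        raise DegenerateSignalError(
            "zero velocity variance: constant recordings cannot be thresholded"
        )
    return VelocityThresholds(mu=mu, sigma=sigma, a=a)


def flag_velocity_artifacts(
    velocity: np.ndarray,
    thresholds: VelocityThresholds,
    sampling_rate: float,
    merge_s: float = 0.016,
) -> np.ndarray:
    """Runs of samples whose velocity strictly exceeds the threshold band.

    The flagged data point is the later sample of each difference. Runs
    separated by less than ``merge_s`` are merged.
    """
    velocity = np.asarray(velocity, dtype=float)
    out = (velocity > thresholds.high) | (velocity < thresholds.low)
    # sample-domain mask: velocity i refers to sample i+1
    sample_mask = np.zeros(velocity.size + 1, dtype=bool)
    sample_mask[1:] = out
    runs = find_runs(sample_mask)
    max_gap = int(np.ceil(merge_s * sampling_rate)) - 1  # gap < merge_s, strict
    return merge_runs(runs, max_gap + 1)


def split_artifacts(
    artifact_runs: np.ndarray,
    zero_run_list: np.ndarray,
    sampling_rate: float,
    adjacency_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition artifact runs into blink-related and isolated ones.

    A run is blink-related iff it lies within ``adjacency_s`` of some
    zero-run; such runs are unioned into their zero-run's interval. Returns
    ``(blink_intervals, non_blink_runs)`` — the former is one interval per
    zero-run (possibly extended by absorbed artifacts, then merged if they
    collide), the latter the remaining artifact runs untouched.
    """
    artifact_runs = sort_runs(artifact_runs)
    zero_run_list = sort_runs(zero_run_list)
    window = int(round(adjacency_s * sampling_rate))
    blink_intervals = [list(zr) for zr in zero_run_list]
    non_blink = []
    for run in artifact_runs:
        gaps = [run_gap(run, zr) for zr in zero_run_list]
        if gaps and min(gaps) <= window:
            k = int(np.argmin(gaps))
            blink_intervals[k][0] = min(blink_intervals[k][0], int(run[0]))
            blink_intervals[k][1] = max(blink_intervals[k][1], int(run[1]))
        else:
            non_blink.append(list(run))
    merged_blinks = merge_runs(np.asarray(blink_intervals, dtype=np.int64).reshape(-1, 2), 1)
    return merged_blinks, np.asarray(non_blink, dtype=np.int64).reshape(-1, 2)


def interpolate_runs(channel: np.ndarray, runs: np.ndarray) -> np.ndarray:
    """Replace samples inside each run by the line between the nearest valid
    samples bracketing it; runs touching a record edge are filled with the
    nearest valid value."""
    channel = np.asarray(channel, dtype=float).copy()
    n = channel.size
    runs = clip_runs(sort_runs(runs), n)
    if runs.shape[0] and runs[0, 0] == 0 and runs[0, 1] == n:
        raise ValidationError("cannot interpolate a run covering the whole recording")
    for start, end in runs:
        left = start - 1
        right = end
        if left < 0 and right >= n:
            raise ValidationError("cannot interpolate a run covering the whole recording")
        if left < 0:
            channel[start:end] = channel[right]
        elif right >= n:
            channel[start:end] = channel[left]
        else:
            channel[start:end] = np.interp(
                np.arange(start, end), [left, right], [channel[left], channel[right]]
            )
    return channel


# ---------------------------------------------------------------------------
# Step 2: fine-grain blink bound refinement
# ---------------------------------------------------------------------------

def _median_sd(v: np.ndarray) -> float:
    """Median-based scale estimate sqrt(median(v^2) - median(v)^2), robust to
    the small fraction of blink samples contaminating the series."""
    med = float(np.median(v))
    est = float(np.median(v * v)) - med * med
    if est <= 0:
        est = float(np.var(v))
    return float(np.sqrt(est))


def detect_blink_bounds(
    pupil: np.ndarray,
    zero_run_list: np.ndarray,
    sampling_rate: float,
    params: PreprocessParams | None = None,
) -> list[BlinkEvent]:
    """Refine blink onsets/offsets by an adaptive velocity-threshold walk.

    From the edges of each zero-run the event is extended outward while the
    absolute (optionally smoothed) velocity exceeds ``lambda * sigma_med``,
    so the perturbed eyelid-closing/opening samples join the blink. Refined
    events closer than ``blink_merge_s`` are merged; events clipped at a
    record boundary are flagged.
    """
    params = params or PreprocessParams()
    blink_intervals = clip_runs(sort_runs(zero_run_list), np.asarray(pupil).size)
    if blink_intervals.shape[0] == 0:
        return []
    v = np.diff(np.asarray(pupil, dtype=float))
    if params.smooth_window > 1:
        kernel = np.ones(params.smooth_window) / params.smooth_window
        v = np.convolve(v, kernel, mode="same")
    thr = params.lam * _median_sd(v)
    n = pupil.size
    raw_events: list[tuple[int, int, bool]] = []  # [onset, offset] inclusive
    for start, end in blink_intervals:
        onset = int(start)
        offset = int(end) - 1
        # v[i] is the change from sample i to i+1
        while onset > 0 and abs(v[onset - 1]) > thr:
            onset -= 1
        while offset < n - 1 and abs(v[offset]) > thr:
            offset += 1
        boundary = onset == 0 or offset == n - 1
        raw_events.append((onset, offset, boundary))
    raw_events.sort()
    merge_gap = int(round(params.blink_merge_s * sampling_rate))
    merged: list[list] = []
    for onset, offset, boundary in raw_events:
        if merged and onset - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], offset)
            merged[-1][2] += 1
            merged[-1][3] = merged[-1][3] or boundary
        else:
            merged.append([onset, offset, 1, boundary])
    fs = sampling_rate
    return [
        BlinkEvent(onset=o / fs, offset=f / fs, n_merged=k, boundary=b)
        for o, f, k, b in merged
    ]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def clean_recording(
    rec: RawRecording, params: PreprocessParams | None = None
) -> CleanRecording:
    """Run both cleaning steps and return the interpolated recording."""
    params = params or PreprocessParams()
    fs = rec.sampling_rate
    n = rec.pupil_area.size
    zruns = zero_runs(rec.pupil_area)

    # Step 1 — statistics on the temporary blink-free data, artifact flagging
    cons_mask, _cons_runs = conservative_blink_mask(rec, params)
    velocity = pupil_velocity(rec)
    thresholds = compute_velocity_thresholds(velocity, cons_mask, a=params.a)
    artifact_runs = flag_velocity_artifacts(
        velocity, thresholds, fs, merge_s=params.artifact_merge_s
    )
    blink_intervals, non_blink_runs = split_artifacts(
        artifact_runs, zruns, fs, adjacency_s=params.adjacency_s
    )
    pupil = interpolate_runs(rec.pupil_area, non_blink_runs)
    gaze_x = interpolate_runs(rec.gaze_x, non_blink_runs)
    gaze_y = interpolate_runs(rec.gaze_y, non_blink_runs)

    # Step 2 — fine-grain blink bounds on the step-1 signal, refined from the
    # zero-run edges; blink-related artifact intervals from step 1 are kept
    # merged with the blink periods for masking/interpolation.
    blinks = detect_blink_bounds(pupil, zruns, fs, params)
    refined_runs = np.asarray(
        [[int(round(b.onset * fs)), int(round(b.offset * fs)) + 1] for b in blinks],
        dtype=np.int64,
    ).reshape(-1, 2)
    blink_runs = merge_runs(
        np.vstack([refined_runs, blink_intervals]) if blink_intervals.size
        else refined_runs,
        1,
    )
    pupil = interpolate_runs(pupil, blink_runs)
    gaze_x = interpolate_runs(gaze_x, blink_runs)
    gaze_y = interpolate_runs(gaze_y, blink_runs)

    mask = np.full(n, VALID, dtype=np.int8)
    for start, end in non_blink_runs:
        mask[start:end] = ARTIFACT
    for start, end in blink_runs:
        mask[start:end] = BLINK

    provenance = {
        "params": dataclasses.asdict(params),
        "thresholds": {"mu": thresholds.mu, "sigma": thresholds.sigma,
                       "a": thresholds.a, "low": thresholds.low,
                       "high": thresholds.high},
        "n_zero_runs": int(zruns.shape[0]),
        "n_artifact_runs": int(artifact_runs.shape[0]),
        "n_non_blink_runs": int(non_blink_runs.shape[0]),
        "n_blinks": len(blinks),
        "n_samples_masked": int(np.sum(mask != VALID)),
    }
    return CleanRecording(
        timestamps=rec.timestamps.copy(),
        pupil=pupil,
        gaze_x=gaze_x,
        gaze_y=gaze_y,
        sampling_rate=fs,
        mask=mask,
        blinks=blinks,
        thresholds=thresholds,
        provenance=provenance,
    )
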