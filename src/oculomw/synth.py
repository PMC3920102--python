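"""Synthetic eye-tracking sessions with full ground truth.

The generator emulates a self-caught mind-wandering protocol: a subject
counts breaths while fixating (state F), occasionally drifts into mind
wandering (state MW), presses a button on noticing, fills a short
questionnaire (state Q, treated like F for the oculometric signal), presses
again to refocus, and resumes. The pupil trace carries a state-dependent
baseline and within-state linear drift, a slow breathing sinusoid, white
measurement noise, hard-zero blink plateaus with spiky boundaries, and
occasional isolated spike artifacts. Every injected event is recorded in a
:class:`GroundTruth` so the downstream cleaning and epoching stages can be
benchmarked exactly.

Durations of F and MW dwells are exponential: the protocol literature only
constrains their means, and the memoryless choice keeps each a one-parameter
family.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import (
    QUESTION_IDS,
    Event,
    EventLog,
    QuestionnaireRecord,
    RawRecording,
)

#: Minimum physiological blink duration used when drawing blink lengths (s).
_MIN_BLINK_S = 0.05
#: Minimum enforced gap between injected blinks (s); real blinks essentially
#: never follow each other faster, and it keeps ground-truth events 1:1 with
#: detected events under the 100-ms merge rule.
_MIN_BLINK_GAP_S = 0.5


@dataclass
class SimulationConfig:
    """Parameters of one synthetic session. Units in field names/comments."""

    sampling_rate: float = 240.0          # samples/s
    session_duration: float = 1200.0      # s (20-min session)

    pupil_baseline_F: float = 2000.0      # px^2
    pupil_baseline_MW: float = 1900.0     # px^2; smaller than F baseline
    pupil_slope_F: float = -2.0           # px^2/s, within-state drift (<= 0)
    pupil_slope_MW: float = 2.0           # px^2/s (>= 0)
    baseline_jitter_sd: float = 50.0      # px^2, per-state-interval baseline wobble
    breathing_frequency: float = 0.2      # Hz, breath-paced oscillation
    breathing_amplitude: float = 30.0     # px^2
    measurement_noise_sd: float = 20.0    # px^2, white noise

    blink_rate_F: float = 10.0            # blinks/min
    blink_rate_MW: float = 15.0           # blinks/min; higher during MW
    blink_duration_mean_F: float = 0.15   # s
    blink_duration_mean_MW: float = 0.25  # s
    boundary_spike_amplitude: float = 300.0  # px^2, eyelid-edge tracking glitches
    spurious_spike_rate: float = 2.0      # events/min, isolated single-sample spikes

    gaze_center_x: float = 640.0          # px (screen center of 1280x1024)
    gaze_center_y: float = 512.0          # px
    gaze_sd_F: float = 10.0               # px, fixation jitter while on task
    gaze_sd_MW: float = 20.0              # px, looser gaze control during MW

    mean_F_duration: float = 45.0         # s, exponential dwell mean
    mean_MW_duration: float = 15.0        # s, exponential dwell mean
    questionnaire_gap_mean: float = 28.0  # s, time to fill the questionnaire
    questionnaire_gap_sd: float = 12.0    # s
    min_questionnaire_gap: float = 5.0    # s

    q1_pupil_coupling: float = 0.0        # in [0, 1]; couples Q1 to epoch pupil mean
    error_press_prob: float = 0.0         # probability a press is marked erroneous

    seed: int = 0

    def validate(self) -> None:
        positive = (
            "sampling_rate", "session_duration", "pupil_baseline_F",
            "pupil_baseline_MW", "blink_duration_mean_F", "blink_duration_mean_MW",
            "mean_F_duration", "mean_MW_duration", "questionnaire_gap_mean",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        nonneg = (
            "breathing_amplitude", "measurement_noise_sd", "blink_rate_F",
            "blink_rate_MW", "boundary_spike_amplitude", "spurious_spike_rate",
            "gaze_sd_F", "gaze_sd_MW", "baseline_jitter_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.session_duration < 60.0:
            raise ValidationError("session_duration must be at least 60 s")
        if self.pupil_slope_F > 0:
            raise ValidationError("pupil_slope_F must be <= 0")
        if self.pupil_slope_MW < 0:
            raise ValidationError("pupil_slope_MW must be >= 0")
        floor = self.breathing_amplitude + 3.0 * self.measurement_noise_sd
        for name in ("pupil_baseline_F", "pupil_baseline_MW"):
            if getattr(self, name) <= floor:
                raise ValidationError(
                    f"{name} must exceed breathing_amplitude + 3*measurement_noise_sd "
                    f"({floor:g} px^2) so the trace stays positive outside blinks"
                )
        if not 0.0 <= self.q1_pupil_coupling <= 1.0:
            raise ValidationError("q1_pupil_coupling must be in [0, 1]")


@dataclass(frozen=True)
class StateInterval:
    start: float
    end: float
    label: str  # "F", "MW", or "Q" (questionnaire gap; F-like signal)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Everything the generator injected, for benchmarking detection."""

    state_intervals: list[StateInterval]
    true_blinks: list[tuple[float, float]]  # (onset s, offset s) of zero plateaus
    true_artifact_samples: np.ndarray       # indices of boundary/spurious spikes
    mw_press_times: list[float]
    refocus_press_times: list[float]


@dataclass
class SessionBundle:
    recording: RawRecording
    event_log: EventLog
    questionnaires: dict[str, QuestionnaireRecord]
    ground_truth: GroundTruth
    config: SimulationConfig
    state_pupil: np.ndarray  # noiseless state signal (baseline + drift), px^2


# ---------------------------------------------------------------------------
# State sequence
# ---------------------------------------------------------------------------

def simulate_state_sequence(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[StateInterval], list[float], list[float]]:
    """Alternating F/MW/Q intervals with exponential dwell times.

    Each MW interval ends exactly at a mind-wandering button press, followed
    by a questionnaire gap and a refocus press that opens the next F
    interval. A mind-wandering dwell that would outlast the session produces
    no press and is absorbed into a final F interval (an unreported episode
    cannot be distinguished from focusing by the event log).
    """
    config.validate()
    T = config.session_duration
    intervals: list[StateInterval] = []
    mw_presses: list[float] = []
    refocus_presses: list[float] = []
    t = 0.0
    while t < T:
        f_end = t + rng.exponential(config.mean_F_duration)
        if f_end >= T:
            intervals.append(StateInterval(t, T, "F"))
            break
        intervals.append(StateInterval(t, f_end, "F"))
        mw_end = f_end + rng.exponential(config.mean_MW_duration)
        if mw_end >= T:
            intervals.append(StateInterval(f_end, T, "F"))
            break
        intervals.append(StateInterval(f_end, mw_end, "MW"))
        mw_presses.append(mw_end)
        gap = max(
            config.min_questionnaire_gap,
            rng.normal(config.questionnaire_gap_mean, config.questionnaire_gap_sd),
        )
        q_end = mw_end + gap
        if q_end >= T:
            intervals.append(StateInterval(mw_end, T, "Q"))
            break
        intervals.append(StateInterval(mw_end, q_end, "Q"))
        refocus_presses.append(q_end)
        t = q_end
    # merge adjacent same-label intervals (arises when an MW tail is absorbed)
    merged: list[StateInterval] = []
    for iv in intervals:
        if merged and merged[-1].label == iv.label and merged[-1].end == iv.start:
            merged[-1] = StateInterval(merged[-1].start, iv.end, iv.label)
        else:
            merged.append(iv)
    return merged, mw_presses, refocus_presses


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def _state_params(config: SimulationConfig, label: str) -> tuple[float, float, float, float]:
    """(baseline, slope, gaze_sd, blink_rate) for a state label; Q behaves like F."""
    if label == "MW":
        return (config.pupil_baseline_MW, config.pupil_slope_MW,
                config.gaze_sd_MW, config.blink_rate_MW)
    return (config.pupil_baseline_F, config.pupil_slope_F,
            config.gaze_sd_F, config.blink_rate_F)


def _interval_slices(intervals: Sequence[StateInterval], fs: float, n: int
                     ) -> list[tuple[StateInterval, slice]]:
    out = []
    for iv in intervals:
        i0 = min(n, int(np.ceil(iv.start * fs - 1e-9)))
        i1 = min(n, int(np.ceil(iv.end * fs - 1e-9)))
        out.append((iv, slice(i0, i1)))
    return out


def synthesize_traces(
    intervals: Sequence[StateInterval],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless state pupil plus noisy pupil/gaze series.

    pupil(t) = baseline(state) + jitter(interval) + slope(state)*(t - state start)
               + breathing sinusoid + white Gaussian noise;
    gaze(t) = screen center + state-dependent Gaussian jitter.
    """
    if not intervals or abs(intervals[0].start) > 1e-9:
        raise ValidationError("state intervals must start at 0 and tile the session")
    for a, b in zip(intervals, intervals[1:]):
        if abs(a.end - b.start) > 1e-9:
            raise ValidationError("state intervals must tile the session without gaps")
    fs = config.sampling_rate
    n = int(round(config.session_duration * fs))
    t = np.arange(n) / fs
    state_pupil = np.empty(n)
    gaze_x = np.empty(n)
    gaze_y = np.empty(n)
    for iv, sl in _interval_slices(intervals, fs, n):
        baseline, slope, gaze_sd, _ = _state_params(config, iv.label)
        jitter = rng.normal(0.0, config.baseline_jitter_sd) if config.baseline_jitter_sd else 0.0
        state_pupil[sl] = baseline + jitter + slope * (t[sl] - iv.start)
        m = sl.stop - sl.start
        gaze_x[sl] = config.gaze_center_x + rng.normal(0.0, gaze_sd, m)
        gaze_y[sl] = config.gaze_center_y + rng.normal(0.0, gaze_sd, m)
    pupil = (
        state_pupil
        + config.breathing_amplitude * np.sin(2.0 * np.pi * config.breathing_frequency * t)
        + rng.normal(0.0, config.measurement_noise_sd, n)
    )
    if np.any(pupil <= 0):
        raise ValidationError(
            "synthesized pupil trace is non-positive; lower pupil_slope magnitudes "
            "or baseline_jitter_sd, or raise pupil_baseline_F/pupil_baseline_MW"
        )
    return state_pupil, pupil, gaze_x, gaze_y


# ---------------------------------------------------------------------------
# Blinks and artifacts
# ---------------------------------------------------------------------------

def _draw_blinks_for_interval(
    iv: StateInterval, rate_per_min: float, dur_mean: float,
    rng: np.random.Generator, placed: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Poisson-count blinks inside one state interval, non-overlapping and
    fully contained (a blink that would cross a press is resampled)."""
    lam = rate_per_min / 60.0 * iv.duration
    count = rng.poisson(lam)
    out: list[tuple[float, float]] = []
    for _ in range(count):
        for _try in range(200):
            dur = _MIN_BLINK_S + rng.exponential(max(dur_mean - _MIN_BLINK_S, 1e-3))
            onset = iv.start + rng.uniform(0.0, iv.duration)
            offset = onset + dur
            if offset >= iv.end - 1.0 / 240.0:
                continue  # never truncate a blink across a press; resample
            ok = all(
                offset + _MIN_BLINK_GAP_S <= b0 or onset >= b1 + _MIN_BLINK_GAP_S
                for b0, b1 in placed + out
            )
            if ok:
                out.append((onset, offset))
                break
    return out


def inject_blinks_and_artifacts(
    state_pupil: np.ndarray,
    pupil: np.ndarray,
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    intervals: Sequence[StateInterval],
    config: SimulationConfig,
    rng: np.random.Generator,
    mw_presses: Sequence[float] = (),
    refocus_presses: Sequence[float] = (),
) -> tuple[RawRecording, GroundTruth]:
    """Zero out blink plateaus, spike their boundaries, add spurious spikes."""
    if np.any(pupil <= 0):
        raise ValidationError("traces must be positive everywhere before blink injection")
    fs = config.sampling_rate
    n = pupil.size
    pupil = pupil.copy()

    blinks: list[tuple[float, float]] = []
    for iv in intervals:
        _, _, _, rate = _state_params(config, iv.label)
        dur_mean = (config.blink_duration_mean_MW if iv.label == "MW"
                    else config.blink_duration_mean_F)
        blinks.extend(_draw_blinks_for_interval(iv, rate, dur_mean, rng, blinks))
    blinks.sort()

    artifact_idx: list[int] = []
    true_blinks: list[tuple[float, float]] = []
    amp = config.boundary_spike_amplitude
    for onset, offset in blinks:
        i0 = int(round(onset * fs))
        i1 = int(round(offset * fs))  # inclusive last zero sample
        i0 = max(0, min(n - 1, i0))
        i1 = max(i0, min(n - 1, i1))
        pupil[i0:i1 + 1] = 0.0
        true_blinks.append((i0 / fs, i1 / fs))
        if amp > 0:
            for k in range(int(rng.integers(1, 4))):
                j = i0 - 1 - k
                if j >= 0:
                    pupil[j] += rng.choice((-amp, amp))
                    artifact_idx.append(j)
            for k in range(int(rng.integers(1, 4))):
                j = i1 + 1 + k
                if j < n:
                    pupil[j] += rng.choice((-amp, amp))
                    artifact_idx.append(j)

    # isolated single-sample spikes away from blinks
    n_spikes = rng.poisson(config.spurious_spike_rate / 60.0 * config.session_duration)
    for _ in range(n_spikes):
        for _try in range(200):
            ts = rng.uniform(1.0, config.session_duration - 1.0)
            if all(ts < b0 - 1.0 or ts > b1 + 1.0 for b0, b1 in true_blinks):
                j = int(round(ts * fs))
                pupil[j] += rng.choice((-amp, amp)) if amp > 0 else 0.0
                artifact_idx.append(j)
                break

    pupil = np.maximum(pupil, 0.0)  # a downward spike may not undershoot zero
    rec = RawRecording(
        timestamps=np.arange(n) / fs,
        gaze_x=gaze_x,
        gaze_y=gaze_y,
        pupil_area=pupil,
        sampling_rate=fs,
    )
    truth = GroundTruth(
        state_intervals=list(intervals),
        true_blinks=true_blinks,
        true_artifact_samples=np.asarray(sorted(set(artifact_idx)), dtype=np.int64),
        mw_press_times=list(mw_presses),
        refocus_press_times=list(refocus_presses),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Questionnaires and full-session composition
# ---------------------------------------------------------------------------

def _questionnaires(
    config: SimulationConfig,
    intervals: Sequence[StateInterval],
    mw_presses: Sequence[float],
    state_pupil: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, QuestionnaireRecord]:
    fs = config.sampling_rate
    mw_by_end = {round(iv.end, 9): iv for iv in intervals if iv.label == "MW"}
    # epoch-window pupil means, used when Q1 is coupled to pupil size
    win_means = []
    for press in mw_presses:
        i0 = max(0, int(np.ceil((press - 10.0) * fs - 1e-9)))
        i1 = max(i0 + 1, int(np.ceil((press - 1.0) * fs - 1e-9)))
        win_means.append(float(np.mean(state_pupil[i0:i1])))
    win_means = np.asarray(win_means)
    if win_means.size > 1 and np.std(win_means) > 0:
        z = (win_means - win_means.mean()) / win_means.std()
    else:
        z = np.zeros_like(win_means)

    out: dict[str, QuestionnaireRecord] = {}
    c = config.q1_pupil_coupling
    for k, press in enumerate(mw_presses):
        answers = {q: int(rng.integers(1, 8)) for q in QUESTION_IDS}
        if c > 0:
            latent = c * z[k] + np.sqrt(max(0.0, 1.0 - c * c)) * rng.normal()
            answers["Q1"] = int(np.clip(round(4.0 + 1.5 * latent), 1, 7))
        mw_iv = mw_by_end.get(round(press, 9))
        dwell = mw_iv.duration if mw_iv is not None else 0.0
        out[f"q{k + 1}"] = QuestionnaireRecord(
            id=f"q{k + 1}",
            answers=answers,
            reported_mw_duration=float(round(dwell)),
            error_press=bool(rng.random() < config.error_press_prob),
        )
    return out


def generate_session(config: SimulationConfig) -> SessionBundle:
    """One complete reproducible session bundle (recording, events,
    questionnaires, ground truth)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_state, rng_trace, rng_blink, rng_q = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    intervals, mw_presses, refocus_presses = simulate_state_sequence(config, rng_state)
    state_pupil, pupil, gaze_x, gaze_y = synthesize_traces(intervals, config, rng_trace)
    rec, truth = inject_blinks_and_artifacts(
        state_pupil, pupil, gaze_x, gaze_y, intervals, config, rng_blink,
        mw_presses=mw_presses, refocus_presses=refocus_presses,
    )
    questionnaires = _questionnaires(config, intervals, mw_presses, state_pupil, rng_q)

    events: list[Event] = [Event(0.0, "session_start")]
    presses = (
        [(t, "mw_press", f"q{i + 1}") for i, t in enumerate(mw_presses)]
        + [(t, "refocus_press", None) for t in refocus_presses]
    )
    for t, kind, qid in sorted(presses):
        events.append(Event(t, kind, qid))
    events.append(Event(config.session_duration, "session_end"))
    log = EventLog(events=events)
    return SessionBundle(
        recording=rec,
        event_log=log,
        questionnaires=questionnaires,
        ground_truth=truth,
        config=config,
        state_pupil=state_pupil,
    )


# ---------------------------------------------------------------------------
# Epoch-level feature simulation (for calibration/parameter-recovery studies)
# ---------------------------------------------------------------------------

#: Epoch-level means per state and a shared SD for each oculometric variable.
#: These mirror the session generator defaults at the scale of one 9-s epoch:
#: the pupil-mean effect is one pooled SD; slope and gaze dispersion carry
#: most of the separability, as they do in the trace model.
EPOCH_FEATURE_MODEL: dict[str, tuple[float, float, float]] = {
    # name: (mean_F, mean_MW, sd)
    "pupil_size_slope": (-2.0, 2.0, 3.0),
    "pupil_size_mean": (2000.0, 1900.0, 100.0),
    "pupil_size_std": (36.0, 36.0, 5.0),
    "gaze_x_position_mean": (640.0, 640.0, 4.0),
    "gaze_x_position_std": (10.0, 20.0, 5.0),
    "gaze_y_position_mean": (512.0, 512.0, 4.0),
    "gaze_y_position_std": (10.0, 20.0, 5.0),
}
_EPOCH_BLINK_LAMBDA = {"F": 1.5, "MW": 2.25}  # expected blinks per 9-s epoch
_EPOCH_BLINK_DUR = {"F": 0.15, "MW": 0.25}    # s


def simulate_epoch_features(
    n_per_class: int,
    seed: int,
    labels: Sequence[str] = ("MW", "F", "CT"),
    ct_position: float = 0.5,
    ct_mw_contamination: float = 0.25,
) -> "pd.DataFrame":
    """Draw per-epoch feature vectors directly from the epoch-level model.

    Control (CT) epochs sit ``ct_position`` of the way from MW toward F on
    every state-dependent variable, except that with probability
    ``ct_mw_contamination`` a CT epoch is an unnoticed mind-wandering episode
    and is drawn from the MW distribution outright — control windows are cut
    from inside the focus period, and nothing guarantees the subject was
    actually on task throughout them.
    """
    import pandas as pd  # local import keeps numpy-only callers light

    rng = np.random.default_rng(seed)
    rows = []
    for label in labels:
        for _ in range(n_per_class):
            eff = label
            if label == "CT":
                eff = "MW" if rng.random() < ct_mw_contamination else "CT"
            row: dict[str, object] = {"label": label}
            for name, (mF, mMW, sd) in EPOCH_FEATURE_MODEL.items():
                if eff == "CT":
                    mu = mMW + ct_position * (mF - mMW)
                else:
                    mu = mMW if eff == "MW" else mF
                row[name] = rng.normal(mu, sd)
            blink_state = eff if eff in ("F", "MW") else "F"
            lam = (
                _EPOCH_BLINK_LAMBDA["MW"]
                if eff == "MW"
                else _EPOCH_BLINK_LAMBDA["F"]
                if eff == "F"
                else (_EPOCH_BLINK_LAMBDA["F"] + _EPOCH_BLINK_LAMBDA["MW"]) / 2.0
            )
            count = rng.poisson(lam)
            row["blink_rate"] = count * (60.0 / 9.0)
            if count:
                dur = (
                    _EPOCH_BLINK_DUR["MW"]
                    if eff == "MW"
                    else _EPOCH_BLINK_DUR["F"]
                    if eff == "F"
                    else (_EPOCH_BLINK_DUR["F"] + _EPOCH_BLINK_DUR["MW"]) / 2.0
                )
                row["blink_duration_mean"] = float(
                    np.mean(_MIN_BLINK_S + rng.exponential(dur, count))
                )
            else:
                row["blink_duration_mean"] = np.nan
            rows.append(row)
    from .io import FEATURE_COLUMNS

    return pd.DataFrame(rows, columns=["label", *FEATURE_COLUMNS])
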