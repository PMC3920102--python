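"""Text-format IO for recordings, event logs, questionnaires, and feature tables.

The native recording dialect is a plain TSV with named columns and times in
seconds. An SMI-IView-text-like dialect (``##`` comment lines, time in
microseconds) is available through the same dialect mechanism, since
high-speed video-oculography exports commonly look like that. All files are
UTF-8 with '.' as decimal separator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical per-epoch oculometric variables, in reporting order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "pupil_size_slope",
    "pupil_size_mean",
    "pupil_size_std",
    "blink_rate",
    "blink_duration_mean",
    "gaze_x_position_mean",
    "gaze_x_position_std",
    "gaze_y_position_mean",
    "gaze_y_position_std",
)

#: Human-readable variable names used in reports.
FEATURE_DISPLAY_NAMES: dict[str, str] = {
    "pupil_size_slope": "Pupil Size Slope",
    "pupil_size_mean": "Pupil Size Mean",
    "pupil_size_std": "Pupil Size Std",
    "blink_rate": "Blink Rate",
    "blink_duration_mean": "Blink Duration Mean",
    "gaze_x_position_mean": "Gaze X Position Mean",
    "gaze_x_position_std": "Gaze X Position Std",
    "gaze_y_position_mean": "Gaze Y Position Mean",
    "gaze_y_position_std": "Gaze Y Position Std",
}

EVENT_KINDS = ("session_start", "session_end", "mw_press", "refocus_press")

#: Ordinal answer bounds per questionnaire item (1..7 Likert-style by default).
QUESTION_IDS = tuple(f"Q{i}" for i in range(1, 11))
QUESTION_SCALE: dict[str, tuple[int, int]] = {q: (1, 7) for q in QUESTION_IDS}


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """Column mapping and parsing rules for a tabular recording export."""

    name: str
    delimiter: str = "\t"
    comment: str = "#"
    time_unit: str = "s"  # "s" or "us"
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "time": "time_s",
            "gaze_x": "gaze_x_px",
            "gaze_y": "gaze_y_px",
            "pupil_area": "pupil_area_px2",
        }
    )


NATIVE_DIALECT = Dialect(name="native")
SMI_LIKE_DIALECT = Dialect(
    name="smi_like",
    delimiter="\t",
    comment="#",
    time_unit="us",
    columns={
        "time": "Time",
        "gaze_x": "POR X [px]",
        "gaze_y": "POR Y [px]",
        "pupil_area": "Pupil Area [px2]",
    },
)
DIALECTS: dict[str, Dialect] = {d.name: d for d in (NATIVE_DIALECT, SMI_LIKE_DIALECT)}


@dataclass
class RawRecording:
    """Uniformly sampled monocular gaze/pupil time series.

    Gaze is in screen pixels (origin top-left, x rightward, y downward on a
    nominal 1280x1024 frame); pupil area is in squared pixels, with 0 marking
    eyelid closure. Sampling is nominally 240 samples/s.
    """

    timestamps: np.ndarray  # seconds
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil_area: np.ndarray
    sampling_rate: float = 240.0

    def __post_init__(self) -> None:
        for name in ("timestamps", "gaze_x", "gaze_y", "pupil_area"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def validate(self) -> None:
        n = self.timestamps.size
        for name in ("gaze_x", "gaze_y", "pupil_area"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"channel length mismatch: {name} has {getattr(self, name).size} "
                    f"samples, timestamps has {n}"
                )
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                idx = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"timestamps not strictly increasing at sample {idx + 1}"
                )
            nominal = 1.0 / self.sampling_rate
            jitter = np.abs(dt - nominal)
            if np.any(jitter > 0.1 * nominal):
                idx = int(np.argmax(jitter > 0.1 * nominal))
                raise ValidationError(
                    f"inter-sample interval at sample {idx + 1} deviates more than "
                    f"10% from nominal {nominal:.6f} s"
                )
        if np.any(self.pupil_area < 0):
            idx = int(np.argmax(self.pupil_area < 0))
            raise ValidationError(f"negative pupil area at sample {idx}")


def read_recording(path: str | Path, dialect: Dialect | str = NATIVE_DIALECT,
                   sampling_rate: float | None = None) -> RawRecording:
    """Read a tabular recording export into a validated :class:`RawRecording`.

    Comment/header lines are skipped per the dialect and the time column is
    normalized to seconds. Errors carry the 0-based sample index at fault.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"recording file not found: {path}")
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, comment=dialect.comment)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"unparseable recording file {path}: {exc}") from exc
    missing = [c for c in dialect.columns.values() if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    for col in dialect.columns.values():
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValidationError(f"{path}: unparseable value in column {col!r}, data row {row}")
    time = df[dialect.columns["time"]].to_numpy(dtype=float)
    if dialect.time_unit == "us":
        time = time / 1e6
    elif dialect.time_unit != "s":
        raise ValidationError(f"unknown time unit {dialect.time_unit!r}")
    if sampling_rate is None:
        if time.size >= 2:
            sampling_rate = 1.0 / float(np.median(np.diff(time)))
        else:
            sampling_rate = 240.0
    return RawRecording(
        timestamps=time,
        gaze_x=df[dialect.columns["gaze_x"]].to_numpy(dtype=float),
        gaze_y=df[dialect.columns["gaze_y"]].to_numpy(dtype=float),
        pupil_area=df[dialect.columns["pupil_area"]].to_numpy(dtype=float),
        sampling_rate=float(sampling_rate),
    )


def write_recording(rec: RawRecording, path: str | Path,
                    dialect: Dialect | str = NATIVE_DIALECT) -> None:
    """Write a recording with deterministic column order and full float precision."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    time = rec.timestamps
    if dialect.time_unit == "us":
        time = time * 1e6
    df = pd.DataFrame(
        {
            dialect.columns["time"]: time,
            dialect.columns["gaze_x"]: rec.gaze_x,
            dialect.columns["gaze_y"]: rec.gaze_y,
            dialect.columns["pupil_area"]: rec.pupil_area,
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Events and questionnaires
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    time: float  # seconds
    kind: str  # one of EVENT_KINDS
    questionnaire_id: str | None = None


@dataclass
class EventLog:
    """Ordered button-press log with session bounds."""

    events: list[Event]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("event times must be non-decreasing")
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise ValidationError(f"unknown event kind {e.kind!r}")

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    @property
    def session_start(self) -> float:
        starts = self.of_kind("session_start")
        return starts[0].time if starts else self.events[0].time

    @property
    def session_end(self) -> float:
        ends = self.of_kind("session_end")
        return ends[-1].time if ends else self.events[-1].time


@dataclass
class QuestionnaireRecord:
    """Per-episode self-report: ordinal answers plus reported episode duration.

    Q1 is memory clarity of the episode, Q5 subjective well-being, Q6
    vigilance, Q10 temporal distance of the thought content; remaining items
    cover thought content and modality on the same ordinal scales.
    """

    id: str
    answers: dict[str, int]
    reported_mw_duration: float  # seconds
    error_press: bool = False

    def __post_init__(self) -> None:
        if self.reported_mw_duration < 0:
            raise ValidationError(
                f"questionnaire {self.id}: reported_mw_duration must be >= 0"
            )
        for q, v in self.answers.items():
            lo, hi = QUESTION_SCALE.get(q, (1, 7))
            if not (lo <= int(v) <= hi):
                raise ValidationError(
                    f"questionnaire {self.id}: answer {q}={v} outside scale [{lo}, {hi}]"
                )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".questionnaires.csv")


def write_events(log: EventLog, path: str | Path,
                 questionnaires: Mapping[str, QuestionnaireRecord] | None = None,
                 questionnaire_path: str | Path | None = None) -> None:
    """Write events as CSV ``time_s,kind,questionnaire_id`` plus a sidecar
    questionnaire CSV keyed by id."""
    path = Path(path)
    rows = [
        {"time_s": e.time, "kind": e.kind, "questionnaire_id": e.questionnaire_id or ""}
        for e in log.events
    ]
    pd.DataFrame(rows, columns=["time_s", "kind", "questionnaire_id"]).to_csv(
        path, index=False, float_format="%.17g"
    )
    if questionnaires is not None:
        qpath = Path(questionnaire_path) if questionnaire_path else _sidecar_path(path)
        qrows = []
        for qid, q in questionnaires.items():
            row = {"id": qid}
            row.update({k: q.answers.get(k, "") for k in QUESTION_IDS})
            row["reported_mw_duration_s"] = q.reported_mw_duration
            row["error_press"] = int(q.error_press)
            qrows.append(row)
        cols = ["id", *QUESTION_IDS, "reported_mw_duration_s", "error_press"]
        pd.DataFrame(qrows, columns=cols).to_csv(qpath, index=False, float_format="%.17g")


def read_events(path: str | Path, questionnaire_path: str | Path | None = None
                ) -> tuple[EventLog, dict[str, QuestionnaireRecord]]:
    """Read an event CSV and its questionnaire sidecar; check link integrity."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"questionnaire_id": str}, keep_default_na=False)
    events = []
    for _, row in df.iterrows():
        qid = str(row.get("questionnaire_id", "") or "").strip() or None
        events.append(Event(time=float(row["time_s"]), kind=str(row["kind"]), questionnaire_id=qid))
    log = EventLog(events=events)

    questionnaires: dict[str, QuestionnaireRecord] = {}
    qpath = Path(questionnaire_path) if questionnaire_path else _sidecar_path(path)
    if qpath.exists():
        qdf = pd.read_csv(qpath, dtype={"id": str})
        for _, row in qdf.iterrows():
            answers = {
                q: int(row[q]) for q in QUESTION_IDS if q in qdf.columns and pd.notna(row[q])
            }
            questionnaires[str(row["id"])] = QuestionnaireRecord(
                id=str(row["id"]),
                answers=answers,
                reported_mw_duration=float(row["reported_mw_duration_s"]),
                error_press=bool(int(row["error_press"])),
            )
    dangling = [
        e.questionnaire_id
        for e in log.events
        if e.questionnaire_id and e.questionnaire_id not in questionnaires
    ]
    if dangling:
        raise ValidationError(f"events reference absent questionnaire id(s): {dangling}")
    return log, questionnaires


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def epochs_to_frame(epochs: Sequence) -> pd.DataFrame:
    """One row per epoch: id, label, anchor time, the 9 oculometric features,
    and the interpolated fraction (13 columns)."""
    rows = []
    for ep in epochs:
        if getattr(ep, "features", None) is None:
            raise ValidationError(f"epoch {getattr(ep, 'epoch_id', '?')} lacks features")
        row = {
            "epoch_id": ep.epoch_id,
            "label": ep.label,
            "anchor_time_s": ep.anchor_time,
        }
        for name in FEATURE_COLUMNS:
            row[name] = ep.features[name]
        row["interpolated_fraction"] = ep.interpolated_fraction
        rows.append(row)
    cols = ["epoch_id", "label", "anchor_time_s", *FEATURE_COLUMNS, "interpolated_fraction"]
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(epochs: Sequence, path: str | Path) -> pd.DataFrame:
    df = epochs_to_frame(epochs)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"epoch_id": str, "label": str})
    expected = ["epoch_id", "label", "anchor_time_s", *FEATURE_COLUMNS, "interpolated_fraction"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table {path} missing column(s) {missing}")
    return df
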