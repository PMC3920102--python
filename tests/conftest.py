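"""Shared fixtures: short synthetic sessions, stub clean recordings, and the
hand-enumerated epoch-filter fixture."""

from __future__ import annotations

import numpy as np
import pytest

from oculomw.io import Event, EventLog, QuestionnaireRecord, RawRecording
from oculomw.preprocess import (
    BLINK,
    ARTIFACT,
    VALID,
    BlinkEvent,
    CleanRecording,
    clean_recording,
)
from oculomw.synth import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def short_config() -> SimulationConfig:
    """A 5-minute default-parameter session, fast enough for unit tests."""
    return SimulationConfig(session_duration=300.0, seed=11)


@pytest.fixture(scope="session")
def session_bundle(short_config):
    return generate_session(short_config)


@pytest.fixture(scope="session")
def clean_session(session_bundle):
    return clean_recording(session_bundle.recording)


def make_recording(pupil, fs: float = 240.0, gaze_x=None, gaze_y=None) -> RawRecording:
    pupil = np.asarray(pupil, dtype=float)
    n = pupil.size
    return RawRecording(
        timestamps=np.arange(n) / fs,
        gaze_x=np.full(n, 640.0) if gaze_x is None else np.asarray(gaze_x, float),
        gaze_y=np.full(n, 512.0) if gaze_y is None else np.asarray(gaze_y, float),
        pupil_area=pupil,
        sampling_rate=fs,
    )


def make_clean(
    duration_s: float,
    fs: float = 240.0,
    pupil=None,
    gaze_x=None,
    gaze_y=None,
    blinks=(),
    mask=None,
) -> CleanRecording:
    """Directly assemble a CleanRecording (bypassing the cleaning pipeline)
    for epoch/feature/statistics unit tests."""
    n = int(round(duration_s * fs))
    pupil = np.full(n, 2000.0) if pupil is None else np.asarray(pupil, float)
    return CleanRecording(
        timestamps=np.arange(n) / fs,
        pupil=pupil,
        gaze_x=np.full(n, 640.0) if gaze_x is None else np.asarray(gaze_x, float),
        gaze_y=np.full(n, 512.0) if gaze_y is None else np.asarray(gaze_y, float),
        sampling_rate=fs,
        mask=np.full(n, VALID, dtype=np.int8) if mask is None else mask,
        blinks=list(blinks),
    )


def match_blinks(truth, detected, fs: float):
    """Overlap-match ground-truth blinks against detected events.

    Returns (n_matched, onset_errors_samples); a detected event matches a
    truth blink when their intervals overlap.
    """
    n_matched = 0
    onset_errors = []
    for onset, offset in truth:
        hits = [d for d in detected if d.onset <= offset and d.offset >= onset]
        if hits:
            n_matched += 1
            onset_errors.append(abs(hits[0].onset - onset) * fs)
    return n_matched, onset_errors


# ---------------------------------------------------------------------------
# Hand-enumerated epoch-filter fixture: five cycles, one violation of every
# exclusion rule, with all expected tallies worked out by hand.
# ---------------------------------------------------------------------------

def build_filter_fixture():
    """A 400-s constant recording with a crafted mask/blink list and a
    five-cycle event log.

    Cycle layout (start -> MW press):
      c0 session_start@0   -> mw@40   clean; MW retained (no F: session start)
      c1 refocus@70        -> mw@95   interval 25 s  -> 30-s rule hits MW, F, CT;
                                      CT [78, 87) also overlaps MW's 10-s epoch
      c2 refocus@125       -> mw@165  questionnaire reports 1 s -> MW discarded;
                                      F window [126, 135) is 51% interpolated
      c3 refocus@195       -> mw@240  error press -> MW discarded; a 4.5-s blink
                                      at [203, 207.5] overlaps F [196, 205)
      c4 (missing refocus) -> mw@280  MW discarded (no refocus press)
      trailing refocus@310: clean F epoch, retained

    Expected: retained MW=1 (mw@40), F=1 (refocus@310), CT=2 (c2, c3);
    tallies: interval 3 (MW1, F1, CT1), reported 1, error 1, missing 1,
    interpolated 1, blink 1, ct_overlap 1.
    """
    fs = 240.0
    n = int(400 * fs)
    mask = np.full(n, VALID, dtype=np.int8)
    # 51% of F window [126, 135): mark [126.0, 130.6) as interpolated artifact
    mask[int(126.0 * fs):int(130.6 * fs)] = ARTIFACT
    blink = BlinkEvent(onset=203.0, offset=207.5)
    mask[int(203.0 * fs):int(207.5 * fs) + 1] = BLINK
    clean = make_clean(400.0, fs=fs, mask=mask, blinks=[blink])

    events = [
        Event(0.0, "session_start"),
        Event(40.0, "mw_press", "q1"),
        Event(70.0, "refocus_press"),
        Event(95.0, "mw_press", "q2"),
        Event(125.0, "refocus_press"),
        Event(165.0, "mw_press", "q3"),
        Event(195.0, "refocus_press"),
        Event(240.0, "mw_press", "q4"),
        Event(280.0, "mw_press", "q5"),
        Event(310.0, "refocus_press"),
        Event(400.0, "session_end"),
    ]
    log = EventLog(events=events)

    def q(qid, duration=10.0, error=False):
        return QuestionnaireRecord(
            id=qid, answers={"Q1": 4}, reported_mw_duration=duration, error_press=error
        )

    questionnaires = {
        "q1": q("q1"),
        "q2": q("q2"),
        "q3": q("q3", duration=1.0),
        "q4": q("q4", error=True),
        "q5": q("q5"),
    }
    expected = {
        "retained": {"MW": 1, "F": 1, "CT": 2},
        "candidates": {"MW": 5, "F": 4, "CT": 3},
        "discarded": {"MW": 4, "F": 3, "CT": 1},
        "rule_counts": {
            "interval_lt_30s": 3,
            "reported_lt_2s": 1,
            "error_press": 1,
            "missing_refocus": 1,
            "interpolated_gt_40pct": 1,
            "blink_gt_4s": 1,
            "ct_overlap": 1,
            "out_of_bounds": 0,
        },
    }
    return clean, log, questionnaires, expected
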