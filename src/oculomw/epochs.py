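"""Event-anchored analysis epochs and the exclusion filters.

Mind-wandering (MW) epochs are the 9-s window [press - 10 s, press - 1 s)
before a mind-wandering button press; focusing (F) epochs the window
[press + 1 s, press + 10 s) after a refocus press; control (CT) epochs a 9-s
window centered between a refocus press and the following MW press, kept
only when disjoint from that cycle's full 10-s MW and F intervals. The
second before and after each press is excluded everywhere because button
presses transiently dilate the pupil.

Windows are half-open so a sample belongs to exactly one abutting window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import EventLog, QuestionnaireRecord
from .preprocess import BlinkEvent, CleanRecording

MW_WINDOW = (-10.0, -1.0)   # relative to the MW press
F_WINDOW = (1.0, 10.0)      # relative to the refocus press
CT_HALF_WIDTH = 4.5
FULL_EPOCH_S = 10.0         # unpruned MW/F interval used for CT overlap checks

# Exclusion rules (report keys)
RULE_INTERVAL = "interval_lt_30s"
RULE_REPORTED = "reported_lt_2s"
RULE_ERROR_PRESS = "error_press"
RULE_MISSING_REFOCUS = "missing_refocus"
RULE_INTERPOLATED = "interpolated_gt_40pct"
RULE_BLINK = "blink_gt_4s"
RULE_CT_OVERLAP = "ct_overlap"
RULE_OUT_OF_BOUNDS = "out_of_bounds"
ALL_RULES = (
    RULE_INTERVAL, RULE_REPORTED, RULE_ERROR_PRESS, RULE_MISSING_REFOCUS,
    RULE_INTERPOLATED, RULE_BLINK, RULE_CT_OVERLAP, RULE_OUT_OF_BOUNDS,
)

@dataclass
class EpochFilterParams:
    """Exclusion thresholds, at their standard values. Inequalities are
    strict, matching the usual phrasing ("lower than 30 s", "more than 40%",
    "greater than 4 s")."""

    min_cycle_interval_s: float = 30.0       # refocus-to-MW-press interval
    min_reported_mw_s: float = 2.0           # self-reported episode duration
    max_interpolated_fraction: float = 0.40
    max_blink_duration_s: float = 4.0


@dataclass
class Cycle:
    """One refocus→MW-press cycle (the first cycle starts at session start)."""

    index: int
    start_time: float
    start_kind: str          # "session_start", "refocus_press", or "mw_press"
    mw_time: float | None    # None for a trailing refocus with no further press
    questionnaire_id: str | None = None
    missing_refocus: bool = False

    @property
    def interval(self) -> float | None:
        return None if self.mw_time is None else self.mw_time - self.start_time


@dataclass
class Epoch:
    """A labeled 9-s analysis window tied to an anchor event."""

    epoch_id: str
    label: str               # "MW", "F", or "CT"
    anchor_time: float       # s; the button press (or CT center)
    window: tuple[float, float]
    cycle_index: int
    flags: set[str] = field(default_factory=set)
    interpolated_fraction: float | None = None
    blinks: list[BlinkEvent] = field(default_factory=list)
    questionnaire: QuestionnaireRecord | None = None
    features: dict | None = None

    @property
    def window_length(self) -> float:
        return self.window[1] - self.window[0]


@dataclass
class EpochSelectionReport:
    candidates: dict[str, int]
    retained: dict[str, int]
    discarded: dict[str, int]
    rule_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "candidates": dict(self.candidates),
            "retained": dict(self.retained),
            "discarded": dict(self.discarded),
            "rule_counts": dict(self.rule_counts),
        }


# ---------------------------------------------------------------------------

def pair_events(log: EventLog) -> list[Cycle]:
    """Group the event log into refocus→MW cycles.

    The first cycle starts at session start. An MW press directly following
    another MW press opens a cycle flagged ``missing_refocus`` (the orphan is
    never silently dropped). A trailing refocus press with no further MW
    press yields a final cycle with ``mw_time=None``.
    """
    cycles: list[Cycle] = []
    start_time = log.session_start
    start_kind = "session_start"
    pending = True  # a cycle start is waiting for its MW press
    missing = False
    for e in log.events:
        if e.kind == "mw_press":
            cycles.append(
                Cycle(
                    index=len(cycles),
                    start_time=start_time,
                    start_kind=start_kind,
                    mw_time=e.time,
                    questionnaire_id=e.questionnaire_id,
                    missing_refocus=missing,
                )
            )
            # until a refocus arrives, the next cycle starts at this press
            start_time, start_kind = e.time, "mw_press"
            pending = False
            missing = True
        elif e.kind == "refocus_press":
            start_time, start_kind = e.time, "refocus_press"
            pending = True
            missing = False
    if pending and start_kind == "refocus_press":
        cycles.append(
            Cycle(index=len(cycles), start_time=start_time, start_kind=start_kind,
                  mw_time=None)
        )
    return cycles


def _window_bounds_ok(window: tuple[float, float], clean: CleanRecording) -> bool:
    t0 = float(clean.timestamps[0])
    return window[0] >= t0 - 1e-9 and window[1] <= t0 + clean.duration + 1e-9


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def extract_epochs(
    cycles: Sequence[Cycle],
    clean: CleanRecording,
    questionnaires: Mapping[str, QuestionnaireRecord] | None = None,
) -> list[Epoch]:
    """All MW/F/CT candidate epochs, annotated but unfiltered.

    Out-of-bounds windows and CT windows overlapping their cycle's full 10-s
    MW/F intervals are emitted with the corresponding flag so the selection
    report can tally them.
    """
    questionnaires = questionnaires or {}
    epochs: list[Epoch] = []

    def attach(ep: Epoch) -> Epoch:
        if not _window_bounds_ok(ep.window, clean):
            ep.flags.add(RULE_OUT_OF_BOUNDS)
            return ep
        ep.interpolated_fraction = clean.interpolated_fraction(*ep.window)
        ep.blinks = [
            b for b in clean.blinks if _overlaps((b.onset, b.offset), ep.window)
        ]
        return ep

    for cyc in cycles:
        if cyc.mw_time is not None:
            mw = Epoch(
                epoch_id=f"MW{cyc.index}",
                label="MW",
                anchor_time=cyc.mw_time,
                window=(cyc.mw_time + MW_WINDOW[0], cyc.mw_time + MW_WINDOW[1]),
                cycle_index=cyc.index,
                questionnaire=questionnaires.get(cyc.questionnaire_id or ""),
            )
            epochs.append(attach(mw))
        if cyc.start_kind == "refocus_press":
            f = Epoch(
                epoch_id=f"F{cyc.index}",
                label="F",
                anchor_time=cyc.start_time,
                window=(cyc.start_time + F_WINDOW[0], cyc.start_time + F_WINDOW[1]),
                cycle_index=cyc.index,
            )
            epochs.append(attach(f))
        if cyc.start_kind == "refocus_press" and cyc.mw_time is not None:
            center = 0.5 * (cyc.start_time + cyc.mw_time)
            ct = Epoch(
                epoch_id=f"CT{cyc.index}",
                label="CT",
                anchor_time=center,
                window=(center - CT_HALF_WIDTH, center + CT_HALF_WIDTH),
                cycle_index=cyc.index,
            )
            full_mw = (cyc.mw_time - FULL_EPOCH_S, cyc.mw_time)
            full_f = (cyc.start_time, cyc.start_time + FULL_EPOCH_S)
            if _overlaps(ct.window, full_mw) or _overlaps(ct.window, full_f):
                ct.flags.add(RULE_CT_OVERLAP)
            epochs.append(attach(ct))
    return epochs


def apply_epoch_filters(
    candidates: Sequence[Epoch],
    cycles: Sequence[Cycle],
    filters: EpochFilterParams | None = None,
    require_questionnaires: bool = True,
) -> tuple[list[Epoch], EpochSelectionReport]:
    """Apply all exclusion rules (a conjunction of per-epoch predicates).

    Per-rule tallies count every epoch violating that rule, so an epoch
    breaking two rules appears in both tallies but is discarded once.
    """
    filters = filters or EpochFilterParams()
    by_index = {c.index: c for c in cycles}
    labels = ("MW", "F", "CT")
    rule_counts = {r: 0 for r in ALL_RULES}
    candidates_n = {lab: 0 for lab in labels}
    retained: list[Epoch] = []
    discarded_n = {lab: 0 for lab in labels}

    for ep in candidates:
        candidates_n[ep.label] += 1
        cyc = by_index[ep.cycle_index]
        violated = set(ep.flags & {RULE_CT_OVERLAP, RULE_OUT_OF_BOUNDS})
        interval = cyc.interval
        if interval is not None and interval < filters.min_cycle_interval_s:
            violated.add(RULE_INTERVAL)
        if cyc.missing_refocus:
            violated.add(RULE_MISSING_REFOCUS)
        if ep.label == "MW":
            if ep.questionnaire is None:
                if require_questionnaires:
                    raise ValidationError(
                        f"MW epoch {ep.epoch_id} has no linked questionnaire; "
                        "every mind-wandering press must be followed by one"
                    )
            else:
                if ep.questionnaire.reported_mw_duration < filters.min_reported_mw_s:
                    violated.add(RULE_REPORTED)
                if ep.questionnaire.error_press:
                    violated.add(RULE_ERROR_PRESS)
        if RULE_OUT_OF_BOUNDS not in violated:
            if (ep.interpolated_fraction or 0.0) > filters.max_interpolated_fraction:
                violated.add(RULE_INTERPOLATED)
            # boundary-clipped blinks count here too: a long closure is
            # disqualifying whether or not its true duration is known
            if any(b.duration > filters.max_blink_duration_s for b in ep.blinks):
                violated.add(RULE_BLINK)
        for rule in violated:
            rule_counts[rule] += 1
        if violated:
            ep.flags |= violated
            discarded_n[ep.label] += 1
        else:
            retained.append(ep)

    report = EpochSelectionReport(
        candidates=candidates_n,
        retained={lab: sum(1 for ep in retained if ep.label == lab) for lab in labels},
        discarded=discarded_n,
        rule_counts=rule_counts,
    )
    return retained, report


def select_epochs(
    clean: CleanRecording,
    log: EventLog,
    questionnaires: Mapping[str, QuestionnaireRecord] | None = None,
    filters: EpochFilterParams | None = None,
    require_questionnaires: bool = True,
) -> tuple[list[Epoch], EpochSelectionReport]:
    """Convenience wrapper: pair events, extract candidates, filter."""
    cycles = pair_events(log)
    candidates = extract_epochs(cycles, clean, questionnaires)
    return apply_epoch_filters(candidates, cycles, filters, require_questionnaires)
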