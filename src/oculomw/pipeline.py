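"""End-to-end orchestration: simulate -> clean -> epoch -> features -> stats
-> classify, with per-stage artifacts and a JSON provenance record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, pairwise_classification
from .epochs import EpochFilterParams, select_epochs
from .errors import ValidationError
from .features import compute_all_features
from .io import epochs_to_frame, write_events, write_recording
from .preprocess import PreprocessParams, clean_recording
from .stats import condition_contrasts, questionnaire_correlations
from .synth import SimulationConfig, generate_session


@dataclass
class PipelineConfig:
    """Every stage's tunables, defaulting to the standard analysis values."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_sessions: int = 1
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    epoch_filters: EpochFilterParams = field(default_factory=EpochFilterParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv_folds: int = 10
    cv_reps: int = 100
    feature_sets: str = "both"
    leak_free: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for section, target in (
            ("simulation", cfg.simulation),
            ("preprocess", cfg.preprocess),
            ("epoch_filters", cfg.epoch_filters),
        ):
            for key, value in (raw.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ValidationError(f"unknown {section} option {key!r}")
                setattr(target, key, value)
        if "classifier" in raw:
            cfg.classifier = ClassifierConfig(**raw["classifier"])
        for key in ("n_sessions", "cv_folds", "cv_reps", "feature_sets",
                    "leak_free", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def as_dict(self) -> dict:
        return {
            "simulation": dataclasses.asdict(self.simulation),
            "n_sessions": self.n_sessions,
            "preprocess": dataclasses.asdict(self.preprocess),
            "epoch_filters": dataclasses.asdict(self.epoch_filters),
            "classifier": dataclasses.asdict(self.classifier),
            "cv_folds": self.cv_folds,
            "cv_reps": self.cv_reps,
            "feature_sets": self.feature_sets,
            "leak_free": self.leak_free,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Simulate ``n_sessions`` sessions, run the full analysis, and return a
    results bundle; when ``outdir`` is given every stage writes its artifact
    there together with a provenance record."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    session_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_sessions)
    frames = []
    reports = []
    all_retained = []
    for s in range(config.n_sessions):
        sim = dataclasses.replace(config.simulation,
                                  seed=int(session_seeds[s] % (2**31 - 1)))
        bundle = generate_session(sim)
        clean = clean_recording(bundle.recording, config.preprocess)
        retained, report = select_epochs(clean, bundle.event_log,
                                         bundle.questionnaires, config.epoch_filters)
        compute_all_features(retained, clean)
        frame = epochs_to_frame(retained)
        frame.insert(0, "session", s)
        frame["epoch_id"] = [f"s{s}_{e}" for e in frame["epoch_id"]]
        frames.append(frame)
        reports.append(report.as_dict())
        all_retained.extend(retained)
        if outdir is not None and s == 0:
            write_recording(bundle.recording, outdir / "session0_raw.tsv")
            write_events(bundle.event_log, outdir / "session0_events.csv",
                         bundle.questionnaires)
    features = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    results: dict = {
        "epoch_reports": reports,
        "n_epochs": {
            lab: int((features["label"] == lab).sum()) if len(features) else 0
            for lab in ("MW", "F", "CT")
        },
    }

    mw = features[features["label"] == "MW"]
    f = features[features["label"] == "F"]
    if len(mw) and len(f):
        _, contrast_table = condition_contrasts(mw, f)
        results["contrasts"] = contrast_table
        if outdir is not None:
            contrast_table.to_csv(outdir / "contrasts.csv", index=False)
    mw_epochs = [ep for ep in all_retained if ep.label == "MW"]
    if len(mw_epochs) >= 3:
        try:
            _, corr = questionnaire_correlations(mw_epochs)
            results["questionnaire_correlations"] = corr
            if outdir is not None:
                corr.to_csv(outdir / "questionnaire_correlations.csv", index=False)
        except ValidationError:
            pass

    counts = features["label"].value_counts() if len(features) else pd.Series(dtype=int)
    if all(counts.get(lab, 0) >= config.cv_folds for lab in ("MW", "F", "CT")):
        table, cv_results = pairwise_classification(
            features, config=config.classifier, k=config.cv_folds,
            reps=config.cv_reps, seed=config.seed, leak_free=config.leak_free,
            feature_sets=config.feature_sets,
        )
        results["classification"] = table
        results["cv_results"] = cv_results
        if outdir is not None:
            table.to_csv(outdir / "classification.csv", index=False)
    if outdir is not None:
        features.to_csv(outdir / "features.csv", index=False)
        provenance = {
            "package_version": __version__,
            "config": config.as_dict(),
            "config_hash": config.config_hash(),
            "epoch_reports": reports,
            "n_epochs": results["n_epochs"],
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    results["features"] = features
    return results
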