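"""End-to-end orchestration: simulate -> preprocess/features -> stats -> ml.

A :class:`RunConfig` fully determines a run; it is serialized verbatim into
``config.lock.json`` in the output directory so every artifact is traceable
to its configuration and seed.  Stage failures are recorded in the log and
dependent stages are skipped; :func:`run_pipeline` returns a report with a
non-zero ``exit_code`` in that case.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ml_analysis as ml
from . import stats_analysis as st
from .features import FeatureConfig, assemble_feature_table, session_feature_rows
from .io import read_session, write_session
from .synthetic import EffectConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "features", "stats", "ml")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # input: either a list of session directories, or simulation settings
    session_dirs: list = field(default_factory=list)
    n_per_group: int = 2
    effect: dict = field(default_factory=dict)  # EffectConfig overrides
    write_sessions: bool = False
    # analysis settings
    feature: dict = field(default_factory=dict)  # FeatureConfig overrides
    ml_features: list = field(default_factory=lambda: list(ml.DEFAULT_FEATURES))
    prune_threshold: float = 0.75
    n_repeats: int = 10
    n_estimators: int = 100
    stages: list = field(default_factory=lambda: list(STAGES))

    @classmethod
    def from_json(cls, path, **overrides):
        data = json.loads(Path(path).read_text())
        data.update(overrides)
        return cls(**data)


def _feature_stage(cfg, sessions, log):
    fc = FeatureConfig(**cfg.feature)
    rows = []
    for sess in sessions:
        try:
            rows.extend(session_feature_rows(sess, fc))
        except ValueError as e:
            log.warning("subject %s excluded: %s", sess.subject_id, e)
    if not rows:
        raise ValueError("no analyzable sessions")
    return assemble_feature_table(rows)


def _stats_stage(cfg, table, log):
    report = {"friedman": [], "group_deltas": [], "normality": {}}
    features = [c for c in table.columns if c not in ("subject", "group", "phase")]
    for f in features:
        report["normality"][f] = st.normality_screen(table[f])
        try:
            res = st.friedman_posthoc(table, f)
            report["friedman"].append(dataclasses.asdict(res))
        except ValueError as e:
            log.warning("Friedman skipped for %s: %s", f, e)
        for task in ("MIST", "MGT", "VS"):
            try:
                report["group_deltas"].append(st.group_delta_test(table, f, task))
            except ValueError as e:
                log.warning("group delta skipped for %s/%s: %s", f, task, e)
    return report


def _ml_stage(cfg, table, log):
    retained = ml.prune_features(table, cfg.ml_features, cfg.prune_threshold)
    log.info("retained features after pruning: %s", retained)
    out = {"features": retained, "contrasts": {}}
    for contrast in ml.CONTRASTS:
        try:
            res = ml.repeat_and_summarize(
                table, contrast, n_repeats=cfg.n_repeats, master_seed=cfg.seed,
                features=retained, n_estimators=cfg.n_estimators)
            out["contrasts"][contrast] = dataclasses.asdict(res)
        except ValueError as e:
            log.warning("ML contrast %s skipped: %s", contrast, e)
    return out


def run_pipeline(config):
    """Run the configured stages; returns a dict report with ``exit_code``."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger(f"autonomics.run.{id(cfg)}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)

    (out / "config.lock.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1))

    report = {"exit_code": 0, "stages": {}}
    table = None
    sessions = None
    t0 = time.time()
    try:
        if "simulate" in cfg.stages and not cfg.session_dirs:
            eff = EffectConfig(**cfg.effect)
            sessions, truths = generate_cohort(cfg.n_per_group, eff, seed=cfg.seed)
            log.info("simulated %d sessions", len(sessions))
            if cfg.write_sessions:
                for s, tr in zip(sessions, truths):
                    write_session(out / "sessions" / s.subject_id, s, tr)
            report["stages"]["simulate"] = {"n_sessions": len(sessions)}
        elif cfg.session_dirs:
            sessions = [read_session(d) for d in cfg.session_dirs]
            report["stages"]["simulate"] = {"n_sessions": len(sessions),
                                            "loaded": True}
    except Exception as e:  # pragma: no cover - defensive
        log.error("simulate failed: %s", e)
        report["exit_code"] = 1
        report["stages"]["simulate"] = {"error": str(e)}

    if "features" in cfg.stages and sessions is not None and report["exit_code"] == 0:
        try:
            table = _feature_stage(cfg, sessions, log)
            table.to_csv(out / "features.csv", index=False)
            report["stages"]["features"] = {"n_rows": len(table)}
        except Exception as e:
            log.error("features failed: %s", e)
            report["exit_code"] = 1
            report["stages"]["features"] = {"error": str(e)}

    if "stats" in cfg.stages and table is not None and report["exit_code"] == 0:
        try:
            stats_report = _stats_stage(cfg, table, log)
            (out / "stats.json").write_text(json.dumps(stats_report, indent=1,
                                                       default=str))
            report["stages"]["stats"] = {
                "n_friedman": len(stats_report["friedman"])}
        except Exception as e:
            log.error("stats failed: %s", e)
            report["exit_code"] = 1
            report["stages"]["stats"] = {"error": str(e)}

    if "ml" in cfg.stages and table is not None and report["exit_code"] == 0:
        try:
            ml_report = _ml_stage(cfg, table, log)
            (out / "ml.json").write_text(json.dumps(ml_report, indent=1))
            report["stages"]["ml"] = {
                "contrasts": list(ml_report["contrasts"])}
        except Exception as e:
            log.error("ml failed: %s", e)
            report["exit_code"] = 1
            report["stages"]["ml"] = {"error": str(e)}

    log.info("pipeline finished in %.1f s (exit %d)", time.time() - t0,
             report["exit_code"])
    fh.close()
    return report
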