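"""File formats, configuration, and seeded run orchestration.

Trial logs are plain CSV with a fixed column order; configuration is a flat
key-value file (INI syntax) whose ``[experiment]`` section selects one of the
two engine modes; a run manifest records everything needed to reproduce a run
bit for bit (config snapshot, master seed, derived per-stage seeds, version).
"""

from __future__ import annotations

import configparser
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import sample_cohort, scenario_preset
from .engine import EngineConfig, TrialRecord, experiment_mode, run_participant
from .equivalence import RopeSpec
from .pipeline import (apply_exclusions, clean_trials, participant_summaries,
                       perseveration_summary, regress_use, run_h1, run_h2,
                       run_h3)

__all__ = [
    "TRIAL_COLUMNS",
    "ConfigError",
    "RunManifest",
    "write_trial_log",
    "read_trial_log",
    "load_config",
    "derive_seed",
    "run_scenario",
]

log = logging.getLogger("extrot")

TRIAL_COLUMNS = ("participant", "block", "role", "trial", "angle", "mirrored",
                 "strategy_used", "rotated", "rt", "correct", "timeout",
                 "unreliable")
_BOOL_FIELDS = {"mirrored", "rotated", "correct", "timeout", "unreliable"}
_INT_FIELDS = {"participant", "block", "trial", "angle"}


class ConfigError(ValueError):
    """Missing or invalid configuration key; the message names it."""


def write_trial_log(records, path) -> None:
    """CSV trial log with the fixed documented header; lossless round-trip."""
    with open(path, "w") as fh:
        fh.write(",".join(TRIAL_COLUMNS) + "\n")
        for r in records:
            vals = []
            for c in TRIAL_COLUMNS:
                v = getattr(r, c)
                if c in _BOOL_FIELDS:
                    vals.append("1" if v else "0")
                elif c == "rt":
                    vals.append(repr(float(v)))
                else:
                    vals.append(str(v))
            fh.write(",".join(vals) + "\n")


def read_trial_log(path) -> list:
    """Read a trial-log CSV back into :class:`TrialRecord` objects."""
    records = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if tuple(header) != TRIAL_COLUMNS:
            raise ConfigError(f"unexpected trial-log header in {path}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            raw = dict(zip(TRIAL_COLUMNS, line.split(",")))
            kw = {}
            for c, v in raw.items():
                if c in _BOOL_FIELDS:
                    kw[c] = v == "1"
                elif c in _INT_FIELDS:
                    kw[c] = int(v)
                elif c == "rt":
                    kw[c] = float(v)
                else:
                    kw[c] = v
            records.append(TrialRecord(**kw))
    return records


_DEFAULTS = {
    ("run", "n_participants"): "54",
    ("run", "reps"): "1000",
    ("run", "dip_null"): "2000",
    ("run", "practice"): "1",
    ("cohort", "scenario"): None,       # defaults to the experiment name
    ("analysis", "rope_rt_ms"): "200",
    ("analysis", "rope_acc"): "0.02",
}
_REQUIRED = (("experiment", "name"), ("run", "seed"))


def load_config(path) -> dict:
    """Parse the flat key-value config file into a plain dict.

    Required keys: ``[experiment] name`` (exp1 or exp2) and ``[run] seed``.
    Optional keys have documented defaults; unknown experiment names raise a
    :class:`ConfigError` naming the key.
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise ConfigError(f"config file not found: {path}")
    def get(section, key, default=None):
        try:
            return parser.get(section, key)
        except (configparser.NoSectionError, configparser.NoOptionError):
            return default
    cfg = {}
    for section, key in _REQUIRED:
        v = get(section, key)
        if v is None:
            raise ConfigError(f"missing config key [{section}] {key}")
        cfg[key] = v
    for (section, key), default in _DEFAULTS.items():
        cfg[key] = get(section, key, default)
    if cfg["name"] not in ("exp1", "exp2"):
        raise ConfigError("config key [experiment] name must be exp1 or exp2")
    try:
        cfg["seed"] = int(cfg["seed"])
        cfg["n_participants"] = int(cfg["n_participants"])
        cfg["reps"] = int(cfg["reps"])
        cfg["dip_null"] = int(cfg["dip_null"])
        cfg["practice"] = bool(int(cfg["practice"]))
        cfg["rope_rt_ms"] = float(cfg["rope_rt_ms"])
        cfg["rope_acc"] = float(cfg["rope_acc"])
    except ValueError as exc:
        raise ConfigError(f"non-numeric config value: {exc}") from exc
    if cfg["scenario"] is None:
        cfg["scenario"] = cfg["name"]
    return cfg


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                 int.from_bytes(stage.encode(), "big") % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Everything needed to reproduce one run's outputs exactly."""

    config: dict
    master_seed: int
    stage_seeds: dict
    version: str
    timestamp: str
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_cohort(experiment: str, n_participants: int, seed: int,
                    practice: bool = True, scenario: str = None) -> list:
    """Sample a cohort and run every participant through the paradigm."""
    scenario = scenario or experiment
    cohort_cfg = scenario_preset(scenario, n_participants=n_participants,
                                 seed=derive_seed(seed, "cohort"))
    engine_cfg = experiment_mode(experiment, practice_enabled=practice)
    records = []
    for pid, profile in enumerate(sample_cohort(cohort_cfg)):
        rng = np.random.default_rng(
            np.random.SeedSequence([derive_seed(seed, "engine"), pid]))
        records.extend(run_participant(profile, engine_cfg, rng,
                                       participant_id=pid))
    return records


def analyze_records(records, rope_rt: RopeSpec, rope_acc: RopeSpec,
                    seed: int, dip_null: int = 2000) -> dict:
    """Clean, exclude, summarise, and run H1-H3 plus exploratory analyses."""
    cleaned, clean_report = clean_trials(records)
    exclusions = apply_exclusions(cleaned)
    clean_report.excluded = exclusions.excluded
    summaries = participant_summaries(cleaned,
                                      exclude=list(exclusions.excluded))
    u = summaries["extended_use"].to_numpy()
    d_rt = summaries["delta_rt"].to_numpy()
    d_acc = summaries["delta_acc"].to_numpy()
    rng = np.random.default_rng(derive_seed(seed, "analysis"))
    reports = {
        "clean": clean_report.to_dict(),
        "n_analyzed": int(len(summaries)),
        "h1_rt": run_h1(d_rt, n_null=dip_null, rng=rng).to_dict(),
        "h1_acc": run_h1(d_acc, n_null=dip_null, rng=rng).to_dict(),
        "h2_rt": run_h2(summaries["rt_block7"], summaries["rt_block8"],
                        rope_rt, rng=rng).to_dict(),
        "h2_acc": run_h2(summaries["acc_block7"], summaries["acc_block8"],
                         rope_acc, rng=rng).to_dict(),
        "h3": run_h3(u, n_null=dip_null, rng=rng).to_dict(),
        "regression_rt": regress_use(u, d_rt / 1000.0).to_dict(),
        "perseveration": {str(k): v for k, v in
                          perseveration_summary(u).items()},
        "correlation_rt_use": float(np.corrcoef(d_rt, u)[0, 1]),
    }
    return {"summaries": summaries, "reports": reports}


def run_scenario(config_path, output_dir) -> RunManifest:
    """simulate -> clean -> analyze -> report, fully seeded and logged."""
    cfg = load_config(config_path)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = RunManifest(
        config=dict(cfg), master_seed=seed,
        stage_seeds={s: derive_seed(seed, s)
                     for s in ("cohort", "engine", "analysis")},
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()))
    try:
        log.info("simulating %d participants (%s)", cfg["n_participants"],
                 cfg["name"])
        records = simulate_cohort(cfg["name"], cfg["n_participants"], seed,
                                  practice=cfg["practice"],
                                  scenario=cfg["scenario"])
        trial_path = out / "trials.csv"
        write_trial_log(records, trial_path)
        manifest.outputs["trials"] = str(trial_path)
        log.info("analyzing %d trial records", len(records))
        result = analyze_records(
            records,
            RopeSpec.symmetric(cfg["rope_rt_ms"]),
            RopeSpec.symmetric(cfg["rope_acc"]),
            seed, dip_null=cfg["dip_null"])
        summary_path = out / "participant_summaries.csv"
        result["summaries"].to_csv(summary_path, index=False)
        manifest.outputs["summaries"] = str(summary_path)
        report_path = out / "reports.json"
        with open(report_path, "w") as fh:
            json.dump(result["reports"], fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.outputs["reports"] = str(report_path)
    except Exception as exc:
        raise RuntimeError(f"scenario run failed: {exc}") from exc
    manifest.to_json(out / "manifest.json")
    log.info("run complete: %s", out)
    return manifest
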