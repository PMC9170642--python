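"""Configuration loading, config hashing, and session-log CSV output.

Configs are JSON or YAML mirroring the engine dataclass field names, with
every absent field defaulting to the published task parameters and unknown
keys rejected with their field path.  Session logs are UTF-8 CSV with a
'#'-prefixed header comment block (schema version, task, config hash,
master seed); output is bitwise-stable for identical inputs, so rewriting
the same session yields a byte-identical file.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from attnbattery.agents import CohortSpec, GroupSpec
from attnbattery.kinematics import PlayfieldBounds
from attnbattery.moa import MOAConfig, MOASessionResult
from attnbattery.mot import MOTConfig, MOTSessionResult
from attnbattery.seeding import TASK_CODES, derive_seed

__all__ = [
    "SCHEMA_VERSION",
    "DSSTSettings",
    "BatteryConfig",
    "SessionLog",
    "config_hash",
    "config_to_dict",
    "load_config",
    "write_session",
    "moa_session_log",
    "mot_session_log",
    "read_session",
]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class DSSTSettings:
    """Simulated-responder settings for the symbol substitution task."""

    rate: float = 0.8
    error_prob: float = 0.05
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError("error_prob must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class BatteryConfig:
    """Aggregate configuration of all tasks plus the cohort generator."""

    moa: MOAConfig = MOAConfig()
    mot: MOTConfig = MOTConfig()
    dsst: DSSTSettings = DSSTSettings()
    cohort: Optional[CohortSpec] = None
    master_seed: int = 0


def _bounds_to_list(b: PlayfieldBounds) -> list[float]:
    return [b.width, b.height]


def config_to_dict(obj: Any) -> Any:
    """Recursively convert config dataclasses to plain JSON-able data."""
    if isinstance(obj, PlayfieldBounds):
        return _bounds_to_list(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: config_to_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [config_to_dict(v) for v in obj]
    return obj


def config_hash(config: Any) -> str:
    """Stable short hash identifying a full configuration."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _build_dataclass(cls, raw: Any, path: str):
    """Instantiate ``cls`` from a mapping, validating unknown keys."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(raw).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        fpath = f"{path}.{name}" if path else name
        ftype = fields[name].type
        if name == "window":
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                raise ValueError(f"{fpath}: expected [width, height]")
            kwargs[name] = PlayfieldBounds(float(value[0]), float(value[1]))
        elif name in ("moa_config", "moa"):
            kwargs[name] = _build_dataclass(MOAConfig, value, fpath)
        elif name in ("mot_config", "mot"):
            kwargs[name] = _build_dataclass(MOTConfig, value, fpath)
        elif name in ("group_a", "group_b"):
            kwargs[name] = _build_dataclass(GroupSpec, value, fpath)
        elif name in ("direction_set", "speed_set"):
            kwargs[name] = tuple(float(v) for v in value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path or cls.__name__}: {exc}") from exc


def load_config(path: str | Path) -> BatteryConfig:
    """Load a battery config from JSON/YAML, applying defaults for absent
    fields and rejecting unknown keys with their field paths."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"moa", "mot", "dsst", "cohort", "master_seed"}
    if unknown:
        raise ValueError(f"unknown top-level keys {sorted(unknown)}")
    moa = _build_dataclass(MOAConfig, raw.get("moa"), "moa")
    mot = _build_dataclass(MOTConfig, raw.get("mot"), "mot")
    dsst = _build_dataclass(DSSTSettings, raw.get("dsst"), "dsst")
    cohort = None
    if "cohort" in raw and raw["cohort"] is not None:
        cohort = _build_dataclass(CohortSpec, raw["cohort"], "cohort")
    master_seed = int(raw.get("master_seed", 0))
    return BatteryConfig(moa=moa, mot=mot, dsst=dsst, cohort=cohort, master_seed=master_seed)


@dataclass(frozen=True)
class SessionLog:
    """One completed session: header metadata plus per-trial rows."""

    task: str
    config_hash: str
    master_seed: int
    columns: tuple[str, ...]
    rows: tuple[tuple, ...]
    session_id: str
    timestamp: Optional[str] = None  # ISO-8601; omitted by default so logs
    # from identical inputs stay byte-identical

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# schema_version={SCHEMA_VERSION}\n")
        buf.write(f"# task={self.task}\n")
        buf.write(f"# config_hash={self.config_hash}\n")
        buf.write(f"# master_seed={self.master_seed}\n")
        if self.timestamp is not None:
            buf.write(f"# timestamp={self.timestamp}\n")
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(self.columns)
        for row in self.rows:
            writer.writerow(row)
        return buf.getvalue()


def write_session(log: SessionLog, path: str | Path) -> None:
    """Write the session log CSV; byte-identical for identical inputs."""
    Path(path).write_text(log.to_csv_text(), encoding="utf-8")


def _fmt(x: float) -> str:
    return repr(float(x))


def moa_session_log(result: MOASessionResult, config: MOAConfig) -> SessionLog:
    h = config_hash(config)
    rows = tuple(
        (
            f"MOA-{config.master_seed}",
            "MOA",
            rec.trial_index,
            int(rec.practice),
            rec.seed,
            _fmt(rec.survival_time),
            int(rec.censored),
        )
        for rec in result.records
    )
    return SessionLog(
        task="MOA",
        config_hash=h,
        master_seed=config.master_seed,
        columns=(
            "session_id",
            "task",
            "trial_index",
            "practice",
            "seed",
            "survival_time_s",
            "censored",
        ),
        rows=rows,
        session_id=f"MOA-{config.master_seed}",
    )


def mot_session_log(result: MOTSessionResult, config: MOTConfig) -> SessionLog:
    h = config_hash(config)
    rows = tuple(
        (
            f"MOT-{config.master_seed}",
            "MOT",
            i,
            derive_seed(config.master_seed, TASK_CODES["MOT"], i),
            trial.n_correct,
            _fmt(trial.accuracy),
        )
        for i, trial in enumerate(result.trials)
    )
    return SessionLog(
        task="MOT",
        config_hash=h,
        master_seed=config.master_seed,
        columns=("session_id", "task", "trial_index", "seed", "n_correct", "accuracy"),
        rows=rows,
        session_id=f"MOT-{config.master_seed}",
    )


def read_session(path: str | Path):
    """Read a session log back into (header dict, pandas DataFrame)."""
    import pandas as pd

    header: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            header[key] = value
            data_start = i + 1
        else:
            break
    frame = pd.read_csv(io.StringIO("\n".join(lines[data_start:])))
    return header, frame
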