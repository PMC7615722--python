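"""File formats: trial logs, ratings, questionnaires, fits, manifests.

All on-disk formats are plain UTF-8 CSV (comma separated, header row,
missing values as empty fields) or JSON.  Response times are stored as
integer milliseconds; score formulas convert to seconds internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "TWO_STEP_LOG_COLUMNS",
    "RATINGS_COLUMNS",
    "QUESTIONNAIRE_COLUMNS",
    "GROUND_TRUTH_COLUMNS",
    "SchemaError",
    "read_trial_log",
    "write_trial_log",
    "read_ratings",
    "write_ratings",
    "read_questionnaires",
    "write_questionnaires",
    "write_fit_results",
    "read_fit_results",
    "RunManifest",
    "write_manifest",
]

#: One row per scheduled trial; response columns stay empty for bare
#: schedules and are filled by simulation or observed data.
TRIAL_LOG_COLUMNS = [
    "participant_id",
    "task",
    "phase",
    "day",
    "trial_number",
    "left_stim",
    "right_stim",
    "cue_side",
    "response_window_ms",
    "choice_side",
    "chosen_stim",
    "outcome_points_left",
    "outcome_points_right",
    "rt_ms",
    "missed",
]

#: The two-step task has its own row shape (two stages per trial).
TWO_STEP_LOG_COLUMNS = [
    "participant_id",
    "trial_number",
    "start_state",
    "left_ship",
    "right_ship",
    "choice_side",
    "chosen_ship",
    "alien",
    "points",
    "rt_ms",
    "missed",
]

RATINGS_COLUMNS = ["participant_id", "task", "stimulus", "timepoint", "rating"]
QUESTIONNAIRE_COLUMNS = ["participant_id", "instrument", "item", "response"]
GROUND_TRUTH_COLUMNS = ["participant_id", "model_id", "param", "value"]

_INT_COLUMNS = {
    "day",
    "trial_number",
    "response_window_ms",
    "rt_ms",
    "missed",
    "start_state",
    "alien",
    "points",
    "item",
}
_FLOAT_COLUMNS = {"outcome_points_left", "outcome_points_right", "rating", "response", "value"}


class SchemaError(ValueError):
    """An input file does not conform to the expected CSV schema."""


def _check_columns(frame: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _coerce(frame: pd.DataFrame) -> pd.DataFrame:
    for col in frame.columns:
        if col in _INT_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="raise").astype("Int64")
        elif col in _FLOAT_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="raise").astype("Float64")
    return frame


def _read_csv(path: str | Path, columns: list[str], what: str) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.replace({"": None})
    _check_columns(frame, columns, what)
    return _coerce(frame[columns])


def _write_csv(frame: pd.DataFrame, path: str | Path, columns: list[str], what: str) -> None:
    _check_columns(frame, columns, what)
    out = _coerce(frame[columns].copy())  # canonical dtypes: ints never gain ".0"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep="")


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, TRIAL_LOG_COLUMNS, "trial log")


def write_trial_log(frame: pd.DataFrame, path: str | Path) -> None:
    _write_csv(frame, path, TRIAL_LOG_COLUMNS, "trial log")


def read_ratings(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, RATINGS_COLUMNS, "ratings")


def write_ratings(frame: pd.DataFrame, path: str | Path) -> None:
    _write_csv(frame, path, RATINGS_COLUMNS, "ratings")


def read_questionnaires(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, QUESTIONNAIRE_COLUMNS, "questionnaires")


def write_questionnaires(frame: pd.DataFrame, path: str | Path) -> None:
    _write_csv(frame, path, QUESTIONNAIRE_COLUMNS, "questionnaires")


def write_fit_results(results: Iterable[Any], path: str | Path) -> None:
    """Serialize fit results as JSON lines (one object per participant x model)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for res in results:
            obj = res.to_dict() if hasattr(res, "to_dict") else dict(res)
            fh.write(json.dumps(obj) + "\n")


def read_fit_results(path: str | Path) -> list[dict]:
    with Path(path).open("r", encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


@dataclasses.dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    command: str
    config_hash: str
    seeds: dict[str, int]
    inputs: list[str]
    outputs: list[str]
    package_version: str = ""
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping[str, Any],
    seeds: Mapping[str, int],
    inputs: Iterable[str] = (),
    outputs: Iterable[str] = (),
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config_hash=config_hash(config),
        seeds=dict(seeds),
        inputs=sorted(map(str, inputs)),
        outputs=sorted(map(str, outputs)),
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    return manifest
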