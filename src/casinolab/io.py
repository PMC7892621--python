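"""Readers/writers for the artifact's file formats.

CSV dialect everywhere: UTF-8, comma-separated, header row, "." decimal, no
index column.  JSON reports use stable key ordering and embed provenance
metadata (package version, seed, input-file hashes) so a report can always be
traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .engine import TRIAL_COLUMNS, ParticipantSession, SessionEvent, records_to_frame
from .survey import GAMBLING_TYPES, N_PGSI_ITEMS, SurveyResponse

__all__ = [
    "SURVEY_COLUMNS",
    "EVENT_COLUMNS",
    "write_trials",
    "read_trials",
    "write_survey",
    "read_survey",
    "survey_to_frame",
    "write_events",
    "read_events",
    "write_report",
    "file_sha256",
]

EVENT_COLUMNS = ["study_id", "timestamp_ms", "event_type", "payload"]

SURVEY_COLUMNS = (
    ["study_id", "age", "sex", "gambling_frequency"]
    + list(GAMBLING_TYPES)
    + ["none"]
    + [f"pgsi_item_{i}" for i in range(1, N_PGSI_ITEMS + 1)]
    + ["pgsi_total"]
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def write_trials(
    records: Union[pd.DataFrame, Sequence[ParticipantSession]],
    path: Union[str, Path],
) -> pd.DataFrame:
    """Write the long-format trial log (one row per gamble)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame([r for s in records for r in s.records])
    _require_columns(df, TRIAL_COLUMNS, "trial log")
    df = df[TRIAL_COLUMNS]
    df.to_csv(path, index=False)
    return df


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, f"trial log {path}")
    return df


def survey_to_frame(surveys: Sequence[SurveyResponse]) -> pd.DataFrame:
    rows = []
    for s in surveys:
        row: dict = {
            "study_id": s.study_id,
            "age": s.age,
            "sex": s.sex,
            "gambling_frequency": s.gambling_frequency,
        }
        for t in GAMBLING_TYPES:
            row[t] = int(t in s.gambling_types)
        row["none"] = int(not s.gambling_types)
        for i, item in enumerate(s.pgsi_items, start=1):
            row[f"pgsi_item_{i}"] = item
        row["pgsi_total"] = s.pgsi_total
        rows.append(row)
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def write_survey(
    surveys: Union[pd.DataFrame, Sequence[SurveyResponse]],
    path: Union[str, Path],
) -> pd.DataFrame:
    df = surveys if isinstance(surveys, pd.DataFrame) else survey_to_frame(surveys)
    _require_columns(df, SURVEY_COLUMNS, "survey table")
    df = df[SURVEY_COLUMNS]
    df.to_csv(path, index=False)
    return df


def read_survey(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_COLUMNS, f"survey table {path}")
    return df


def frame_to_surveys(df: pd.DataFrame) -> list[SurveyResponse]:
    """Inverse of :func:`survey_to_frame` (round-trip identity)."""
    out = []
    for _, row in df.iterrows():
        out.append(
            SurveyResponse(
                study_id=row["study_id"],
                age=float(row["age"]),
                sex=row["sex"],
                gambling_frequency=int(row["gambling_frequency"]),
                gambling_types=tuple(t for t in GAMBLING_TYPES if row[t]),
                pgsi_items=tuple(
                    int(row[f"pgsi_item_{i}"]) for i in range(1, N_PGSI_ITEMS + 1)
                ),
            )
        )
    return out


def write_events(
    events: Union[pd.DataFrame, Sequence[ParticipantSession], Sequence[SessionEvent]],
    path: Union[str, Path],
) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        flat: list[SessionEvent] = []
        for item in events:
            if isinstance(item, ParticipantSession):
                flat.extend(item.events)
            else:
                flat.append(item)
        df = pd.DataFrame([e.__dict__ for e in flat], columns=EVENT_COLUMNS)
    _require_columns(df, EVENT_COLUMNS, "event log")
    df = df[EVENT_COLUMNS]
    df.to_csv(path, index=False)
    return df


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, f"event log {path}")
    return df


def file_sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(
    payload: dict,
    path: Union[str, Path],
    seed: Optional[int] = None,
    inputs: Sequence[Union[str, Path]] = (),
) -> dict:
    """Write a JSON report with embedded provenance metadata."""
    doc = {
        "metadata": {
            "artifact": "casinolab",
            "version": __version__,
            "seed": seed,
            "input_hashes": {str(p): file_sha256(p) for p in inputs},
        },
        "report": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=_json_default) + "\n")
    return doc


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
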