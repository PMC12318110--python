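"""Readers and writers for cohort tables, decision tables and reports.

One pinned dialect: comma-separated UTF-8 with a mandatory header and "."
decimals; a ``.tsv`` extension switches the delimiter to tabs. Booleans are
serialized as 0/1 and undefined fields (malignancy and size class of
no-lesion images) as empty strings, so a write-read round trip reproduces
the in-memory table exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS
from .config import RunConfig
from .strategies import DECISION_COLUMNS

_BOOL_COHORT = ["has_lesion", "detector_flag", "rad_detect_flag",
                "rad_class_flag", "rad_assisted_flag"]


class ParseError(ValueError):
    """Malformed input file; the message names the file and location."""


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def write_cohort(cohort: pd.DataFrame, path) -> None:
    path = Path(path)
    out = cohort.copy()
    for col in _BOOL_COHORT:
        out[col] = out[col].astype(int)
    # nullable fields: 0/1 or empty
    out["malignant"] = cohort["malignant"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out["size_class"] = cohort["size_class"].map(
        lambda v: "" if pd.isna(v) else str(v)
    )
    out[COHORT_COLUMNS].to_csv(path, sep=_sep(path), index=False)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            sep=_sep(path),
            dtype={"image_id": str, "screening_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = raw.copy()
    for col in _BOOL_COHORT:
        df[col] = df[col].astype(int).astype(bool)
    df["malignant"] = pd.array(
        [None if pd.isna(v) else bool(int(v)) for v in raw["malignant"]],
        dtype="boolean",
    )
    df["size_class"] = pd.array(
        [None if pd.isna(v) else str(v) for v in raw["size_class"]],
        dtype="string",
    )
    df["center_id"] = df["center_id"].astype(np.int64)
    for col in ("classifier_score", "rad_confidence"):
        df[col] = df[col].astype(float)
    return df[COHORT_COLUMNS]


def write_decisions(decisions: pd.DataFrame, path) -> None:
    path = Path(path)
    out = decisions.copy()
    out["recall"] = out["recall"].astype(int)
    out[DECISION_COLUMNS].to_csv(path, sep=_sep(path), index=False)


def read_decisions(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=_sep(path), dtype={"image_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in DECISION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["recall"] = df["recall"].astype(int).astype(bool)
    for col in ("detection_reads", "classification_reads"):
        df[col] = df[col].astype(np.int64)
    df["recall_prob"] = df["recall_prob"].astype(float)
    return df[DECISION_COLUMNS]


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def load_run_config(path) -> RunConfig:
    """Load a run configuration from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return RunConfig.model_validate(data)
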