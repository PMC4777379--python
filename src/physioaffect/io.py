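"""Plain-text serialisation of recordings, timelines, profiles and features.

Recordings are written one delimited-text file per channel (``time_s``,
``value``) plus a JSON sidecar with subject id, units and sampling rates;
timelines follow the BIDS-events convention (``onset``, ``duration``,
``trial_type``); profiles and feature matrices are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CompletenessError
from .features import FEATURE_NAMES
from .synth import EventTimeline, RawRecording, SubjectProfile


def write_timeline(timeline: EventTimeline, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"onset": onset, "duration": offset - onset, "trial_type": label}
            for onset, offset, label in timeline.intervals
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_timeline(path) -> EventTimeline:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    intervals = tuple(
        (float(r.onset), float(r.onset) + float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    )
    timeline = EventTimeline(intervals)
    timeline.validate()
    return timeline


def write_profiles(profiles: list[SubjectProfile], path) -> Path:
    path = Path(path)
    rows = [
        {
            "subject_id": p.subject_id,
            "age": p.age,
            "gender": p.gender,
            **{f: getattr(p, f) for f in SubjectProfile.TRAIT_FIELDS},
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_profiles(path) -> list[SubjectProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SubjectProfile(
            subject_id=str(r.subject_id),
            age=float(r.age),
            gender=str(r.gender),
            **{f: float(getattr(r, f)) for f in SubjectProfile.TRAIT_FIELDS},
        )
        for r in df.itertuples()
    ]


def write_recording(recording: RawRecording, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {"subject_id": recording.subject_id, "channels": {}}
    for name, (samples, fs, units) in recording.channels.items():
        t = np.arange(len(samples)) / fs
        pd.DataFrame({"time_s": t, "value": samples}).to_csv(
            directory / f"{recording.subject_id}_{name}.tsv", sep="\t", index=False
        )
        sidecar["channels"][name] = {"fs": fs, "units": units}
    with open(directory / f"{recording.subject_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return directory


def read_recording(directory, subject_id: str) -> RawRecording:
    directory = Path(directory)
    with open(directory / f"{subject_id}.json") as fh:
        sidecar = json.load(fh)
    channels = {}
    for name, meta in sidecar["channels"].items():
        df = pd.read_csv(directory / f"{subject_id}_{name}.tsv", sep="\t")
        channels[name] = (df["value"].to_numpy(), float(meta["fs"]), meta["units"])
    return RawRecording(subject_id=subject_id, channels=channels)


def write_feature_matrix(matrix: pd.DataFrame, path) -> Path:
    path = Path(path)
    matrix.to_csv(path, index=False)
    return path


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    features = [c for c in FEATURE_NAMES if c in df.columns]
    if df[features].isna().any().any():
        raise CompletenessError(f"feature matrix {path} contains missing values")
    return df


def read_s1_feature_table(xlsx_path, sheet_name=0) -> pd.DataFrame:
    """Read a supplementary per-(subject, condition) feature workbook.

    Expects a sheet whose columns include ``subject_id``, ``condition`` and
    feature columns named after the canonical feature list (extra columns
    are ignored).  Returns a feature matrix in the standard schema.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet_name, engine="openpyxl")
    df.columns = [str(c).strip() for c in df.columns]
    required = {"subject_id", "condition"}
    if not required.issubset(df.columns):
        raise CompletenessError(
            f"supplementary table must contain columns {sorted(required)}"
        )
    features = [c for c in FEATURE_NAMES if c in df.columns]
    if not features:
        raise CompletenessError("supplementary table contains no recognised feature columns")
    out = df[["subject_id", "condition"] + features].copy()
    if out[features].isna().any().any():
        raise CompletenessError("supplementary feature table contains missing values")
    return out
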