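"""Reading and writing session tables (CSV long format and JSON documents).

CSV dialect: comma-separated, UTF-8, header required, "." decimal. One row
per replicate COHb reading; baseline rows use ``sample_time_min = -1``.
Required columns::

    subject_id, sex, age_y, height_cm, weight_kg, hb_g_l, hct,
    performance_status, dose_co_ml, rebreathe_end_min,
    sample_time_min, cohb_pct, replicate_index

Optional columns: ``hb_unit`` ("g/l" default; "g/dl" values are converted
×10 on read), ``residual_system_co_ml``, ``exhale_rate_ml_per_min``.
Schema violations raise :class:`~ocor.errors.SchemaError` naming the row
and column.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import SchemaError
from .session import COSample, OcorSession, Subject

__all__ = ["read_sessions", "read_study", "write_sessions", "sessions_to_table"]

REQUIRED_COLUMNS = [
    "subject_id", "sex", "age_y", "height_cm", "weight_kg", "hb_g_l", "hct",
    "performance_status", "dose_co_ml", "rebreathe_end_min",
    "sample_time_min", "cohb_pct", "replicate_index",
]
OPTIONAL_COLUMNS = ["hb_unit", "residual_system_co_ml", "exhale_rate_ml_per_min"]

BASELINE_TIME = -1.0


def _fail(row: int, column: str, message: str) -> None:
    raise SchemaError(f"row {row}, column {column!r}: {message}")


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.copy()
    # row numbers as in the file (header = row 1)
    df["_row"] = df.index + 2

    for _, r in df.iterrows():
        row = int(r["_row"])
        if not 0.0 <= r["cohb_pct"] <= 100.0:
            _fail(row, "cohb_pct", f"{r['cohb_pct']} outside [0, 100]")
        if r["dose_co_ml"] <= 0:
            _fail(row, "dose_co_ml", "must be positive")
        if r["weight_kg"] <= 0:
            _fail(row, "weight_kg", "must be positive")
        if r["sample_time_min"] < 0 and r["sample_time_min"] != BASELINE_TIME:
            _fail(row, "sample_time_min", "negative times other than -1 (baseline) not allowed")

    if "hb_unit" in df.columns:
        mask = df["hb_unit"].fillna("g/l").str.lower().str.replace(" ", "") == "g/dl"
        df.loc[mask, "hb_g_l"] = df.loc[mask, "hb_g_l"] * 10.0

    dup = df.duplicated(subset=["subject_id", "sample_time_min", "replicate_index"])
    if dup.any():
        row = int(df.loc[dup, "_row"].iloc[0])
        raise SchemaError(
            f"row {row}: duplicate (subject_id, sample_time_min, replicate_index) key"
        )
    return df


def _build_session(sid: str, group: pd.DataFrame) -> OcorSession:
    first = group.iloc[0]
    samples: dict[float, list[float]] = {}
    for _, r in group.sort_values(["sample_time_min", "replicate_index"]).iterrows():
        samples.setdefault(float(r["sample_time_min"]), []).append(float(r["cohb_pct"]))
    baseline = [COSample(t, reads) for t, reads in samples.items() if t == BASELINE_TIME]
    timed = [COSample(t, reads) for t, reads in sorted(samples.items()) if t >= 0]
    residual = first.get("residual_system_co_ml")
    exhale = first.get("exhale_rate_ml_per_min")
    return OcorSession(
        subject_id=sid,
        dose_co_ml=float(first["dose_co_ml"]),
        baseline=baseline,
        timed=timed,
        rebreathe_end_min=float(first["rebreathe_end_min"]),
        residual_system_co_ml=None if residual is None or pd.isna(residual) else float(residual),
        exhale_rate_ml_per_min=None if exhale is None or pd.isna(exhale) else float(exhale),
    )


def _build_subject(sid: str, group: pd.DataFrame) -> Subject:
    first = group.iloc[0]
    hct = first["hct"]
    return Subject(
        id=sid,
        sex=str(first["sex"]),
        age_y=None if pd.isna(first["age_y"]) else float(first["age_y"]),
        weight_kg=float(first["weight_kg"]),
        height_cm=float(first["height_cm"]),
        hb_g_l=float(first["hb_g_l"]),
        hct=None if pd.isna(hct) else float(hct),
        performance_status=int(first["performance_status"]),
    )


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            docs = json.load(fh)
        rows = []
        for doc in docs:
            subj = doc["subject"]
            sess = doc["session"]
            for sample in sess["samples"]:
                for i, reading in enumerate(sample["readings"]):
                    rows.append(
                        {
                            **{k: subj.get(k) for k in
                               ("sex", "age_y", "height_cm", "weight_kg", "hb_g_l",
                                "hct", "performance_status")},
                            "subject_id": subj["id"],
                            "dose_co_ml": sess["dose_co_ml"],
                            "rebreathe_end_min": sess.get("rebreathe_end_min", 2.0),
                            "residual_system_co_ml": sess.get("residual_system_co_ml"),
                            "exhale_rate_ml_per_min": sess.get("exhale_rate_ml_per_min"),
                            "sample_time_min": sample["time_min"],
                            "cohb_pct": reading,
                            "replicate_index": i,
                        }
                    )
        df = pd.DataFrame(rows)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                df[col] = math.nan
        return df
    return pd.read_csv(path)


def read_study(path: str | Path) -> tuple[list[Subject], list[OcorSession]]:
    """Read a session table (CSV or JSON) into validated subjects + sessions."""
    df = _validate_table(_load_frame(path))
    subjects, sessions = [], []
    for sid, group in df.groupby("subject_id", sort=False):
        try:
            subjects.append(_build_subject(str(sid), group))
            sessions.append(_build_session(str(sid), group))
        except ValueError as exc:
            raise SchemaError(
                f"row {int(group['_row'].iloc[0])}: subject {sid}: {exc}"
            ) from exc
    return subjects, sessions


def read_sessions(path: str | Path) -> list[OcorSession]:
    """Read a session table, returning validated sessions only."""
    return read_study(path)[1]


def sessions_to_table(
    subjects: Sequence[Subject], sessions: Sequence[OcorSession]
) -> pd.DataFrame:
    """Long-format table (one row per replicate reading) for a cohort."""
    by_id = {s.id: s for s in subjects}
    rows = []
    for session in sessions:
        subj = by_id[session.subject_id]
        tagged = [(BASELINE_TIME, s) for s in session.baseline] + [
            (s.time_min, s) for s in session.timed
        ]
        for time, sample in tagged:
            for i, reading in enumerate(sample.readings):
                rows.append(
                    {
                        "subject_id": subj.id,
                        "sex": subj.sex,
                        "age_y": subj.age_y,
                        "height_cm": subj.height_cm,
                        "weight_kg": subj.weight_kg,
                        "hb_g_l": subj.hb_g_l,
                        "hct": subj.hct,
                        "performance_status": subj.performance_status,
                        "dose_co_ml": session.dose_co_ml,
                        "rebreathe_end_min": session.rebreathe_end_min,
                        "residual_system_co_ml": session.residual_system_co_ml,
                        "exhale_rate_ml_per_min": session.exhale_rate_ml_per_min,
                        "sample_time_min": time,
                        "cohb_pct": reading,
                        "replicate_index": i,
                    }
                )
    return pd.DataFrame(rows)


def write_sessions(
    path: str | Path,
    subjects: Sequence[Subject],
    sessions: Sequence[OcorSession],
    fmt: Optional[str] = None,
) -> None:
    """Write a cohort as CSV (long format) or JSON session documents."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        sessions_to_table(subjects, sessions).to_csv(path, index=False)
        return
    by_id = {s.id: s for s in subjects}
    docs = []
    for session in sessions:
        subj = by_id[session.subject_id]
        samples = [
            {"time_min": BASELINE_TIME, "readings": list(s.readings)}
            for s in session.baseline
        ] + [
            {"time_min": s.time_min, "readings": list(s.readings)} for s in session.timed
        ]
        docs.append(
            {
                "subject": {
                    "id": subj.id,
                    "sex": subj.sex,
                    "age_y": subj.age_y,
                    "height_cm": subj.height_cm,
                    "weight_kg": subj.weight_kg,
                    "hb_g_l": subj.hb_g_l,
                    "hct": subj.hct,
                    "performance_status": subj.performance_status,
                },
                "session": {
                    "dose_co_ml": session.dose_co_ml,
                    "rebreathe_end_min": session.rebreathe_end_min,
                    "residual_system_co_ml": session.residual_system_co_ml,
                    "exhale_rate_ml_per_min": session.exhale_rate_ml_per_min,
                    "samples": samples,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(docs, fh, indent=2)
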