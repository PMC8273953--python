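"""CSV schemas and audit-headed file I/O for the pipeline.

Subject files are comma-separated UTF-8 with a mandatory header::

    id,group,sex,age,education,nct_a_s,nct_b_s,sdt_s,ltt_time_s,ltt_errors,
    dst_points,child_pugh,ascites,jaundice,gi_bleed

Empty cells are missing values.  Every file the pipeline writes starts with
``#``-prefixed comment lines recording tool version, normative-model name,
seed and MHE rule, so a result can always be traced to its inputs.
"""

from __future__ import annotations

import csv
import os
from typing import IO, Iterable, Optional, Union

import pandas as pd

from . import __version__
from .models import (
    Group,
    MheRule,
    ParseError,
    PhesResult,
    RawBattery,
    Sex,
    Subject,
    Test,
    ValidationError,
)

__all__ = ["read_subjects", "write_subjects", "write_scored", "read_scored", "SUBJECT_COLUMNS"]

SUBJECT_COLUMNS = [
    "id",
    "group",
    "sex",
    "age",
    "education",
    "nct_a_s",
    "nct_b_s",
    "sdt_s",
    "ltt_time_s",
    "ltt_errors",
    "dst_points",
    "child_pugh",
    "ascites",
    "jaundice",
    "gi_bleed",
]

_COVARIATE_COLUMNS = ("child_pugh", "ascites", "jaundice", "gi_bleed")


def _parse_float(value: str, row: int, column: str, minimum: Optional[float] = None,
                 strict_min: bool = False) -> Optional[float]:
    if value == "":
        return None
    try:
        x = float(value)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {column!r}: not numeric: {value!r}") from exc
    if minimum is not None and (x < minimum or (strict_min and x == minimum)):
        op = ">" if strict_min else ">="
        raise ParseError(f"row {row}, column {column!r}: must be {op} {minimum}, got {x}")
    return x


def read_subjects(path: Union[str, os.PathLike, IO[str]]) -> list[tuple[Subject, RawBattery]]:
    """Parse a subject/battery CSV; errors are addressed by row and column."""
    if hasattr(path, "read"):
        return _read_subjects_fh(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_subjects_fh(fh)


def _read_subjects_fh(fh: IO[str]) -> list[tuple[Subject, RawBattery]]:
    rows = [r for r in csv.reader(line for line in fh if not line.startswith("#"))]
    if not rows:
        raise ParseError("empty file: no header row")
    header = rows[0]
    if header != SUBJECT_COLUMNS:
        unknown = [c for c in header if c not in SUBJECT_COLUMNS]
        missing = [c for c in SUBJECT_COLUMNS if c not in header]
        raise ParseError(
            f"malformed header: unknown columns {unknown}, missing columns {missing}"
        )
    out = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(SUBJECT_COLUMNS):
            raise ParseError(f"row {i}: expected {len(SUBJECT_COLUMNS)} fields, got {len(row)}")
        rec = dict(zip(SUBJECT_COLUMNS, row))
        try:
            group = Group(rec["group"])
        except ValueError as exc:
            raise ParseError(f"row {i}, column 'group': unknown group {rec['group']!r}") from exc
        try:
            sex = Sex(rec["sex"]) if rec["sex"] else Sex.UNKNOWN
        except ValueError as exc:
            raise ParseError(f"row {i}, column 'sex': unknown sex {rec['sex']!r}") from exc
        age = _parse_float(rec["age"], i, "age", minimum=0, strict_min=True)
        education = _parse_float(rec["education"], i, "education", minimum=0)
        if age is None or education is None:
            raise ParseError(f"row {i}: age and education are required")
        clinical = {c: rec[c] for c in _COVARIATE_COLUMNS if rec[c] != ""}
        try:
            subject = Subject(
                id=rec["id"], age=age, education=education, group=group, sex=sex,
                clinical=clinical,
            )
            battery = RawBattery(
                nct_a=_parse_float(rec["nct_a_s"], i, "nct_a_s", 0, True),
                nct_b=_parse_float(rec["nct_b_s"], i, "nct_b_s", 0, True),
                sdt=_parse_float(rec["sdt_s"], i, "sdt_s", 0, True),
                ltt_time=_parse_float(rec["ltt_time_s"], i, "ltt_time_s", 0, True),
                ltt_errors=_parse_float(rec["ltt_errors"], i, "ltt_errors", 0),
                dst=_parse_float(rec["dst_points"], i, "dst_points", 0),
            )
        except ValidationError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        out.append((subject, battery))
    return out


def _audit_header(norms_name: str = "", seed: Optional[int] = None,
                  mhe_rule: Optional[MheRule] = None) -> str:
    parts = [f"phescore version: {__version__}"]
    if norms_name:
        parts.append(f"norms: {norms_name}")
    if seed is not None:
        parts.append(f"seed: {seed}")
    if mhe_rule is not None:
        parts.append(f"mhe_rule: {MheRule(mhe_rule).value}")
    return "".join(f"# {p}\n" for p in parts)


def _fmt(x: object) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)  # full precision, lossless round trip
    return str(x)


def write_subjects(
    sample: Iterable[tuple[Subject, RawBattery]],
    path: Union[str, os.PathLike],
    seed: Optional[int] = None,
    norms_name: str = "",
) -> None:
    """Write a subject/battery CSV in the schema :func:`read_subjects` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_audit_header(norms_name=norms_name, seed=seed))
        writer = csv.writer(fh)
        writer.writerow(SUBJECT_COLUMNS)
        for subject, battery in sample:
            writer.writerow(
                [
                    subject.id,
                    subject.group.value,
                    subject.sex.value,
                    _fmt(subject.age),
                    _fmt(subject.education),
                    _fmt(battery.nct_a),
                    _fmt(battery.nct_b),
                    _fmt(battery.sdt),
                    _fmt(battery.ltt_time),
                    _fmt(battery.ltt_errors),
                    _fmt(battery.dst),
                ]
                + [subject.clinical.get(c, "") for c in _COVARIATE_COLUMNS]
            )


SCORED_COLUMNS = (
    ["id", "group", "sex", "age", "education"]
    + [
        f"{t.value.lower()}_{field}"
        for t in Test
        for field in ("observed", "expected", "deficit_z", "points")
    ]
    + ["phes", "mhe"]
    + list(_COVARIATE_COLUMNS)
)


def write_scored(
    scored: Iterable[tuple[Subject, PhesResult]],
    path: Union[str, os.PathLike],
    norms_name: str = "",
    seed: Optional[int] = None,
    mhe_rule: MheRule = MheRule.STRICT_LESS,
) -> None:
    """Write per-subject component scores, PHES and MHE flags as CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_audit_header(norms_name=norms_name, seed=seed, mhe_rule=mhe_rule))
        writer = csv.writer(fh)
        writer.writerow(SCORED_COLUMNS)
        for subject, result in scored:
            row = [subject.id, subject.group.value, subject.sex.value,
                   _fmt(subject.age), _fmt(subject.education)]
            for t in Test:
                c = result.component(t)
                row += [_fmt(c.observed), _fmt(c.expected), _fmt(c.deficit_z), c.points]
            row += [result.phes, str(bool(result.mhe)).lower()]
            row += [subject.clinical.get(c, "") for c in _COVARIATE_COLUMNS]
            writer.writerow(row)


def read_scored(path: Union[str, os.PathLike, IO[str]]) -> pd.DataFrame:
    """Read a scored CSV into a cohort frame (``mhe`` boolean, NaN = missing)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCORED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"scored file missing columns {missing}")
    df["mhe"] = df["mhe"].map({True: True, False: False, "true": True, "false": False})
    if df["mhe"].isna().any():
        raise ParseError("scored file: column 'mhe' must be true/false")
    return df
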