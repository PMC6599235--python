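"""Plain-text table formats and configuration for the estimation pipelines.

Prevalence tables are comma-separated UTF-8 files with a header
``age,prevalence`` (optionally ``age,prevalence,n``) and the survey's
calendar time in a leading comment line ``# time=<decimal year>``.  Rate
tables (incidence, background mortality m0, general mortality) have a header
``age,rate`` and are interpreted as piecewise-linear, time-constant rates.
Numbers round-trip at 12 significant digits, and identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .rates import TabulatedRate
from .scenario import PrevalenceCrossSection

__all__ = [
    "read_prevalence_table",
    "write_prevalence_table",
    "read_rate_table",
    "write_rate_table",
    "read_yaml_config",
    "write_json_summary",
    "file_sha256",
    "config_hash",
]

_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FMT % x


def _parse_header_comments(lines):
    meta = {}
    body_start = 0
    for k, line in enumerate(lines):
        s = line.strip()
        if s.startswith("#"):
            body_start = k + 1
            s = s.lstrip("#").strip()
            if "=" in s:
                key, _, val = s.partition("=")
                meta[key.strip()] = val.strip()
        elif s == "":
            body_start = k + 1
        else:
            break
    return meta, body_start


def _read_delimited(path, expected_columns):
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    meta, start = _parse_header_comments(lines)
    if start >= len(lines):
        raise ValueError(f"{path}: no header row found")
    header = [c.strip() for c in lines[start].split(",")]
    for col in expected_columns:
        if col not in header:
            raise ValueError(f"{path}: missing required column {col!r} (header {header})")
    rows = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip() or line.strip().startswith("#"):
            continue
        fields = [c.strip() for c in line.split(",")]
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        row = {}
        for col, val in zip(header, fields):
            try:
                row[col] = float(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: column {col!r}: {val!r} is not a number") from exc
        row["__line__"] = lineno
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: table has no data rows")
    return meta, header, rows


def read_prevalence_table(
    path, calendar_time: Optional[float] = None
) -> PrevalenceCrossSection:
    """Read a prevalence cross-section; validates ranges and monotone ages.

    ``calendar_time`` overrides (or substitutes for) the ``# time=`` comment.
    """
    meta, header, rows = _read_delimited(path, ("age", "prevalence"))
    if calendar_time is None:
        if "time" not in meta:
            raise ValueError(f"{path}: no '# time=' header comment and no calendar_time given")
        calendar_time = float(meta["time"])
    ages = np.array([r["age"] for r in rows])
    prev = np.array([r["prevalence"] for r in rows])
    for r in rows:
        if not 0.0 <= r["prevalence"] <= 1.0:
            raise ValueError(
                f"{path}:{r['__line__']}: column 'prevalence': {r['prevalence']} outside [0, 1]"
            )
    if np.any(np.diff(ages) <= 0):
        j = int(np.argmax(np.diff(ages) <= 0))
        raise ValueError(f"{path}:{rows[j + 1]['__line__']}: column 'age': ages must be strictly increasing")
    n = None
    if "n" in header:
        n = np.array([r["n"] for r in rows])
        for r in rows:
            if r["n"] <= 0:
                raise ValueError(f"{path}:{r['__line__']}: column 'n': {r['n']} must be positive")
    return PrevalenceCrossSection(
        calendar_time=calendar_time, ages=ages, prevalence=prev, group_sizes=n
    )


def write_prevalence_table(cs: PrevalenceCrossSection, path) -> None:
    lines = [f"# time={_fmt(cs.calendar_time)}"]
    if cs.group_sizes is not None:
        lines.append("age,prevalence,n")
        for a, p, n in zip(cs.ages, cs.prevalence, cs.group_sizes):
            lines.append(f"{_fmt(a)},{_fmt(p)},{_fmt(n)}")
    else:
        lines.append("age,prevalence")
        for a, p in zip(cs.ages, cs.prevalence):
            lines.append(f"{_fmt(a)},{_fmt(p)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rate_table(path) -> TabulatedRate:
    """Read an ``age,rate`` table as a piecewise-linear time-constant rate."""
    _, _, rows = _read_delimited(path, ("age", "rate"))
    ages = np.array([r["age"] for r in rows])
    rates = np.array([r["rate"] for r in rows])
    for r in rows:
        if r["rate"] < 0:
            raise ValueError(f"{path}:{r['__line__']}: column 'rate': {r['rate']} is negative")
    if np.any(np.diff(ages) <= 0):
        j = int(np.argmax(np.diff(ages) <= 0))
        raise ValueError(f"{path}:{rows[j + 1]['__line__']}: column 'age': ages must be strictly increasing")
    return TabulatedRate(ages, rates)


def write_rate_table(ages, rates, path) -> None:
    ages = np.asarray(ages, dtype=float)
    rates = np.asarray(rates, dtype=float)
    lines = ["age,rate"]
    for a, r in zip(ages, rates):
        lines.append(f"{_fmt(a)},{_fmt(r)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def write_json_summary(summary: dict, path) -> None:
    Path(path).write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
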