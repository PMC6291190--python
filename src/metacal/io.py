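"""Readers and writers for PLUMED-dialect text files and run configuration.

COLVAR/HILLS files are whitespace-delimited numeric tables headed by a line
``#! FIELDS name1 name2 ...``; additional ``#! SET key value`` lines carry
scalar metadata and are preserved on round trips.  All numeric output uses
C-locale ``%.10g`` formatting (10 significant digits), enough to round-trip
through the parsers bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, InvalidParameterError, ParseError
from .metad_reweight import HillsLog

__all__ = [
    "ColvarTable",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "write_tsv",
    "RunConfig",
    "read_config",
]

_FMT = "%.10g"


@dataclass
class ColvarTable:
    """Parsed COLVAR-dialect table: named numeric columns plus SET metadata."""

    data: pd.DataFrame
    set_lines: tuple[str, ...] = ()

    def __post_init__(self):
        if "time" in self.data.columns:
            t = self.data["time"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise InvalidInputError("time column must be non-decreasing")

    @property
    def columns(self):
        return list(self.data.columns)


def read_colvar(path) -> ColvarTable:
    """Read a PLUMED-dialect COLVAR file.

    The first ``#! FIELDS`` line defines the columns; ``#! SET`` lines are
    preserved verbatim; other comment lines are ignored.  Ragged rows or a
    missing header raise :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    names = None
    set_lines = []
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    if len(parts) < 3:
                        raise ParseError("FIELDS header names no columns", lineno)
                    if names is None:
                        names = parts[2:]
                    continue
                if len(parts) >= 2 and parts[1] == "SET":
                    set_lines.append(line)
                    continue
                continue
            if line.startswith("#"):
                continue
            if names is None:
                raise ParseError("data before any '#! FIELDS' header", lineno)
            vals = line.split()
            if len(vals) != len(names):
                raise ParseError(
                    f"row has {len(vals)} values, header defines {len(names)}",
                    lineno,
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"non-numeric value: {exc}", lineno) from None
    if names is None:
        raise ParseError(f"{path}: no '#! FIELDS' header found")
    df = pd.DataFrame(rows, columns=names, dtype=float)
    return ColvarTable(data=df, set_lines=tuple(set_lines))


def write_colvar(table, path, set_lines=None) -> None:
    """Write a DataFrame or :class:`ColvarTable` in COLVAR dialect."""
    if isinstance(table, ColvarTable):
        df = table.data
        set_lines = table.set_lines if set_lines is None else set_lines
    else:
        df = table
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(map(str, df.columns)) + "\n")
        for s in set_lines or ():
            fh.write(s.rstrip("\n") + "\n")
        arr = df.to_numpy(dtype=float)
        for row in arr:
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_hills(path) -> HillsLog:
    """Read a PLUMED-dialect HILLS file into a :class:`HillsLog`.

    Expects columns ``time <cv...> sigma_<cv>... height`` with optional
    ``biasf``; SET lines ``#! SET temperature`` / ``#! SET kB`` /
    ``#! SET period`` override the defaults when present.
    """
    table = read_colvar(path)
    names = table.columns
    if not names or names[0] != "time":
        raise ParseError(f"{path}: HILLS first column must be 'time'")
    sigma_cols = [c for c in names if c.startswith("sigma_")]
    if not sigma_cols or "height" not in names:
        raise ParseError(f"{path}: HILLS needs sigma_* and height columns")
    cv_cols = [c for c in names[1:] if not c.startswith("sigma_")
               and c not in ("height", "biasf")]
    if [f"sigma_{c}" for c in cv_cols] != sigma_cols:
        raise ParseError(f"{path}: sigma columns do not match CV columns")
    df = table.data
    meta = {}
    for line in table.set_lines:
        parts = line.split()
        if len(parts) == 4:
            meta[parts[2]] = float(parts[3])
    gamma = float(df["biasf"].iloc[0]) if "biasf" in df else meta.get("biasf", 12.0)
    return HillsLog(
        times=df["time"].to_numpy(),
        centers=df[cv_cols].to_numpy(),
        sigmas=df[sigma_cols].to_numpy(),
        heights=df["height"].to_numpy(),
        bias_factor=gamma,
        temperature=meta.get("temperature", 300.0),
        period=meta.get("period"),
        cv_names=tuple(cv_cols),
        kB=meta.get("kB", HillsLog.kB),
    )


def write_hills(hills: HillsLog, path) -> None:
    """Write a :class:`HillsLog` in PLUMED HILLS dialect (round-trip safe)."""
    names = hills.cv_names or tuple(f"cv{i}" for i in range(hills.n_cv))
    cols = (["time"] + list(names) + [f"sigma_{c}" for c in names]
            + ["height", "biasf"])
    df = pd.DataFrame(
        np.column_stack([
            hills.times, hills.centers, hills.sigmas, hills.heights,
            np.full(len(hills), hills.bias_factor),
        ]),
        columns=cols,
    )
    set_lines = [
        f"#! SET temperature {_FMT % hills.temperature}",
        f"#! SET kB {_FMT % hills.kB}",
    ]
    if hills.period is not None:
        set_lines.append(f"#! SET period {_FMT % hills.period}")
    write_colvar(df, path, set_lines=set_lines)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Tab-separated output at 10 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


_KNOWN_STAGES = (
    "simulate", "path_find", "cv_eval", "reweight", "fes", "nbit",
    "maxcal", "mfpt",
)
_KNOWN_TOP = _KNOWN_STAGES + ("seed", "out_dir", "temperature", "kB")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Unknown top-level keys are rejected; every stochastic stage inherits the
    top-level seed unless it sets its own.
    """

    seed: int = 0
    out_dir: str = "metacal_run"
    temperature: float = 1.0
    kB: float = 1.0
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_KNOWN_TOP)
        if unknown:
            raise InvalidParameterError(
                f"unknown config keys: {sorted(unknown)}; "
                f"allowed: {sorted(_KNOWN_TOP)}"
            )
        stages = {k: dict(raw[k]) for k in _KNOWN_STAGES if k in raw}
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "metacal_run")),
            temperature=float(raw.get("temperature", 1.0)),
            kB=float(raw.get("kB", 1.0)),
            stages=stages,
        )
        for name, sc in cfg.stages.items():
            sc.setdefault("seed", cfg.seed)
        return cfg

    def stage(self, name: str) -> dict:
        return self.stages.get(name, {})


def read_config(path) -> RunConfig:
    """Load a YAML-compatible run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
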