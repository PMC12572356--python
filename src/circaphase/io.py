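"""File formats: expression TSV, sample tables, model JSON, metrics TSV.

Schemas
-------
ExpressionMatrix TSV: header row of sample ids, first column feature ids,
tab-separated reals; no duplicates, no missing cells. SampleTable TSV:
columns ``sample_id  participant_id  condition  phase_hours`` — phases are
stored in hours relative to DLMO and converted to radians on load
(``phase_rad`` column). Model files are JSON; write/read round-trips give
bit-identical predictions. Numeric values are written with 17 significant
digits so round-trips preserve them exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import hours_to_radians
from .exceptions import SchemaError
from .models import model_from_dict
from .zeitzeiger import ZeitZeigerPhaseRegressor

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "save_model",
    "load_model",
    "write_metrics",
    "read_metrics",
    "RunManifest",
    "file_sha256",
]

_FLOAT_FMT = "%.17g"


def _check_rectangular(path: Path, expected_fields: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            n = line.rstrip("\n").count("\t") + 1
            if n != expected_fields:
                raise SchemaError(
                    f"{path}: expected {expected_fields} fields, found {n}",
                    line=lineno,
                )


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a features x samples TSV; validates ids and numeric cells."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise SchemaError(f"{path}: header must name at least one sample",
                          line=1)
    _check_rectangular(path, len(header))
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise SchemaError(f"{path}: duplicate sample id {dup!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric cell ({exc})") from exc
    if df.isna().to_numpy().any():
        raise SchemaError(f"{path}: missing values are not supported")
    df.index.name = "feature_id"
    return df


def write_expression_matrix(matrix: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


_TABLE_COLUMNS = ["sample_id", "participant_id", "condition", "phase_hours"]


def read_sample_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}", line=1)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample id {dup!r}")
    phases = pd.to_numeric(df["phase_hours"], errors="coerce")
    if phases.isna().any():
        bad = int(np.flatnonzero(phases.isna())[0]) + 2  # header + 1-based
        raise SchemaError(f"{path}: non-finite phase", line=bad)
    df["phase_hours"] = phases
    df["phase_rad"] = hours_to_radians(phases.to_numpy())
    return df


def write_sample_table(table: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[_TABLE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def save_model(model, path):
    """Serialize any fitted phase predictor to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d.get("method") == "zeitzeiger":
        est = ZeitZeigerPhaseRegressor(**d.get("config", {}))
        return est._restore(d)
    return model_from_dict(d)


def write_metrics(records: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every output set."""

    command: str
    seed: int
    config: dict
    package_version: str
    input_hashes: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def write(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))
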