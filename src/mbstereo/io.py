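"""Reading response tables and writing experiment results.

Response tables are delimited text: a header row of odor labels, a first
column of individual labels, numeric cells (trial-averaged responses).
Experiment outputs go to a directory as a per-iteration CSV, an aggregate
JSON (seed, package version, fully resolved configuration included) and a
manifest listing every file with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ResponseTable

__all__ = ["load_response_table", "write_response_table", "write_results"]

# 10 significant digits: enough to make byte-identical reruns meaningful
# without bloating the files.
_CSV_FLOAT_FORMAT = "%.10g"


def load_response_table(path, delimiter: str = ",") -> ResponseTable:
    """Load and validate an individuals x odors response table from CSV."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate odor labels {dupes}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least 2 individuals (rows) and 2 odors "
            f"(columns), got {df.shape[0]} x {df.shape[1]}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate individual labels {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate odor labels {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric cell at individual "
            f"{df.index[row]!r}, odor {df.columns[col]!r}")
    return ResponseTable(numeric.to_numpy(dtype=float),
                         individuals=numeric.index, odors=numeric.columns)


def write_response_table(table: ResponseTable, path) -> None:
    table.to_dataframe().to_csv(path, float_format=_CSV_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(output_dir, report=None, tables: dict | None = None,
                  config: dict | None = None, seed=None) -> dict:
    """Write a report and/or named tables to ``output_dir``.

    ``report`` is a :class:`~mbstereo.experiments.StereotypyReport`;
    ``tables`` maps names to DataFrames (sweep/grid tables, metric
    results).  Returns the manifest (also written as manifest.json).
    """
    from . import __version__

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_csv(name, df):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=_CSV_FLOAT_FORMAT)
        written.append(p)

    aggregates = {"package_version": __version__}
    if seed is not None:
        aggregates["seed"] = seed
    if config is not None:
        aggregates["config"] = config
    if report is not None:
        _write_csv("per_iteration", report.per_iteration)
        _write_csv("auxiliaries", report.auxiliaries)
        if report.kc_pool is not None:
            _write_csv("kc_pool", report.kc_pool)
        aggregates["experiment"] = report.meta
        aggregates["aggregates"] = report.aggregates.to_dict(orient="records")
        if report.params is not None:
            aggregates["network"] = report.params.to_dict()
        if seed is None and "seed" in report.meta:
            aggregates["seed"] = report.meta["seed"]
    for name, df in (tables or {}).items():
        _write_csv(name, df)
    agg_path = outdir / "aggregates.json"
    with open(agg_path, "w") as fh:
        json.dump(aggregates, fh, indent=2, default=_json_default)
    written.append(agg_path)
    manifest = {"files": [{"name": p.name, "sha256": _sha256(p)}
                          for p in sorted(written)]}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
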