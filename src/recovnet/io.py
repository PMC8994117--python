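"""Plain-text readers and writers.

All tabular formats are TSV; node sets are JSON. Floating-point values
are written with 17 significant digits so every matrix and time series
round-trips bit-exactly through write -> read. Malformed inputs raise
:class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import NetworkDefinition, SubjectTimeSeries
from .connectivity import _network_from_dict

__all__ = [
    "ParseError",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_motion_tsv",
    "read_motion_tsv",
    "write_nodeset_json",
    "read_nodeset_json",
    "write_scores_tsv",
    "read_scores_tsv",
    "load_table2",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edgelist_tsv",
]

_FLOAT_FMT = "%.17g"

MOTION_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz")
SCORE_COLUMNS = ("subject", "timepoint", "ss", "com", "rep", "nam", "aq")


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _read_table(path, expected_cols: int | None = None) -> tuple[list[str], list[list[str]]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    header = lines[0].split("\t")
    width = expected_cols if expected_cols is not None else len(header)
    if len(header) != width:
        raise ParseError(path, 1, f"expected {width} columns, found {len(header)}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(path, i,
                             f"ragged row: {len(cells)} cells, expected {len(header)}")
        rows.append(cells)
    return header, rows


def write_timeseries_tsv(ts: SubjectTimeSeries, path) -> None:
    """Header row = node ids; one row per volume."""
    with open(path, "w") as fh:
        fh.write("\t".join(ts.node_ids) + "\n")
        for row in ts.data:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_timeseries_tsv(path, tr: float, motion: np.ndarray | None = None,
                        subject_id: str = "", timepoint: str | None = None,
                        wm: np.ndarray | None = None,
                        csf: np.ndarray | None = None) -> SubjectTimeSeries:
    header, rows = _read_table(path)
    try:
        data = np.array([[float(c) for c in row] for row in rows])
    except ValueError as exc:
        for i, row in enumerate(rows, start=2):
            try:
                [float(c) for c in row]
            except ValueError:
                raise ParseError(path, i, f"non-numeric cell: {exc}") from None
        raise
    return SubjectTimeSeries(data=data, node_ids=header, tr=tr, motion=motion,
                             wm=wm, csf=csf, subject_id=subject_id,
                             timepoint=timepoint)


def write_motion_tsv(motion: np.ndarray, path) -> None:
    """6-column trace: tx, ty, tz (mm), rx, ry, rz (radians)."""
    motion = np.asarray(motion, dtype=float)
    with open(path, "w") as fh:
        fh.write("\t".join(MOTION_COLUMNS) + "\n")
        for row in motion:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_motion_tsv(path) -> np.ndarray:
    header, rows = _read_table(path, expected_cols=6)
    if tuple(header) != MOTION_COLUMNS:
        raise ParseError(path, 1, f"expected header {MOTION_COLUMNS}, got {tuple(header)}")
    return np.array([[float(c) for c in row] for row in rows])


def write_nodeset_json(network: NetworkDefinition, path) -> None:
    payload = {"name": network.name,
               "nodes": [{"id": n.id, "hemisphere": n.hemisphere, "region": n.region,
                          **({"mni": list(n.mni)} if n.mni else {})}
                         for n in network.nodes]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_nodeset_json(path) -> NetworkDefinition:
    payload = json.loads(Path(path).read_text())
    try:
        return _network_from_dict(payload)
    except (KeyError, ValueError) as exc:
        raise ParseError(path, 1, str(exc)) from exc


def write_scores_tsv(records, path) -> None:
    """Long-format language scores: subject, timepoint, ss, com, rep, nam, aq."""
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for rec in records:
            cells = [rec.subject, rec.timepoint]
            for attr in ("ss", "com", "rep", "nam", "aq"):
                v = getattr(rec, attr)
                cells.append("" if v is None else _fmt(v))
            fh.write("\t".join(cells) + "\n")


def read_scores_tsv(path):
    from .datatypes import LanguageRecord

    header, rows = _read_table(path)
    if tuple(header) != SCORE_COLUMNS:
        raise ParseError(path, 1, f"expected header {SCORE_COLUMNS}, got {tuple(header)}")
    records = []
    for i, row in enumerate(rows, start=2):
        try:
            vals = [float(c) if c else None for c in row[2:]]
            records.append(LanguageRecord(subject=row[0], timepoint=row[1],
                                          ss=vals[0], com=vals[1], rep=vals[2],
                                          nam=vals[3], aq=vals[4]))
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from exc
    return records


def load_table2(path=None) -> pd.DataFrame:
    """The packaged per-patient AQ trajectory table (or a user file like it).

    Columns: subject, group, sex, age, education, grade, location,
    resection, aq_pre, aq_w2, aq_m1, aq_m3, aq_m6.
    """
    if path is None:
        ref = resources.files("recovnet.data").joinpath("table2.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"subject", "aq_pre"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path or "table2.tsv", 1, f"missing columns: {sorted(missing)}")
    return df


def write_matrix_tsv(node_ids: Sequence[str], matrix: np.ndarray, path) -> None:
    """Square matrix with a node-id header row and index column."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(node_ids) + "\n")
        for nid, row in zip(node_ids, matrix):
            fh.write(nid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    header, rows = _read_table(path)
    node_ids = header[1:]
    if len(rows) != len(node_ids):
        raise ParseError(path, len(rows) + 1,
                         f"{len(rows)} rows for {len(node_ids)} nodes")
    mat = np.empty((len(node_ids), len(node_ids)))
    for i, row in enumerate(rows):
        if row[0] != node_ids[i]:
            raise ParseError(path, i + 2,
                             f"row label {row[0]!r} != header label {node_ids[i]!r}")
        mat[i] = [float(c) for c in row[1:]]
    return node_ids, mat


def write_edgelist_tsv(edges: pd.DataFrame, path) -> None:
    """Long-format edge list (node_a, node_b, r, z, weight, class, bin)."""
    edges.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
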