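"""A minimal BiblioSpec-compatible spectral-library dialect.

A ``.blib`` library is a single SQLite file. This module reads and writes a
deliberately small, version-agnostic subset of the schema — enough to carry
peptide identities, precursor m/z, per-run retention-time boundaries and
transition lists, so that imputed boundaries can be written back into a
library and picked up by downstream quantitation. The exact tables and
columns are documented in ``FORMAT.md`` at the repository root.

Boundary provenance (observed vs imputed) is kept in an auxiliary
``BoundaryProvenance`` table rather than overloading standard columns, so
tools unaware of it still read the library.
"""

from __future__ import annotations

import logging
import re
import shutil
import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .chrom import Transition, TransitionTable
from .errors import FormatError, ValidationError
from .matrices import (
    PROV_MISSING,
    PROV_OBSERVED,
    PrecursorKey,
    RTBoundaryMatrix,
    key_index,
)

__all__ = ["read_blib", "write_blib"]

logger = logging.getLogger(__name__)

_SCHEMA = """
CREATE TABLE LibInfo (
    libLSID TEXT, createTime TEXT, numSpecs INTEGER,
    majorVersion INTEGER, minorVersion INTEGER
);
CREATE TABLE SpectrumSourceFiles (
    id INTEGER PRIMARY KEY, fileName TEXT NOT NULL
);
CREATE TABLE RefSpectra (
    id INTEGER PRIMARY KEY,
    peptideSeq TEXT NOT NULL,
    peptideModSeq TEXT NOT NULL,
    precursorCharge INTEGER NOT NULL,
    precursorMZ REAL,
    retentionTime REAL,
    startTime REAL,
    endTime REAL,
    fileID INTEGER NOT NULL REFERENCES SpectrumSourceFiles(id)
);
CREATE TABLE TransitionList (
    id INTEGER PRIMARY KEY,
    peptideModSeq TEXT NOT NULL,
    precursorCharge INTEGER NOT NULL,
    precursorMZ REAL NOT NULL,
    productMZ REAL NOT NULL,
    label TEXT
);
CREATE TABLE BoundaryProvenance (
    peptideModSeq TEXT NOT NULL,
    precursorCharge INTEGER NOT NULL,
    fileName TEXT NOT NULL,
    provenance TEXT NOT NULL
);
"""

_REQUIRED = {
    "SpectrumSourceFiles": {"id", "fileName"},
    "RefSpectra": {
        "peptideSeq", "peptideModSeq", "precursorCharge", "precursorMZ",
        "retentionTime", "startTime", "endTime", "fileID",
    },
}


def _strip_mods(modseq: str) -> str:
    return re.sub(r"\[[^\]]*\]", "", modseq)


def _run_id(file_name: str) -> str:
    return Path(file_name).stem


def _check_schema(con: sqlite3.Connection) -> None:
    tables = {
        r[0] for r in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
    }
    for table, cols in _REQUIRED.items():
        if table not in tables:
            raise FormatError(f"library is missing required table {table!r}")
        have = {r[1] for r in con.execute(f"PRAGMA table_info({table})")}
        missing = cols - have
        if missing:
            raise FormatError(
                f"table {table!r} is missing columns {sorted(missing)}"
            )


def read_blib(path: str | Path) -> tuple[RTBoundaryMatrix, TransitionTable]:
    """Read a library into an RT-boundary matrix and a transition table.

    Each record carrying both a start and an end time yields a present cell;
    records lacking either contribute a missing cell for that
    (precursor, run). Run identifiers are source file basenames without
    extension.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such library: {path}")
    con = sqlite3.connect(path)
    try:
        _check_schema(con)
        files = con.execute(
            "SELECT id, fileName FROM SpectrumSourceFiles ORDER BY id"
        ).fetchall()
        runs_by_id = {fid: _run_id(name) for fid, name in files}
        records = con.execute(
            "SELECT peptideModSeq, precursorCharge, startTime, endTime, fileID "
            "FROM RefSpectra ORDER BY id"
        ).fetchall()
        if not records:
            logger.warning("library %s contains zero records", path)
        keys: list[PrecursorKey] = []
        seen: set[PrecursorKey] = set()
        for modseq, z, *_ in records:
            k = PrecursorKey(modseq, int(z))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        run_ids = [runs_by_id[fid] for fid, _ in files]
        idx = key_index(keys)
        starts = pd.DataFrame(np.nan, index=idx, columns=run_ids)
        ends = pd.DataFrame(np.nan, index=idx, columns=run_ids)
        for modseq, z, st, en, fid in records:
            if fid not in runs_by_id:
                raise FormatError(f"record references unknown fileID {fid}")
            if st is None or en is None:
                continue
            key = (modseq, int(z))
            starts.at[key, runs_by_id[fid]] = float(st)
            ends.at[key, runs_by_id[fid]] = float(en)
        prov = None
        tables = {
            r[0]
            for r in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        if "BoundaryProvenance" in tables:
            prov = pd.DataFrame(PROV_MISSING, index=idx, columns=run_ids, dtype=object)
            prov[starts.notna()] = PROV_OBSERVED
            for modseq, z, fname, code in con.execute(
                "SELECT peptideModSeq, precursorCharge, fileName, provenance "
                "FROM BoundaryProvenance"
            ):
                key = (modseq, int(z))
                if key in starts.index and _run_id(fname) in run_ids:
                    prov.at[key, _run_id(fname)] = code
        transitions: list[Transition] = []
        if "TransitionList" in tables:
            for modseq, z, pmz, prodmz, label in con.execute(
                "SELECT peptideModSeq, precursorCharge, precursorMZ, productMZ, "
                "COALESCE(label, '') FROM TransitionList ORDER BY id"
            ):
                transitions.append(
                    Transition(
                        precursor=PrecursorKey(modseq, int(z)),
                        precursor_mz=float(pmz),
                        product_mz=float(prodmz),
                        label=label,
                    )
                )
        matrix = RTBoundaryMatrix(starts, ends, prov)
        return matrix, TransitionTable(transitions)
    finally:
        con.close()


def write_blib(
    matrix: RTBoundaryMatrix,
    transitions: TransitionTable,
    out: str | Path,
    template: str | Path | None = None,
) -> None:
    """Write a matrix (and its transitions) to a library file.

    Without a template, a fresh library is created: one record per matrix
    cell, boundary times NULL on missing cells so that reading the library
    back reproduces the matrix including its missingness pattern. With a
    template, the template is copied and only start/end times are replaced
    (records are inserted for cells the template lacks); all other fields of
    untouched records remain byte-identical.
    """
    for p in matrix.precursors:
        if p not in transitions:
            raise ValidationError(f"matrix row {p} has no transitions")
    out = Path(out)
    if template is not None:
        shutil.copyfile(template, out)
        con = sqlite3.connect(out)
        try:
            _check_schema(con)
            _update_boundaries(con, matrix, transitions)
            con.commit()
        finally:
            con.close()
        return
    if out.exists():
        out.unlink()
    con = sqlite3.connect(out)
    try:
        con.executescript(_SCHEMA)
        file_ids = {}
        for i, run in enumerate(matrix.runs, start=1):
            con.execute(
                "INSERT INTO SpectrumSourceFiles (id, fileName) VALUES (?, ?)",
                (i, f"{run}.mzML"),
            )
            file_ids[run] = i
        mz_by_key = {
            p: transitions.transitions_for(p)[0].precursor_mz
            for p in matrix.precursors
        }
        n = 0
        for p in matrix.precursors:
            for run in matrix.runs:
                st = matrix.starts.at[tuple(p), run]
                en = matrix.ends.at[tuple(p), run]
                present = not pd.isna(st)
                con.execute(
                    "INSERT INTO RefSpectra (peptideSeq, peptideModSeq, "
                    "precursorCharge, precursorMZ, retentionTime, startTime, "
                    "endTime, fileID) VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    (
                        _strip_mods(p.sequence),
                        p.sequence,
                        p.charge,
                        mz_by_key[p],
                        (float(st) + float(en)) / 2.0 if present else None,
                        float(st) if present else None,
                        float(en) if present else None,
                        file_ids[run],
                    ),
                )
                n += 1
                code = matrix.provenance.at[tuple(p), run]
                if code not in (PROV_OBSERVED, PROV_MISSING):
                    con.execute(
                        "INSERT INTO BoundaryProvenance VALUES (?, ?, ?, ?)",
                        (p.sequence, p.charge, f"{run}.mzML", code),
                    )
        for t in transitions:
            if t.precursor in set(matrix.precursors):
                con.execute(
                    "INSERT INTO TransitionList (peptideModSeq, precursorCharge, "
                    "precursorMZ, productMZ, label) VALUES (?, ?, ?, ?, ?)",
                    (t.precursor.sequence, t.precursor.charge, t.precursor_mz,
                     t.product_mz, t.label),
                )
        con.execute(
            "INSERT INTO LibInfo VALUES (?, datetime('now'), ?, 1, 1)",
            ("urn:lsid:rtimpute:spectral_library", n),
        )
        con.commit()
    finally:
        con.close()


def _update_boundaries(
    con: sqlite3.Connection, matrix: RTBoundaryMatrix, transitions: TransitionTable
) -> None:
    files = con.execute("SELECT id, fileName FROM SpectrumSourceFiles").fetchall()
    id_by_run = {_run_id(name): fid for fid, name in files}
    name_by_run = {_run_id(name): name for fid, name in files}
    next_fid = max((fid for fid, _ in files), default=0) + 1
    tables = {
        r[0] for r in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
    }
    if "BoundaryProvenance" not in tables:
        con.execute(
            "CREATE TABLE BoundaryProvenance (peptideModSeq TEXT, "
            "precursorCharge INTEGER, fileName TEXT, provenance TEXT)"
        )
    for p in matrix.precursors:
        for run in matrix.runs:
            st = matrix.starts.at[tuple(p), run]
            en = matrix.ends.at[tuple(p), run]
            if pd.isna(st):
                continue
            if run not in id_by_run:
                con.execute(
                    "INSERT INTO SpectrumSourceFiles (id, fileName) VALUES (?, ?)",
                    (next_fid, f"{run}.mzML"),
                )
                id_by_run[run] = next_fid
                name_by_run[run] = f"{run}.mzML"
                next_fid += 1
            fid = id_by_run[run]
            cur = con.execute(
                "UPDATE RefSpectra SET startTime = ?, endTime = ? "
                "WHERE peptideModSeq = ? AND precursorCharge = ? AND fileID = ?",
                (float(st), float(en), p.sequence, p.charge, fid),
            )
            if cur.rowcount == 0:
                mz = transitions.transitions_for(p)[0].precursor_mz
                con.execute(
                    "INSERT INTO RefSpectra (peptideSeq, peptideModSeq, "
                    "precursorCharge, precursorMZ, retentionTime, startTime, "
                    "endTime, fileID) VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    (_strip_mods(p.sequence), p.sequence, p.charge, mz,
                     (float(st) + float(en)) / 2.0, float(st), float(en), fid),
                )
            code = matrix.provenance.at[tuple(p), run]
            if code not in (PROV_OBSERVED, PROV_MISSING):
                con.execute(
                    "DELETE FROM BoundaryProvenance WHERE peptideModSeq = ? "
                    "AND precursorCharge = ? AND fileName = ?",
                    (p.sequence, p.charge, name_by_run[run]),
                )
                con.execute(
                    "INSERT INTO BoundaryProvenance VALUES (?, ?, ?, ?)",
                    (p.sequence, p.charge, name_by_run[run], code),
                )
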