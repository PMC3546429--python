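"""Delimited-text matrix I/O and run outputs.

Matrices travel as TSV/CSV: header row = column names (first header field
may be blank), first field of each data row = row name.  Missing or blank
names are replaced by the 1-based index of the dimension, matching the
automatic ``dimnames`` assignment of the R original.  A file whose first
row is entirely numeric is treated as a bare numeric table and both axes
get automatic names.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .decomposition import CURResult
from .matrix import DataMatrix


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return "\t"


def _fill_names(raw: list[str], what: str) -> list[str]:
    names = [tok.strip() if tok.strip() else str(i + 1) for i, tok in enumerate(raw)]
    seen: dict[str, int] = {}
    for i, n in enumerate(names):
        if n in seen:
            raise ValueError(
                f"duplicate {what} name {n!r} (positions {seen[n] + 1} and {i + 1})"
            )
        seen[n] = i
    return names


def read_matrix(path, delimiter: str = "auto") -> DataMatrix:
    """Read a named numeric matrix from delimited text.

    ``delimiter`` is ``"auto"`` (sniffed from the first line), ``"tab"``
    or ``"comma"``.  Ragged rows, non-numeric cells and duplicate names
    raise ``ValueError`` with the offending location.
    """
    path = Path(path)
    text = path.read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = {"auto": _sniff_delimiter(lines[0]), "tab": "\t", "comma": ","}.get(delimiter)
    if delim is None:
        raise ValueError(f"delimiter must be 'auto', 'tab' or 'comma', got {delimiter!r}")
    rows = list(csv.reader(lines, delimiter=delim))

    first = [tok.strip() for tok in rows[0]]
    # a blank leading field marks the header corner over the row names;
    # an entirely numeric first row means a bare table with no names at all
    bare_numeric = first[0] != "" and all(_is_number(tok) for tok in first)
    if bare_numeric:
        header = None
        data_rows = rows
        n = len(first)
        col_names = [str(j + 1) for j in range(n)]
        has_row_names = False
    else:
        header = first
        data_rows = rows[1:]
        if not data_rows:
            raise ValueError(f"{path}: header but no data rows")
        n = len(data_rows[0]) - 1
        # header may or may not carry the blank corner field over row names
        raw_cols = header[1:] if len(header) == n + 1 else header
        if len(raw_cols) != n:
            raise ValueError(
                f"{path}: header has {len(header)} fields but data rows have {n} values"
            )
        col_names = _fill_names(raw_cols, "column")
        has_row_names = True

    values = []
    row_names_raw = []
    width = len(data_rows[0])
    for i, row in enumerate(data_rows):
        lineno = i + (2 if header is not None else 1)
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
        toks = [t.strip() for t in row]
        if has_row_names:
            row_names_raw.append(toks[0])
            toks = toks[1:]
        else:
            row_names_raw.append("")
        vals = []
        for j, t in enumerate(toks):
            if not _is_number(t):
                raise ValueError(
                    f"{path}: non-numeric value {t!r} at line {lineno}, "
                    f"column {j + 1 + int(has_row_names)}"
                )
            vals.append(float(t))
        values.append(vals)
    row_names = _fill_names(row_names_raw, "row")
    return DataMatrix(np.array(values, dtype=float), row_names, col_names)


def write_matrix(dm: DataMatrix, path, delimiter: str = "\t") -> None:
    """Write a DataMatrix as delimited text (blank corner + column names
    header, row names in the first field)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow([""] + list(dm.col_names))
        for name, row in zip(dm.row_names, dm.values):
            w.writerow([name] + [f"{v:.12g}" for v in row])


def read_labels(path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column sample→group table; returns an ordered mapping."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 2 fields at line {lineno}")
        name, group = (p.strip() for p in parts)
        if name in labels:
            raise ValueError(f"{path}: duplicate sample {name!r} at line {lineno}")
        labels[name] = group
    if not labels:
        raise ValueError(f"{path}: no label rows")
    return labels


def write_outputs(result: CURResult, prefix) -> list[Path]:
    """Write the decomposition: C/U/R matrices, a per-feature scores table
    (name, axis, leverage, selected flag; 1-based positions) and a JSON
    run summary carrying enough to reproduce the run exactly."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_matrix(dm: DataMatrix, tag: str) -> None:
        p = prefix.parent / f"{prefix.name}_{tag}.tsv"
        write_matrix(dm, p)
        written.append(p)

    emit_matrix(result.C, "C")
    u_rows = list(result.C.col_names)
    if result.restricted:
        u_cols = [str(i + 1) for i in range(result.U.shape[1])]
    else:
        u_cols = list(result.R.row_names)
        emit_matrix(result.R, "R")
    emit_matrix(DataMatrix(result.U, u_rows, u_cols), "U")

    lev = result.leverage
    scores_path = prefix.parent / f"{prefix.name}_scores.tsv"
    with scores_path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "axis", "position", "leverage", "selected"])
        sel_rows = (set(result.row_selection.indices.tolist())
                    if result.row_selection is not None else set())
        sel_cols = set(result.column_selection.indices.tolist())
        if lev is not None:
            for i, name in enumerate(lev.row_names):
                w.writerow([name, "rows", i + 1, f"{lev.row_scores[i]:.12g}",
                            int(i in sel_rows)])
            for j, name in enumerate(lev.col_names):
                w.writerow([name, "columns", j + 1, f"{lev.column_scores[j]:.12g}",
                            int(j in sel_cols)])
    written.append(scores_path)

    summary = {
        "k": result.k,
        "c": int(result.column_selection.indices.size),
        "r": ("all" if result.restricted
              else int(result.row_selection.indices.size)),
        "method": result.column_selection.method,
        "seed": result.seed,
        "restricted": result.restricted,
        "relative_error": result.relative_error,
        "selected_columns": [int(i) + 1 for i in result.column_selection.indices],
        "selected_rows": (None if result.restricted
                          else [int(i) + 1 for i in result.row_selection.indices]),
    }
    summary_path = prefix.parent / f"{prefix.name}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    written.append(summary_path)
    return written
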