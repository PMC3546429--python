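"""Named dense matrix container.

Every operation in the package consumes or produces a :class:`DataMatrix`:
an ``m × n`` dense real matrix with unique, non-empty row and column names.
Names default to 1-based indices rendered as strings, mirroring how R
assigns ``dimnames`` when none are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def auto_names(count: int) -> list[str]:
    """1-based index names: "1", "2", ..., str(count)."""
    return [str(i + 1) for i in range(count)]


def _check_names(names: list[str], expected: int, what: str) -> list[str]:
    if len(names) != expected:
        raise ValueError(f"{what}: expected {expected} names, got {len(names)}")
    if any(not str(n) for n in names):
        raise ValueError(f"{what}: names must be non-empty strings")
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
        raise ValueError(f"{what}: duplicate name {dup!r}")
    return [str(n) for n in names]


@dataclass
class DataMatrix:
    """Dense real matrix with row/column names.

    Parameters
    ----------
    values
        ``m × n`` array-like of finite reals.
    row_names, col_names
        Unique non-empty labels; ``None`` assigns 1-based index strings.
    """

    values: np.ndarray
    row_names: list[str] = field(default=None)  # type: ignore[assignment]
    col_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be two-dimensional")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one row and one column")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite entry at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        self.row_names = (
            auto_names(m) if self.row_names is None
            else _check_names(list(self.row_names), m, "row_names")
        )
        self.col_names = (
            auto_names(n) if self.col_names is None
            else _check_names(list(self.col_names), n, "col_names")
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def transpose(self) -> "DataMatrix":
        return DataMatrix(self.values.T.copy(), list(self.col_names), list(self.row_names))

    def take_rows(self, indices) -> "DataMatrix":
        idx = np.asarray(indices, dtype=int)
        return DataMatrix(
            self.values[idx, :].copy(),
            [self.row_names[i] for i in idx],
            list(self.col_names),
        )

    def take_cols(self, indices) -> "DataMatrix":
        idx = np.asarray(indices, dtype=int)
        return DataMatrix(
            self.values[:, idx].copy(),
            list(self.row_names),
            [self.col_names[i] for i in idx],
        )


def as_data_matrix(A) -> DataMatrix:
    """Coerce an array-like (or pass through a DataMatrix) with auto names."""
    if isinstance(A, DataMatrix):
        return A
    return DataMatrix(np.asarray(A, dtype=float))
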