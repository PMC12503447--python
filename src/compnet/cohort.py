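"""Patient-level cohort matrix and its delimited-text (CSV/TSV) round trip.

A cohort is an N x V matrix of 0/1 indicators, one row per patient, one
column per catalog variable. Ingestion is strict: every cell must parse as a
binary value — patients with missing complication information are rejected,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import VariableCatalog
from .errors import FormatError, ValidationError

__all__ = ["CohortMatrix", "read_cohort", "write_cohort", "filter_any_complication"]

_TRUTHY = {"1", "true"}
_FALSY = {"0", "false"}


@dataclass(frozen=True)
class CohortMatrix:
    """Validated N x V binary matrix with named columns.

    ``values`` is a ``uint8`` array; every entry is exactly 0 or 1 and the
    column count equals the catalog size. N >= 1 always holds.
    """

    catalog: VariableCatalog
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValidationError("cohort values must be a 2-D array")
        if arr.shape[0] < 1:
            raise ValidationError("cohort must contain at least one patient")
        if arr.shape[1] != self.catalog.size:
            raise ValidationError(
                f"cohort has {arr.shape[1]} columns but catalog names "
                f"{self.catalog.size} variables"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("cohort entries must all be 0 or 1")
        object.__setattr__(self, "values", arr.astype(np.uint8, copy=False))

    @property
    def n_patients(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_variables(self) -> int:
        return int(self.values.shape[1])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.catalog.index(name)]

    def complication_columns(self) -> np.ndarray:
        """The matrix restricted to non-outcome variables (catalog order)."""
        idx = [self.catalog.index(n) for n in self.catalog.complications]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.catalog.names))


def _parse_cell(raw: object, row: int, col: str) -> int:
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return 1
    if text in _FALSY:
        return 0
    raise ValidationError(
        f"non-binary cell {raw!r} at data row {row}, column {col!r} "
        "(expected 0/1 or true/false)"
    )


def read_cohort(
    path: str | Path,
    delimiter: str = ",",
    outcome: str = "death",
) -> CohortMatrix:
    """Read a delimited text file (header row + 0/1 body) into a cohort.

    Accepts ``0``/``1`` and case-insensitive ``true``/``false`` cells.
    Row order is preserved. Raises :class:`FormatError` for structural
    problems (missing/duplicate headers, fewer than 2 columns) and
    :class:`ValidationError` for non-binary or empty cells, naming the
    offending 1-based data row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort file not found: {path}")
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\r\n")
    header = [h.strip() for h in header_line.split(delimiter)]
    if len(header) < 2:
        raise FormatError(
            f"cohort file must have at least 2 columns, found {len(header)}"
        )
    if any(h == "" for h in header):
        raise FormatError("cohort header contains an empty column name")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate column names in header: {dupes}")

    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skiprows=1,
        header=None, names=header,
    )
    if raw.shape[0] < 1:
        raise ValidationError("cohort file contains a header but no patients")

    values = np.empty(raw.shape, dtype=np.uint8)
    for j, col in enumerate(header):
        cells = raw[col].to_numpy()
        lowered = np.char.lower(np.char.strip(cells.astype(str)))
        ones = np.isin(lowered, list(_TRUTHY))
        zeros = np.isin(lowered, list(_FALSY))
        bad = ~(ones | zeros)
        if bad.any():
            i = int(np.argmax(bad))
            _parse_cell(cells[i], i + 1, col)  # raises with coordinates
        values[:, j] = ones

    catalog = VariableCatalog(names=tuple(header), outcome=outcome)
    return CohortMatrix(catalog=catalog, values=values)


def write_cohort(
    cohort: CohortMatrix, path: str | Path, delimiter: str = ","
) -> Path:
    """Write header + N rows of 0/1; exact inverse of :func:`read_cohort`."""
    path = Path(path)
    try:
        frame = cohort.to_frame()
        frame.to_csv(path, sep=delimiter, index=False)
    except OSError as exc:
        raise FormatError(f"cannot write cohort to {path}: {exc}") from exc
    return path


def filter_any_complication(cohort: CohortMatrix) -> CohortMatrix:
    """Retain patients with at least one complication (outcome excluded).

    The outcome column does not count: a patient who died without any
    recorded complication is dropped. Raises :class:`ValidationError` if no
    patient qualifies. Idempotent.
    """
    mask = cohort.complication_columns().sum(axis=1) >= 1
    if not mask.any():
        raise ValidationError("no patients with complications after filtering")
    return CohortMatrix(catalog=cohort.catalog, values=cohort.values[mask])
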