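"""Subject-level biochemistry tables: a thin typed wrapper around pandas I/O.

A :class:`BiomarkerTable` is a subjects x variables matrix of real
measurements in which any cell may be missing.  Subject identifiers are
opaque strings (never positional integers) so that subject-set operations in
the search modules survive row filtering and reordering.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-value codes recognised on load; clinical tables in this field use
#: all of these interchangeably.
DEFAULT_MISSING_CODES = ("", "NA", "ND", "n.d.")

_DELIMS = (",", "\t", ";")


@dataclass
class BiomarkerTable:
    """Per-subject measurement matrix with missing-value semantics.

    Parameters
    ----------
    subject_ids
        Unique opaque identifiers, one per row.
    variables
        Unique variable names (may carry unit strings, e.g.
        ``"CoQ [nmol/g protein]"``).
    values
        ``(n_subjects, n_variables)`` float array; missing cells are NaN.
    """

    subject_ids: list[str]
    variables: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.variables = [str(v) for v in self.variables]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"row count {n} does not match {len(self.subject_ids)} subject ids"
            )
        if m != len(self.variables):
            raise ValueError(
                f"column count {m} does not match {len(self.variables)} variables"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("non-finite (infinite) measurement values")
            if np.nanmin(self.values, initial=0.0) < 0:
                warnings.warn(
                    "negative measurement values present; concentrations and "
                    "activities are physically non-negative",
                    UserWarning,
                    stacklevel=2,
                )

    # -- convenience ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, name: str) -> np.ndarray:
        """Return one variable's values (NaN where missing)."""
        try:
            j = self.variables.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}; have {self.variables}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.variables)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BiomarkerTable":
        return cls(
            subject_ids=[str(i) for i in df.index],
            variables=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BiomarkerTable):
            return NotImplemented
        if self.subject_ids != other.subject_ids or self.variables != other.variables:
            return False
        a, b = self.values, other.values
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="".join(_DELIMS)).delimiter
    except csv.Error:
        return ","


def read_table(
    path,
    *,
    delimiter: str | None = None,
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
    id_column: str | int = 0,
    column_map: dict[str, str] | None = None,
    comma_decimal: bool = False,
) -> BiomarkerTable:
    """Read a delimited text file into a :class:`BiomarkerTable`.

    Parameters
    ----------
    path
        CSV/TSV file; first row must name the variables.
    delimiter
        Force a delimiter; by default sniffed from ``{",", ";", TAB}``.
    missing_codes
        Cell contents treated as missing (besides genuinely empty cells).
    id_column
        Name or position of the subject-identifier column.
    column_map
        Optional ``{file column -> canonical variable name}`` renaming, so a
        source file's layout need not match the analysis vocabulary.
    comma_decimal
        Convert ``,`` decimal separators (European exports) to ``.``.

    Raises
    ------
    ValueError
        On duplicate subject ids or non-numeric non-missing cells (the error
        names the offending row and column).
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:4096] or ",")
    if comma_decimal and delimiter != ",":
        text = text.replace(",", ".")

    df = pd.read_csv(
        io.StringIO(text),
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    if isinstance(id_column, int):
        id_name = df.columns[id_column]
    else:
        id_name = id_column
        if id_name not in df.columns:
            raise ValueError(f"id column {id_name!r} not in header {list(df.columns)}")
    ids = [s.strip() for s in df[id_name].tolist()]
    df = df.drop(columns=[id_name])
    if column_map:
        df = df.rename(columns=column_map)

    codes = set(missing_codes) | {""}
    vals = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in codes:
                vals[i, j] = np.nan
                continue
            try:
                vals[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {ids[i]!r}, column {col!r}"
                ) from None
    return BiomarkerTable(subject_ids=ids, variables=list(df.columns), values=vals)


def write_table(table: BiomarkerTable, path, *, delimiter: str = ",") -> None:
    """Write a table as delimited text; missing cells become empty strings.

    Values are printed with ``repr`` round-trip precision so that
    ``read_table(write_table(t)) == t``.
    """
    df = table.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep=delimiter, na_rep="", float_format=lambda v: format(v, ".17g"))
    logger.debug("wrote %d x %d table to %s", table.n_subjects, len(table.variables), path)
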