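"""Reading abundance tables.

The native interchange is deliberately minimal: a two-column delimited
table (label, count) or a bare column of counts, one entity per row.  The
theory applies to any entity-abundance list — species, words, cities,
firms — so this is the least-commitment format.  Validation is strict by
default: every count must be >= 1 and integer-valued; malformed rows are
fatal with their line number, or counted and skipped with ``skip_bad``.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .fitting import AbundanceSample

__all__ = ["read_abundances", "ReadReport"]

logger = logging.getLogger(__name__)

_DIALECTS = ("auto", "two_column", "bare_counts")


def _parse_count(text: str, lineno: int, allow_real: bool) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"line {lineno}: {text!r} is not a number") from None
    if value < 1:
        raise ValueError(f"line {lineno}: count {text!r} is < 1")
    if not allow_real and value != int(value):
        raise ValueError(
            f"line {lineno}: count {text!r} is not an integer "
            "(pass allow_real to accept real-valued abundances)"
        )
    return value


def read_abundances(
    path,
    dialect: str = "auto",
    allow_real: bool = False,
    skip_bad: bool = False,
) -> AbundanceSample:
    """Read an abundance table into an :class:`AbundanceSample`.

    Parameters
    ----------
    path : path-like
        File with either two whitespace/tab-delimited columns
        (label, count) or one count per line.  An optional header line is
        detected (first line whose count column is non-numeric).
    dialect : str
        "two_column", "bare_counts", or "auto" (sniff from the first data
        row).
    allow_real : bool
        Accept non-integer abundances (still >= 1).
    skip_bad : bool
        Skip malformed rows instead of failing; the number skipped is
        logged.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    path = Path(path)
    rows = []  # (lineno, fields)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split("\t") if "\t" in line else line.split()))
    if not rows:
        raise ValueError(f"{path}: empty abundance table")

    if dialect == "auto":
        dialect = "two_column" if len(rows[0][1]) >= 2 else "bare_counts"

    # header detection: first row whose count field is non-numeric
    count_col = 1 if dialect == "two_column" else 0
    first_fields = rows[0][1]
    if len(first_fields) > count_col:
        try:
            float(first_fields[count_col])
        except ValueError:
            rows = rows[1:]
            if not rows:
                raise ValueError(f"{path}: table has a header but no data rows")

    values, labels = [], []
    n_skipped = 0
    for lineno, fields in rows:
        try:
            if dialect == "two_column":
                if len(fields) < 2:
                    raise ValueError(f"line {lineno}: expected 2 columns, got {len(fields)}")
                label = fields[0]
                value = _parse_count(fields[1], lineno, allow_real)
                labels.append(label)
            else:
                if len(fields) != 1:
                    raise ValueError(f"line {lineno}: expected 1 column, got {len(fields)}")
                value = _parse_count(fields[0], lineno, allow_real)
        except ValueError as exc:
            if skip_bad:
                n_skipped += 1
                continue
            raise ValueError(f"{path}: {exc}") from None
        values.append(value)
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    if not values:
        raise ValueError(f"{path}: no valid abundance rows")
    return AbundanceSample(values, labels if dialect == "two_column" else None)
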