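"""Tiny filter-expression language for the protein and peptide tables.

Grammar: one or more clauses joined by ``and``; each clause is
``<column> <op> <value>`` with op one of > < >= <= = (Unicode >= / <=
accepted).  ``=`` on a text column is a case-insensitive substring
match; on numeric columns all operators compare numerically.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["FilterExpressionError", "apply_filter"]

_OPS = ("<=", ">=", "≥", "≤", ">", "<", "=")


class FilterExpressionError(ValueError):
    """Malformed filter expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _parse_clause(clause: str, offset: int):
    for op in _OPS:
        idx = clause.find(op)
        if idx >= 0:
            col = clause[:idx].strip()
            val = clause[idx + len(op):].strip()
            if not col:
                raise FilterExpressionError("missing column name", offset)
            if not val:
                raise FilterExpressionError("missing comparison value",
                                            offset + idx + len(op))
            return col, op.replace("≥", ">=").replace("≤", "<="), val
    raise FilterExpressionError("no comparison operator found", offset)


def apply_filter(table: pd.DataFrame, expression: str) -> pd.DataFrame:
    """Return the rows of ``table`` satisfying ``expression``.

    An empty/blank expression keeps all rows.
    """
    if not expression or not expression.strip():
        return table
    mask = pd.Series(True, index=table.index)
    offset = 0
    for clause in re.split(r"\s+and\s+", expression, flags=re.IGNORECASE):
        col, op, val = _parse_clause(clause, offset)
        if col not in table.columns:
            raise FilterExpressionError(f"unknown column {col!r}",
                                        offset + expression[offset:].find(col))
        series = table[col]
        if pd.api.types.is_numeric_dtype(series):
            try:
                num = float(val)
            except ValueError:
                raise FilterExpressionError(
                    f"non-numeric value {val!r} for numeric column {col!r}",
                    offset) from None
            mask &= {
                ">": series > num, "<": series < num,
                ">=": series >= num, "<=": series <= num,
                "=": series == num,
            }[op]
        else:
            if op != "=":
                raise FilterExpressionError(
                    f"operator {op!r} not supported on text column {col!r}",
                    offset)
            mask &= series.astype(str).str.contains(re.escape(val),
                                                    case=False, na=False)
        offset += len(clause) + 5  # approximate: clause + " and "
    return table[mask]
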