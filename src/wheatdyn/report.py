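"""Table construction and rendering (CSV / JSON / markdown).

Numeric rendering is lossless by default; a printed-precision view (times
at one decimal, rates at two, half-up rounding) is available for direct
comparison against the published eigenvalue tables.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .growth_curve import LogisticParams, eigenvalues

__all__ = [
    "round_half_up",
    "eigenvalue_table",
    "printed_precision_eigenvalues",
    "render_table",
]

#: Eigenvalue table column order: fast phase bounds/duration/mean rate,
#: then inflection point and peak rate.
EIGEN_COLUMNS = ["t1", "t2", "duration", "vt", "tm", "vm"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero).

    Printed tables use conventional rounding, not banker's rounding, so
    comparisons at printed precision go through this helper.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def eigenvalue_table(coefficients: pd.DataFrame) -> pd.DataFrame:
    """Closed-form eigenvalues for each coefficient row.

    ``coefficients`` needs columns ``w_max``, ``a``, ``k``; identifying
    columns (season, sowing label, variable, ...) are carried through.
    Returns full-precision t1, t2, duration, vt, tm, vm.
    """
    for col in ("w_max", "a", "k"):
        if col not in coefficients.columns:
            raise KeyError(f"coefficient table missing column {col!r}")
    id_cols = [c for c in coefficients.columns if c not in ("w_max", "a", "k", "r_squared")]
    rows = []
    for rec in coefficients.to_dict("records"):
        ev = eigenvalues(LogisticParams(rec["w_max"], rec["a"], rec["k"]))
        out = {c: rec[c] for c in id_cols}
        out.update({c: getattr(ev, c) for c in EIGEN_COLUMNS})
        rows.append(out)
    return pd.DataFrame(rows, columns=id_cols + EIGEN_COLUMNS)


def printed_precision_eigenvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Round an eigenvalue table the way the published tables print it:
    times (t1, t2, duration, tm) to one decimal, rates (vt, vm) to two."""
    out = table.copy()
    for col in ("t1", "t2", "duration", "tm"):
        if col in out:
            out[col] = out[col].map(lambda v: round_half_up(v, 1))
    for col in ("vt", "vm"):
        if col in out:
            out[col] = out[col].map(lambda v: round_half_up(v, 2))
    return out


def _markdown(df: pd.DataFrame) -> str:
    headers = [str(c) for c in df.columns]
    body = [[_cell(v) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(headers[i]), *(len(r[i]) for r in body)) if body else len(headers[i])
        for i in range(len(headers))
    ]
    def fmt(cells: list[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(headers), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines.extend(fmt(r) for r in body)
    return "\n".join(lines) + "\n"


def _cell(v) -> str:
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def render_table(df: pd.DataFrame, dialect: str = "csv") -> str:
    """Render a result table as ``csv``, ``json`` (records) or ``markdown``.

    CSV and JSON are lossless (full float precision); an empty table
    renders as its header only.
    """
    if dialect == "csv":
        return df.to_csv(index=False)
    if dialect == "json":
        return json.dumps(df.to_dict("records"), indent=2, default=str) + "\n"
    if dialect == "markdown":
        return _markdown(df)
    raise ValueError(f"unknown dialect {dialect!r}; expected csv, json or markdown")
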