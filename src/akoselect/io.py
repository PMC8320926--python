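"""Reading and writing delimited metabolomics feature tables.

A feature table is held in memory as a :class:`pandas.DataFrame` of
intensities with samples as rows, metabolites as columns and ``NaN`` marking
missing entries; class labels are an aligned integer :class:`pandas.Series`
with a ``label_names`` attribute mapping codes to group names (e.g. CD, UC,
non-IBD).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_feature_table", "write_feature_table", "DEFAULT_MISSING_CODES"]

#: Cell contents interpreted as a missing measurement.  Workbench-style
#: exports encode absent peaks either as blanks/NA or as literal zeros; the
#: ``zero_is_missing`` flag controls the latter convention.
DEFAULT_MISSING_CODES = ("", "NA", "NaN", "nan", "N/A")


def _parse_cell(value: str) -> float:
    try:
        return float(value)
    except ValueError:
        return np.nan


def _coerce_numeric(df: pd.DataFrame, missing_codes: tuple[str, ...]) -> pd.DataFrame:
    out = df.replace(list(missing_codes), np.nan)
    # exact strtod parsing (pandas' fast parser can be off by 1 ulp)
    coerced = out.map(lambda v: _parse_cell(v) if isinstance(v, str) else v)
    bad = coerced.isna() & out.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ValueError(
            f"non-numeric cell {out.iat[r, c]!r} at row {out.index[r]!r}, "
            f"column {out.columns[c]!r} is not a recognised missing-value code"
        )
    return coerced.astype(float)


def read_feature_table(
    path: str | Path,
    *,
    class_column: str = "class",
    orientation: str = "samples-rows",
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
    zero_is_missing: bool = True,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a delimited feature table and its class labels.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.  The first column is taken as the
        sample or metabolite identifier depending on ``orientation``.
    class_column : str
        Name of the column (or row, for ``metabolites-rows``) holding the
        per-sample group label.
    orientation : str
        ``"samples-rows"`` or ``"metabolites-rows"``; the latter is
        transposed after reading so the returned table always has samples as
        rows.
    missing_codes : tuple of str
        Cell contents flagged as missing (in addition to empty cells).
    zero_is_missing : bool
        Treat exact zeros as missing (the common convention for undetected
        peaks); set False when zero is a genuine measurement.
    sep : str or None
        Field separator; inferred from the file extension when None.

    Returns
    -------
    (table, labels)
        Intensity DataFrame with ``NaN`` for missing values, and an integer
        label Series with ``labels.attrs["label_names"]`` listing the group
        names in code order.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    # pandas silently renames duplicate header fields, so check the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    seen: dict[str, int] = {}
    for name in header:
        seen[name] = seen.get(name, 0) + 1
    dup_header = [name for name, c in seen.items() if c > 1]
    if dup_header:
        what = (
            "sample ids" if orientation == "metabolites-rows" else "metabolite names"
        )
        raise ValueError(f"duplicate {what}: {dup_header}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)

    if orientation == "metabolites-rows":
        raw = raw.T
    elif orientation != "samples-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    if class_column not in raw.columns:
        raise ValueError(
            f"class column {class_column!r} not found; available columns include "
            f"{list(raw.columns[:5])!r}"
        )
    class_raw = raw[class_column]
    table = raw.drop(columns=[class_column])

    dup = table.columns[table.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate metabolite names: {dup}")
    dup_ids = table.index[table.index.duplicated()].unique().tolist()
    if dup_ids:
        raise ValueError(f"duplicate sample ids: {dup_ids}")

    table = _coerce_numeric(table, missing_codes)
    if zero_is_missing:
        table = table.mask(table == 0)

    table.index.name = None
    table.columns.name = None
    codes, uniques = pd.factorize(class_raw, sort=True)
    labels = pd.Series(codes, index=table.index, name=class_column)
    labels.attrs["label_names"] = [str(u) for u in uniques]
    return table, labels


def write_feature_table(
    table: pd.DataFrame,
    labels: pd.Series | None,
    path: str | Path,
    *,
    class_column: str = "class",
) -> None:
    """Write a feature table (optionally with its class column) as CSV.

    Missing entries are written as blank cells, the convention
    :func:`read_feature_table` flags as missing by default.
    """
    out = table.copy()
    if labels is not None:
        names = labels.attrs.get("label_names")
        col = labels.map(dict(enumerate(names))) if names else labels
        out.insert(0, class_column, col.to_numpy())
    out.to_csv(Path(path), index_label="sample_id", float_format="%.17g")
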