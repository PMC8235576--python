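"""Readers and writers for abundance matrices, metadata, markers, and GMT.

Disk convention: abundance tables are proteins x samples, first column
gene symbols, tab- or comma-delimited, log2 scale; missing cells are the
empty string or a configurable token (default ``NA``). In memory the
matrix is a float DataFrame with NaN marking missingness — no sentinel
numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed input file; message reports the offending row/column."""


def _resolve_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene symbols to one row each.

    Rule: keep the row with fewest missing cells; ties broken by highest
    median abundance, then by first occurrence (stable order).
    """
    if df.index.is_unique:
        return df
    n_missing = df.isna().sum(axis=1).to_numpy()
    med = df.median(axis=1, skipna=True).fillna(-np.inf).to_numpy()
    order = pd.DataFrame(
        {"sym": df.index, "miss": n_missing, "negmed": -med, "pos": np.arange(len(df))}
    )
    keep_pos = (
        order.sort_values(["miss", "negmed", "pos"], kind="stable")
        .drop_duplicates("sym", keep="first")["pos"]
        .sort_values()
        .to_numpy()
    )
    return df.iloc[keep_pos]


def read_abundance(
    path: str | Path,
    sep: str | None = None,
    missing_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan"),
) -> pd.DataFrame:
    """Read a proteins x samples abundance table.

    Duplicate symbols are resolved by the documented rule (fewest
    missing, then highest median, then original order). Non-numeric
    cells other than the missing tokens raise :class:`ParseError`
    naming the row and column.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip()
    values = raw.replace({t: np.nan for t in missing_tokens})
    try:
        df = values.astype(float)
    except ValueError:
        for col in values.columns:
            bad = pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()
            if bad.any():
                row = values.index[bad.to_numpy().nonzero()[0][0]]
                cell = values.loc[row, col]
                raise ParseError(
                    f"non-numeric cell {cell!r} at protein {row!r}, sample {col!r} in {path}"
                ) from None
        raise
    return _resolve_duplicates(df)


def write_abundance(df: pd.DataFrame, path: str | Path, missing_token: str = "NA") -> None:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, na_rep=missing_token)


def read_sample_meta(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read per-sample metadata (SampleID first column)."""
    meta = pd.read_csv(path, sep=sep, index_col=0)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ParseError(f"duplicated sample id {dup!r} in {path}")
    if "is_gis" in meta.columns:
        meta["is_gis"] = meta["is_gis"].astype(bool)
    return meta


def check_matrix_meta(ab: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every abundance column must have exactly one metadata row."""
    missing = [s for s in ab.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}{'...' if len(missing) > 5 else ''}")


def read_markers(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (cell_type, symbol) -> cell type marker sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "symbol"], dtype=str)
    out: dict[str, list[str]] = {}
    for t, grp in df.groupby("cell_type", sort=False):
        out[str(t)] = [s for s in grp["symbol"].tolist() if s]
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Standard GMT: name <tab> description <tab> member symbols."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"GMT line {i + 1} has fewer than 3 fields in {path}")
        sets[parts[0]] = [s for s in parts[2:] if s]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = ["\t".join([name, description, *members]) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping foreign -> local symbols.

    Many-to-one collisions keep the first row per foreign symbol in
    file order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["src", "dst"], dtype=str)
    mapping: dict[str, str] = {}
    for src, dst in zip(df["src"], df["dst"]):
        if src and src not in mapping:
            mapping[src] = dst
    return mapping
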