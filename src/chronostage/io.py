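"""Readers and writers for the plain-text formats used by the pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import META_COLUMNS


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes-x-samples TSV (first column = probe ids) as float."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a 0/1 presence-call TSV as booleans."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int).astype(bool)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file lacks columns {missing}")
    return meta


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Import the expression table of a GEO series-matrix file.

    Parses the tab-delimited block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``; sample titles and annotation lines outside
    the block are ignored.  Values are returned as a float DataFrame indexed
    by the ID_REF column (probe set ids).
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise ValueError("no !series_matrix_table_begin/_end sentinels found") from None
    block = "\n".join(lines[start + 1 : end])
    from io import StringIO

    df = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index.name = "probe_id"
    return df.astype(float)
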