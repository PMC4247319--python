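"""Tab-delimited readers/writers for the single TSV dialect used at every
stage boundary.

Every file is UTF-8, has a header row, and may start with ``#`` comment
lines carrying provenance (stage name, config hash).  Expression tables put
feature ids in a ``feature_id`` column; all other tables are plain columnar
TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False,
              header_comment: str | None = None) -> Path:
    """Write a DataFrame as TSV, optionally preceded by a ``#`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_expression_tsv(values: pd.DataFrame, path: str | Path,
                         header_comment: str | None = None) -> Path:
    """Write a features x samples matrix with a ``feature_id`` column."""
    out = values.copy()
    out.insert(0, "feature_id", values.index)
    return write_tsv(out, path, header_comment=header_comment)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples matrix keyed by ``feature_id``."""
    df = read_tsv(path)
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: expression table lacks a feature_id column")
    return df.set_index("feature_id")
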