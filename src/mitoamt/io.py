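"""Tab-delimited serialization with the "NA" missing-value convention."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

NA = "NA"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=NA)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kwargs)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a peptide x column matrix with a peptide_id first column."""
    out = df.copy()
    out.insert(0, "peptide_id", df.index)
    write_tsv(out, path)


def read_matrix(path) -> pd.DataFrame:
    df = read_tsv(path)
    return df.set_index("peptide_id")


def read_run_table(path) -> pd.DataFrame:
    """Read one run's UMC feature table, keeping blank peptide_id as ''."""
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=[NA],
        keep_default_na=False,
        dtype={"peptide_id": str},
    )
    df["peptide_id"] = df["peptide_id"].fillna("")
    return df
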