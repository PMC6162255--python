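"""Peptide x run abundance alignment, normalization, replicate collapse.

The assigned UMCs of all runs are combined into an alignment table whose
cell (peptide, run) sums the intensities of every UMC carrying that
peptide in that run; absent pairs stay missing (NaN), never zero.
Run-level log2 intensities are quantile-normalized to remove systematic
per-run variation, then technical replicates are averaged into one
column per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "build_alignment",
    "quantile_normalize",
    "collapse_replicates",
    "InputIntegrityError",
    "ColumnDegenerateError",
    "SampleSheetError",
]


class InputIntegrityError(ValueError):
    """Duplicate (run, umc) records in the input."""


class ColumnDegenerateError(ValueError):
    """A column has fewer than two observed values."""


class SampleSheetError(ValueError):
    """A run column is not mapped to a subject."""


def build_alignment(
    assignments: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Pivot assigned UMC intensities into a peptide x run matrix.

    ``assignments`` holds (run_id, umc_id, peptide_id, source) for all
    runs; ``features`` holds (run_id, umc_id, intensity). Cells are raw
    intensity sums; unobserved (peptide, run) pairs are NaN.
    """
    for name, df in ("assignments", assignments), ("features", features):
        dup = df.duplicated(subset=["run_id", "umc_id"])
        if dup.any():
            raise InputIntegrityError(
                f"{name} contains {int(dup.sum())} duplicate (run, umc) records"
            )
    assigned = assignments.loc[assignments["peptide_id"].astype(str) != ""]
    merged = assigned.merge(
        features[["run_id", "umc_id", "intensity"]],
        on=["run_id", "umc_id"],
        how="left",
        validate="one_to_one",
    )
    if merged["intensity"].isna().any():
        raise InputIntegrityError("assignment references a missing feature record")
    table = merged.pivot_table(
        index="peptide_id",
        columns="run_id",
        values="intensity",
        aggfunc="sum",
    )
    # keep every run as a column even if it contributed no assigned UMC
    all_runs = pd.Index(pd.unique(features["run_id"]), name="run_id")
    table = table.reindex(columns=all_runs)
    table.index.name = "peptide_id"
    return table


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (log2 scale) with missing-aware grids.

    Complete equal-depth columns get the textbook behavior: each column's
    sorted values are replaced by across-column means of order statistics,
    ties receiving the mean of the reference values they span. Columns
    with missing cells are mapped through their own empirical quantile
    ranks onto a shared reference quantile function (the across-column
    mean of per-column interpolated quantiles); missing cells remain
    missing and never enter the quantile computation.
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    counts = table.notna().sum(axis=0)
    bad = counts[counts < 2]
    if len(bad):
        raise ColumnDegenerateError(
            f"columns with <2 observed values: {list(bad.index)}"
        )

    X = table.to_numpy(float)
    n_rows, n_cols = X.shape
    col_vals = [np.sort(X[~np.isnan(X[:, j]), j]) for j in range(n_cols)]

    # reference quantile function on a common probability grid
    grid = np.linspace(0.0, 1.0, int(counts.max()))
    ref = np.zeros_like(grid)
    for v in col_vals:
        p = np.linspace(0.0, 1.0, len(v))
        ref += np.interp(grid, p, v)
    ref /= n_cols

    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        obs = ~np.isnan(X[:, j])
        v = X[obs, j]
        order = np.argsort(v, kind="stable")
        ranks_p = np.linspace(0.0, 1.0, len(v))
        mapped_sorted = np.interp(ranks_p, grid, ref)
        mapped = np.empty(len(v))
        mapped[order] = mapped_sorted
        # ties share the mean of the reference values they span
        uniq, inv = np.unique(v, return_inverse=True)
        if len(uniq) < len(v):
            sums = np.bincount(inv, weights=mapped)
            cnts = np.bincount(inv)
            mapped = (sums / cnts)[inv]
        out[obs, j] = mapped
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def collapse_replicates(
    table: pd.DataFrame, sample_sheet: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average each subject's observed replicate columns.

    ``table`` is a peptide x run matrix (log2 scale); the sample sheet
    maps run_id -> (subject_id, group, replicate). A subject cell is the
    mean of that subject's observed replicate values and missing only if
    every replicate is missing. Returns (subject table, subject metadata
    with columns subject_id, group indexed like the new columns).
    """
    sheet = sample_sheet.set_index("run_id")
    unmapped = [c for c in table.columns if c not in sheet.index]
    if unmapped:
        raise SampleSheetError(f"runs missing from the sample sheet: {unmapped}")

    subjects = sheet.loc[table.columns, "subject_id"]
    collapsed = table.T.groupby(subjects, sort=False).mean().T
    meta = (
        sheet.loc[table.columns, ["subject_id", "group"]]
        .drop_duplicates("subject_id")
        .set_index("subject_id")
        .loc[collapsed.columns]
        .reset_index()
    )
    collapsed.columns.name = "subject_id"
    return collapsed, meta
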