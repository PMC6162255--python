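"""Accurate mass and time tag (AMT) database construction.

Identified UMC features from many LC-MS runs are reduced to one consensus
entry per peptide: the arithmetic mean of its observed monoisotopic masses
and the median of its calibrated normalized elution times (NETs). Each
run's raw elution axis (scan units) is first rescaled to [0, 1] and then
calibrated onto the database's consensus NET scale with an affine
least-squares fit anchored on the run's identified peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMTEntry",
    "AMTDatabase",
    "CalibrationReport",
    "compute_net",
    "calibrate_net",
    "build_amt_db",
    "compile_amt_database",
    "DegenerateRunError",
    "CalibrationError",
    "EmptyDatabaseError",
]


class DegenerateRunError(ValueError):
    """All elution values in a run are identical: NET undefined."""


class CalibrationError(ValueError):
    """Too few shared identified peptides to fit the affine NET map."""


class EmptyDatabaseError(ValueError):
    """No identified features to compile."""


@dataclass(frozen=True)
class AMTEntry:
    peptide_id: str
    avg_mass: float
    median_net: float
    n_observations: int
    protein_ids: frozenset[str] = frozenset()


@dataclass
class AMTDatabase:
    """Consensus peptide mass/NET reference compiled across runs.

    Keeps a mass-sorted index for tolerance matching; semantics of any
    query are defined by exhaustive search over the entries.
    """

    entries: dict[str, AMTEntry]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise EmptyDatabaseError("AMT database cannot be empty")
        order = np.argsort([e.avg_mass for e in self.entries.values()], kind="stable")
        ids = np.array(list(self.entries), dtype=object)[order]
        self._sorted_ids = ids
        self._sorted_mass = np.array([self.entries[i].avg_mass for i in ids])
        self._sorted_net = np.array([self.entries[i].median_net for i in ids])

    def __len__(self) -> int:
        return len(self.entries)

    def median_nets(self) -> pd.Series:
        return pd.Series({p: e.median_net for p, e in self.entries.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peptide_id": e.peptide_id,
                "avg_mass_da": e.avg_mass,
                "median_net": e.median_net,
                "n_observations": e.n_observations,
                "protein_ids": ";".join(sorted(e.protein_ids)),
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows).sort_values("peptide_id", ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AMTDatabase":
        entries = {}
        for row in df.itertuples(index=False):
            prots = frozenset(
                p for p in str(getattr(row, "protein_ids", "") or "").split(";") if p
            )
            entries[row.peptide_id] = AMTEntry(
                peptide_id=row.peptide_id,
                avg_mass=float(row.avg_mass_da),
                median_net=float(row.median_net),
                n_observations=int(row.n_observations),
                protein_ids=prots,
            )
        return cls(entries=entries)


@dataclass(frozen=True)
class CalibrationReport:
    run_id: str
    slope: float
    intercept: float
    residual_sd: float
    n_anchors: int
    calibrated: bool = True


def compute_net(features: pd.DataFrame) -> pd.DataFrame:
    """Rescale one run's elution axis to [0, 1] by min-max normalization.

    Returns a copy with a ``net`` column; elution rank order is preserved.
    Raises DegenerateRunError when all elution values coincide.
    """
    elut = features["elution_scan"].to_numpy(float)
    lo, hi = elut.min(), elut.max()
    if hi == lo:
        raise DegenerateRunError(
            f"run has a single distinct elution value ({lo}); NET undefined"
        )
    out = features.copy()
    out["net"] = (elut - lo) / (hi - lo)
    return out


def calibrate_net(
    features: pd.DataFrame,
    reference: "AMTDatabase | pd.Series",
    min_anchors: int = 3,
    outlier_sd: float = 3.0,
) -> tuple[pd.DataFrame, CalibrationReport]:
    """Affine-calibrate one run's NETs onto the reference NET scale.

    An ordinary least-squares line from the run's NETs to the reference
    median NETs is fitted on the identified peptides the two share, with
    one pass of outlier rejection at ``|residual| > outlier_sd * sd`` and
    a refit, then applied to every feature of the run; calibrated values
    are clipped to [0, 1]. Fewer than ``min_anchors`` shared anchors
    raises CalibrationError (caller may keep the run uncalibrated).
    """
    ref = reference.median_nets() if isinstance(reference, AMTDatabase) else reference
    run_id = str(features["run_id"].iloc[0]) if len(features) else "<empty>"

    idents = features.loc[features["peptide_id"].astype(str) != ""]
    shared = idents.loc[idents["peptide_id"].isin(ref.index)]
    if shared["peptide_id"].nunique() < min_anchors:
        raise CalibrationError(
            f"run {run_id}: {shared['peptide_id'].nunique()} anchor peptides "
            f"shared with the reference; need >= {min_anchors}"
        )

    x = shared["net"].to_numpy(float)
    y = ref.loc[shared["peptide_id"]].to_numpy(float)

    slope, intercept = _ols_line(x, y)
    resid = y - (slope * x + intercept)
    sd = float(resid.std(ddof=0))
    if sd > 0:
        keep = np.abs(resid) <= outlier_sd * sd
        if keep.sum() >= min_anchors and keep.sum() < len(x):
            slope, intercept = _ols_line(x[keep], y[keep])
            resid = y[keep] - (slope * x[keep] + intercept)
            sd = float(resid.std(ddof=0))
            x = x[keep]

    out = features.copy()
    out["net"] = np.clip(slope * out["net"].to_numpy(float) + intercept, 0.0, 1.0)
    report = CalibrationReport(
        run_id=run_id,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=sd,
        n_anchors=int(len(x)),
    )
    return out, report


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise CalibrationError("anchor NETs are constant; affine fit undefined")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    return slope, float(ym - slope * xm)


def build_amt_db(
    identified: pd.DataFrame,
    protein_map: pd.Series | None = None,
    provenance: tuple[str, ...] = (),
) -> AMTDatabase:
    """Compile identified, NET-bearing features into an AMT database.

    One entry per distinct peptide: avg_mass is the arithmetic mean of
    the observed masses, median_net the median of observed NETs (midpoint
    of the central pair for even counts).
    """
    if len(identified) == 0:
        raise EmptyDatabaseError("no identified features supplied")
    if (identified["peptide_id"].astype(str) == "").any():
        raise ValueError("build_amt_db requires every feature to carry a peptide_id")
    if identified["net"].isna().any():
        raise ValueError("build_amt_db requires every feature to carry a NET")

    grouped = identified.groupby("peptide_id", sort=True)
    entries = {}
    for pep, g in grouped:
        prots: frozenset[str] = frozenset()
        if protein_map is not None and pep in protein_map.index:
            prots = frozenset([str(protein_map.loc[pep])])
        entries[pep] = AMTEntry(
            peptide_id=str(pep),
            avg_mass=float(g["monoisotopic_mass_da"].mean()),
            median_net=float(g["net"].median()),
            n_observations=int(len(g)),
            protein_ids=prots,
        )
    return AMTDatabase(entries=entries, provenance=provenance)


def compile_amt_database(
    runs: dict[str, pd.DataFrame],
    protein_map: pd.Series | None = None,
    min_anchors: int = 3,
) -> tuple[AMTDatabase, dict[str, pd.DataFrame], list[CalibrationReport]]:
    """Two-pass master-DB build: normalize, calibrate, recompile.

    Pass 1 compiles consensus median NETs from each run's min-max
    normalized NETs; pass 2 affine-calibrates every run against those
    medians and recompiles the database from the calibrated NETs. Runs
    with too few anchors are kept uncalibrated and flagged in the report.
    Returns (database, calibrated runs, calibration reports).
    """
    normed = {rid: compute_net(df) for rid, df in runs.items()}
    pooled = pd.concat(
        [df.loc[df["peptide_id"].astype(str) != ""] for df in normed.values()],
        ignore_index=True,
    )
    if len(pooled) == 0:
        raise EmptyDatabaseError("no identified features in any run")
    provisional = build_amt_db(pooled, protein_map, provenance=tuple(runs))

    calibrated: dict[str, pd.DataFrame] = {}
    reports: list[CalibrationReport] = []
    for rid, df in normed.items():
        try:
            cal, rep = calibrate_net(df, provisional, min_anchors=min_anchors)
        except CalibrationError:
            cal = df
            rep = CalibrationReport(
                run_id=rid, slope=np.nan, intercept=np.nan,
                residual_sd=np.nan, n_anchors=0, calibrated=False,
            )
        calibrated[rid] = cal
        reports.append(rep)

    pooled2 = pd.concat(
        [df.loc[df["peptide_id"].astype(str) != ""] for df in calibrated.values()],
        ignore_index=True,
    )
    final = build_amt_db(pooled2, protein_map, provenance=tuple(runs))
    return final, calibrated, reports
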