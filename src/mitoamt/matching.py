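"""Peptide assignment to unidentified UMCs by AMT database lookup.

An unidentified feature is matched against the database within a mass
tolerance (ppm, relative to the database entry's consensus mass) and a
NET tolerance. When several entries fall inside the tolerance box the
nearest one under the tolerance-scaled Euclidean distance wins and the
match is flagged ambiguous; a strict mode drops ambiguous matches.

The production matcher windows candidates with a binary search on a
mass-sorted index; its semantics are defined by (and tested against)
exhaustive pairwise search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amtdb import AMTDatabase

__all__ = [
    "MatchTolerances",
    "MatchResult",
    "AssignmentSummary",
    "match_umc",
    "assign_peptides",
    "summarize_assignments",
]


class EmptyInputError(ValueError):
    """No features to assign."""


@dataclass(frozen=True)
class MatchTolerances:
    mass_ppm: float = 10.0
    net_tol: float = 0.025

    def __post_init__(self) -> None:
        if self.mass_ppm <= 0 or self.net_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class MatchResult:
    umc_id: str
    matched_peptide_id: str | None
    delta_ppm: float
    delta_net: float
    n_candidates: int
    ambiguous: bool


@dataclass(frozen=True)
class AssignmentSummary:
    """Bookkeeping of one dataset's identification inventory."""

    n_total: int
    n_identified: int
    n_amt_assigned: int

    @property
    def n_with_id(self) -> int:
        return self.n_identified + self.n_amt_assigned

    @property
    def id_fraction(self) -> float:
        return self.n_identified / self.n_total if self.n_total else 0.0


def summarize_assignments(
    n_total: int, n_identified: int, n_amt_assigned: int
) -> AssignmentSummary:
    if n_identified + n_amt_assigned > n_total:
        raise ValueError("identified + assigned exceeds total features")
    return AssignmentSummary(n_total, n_identified, n_amt_assigned)


def _window(db: AMTDatabase, mass: float, mass_ppm: float) -> tuple[int, int]:
    # entry qualifies iff |1e6 (m - a)/a| <= tol  <=>  a in [m/(1+t), m/(1-t)]
    t = mass_ppm / 1e6
    lo = mass / (1.0 + t) * (1.0 - 1e-12)
    hi = mass / (1.0 - t) * (1.0 + 1e-12)
    i = int(np.searchsorted(db._sorted_mass, lo, side="left"))
    j = int(np.searchsorted(db._sorted_mass, hi, side="right"))
    return i, j


def match_umc(
    mass: float,
    net: float,
    db: AMTDatabase,
    tol: MatchTolerances = MatchTolerances(),
    umc_id: str = "",
) -> MatchResult:
    """Match one feature's (mass, NET) against the database.

    Candidates satisfy both tolerance bounds; the winner minimizes
    sqrt((dppm/mass_ppm)^2 + (dnet/net_tol)^2). ppm deviation is computed
    relative to the database entry's consensus mass.
    """
    i, j = _window(db, mass, tol.mass_ppm)
    if i == j:
        return MatchResult(umc_id, None, np.nan, np.nan, 0, False)
    dm = db._sorted_mass[i:j]
    dn = db._sorted_net[i:j]
    dppm = 1e6 * (mass - dm) / dm
    dnet = net - dn
    ok = (np.abs(dppm) <= tol.mass_ppm) & (np.abs(dnet) <= tol.net_tol)
    n_cand = int(ok.sum())
    if n_cand == 0:
        return MatchResult(umc_id, None, np.nan, np.nan, 0, False)
    idx = np.flatnonzero(ok)
    dist = np.hypot(dppm[idx] / tol.mass_ppm, dnet[idx] / tol.net_tol)
    best = idx[int(np.argmin(dist))]
    return MatchResult(
        umc_id=umc_id,
        matched_peptide_id=str(db._sorted_ids[i + best]),
        delta_ppm=float(dppm[best]),
        delta_net=float(dnet[best]),
        n_candidates=n_cand,
        ambiguous=n_cand >= 2,
    )


def assign_peptides(
    features: pd.DataFrame,
    db: AMTDatabase,
    tol: MatchTolerances = MatchTolerances(),
    drop_ambiguous: bool = False,
) -> tuple[pd.DataFrame, AssignmentSummary]:
    """Assign AMT identities to every unidentified feature of one run.

    Search-derived identities are never touched. Returns the assignment
    table (run_id, umc_id, peptide_id, source, delta_ppm, delta_net,
    ambiguous) plus the per-run AssignmentSummary; with
    ``drop_ambiguous`` multi-candidate matches are discarded.
    """
    if len(features) == 0:
        raise EmptyInputError("no features to assign")
    if features["net"].isna().any():
        raise ValueError("features must carry calibrated NETs before assignment")

    pep = features["peptide_id"].astype(str)
    is_ident = (pep != "").to_numpy()
    masses = features["monoisotopic_mass_da"].to_numpy(float)
    nets = features["net"].to_numpy(float)
    umc_ids = features["umc_id"].astype(str).to_numpy()

    rows = []
    n_assigned = 0
    for k in range(len(features)):
        if is_ident[k]:
            rows.append(
                (umc_ids[k], pep.iloc[k], "searched", 0.0, 0.0, False)
            )
            continue
        m = match_umc(masses[k], nets[k], db, tol, umc_id=umc_ids[k])
        if m.matched_peptide_id is None or (drop_ambiguous and m.ambiguous):
            rows.append((umc_ids[k], "", "none", np.nan, np.nan, m.ambiguous))
        else:
            n_assigned += 1
            rows.append(
                (
                    umc_ids[k],
                    m.matched_peptide_id,
                    "amt",
                    m.delta_ppm,
                    m.delta_net,
                    m.ambiguous,
                )
            )

    out = pd.DataFrame(
        rows,
        columns=["umc_id", "peptide_id", "source", "delta_ppm", "delta_net", "ambiguous"],
    )
    out.insert(0, "run_id", features["run_id"].to_numpy())
    summary = AssignmentSummary(
        n_total=len(features),
        n_identified=int(is_ident.sum()),
        n_amt_assigned=n_assigned,
    )
    return out, summary
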