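"""Hypergeometric GO-term enrichment over DEP sets.

Over-representation of an annotation term in a query protein set is
scored with the one-sided hypergeometric upper tail P(X >= overlap)
against a measured-proteome universe; the EASE variant subtracts one
from the overlap (floored at zero) before taking the tail, a
conservative correction for small overlaps. Significance follows the
p <= 0.05 convention; a q-value column is provided for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .depstats import storey_fdr

__all__ = ["AnnotationSet", "read_gmt", "enrich_terms", "hypergeom_upper_tail"]


class EnrichmentInputError(ValueError):
    """Empty query or universe."""


@dataclass(frozen=True)
class AnnotationSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation term {self.term_id} has no members")


def read_gmt(path) -> list[AnnotationSet]:
    """Parse a GMT file: term <tab> description <tab> member ids..."""
    out = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, *members = parts
            members = [m for m in members if m]
            if not members or term in seen:
                continue
            seen.add(term)
            out.append(AnnotationSet(term, desc, frozenset(members)))
    return out


def hypergeom_upper_tail(overlap: int, universe: int, term: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    if overlap <= 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, universe, term, query))


def enrich_terms(
    query: set[str],
    annotations: list[AnnotationSet],
    universe: set[str],
    mode: str = "fisher",
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score every annotation term against the query set.

    Terms are intersected with the universe first; ``mode`` is
    ``fisher`` (plain upper tail) or ``ease``. Results are sorted by p,
    with a significant flag at p <= ``p_threshold`` and an informational
    q-value column.
    """
    if mode not in ("fisher", "ease"):
        raise ValueError("mode must be 'fisher' or 'ease'")
    query = set(query) & set(universe)
    if not query or not universe:
        raise EnrichmentInputError("empty query or universe")

    rows = []
    for ann in annotations:
        members = ann.members & universe
        if not members:
            continue
        overlap = len(members & query)
        k = max(overlap - 1, 0) if mode == "ease" else overlap
        p = hypergeom_upper_tail(k, len(universe), len(members), len(query))
        rows.append(
            {
                "term_id": ann.term_id,
                "term_name": ann.term_name,
                "overlap": overlap,
                "term_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = storey_fdr(df["p_value"].to_numpy())
        df["significant"] = df["p_value"] <= p_threshold
        df = df.sort_values(["p_value", "term_id"], ignore_index=True)
    return df
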