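"""Composite permutation test for two-group differential expression.

For each peptide passing the detection and sibling-peptide filters the
pipeline computes a pooled-variance Student t statistic and a log2-median
ratio (case minus control). Empirical null distributions for the two
statistics are built by recomputing them under random balanced
relabelings of the subjects and pooling the null values across peptides
and permutations; adjusted two-sided p-values are read off the pooled
null. The two adjusted p-values are combined per peptide with a signed-z
Stouffer transform and converted to q-values with Storey's FDR method.
Peptides with q <= 0.1 and |log2-median ratio| >= log2(1.5) are called
differentially expressed, and any protein containing such a peptide is a
differentially expressed protein (DEP) with a direction given by the
sign of its significant peptides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FilterConfig",
    "TestConfig",
    "filter_peptides",
    "t_statistic",
    "log2_median_ratio",
    "balanced_permutations",
    "permutation_null",
    "stouffer_combine",
    "storey_fdr",
    "select_and_rollup",
    "run_differential_test",
]


@dataclass(frozen=True)
class FilterConfig:
    """Peptide retention rules applied before testing.

    A peptide is kept when it is detected in strictly more than
    ``min_detect_fraction`` of the subjects of EACH group and its protein
    retains at least ``min_sibling_peptides`` distinct such peptides.
    """

    min_sibling_peptides: int = 2
    min_detect_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_sibling_peptides < 1:
            raise ValueError("min_sibling_peptides must be >= 1")
        if not (0.0 <= self.min_detect_fraction < 1.0):
            raise ValueError("min_detect_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TestConfig:
    __test__ = False  # not a pytest class despite the name

    n_permutations: int = 1000
    seed: int = 0
    fdr_threshold: float = 0.1
    fold_threshold: float = 1.5
    storey_lambda: float = 0.5

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold must be >= 1")


def filter_peptides(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    protein_map: pd.Series,
    cfg: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Apply the detection and sibling-peptide filters.

    ``table`` is the subject-level peptide matrix, ``meta`` maps its
    columns to groups, ``protein_map`` maps peptide id -> protein id.
    Membership is recomputed after detection filtering and iterated to a
    fixed point. An empty result is returned as-is (caller may warn).
    """
    groups = meta.set_index("subject_id").loc[table.columns, "group"]
    keep = pd.Series(True, index=table.index)
    for g in groups.unique():
        cols = table.columns[groups.to_numpy() == g]
        frac_needed = cfg.min_detect_fraction * len(cols)
        detected = table[cols].notna().sum(axis=1)
        keep &= detected > frac_needed

    retained = table.index[keep]
    while True:
        prots = protein_map.reindex(retained)
        sib = prots.groupby(prots).transform("size")
        ok = sib >= cfg.min_sibling_peptides
        new = retained[ok.to_numpy(bool)]
        if len(new) == len(retained):
            break
        retained = new
    return table.loc[retained]


def t_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-variance two-sample Student t on observed log2 values.

    Positive means higher in the first (case) group. With zero pooled
    variance: 0 for equal means, signed infinity otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observed values per group")
    nx, ny = len(x), len(y)
    d = x.mean() - y.mean()
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        return 0.0 if d == 0.0 else float(np.sign(d) * np.inf)
    return float(d / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny)))


def log2_median_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """median(x) - median(y) on already-log2 values (case minus control)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need >= 1 observed value per group")
    return float(np.median(x) - np.median(y))


def balanced_permutations(
    n1: int, n2: int, n_permutations: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], bool]:
    """Distinct balanced relabelings of n1+n2 subjects, identity excluded.

    Returns (list of group-1 index arrays, exhaustive flag). When the
    number of distinct non-identity relabelings does not exceed the
    request, all of them are returned (exhaustive enumeration);
    otherwise that many distinct relabelings are sampled without
    replacement.
    """
    n = n1 + n2
    identity = tuple(range(n1))
    total = comb(n, n1) - 1  # excluding identity
    if total <= n_permutations:
        perms = [
            np.array(c)
            for c in itertools.combinations(range(n), n1)
            if c != identity
        ]
        return perms, True
    seen = {identity}
    out: list[np.ndarray] = []
    while len(out) < n_permutations:
        c = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if c in seen:
            continue
        seen.add(c)
        out.append(np.array(c))
    return out, False


def _masked_median(X: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Row medians of X[:, cols] ignoring NaN (NaN row if none observed)."""
    sub = X[:, cols]
    filled = np.where(np.isnan(sub), np.inf, sub)
    s = np.sort(filled, axis=1)
    n = (~np.isnan(sub)).sum(axis=1)
    med = np.full(X.shape[0], np.nan)
    ok = n > 0
    lo = (n[ok] - 1) // 2
    hi = n[ok] // 2
    r = np.flatnonzero(ok)
    med[ok] = 0.5 * (s[r, lo] + s[r, hi])
    return med


def _masked_t(X: np.ndarray, cols1: np.ndarray, cols2: np.ndarray) -> np.ndarray:
    """Row-wise pooled t between two column sets, NaN-aware, vectorized."""
    out = np.full(X.shape[0], np.nan)
    stats_ = []
    for cols in (cols1, cols2):
        sub = X[:, cols]
        m = ~np.isnan(sub)
        n = m.sum(axis=1).astype(float)
        z = np.where(m, sub, 0.0)
        s1 = z.sum(axis=1)
        s2 = (z * z).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / n
            var = np.where(n > 1, (s2 - n * mean**2) / (n - 1), np.nan)
        stats_.append((n, mean, np.maximum(var, 0.0)))
    (n1, m1, v1), (n2, m2, v2) = stats_
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        d = m1 - m2
        t = np.where(se > 0, d / se, np.where(d == 0, 0.0, np.sign(d) * np.inf))
    out[ok] = t[ok]
    return out


def permutation_null(
    X: np.ndarray,
    cols1: np.ndarray,
    cols2: np.ndarray,
    statistic: str,
    cfg: TestConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Observed statistics and pooled-null adjusted p-values.

    Group labels are permuted over distinct balanced relabelings
    (identity excluded); the statistic is recomputed for every peptide
    per permutation and the null values pooled across peptides and
    permutations. Adjusted p for peptide i is
    (1 + #{|null| >= |obs_i|}) / (1 + N_null), two-sided via absolute
    values. Returns (observed, p, n_null).
    """
    if statistic not in ("t", "ratio"):
        raise ValueError("statistic must be 't' or 'ratio'")
    rng = rng or np.random.default_rng(cfg.seed)
    n1, n2 = len(cols1), len(cols2)
    all_cols = np.concatenate([cols1, cols2])

    def stat(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
        if statistic == "t":
            return _masked_t(X, c1, c2)
        return _masked_median(X, c1) - _masked_median(X, c2)

    observed = stat(cols1, cols2)
    perms, _ = balanced_permutations(n1, n2, cfg.n_permutations, rng)
    null_parts = []
    all_set = set(range(n1 + n2))
    for g1 in perms:
        g2 = np.array(sorted(all_set - set(g1.tolist())))
        null_parts.append(stat(all_cols[g1], all_cols[g2]))
    null = np.abs(np.concatenate(null_parts))
    null = null[np.isfinite(null)]
    null.sort()
    n_null = len(null)

    a = np.abs(observed)
    cnt = n_null - np.searchsorted(null, a, side="left")
    # non-finite observed values exceed every finite null value
    cnt = np.where(np.isnan(a), n_null, cnt)
    p = (1.0 + cnt) / (1.0 + n_null)
    return observed, p, n_null


def stouffer_combine(
    p_t: np.ndarray,
    sign_t: np.ndarray,
    p_ratio: np.ndarray,
    sign_ratio: np.ndarray,
) -> np.ndarray:
    """Signed-z Stouffer combination of two two-sided p-values.

    z_i = sign_i * Phi^-1(1 - p_i/2); z_c = (z_t + z_ratio)/sqrt(2);
    p_combined = 2 (1 - Phi(|z_c|)), clamped into (0, 1].
    """
    tiny = np.finfo(float).tiny
    p_t = np.clip(np.asarray(p_t, float), tiny, 1.0)
    p_ratio = np.clip(np.asarray(p_ratio, float), tiny, 1.0)
    z_t = np.asarray(sign_t, float) * sps.norm.isf(p_t / 2.0)
    z_r = np.asarray(sign_ratio, float) * sps.norm.isf(p_ratio / 2.0)
    z_c = (z_t + z_r) / np.sqrt(2.0)
    return np.clip(2.0 * sps.norm.sf(np.abs(z_c)), tiny, 1.0)


def storey_fdr(p: np.ndarray, storey_lambda: float = 0.5) -> np.ndarray:
    """Storey q-values: BH step-down scaled by the estimated null fraction.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m));
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j, clamped into (0, 1].
    """
    p = np.asarray(p, float)
    m = len(p)
    if m == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    pi0 = min(1.0, float((p > storey_lambda).sum()) / ((1.0 - storey_lambda) * m))
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, np.finfo(float).tiny, 1.0)
    return q


def select_and_rollup(
    results: pd.DataFrame,
    protein_map: pd.Series,
    cfg: TestConfig = TestConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag significant peptides and roll them up to DEP calls.

    A peptide is significant iff q <= fdr_threshold and
    |log2_median_ratio| >= log2(fold_threshold). A protein is a DEP iff
    it has >= 1 significant sibling; its log2fc is the median ratio of
    its significant siblings (all siblings when none is significant) and
    its direction is up/down by sign, ``mixed`` when significant
    siblings disagree in sign.
    """
    res = results.copy()
    lf_thresh = np.log2(cfg.fold_threshold)
    res["significant"] = (res["q_value"] <= cfg.fdr_threshold) & (
        res["log2_median_ratio"].abs() >= lf_thresh
    )
    res["protein_id"] = protein_map.reindex(res["peptide_id"]).to_numpy()

    rows = []
    for prot, g in res.groupby("protein_id", sort=True):
        sig = g.loc[g["significant"]]
        n_sig = len(sig)
        src = sig if n_sig else g
        lfc = float(src["log2_median_ratio"].median())
        if n_sig:
            pos = (sig["log2_median_ratio"] > 0).any()
            neg = (sig["log2_median_ratio"] < 0).any()
            direction = "mixed" if (pos and neg) else ("up" if pos else "down")
        else:
            direction = "up" if lfc > 0 else "down"
        rows.append(
            {
                "protein_id": prot,
                "n_sibling_peptides": len(g),
                "n_significant_peptides": n_sig,
                "protein_log2fc": lfc,
                "direction": direction,
                "is_dep": n_sig >= 1,
            }
        )
    return res, pd.DataFrame(rows)


def run_differential_test(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    protein_map: pd.Series,
    filter_cfg: FilterConfig = FilterConfig(),
    test_cfg: TestConfig = TestConfig(),
    case_group: str = "T2DM",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, test, combine, FDR-correct, and roll up one cohort.

    ``table`` is a subject-level log2 peptide matrix; ``meta`` maps its
    columns to groups. Returns (peptide results, protein results).
    """
    filt = filter_peptides(table, meta, protein_map, filter_cfg)
    if len(filt) == 0:
        empty_pep = pd.DataFrame(
            columns=[
                "peptide_id", "t_value", "log2_median_ratio",
                "p_t", "p_ratio", "p_combined", "q_value",
                "significant", "protein_id",
            ]
        )
        empty_prot = pd.DataFrame(
            columns=[
                "protein_id", "n_sibling_peptides", "n_significant_peptides",
                "protein_log2fc", "direction", "is_dep",
            ]
        )
        return empty_pep, empty_prot

    groups = meta.set_index("subject_id").loc[filt.columns, "group"].to_numpy()
    cols1 = np.flatnonzero(groups == case_group)
    cols2 = np.flatnonzero(groups != case_group)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 subjects per group")

    X = filt.to_numpy(float)
    rng = np.random.default_rng(test_cfg.seed)
    t_obs, p_t, _ = permutation_null(X, cols1, cols2, "t", test_cfg, rng)
    r_obs, p_r, _ = permutation_null(X, cols1, cols2, "ratio", test_cfg, rng)

    p_comb = stouffer_combine(p_t, np.sign(t_obs), p_r, np.sign(r_obs))
    q = storey_fdr(p_comb, test_cfg.storey_lambda)

    results = pd.DataFrame(
        {
            "peptide_id": filt.index,
            "t_value": t_obs,
            "log2_median_ratio": r_obs,
            "p_t": p_t,
            "p_ratio": p_r,
            "p_combined": p_comb,
            "q_value": q,
        }
    )
    return select_and_rollup(results, protein_map, test_cfg)
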