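"""Composite permutation test: filters, statistics, combination, FDR, rollup."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoamt.depstats import (
    FilterConfig,
    TestConfig,
    balanced_permutations,
    filter_peptides,
    log2_median_ratio,
    permutation_null,
    run_differential_test,
    select_and_rollup,
    storey_fdr,
    stouffer_combine,
    t_statistic,
)


def subject_meta(n1, n2):
    subs = [f"t{i}" for i in range(n1)] + [f"c{i}" for i in range(n2)]
    groups = ["T2DM"] * n1 + ["control"] * n2
    return subs, pd.DataFrame({"subject_id": subs, "group": groups})


class TestFilterPeptides:
    def make_table(self, detect_t, detect_c, protein_sizes):
        """One protein per entry of protein_sizes; each peptide detected in
        detect_t of 9 case and detect_c of 9 control subjects."""
        subs, meta = subject_meta(9, 9)
        rows, prots = [], {}
        for pi, size in enumerate(protein_sizes):
            for k in range(size):
                pep = f"P{pi}.pep{k}"
                prots[pep] = f"P{pi}"
                vals = [1.0 if i < detect_t else np.nan for i in range(9)]
                vals += [1.0 if i < detect_c else np.nan for i in range(9)]
                rows.append(pd.Series(vals, index=subs, name=pep))
        return pd.DataFrame(rows), meta, pd.Series(prots)

    def test_peptide_detected_in_4_of_9_removed(self):
        table, meta, prots = self.make_table(4, 9, [3])
        out = filter_peptides(table, meta, prots)
        assert len(out) == 0

    def test_peptide_detected_in_5_of_9_both_groups_kept(self):
        table, meta, prots = self.make_table(5, 5, [3])
        out = filter_peptides(table, meta, prots)
        assert len(out) == 3

    def test_single_peptide_protein_removed(self):
        table, meta, prots = self.make_table(9, 9, [1, 3])
        out = filter_peptides(table, meta, prots)
        assert set(out.index) == {"P1.pep0", "P1.pep1", "P1.pep2"}

    def test_sibling_count_recomputed_after_detection_filter(self):
        """A protein whose second peptide fails detection loses both."""
        subs, meta = subject_meta(9, 9)
        good = pd.Series([1.0] * 18, index=subs, name="P0.a")
        bad = pd.Series([1.0] * 4 + [np.nan] * 5 + [1.0] * 9, index=subs, name="P0.b")
        table = pd.DataFrame([good, bad])
        prots = pd.Series({"P0.a": "P0", "P0.b": "P0"})
        out = filter_peptides(table, meta, prots)
        assert len(out) == 0


class TestStatistics:
    def test_t_identical_groups_zero(self):
        assert t_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_t_hand_computed_value(self):
        # pooled sd 1, se = sqrt(2/3) = 0.8165, t = -3/0.8165
        assert t_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.6742, abs=1e-4)

    def test_t_antisymmetric(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=7)
        assert t_statistic(x, y) == pytest.approx(-t_statistic(y, x))

    def test_t_zero_variance_unequal_means_is_signed_inf(self):
        assert t_statistic([2.0, 2.0], [1.0, 1.0]) == np.inf
        assert t_statistic([1.0, 1.0], [2.0, 2.0]) == -np.inf

    def test_ratio_equal_medians_zero(self):
        assert log2_median_ratio([5.0, 6.0, 7.0], [4.0, 6.0, 8.0]) == 0.0

    def test_ratio_twofold_linear_is_one(self):
        x = np.log2([8, 8, 32])
        y = np.log2([4, 4, 4])
        assert log2_median_ratio(x, y) == pytest.approx(1.0)

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValueError):
            t_statistic([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            log2_median_ratio([], [1.0])


class TestPermutationNull:
    def test_exhaustive_when_few_relabelings(self, rng):
        perms, exhaustive = balanced_permutations(3, 3, 1000, rng)
        assert exhaustive and len(perms) == 19  # C(6,3) - 1
        assert all(tuple(p) != (0, 1, 2) for p in perms)
        assert len({tuple(p) for p in perms}) == 19

    def test_sampled_permutations_distinct(self, rng):
        perms, exhaustive = balanced_permutations(9, 9, 500, rng)
        assert not exhaustive and len(perms) == 500
        assert len({tuple(p) for p in perms}) == 500

    def test_boundary_p_when_observed_exceeds_null(self):
        """A huge planted separation gives the minimal attainable p.

        With balanced relabelings the complement of the identity always
        reproduces |observed|, so the floor is 2/(1 + N_null)."""
        X = np.array([[0.0, 1.0, 2.0, 10.0, 11.0, 12.0]])
        cfg = TestConfig(n_permutations=100, seed=1)
        obs, p, n_null = permutation_null(
            X, np.arange(3), np.arange(3, 6), "t", cfg
        )
        assert p[0] == pytest.approx((1 + 1) / (1 + n_null))

    def test_symmetric_null_center_has_p_near_one(self):
        X = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        cfg = TestConfig(n_permutations=100, seed=1)
        _, p, _ = permutation_null(X, np.arange(3), np.arange(3, 6), "t", cfg)
        assert p[0] > 0.9

    @pytest.mark.parametrize("statistic", ["t", "ratio"])
    def test_full_enumeration_oracle_3v3(self, rng, statistic):
        """Pooled-null p equals naive enumeration over all relabelings."""
        X = rng.normal(size=(2, 6))
        cols1, cols2 = np.arange(3), np.arange(3, 6)
        cfg = TestConfig(n_permutations=100, seed=2)
        obs, p, n_null = permutation_null(X, cols1, cols2, statistic, cfg)

        def naive_stat(vals, g1):
            g2 = [i for i in range(6) if i not in g1]
            x, y = vals[list(g1)], vals[g2]
            if statistic == "t":
                return t_statistic(x, y)
            return log2_median_ratio(x, y)

        null = []
        for g1 in itertools.combinations(range(6), 3):
            if g1 == (0, 1, 2):
                continue
            for r in range(2):
                null.append(abs(naive_stat(X[r], g1)))
        assert n_null == len(null)
        for r in range(2):
            expected = (1 + sum(v >= abs(naive_stat(X[r], (0, 1, 2))) for v in null)) / (
                1 + len(null)
            )
            assert p[r] == pytest.approx(expected, abs=1e-12)

    def test_seeded_reproducibility(self, rng):
        X = np.random.default_rng(5).normal(size=(20, 18))
        cols1, cols2 = np.arange(9), np.arange(9, 18)
        cfg = TestConfig(n_permutations=200, seed=9)
        _, p1, _ = permutation_null(X, cols1, cols2, "t", cfg)
        _, p2, _ = permutation_null(X, cols1, cols2, "t", cfg)
        assert np.array_equal(p1, p2)
        assert p1.min() >= 1 / (1 + 200 * 20) and p1.max() <= 1.0


class TestStouffer:
    def test_equal_halves_concordant(self):
        p = stouffer_combine([0.5], [1.0], [0.5], [1.0])
        assert p[0] == pytest.approx(0.340, abs=1e-3)

    def test_opposite_signs_cancel(self):
        p = stouffer_combine([0.2], [1.0], [0.2], [-1.0])
        assert p[0] == pytest.approx(1.0)

    def test_concordant_small_p(self):
        p = stouffer_combine([0.05], [1.0], [0.05], [1.0])
        assert p[0] == pytest.approx(0.00558, abs=5e-5)

    def test_zero_p_clamped_not_crashing(self):
        p = stouffer_combine([0.0], [1.0], [0.01], [1.0])
        assert 0.0 < p[0] < 0.01

    @given(
        p1=st.floats(0.001, 1.0),
        p2=st.floats(0.001, 1.0),
        delta=st.floats(0.0005, 0.5),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_each_p_at_concordant_signs(self, p1, p2, delta):
        lo = stouffer_combine([max(p1 - delta, 1e-6)], [1.0], [p2], [1.0])
        hi = stouffer_combine([p1], [1.0], [p2], [1.0])
        assert lo[0] <= hi[0] + 1e-12


def storey_oracle(p, lam):
    """Naive step-down reference implementation."""
    m = len(p)
    pi0 = min(1.0, sum(v > lam for v in p) / ((1 - lam) * m))
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    best = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pi0 * m * p[i] / rank)
        q[i] = min(best, 1.0)
    return q


class TestStoreyFdr:
    def test_all_ones(self):
        assert storey_fdr(np.ones(5)).tolist() == [1.0] * 5

    def test_hand_case_m4(self):
        q = storey_fdr(np.array([0.01, 0.02, 0.8, 0.9]), 0.5)
        assert np.allclose(q, [0.04, 0.04, 0.9, 0.9])

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20),
        st.sampled_from([0.25, 0.5, 0.75]),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_oracle(self, p, lam):
        q = storey_fdr(np.array(p), lam)
        expected = storey_oracle(p, lam)
        assert np.allclose(q, expected, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q = storey_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_uniform_p_pi0_near_one(self):
        p = np.random.default_rng(3).uniform(size=10_000)
        lam = 0.5
        pi0 = min(1.0, (p > lam).sum() / ((1 - lam) * len(p)))
        assert 0.9 <= pi0 <= 1.0  # binomial: sd of pi0-hat ~ 0.01
        q = storey_fdr(p, lam)
        assert q.min() > 0 and q.max() <= 1.0


class TestRollup:
    def make_results(self, entries):
        """entries: (peptide, protein, q, ratio)."""
        df = pd.DataFrame(entries, columns=["peptide_id", "protein_id", "q_value",
                                            "log2_median_ratio"])
        df["t_value"] = np.sign(df["log2_median_ratio"])
        prots = df.set_index("peptide_id")["protein_id"]
        return df.drop(columns="protein_id"), prots

    def test_single_significant_peptide_makes_dep_up(self):
        res, prots = self.make_results(
            [("a1", "A", 0.05, 1.2), ("a2", "A", 0.5, 0.1)]
        )
        pep, prot = select_and_rollup(res, prots)
        row = prot.set_index("protein_id").loc["A"]
        assert row["is_dep"] and row["direction"] == "up"
        assert row["n_significant_peptides"] == 1

    def test_conflicting_significant_siblings_flagged_mixed(self):
        res, prots = self.make_results(
            [("a1", "A", 0.01, 1.0), ("a2", "A", 0.01, -0.9)]
        )
        _, prot = select_and_rollup(res, prots)
        assert prot.set_index("protein_id").loc["A", "direction"] == "mixed"

    def test_fold_and_fdr_are_conjunctive(self):
        res, prots = self.make_results(
            [("a1", "A", 0.09, 0.3)]  # q passes, |ratio| < log2(1.5)
        )
        pep, prot = select_and_rollup(res, prots)
        assert not pep["significant"].any()
        assert not prot["is_dep"].any()

    def test_protein_log2fc_is_median_of_significant_siblings(self):
        res, prots = self.make_results(
            [("a1", "A", 0.01, 1.0), ("a2", "A", 0.01, 2.0), ("a3", "A", 0.9, -5.0)]
        )
        _, prot = select_and_rollup(res, prots)
        assert prot.set_index("protein_id").loc["A", "protein_log2fc"] == 1.5


class TestEndToEndCohortStatistics:
    def test_planted_effects_recovered(self, rng):
        """9v9 subject-level table with strong planted shifts: DEPs found."""
        subs, meta = subject_meta(9, 9)
        n_prot, pep_per = 30, 3
        rows, prots, planted = [], {}, {}
        for pi in range(n_prot):
            lfc = 1.0 if pi < 5 else (-1.0 if pi < 10 else 0.0)
            planted[f"P{pi}"] = lfc
            for k in range(pep_per):
                pep = f"P{pi}.{k}"
                prots[pep] = f"P{pi}"
                vals = np.concatenate(
                    [rng.normal(20 + lfc, 0.3, 9), rng.normal(20, 0.3, 9)]
                )
                rows.append(pd.Series(vals, index=subs, name=pep))
        table = pd.DataFrame(rows)
        pep_res, prot_res = run_differential_test(
            table, meta, pd.Series(prots),
            test_cfg=TestConfig(n_permutations=300, seed=4),
        )
        calls = prot_res.set_index("protein_id")
        de = {p for p, v in planted.items() if v != 0}
        recovered = {p for p in de if calls.loc[p, "is_dep"]}
        assert len(recovered) >= 0.9 * len(de)
        for p in recovered:
            expected = "up" if planted[p] > 0 else "down"
            assert calls.loc[p, "direction"] == expected
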