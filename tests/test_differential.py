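"""Rank tests, multiplicity adjustment, comparison driver, Venn algebra.

The WMW and BH oracles here are deliberately independent implementations
(exhaustive label enumeration; the literal step-up definition) so the
production paths are checked against first principles.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdiag import (ExpressionMatrix, SampleAnnotation, bh_adjust,
                     build_venn, run_comparison, shapiro_wilk, wmw_test)


# --- independent oracles --------------------------------------------------

def wmw_exact_oracle(a, b):
    """Two-sided exact WMW p by brute-force enumeration of all labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n, n_a = len(pooled), len(a)

    def u_stat(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in range(n) if i not in group_a_idx]
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_stat(tuple(range(n_a)))
    us = [u_stat(idx) for idx in combinations(range(n), n_a)]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def bh_stepup_oracle(p):
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# --- wmw_test -------------------------------------------------------------

class TestWmw:
    def test_complete_separation_small_groups(self):
        u, p = wmw_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.10)  # 2/20 labelings as extreme

    def test_interleaved_pairs(self):
        _, p = wmw_test([1, 3], [2, 4])
        assert p == pytest.approx(2 / 3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wmw_test([], [1.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_enumeration_oracle(self, data):
        """Exact path vs brute-force enumeration for n <= 10, no ties."""
        n_a = data.draw(st.integers(2, 5))
        n_b = data.draw(st.integers(2, 10 - n_a))
        pool = data.draw(st.lists(
            st.floats(-50, 50, allow_nan=False),
            min_size=n_a + n_b, max_size=n_a + n_b, unique=True))
        a, b = pool[:n_a], pool[n_a:]
        u, p = wmw_test(a, b)
        u_ref, p_ref = wmw_exact_oracle(a, b)
        assert u == pytest.approx(u_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=8,
                    max_size=30, unique=True))
    def test_invariant_under_monotone_transform(self, pool):
        """A rank test cannot see strictly monotone re-expressions."""
        pool = [x / 100 for x in pool]  # well-separated reals
        a, b = pool[: len(pool) // 2], pool[len(pool) // 2:]
        _, p1 = wmw_test(a, b)
        f = lambda x: np.exp(0.3 * np.asarray(x)) + 5
        _, p2 = wmw_test(f(a), f(b))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_null_type_one_error_rate(self, rng):
        """Under H0 the rejection rate at alpha=0.05 is near nominal."""
        rejections = sum(
            wmw_test(rng.normal(size=12), rng.normal(size=12))[1] < 0.05
            for _ in range(2000))
        assert rejections / 2000 == pytest.approx(0.05, abs=0.017)


# --- shapiro_wilk -----------------------------------------------------------

class TestShapiro:
    def test_normal_quantiles_fit_well(self):
        from scipy import stats
        grid = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        _, p = shapiro_wilk(grid)
        assert p > 0.5

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 1.0, 1.0, 1.0])

    def test_lognormal_sample_rejected_as_normal(self, rng):
        values = np.exp(rng.normal(size=50))
        _, p = shapiro_wilk(values)
        assert p < 0.05


# --- bh_adjust --------------------------------------------------------------

class TestBH:
    def test_hand_computed_example(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.002])
        assert out == pytest.approx([0.02, 0.04, 0.04, 0.008])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 6) == pytest.approx([0.2] * 6)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_literal_stepup_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p),
                                                 abs=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


# --- run_comparison ---------------------------------------------------------

def _tiny_dataset():
    import pandas as pd
    frame = pd.DataFrame({"mir-a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                         index=[f"s{i}" for i in range(6)])
    matrix = ExpressionMatrix(frame, stage="normalized")
    annotation = SampleAnnotation.from_labels(
        list(frame.index), ["PDAC"] * 3 + ["healthy"] * 3)
    return matrix, annotation


class TestRunComparison:
    def test_single_mirna_clear_separation(self):
        matrix, annotation = _tiny_dataset()
        result = run_comparison(matrix, annotation, "PDAC", "healthy")
        row = result.table.loc["mir-a"]
        assert row["raw_p"] == pytest.approx(0.10)
        assert row["adjusted_p"] == pytest.approx(0.10)  # m = 1
        assert not row["significant"]
        assert row["median_diff"] == pytest.approx(2.0 - 5.0)

    def test_absent_class_rejected(self):
        matrix, annotation = _tiny_dataset()
        with pytest.raises(ValueError):
            run_comparison(matrix, annotation, "PDAC", "CP")

    def test_recovers_planted_markers(self, small_normalized):
        matrix, annotation, truth, _ = small_normalized
        result = run_comparison(matrix, annotation, "PDAC", "healthy")
        planted = truth.differential_sets["PDAC_vs_healthy"]
        recovered = result.significant_set & planted
        assert len(recovered) >= 0.75 * len(planted)
        false_pos = result.significant_set - planted
        assert len(false_pos) <= 0.05 * len(matrix.mirna_ids) + 3

    def test_label_permutation_kills_discoveries(self, small_normalized,
                                                 rng):
        """BH controls the FDR: with class labels permuted the expected
        discovery count is ~0."""
        matrix, annotation, _, _ = small_normalized
        perm = annotation.table.copy()
        counts = []
        for _ in range(5):
            perm["class"] = rng.permutation(perm["class"].to_numpy())
            result = run_comparison(matrix, SampleAnnotation(perm),
                                    "PDAC", "healthy")
            counts.append(result.n_significant)
        assert np.mean(counts) <= 1.0

    def test_pvalue_ordering_invariant(self, small_normalized):
        matrix, annotation, _, _ = small_normalized
        result = run_comparison(matrix, annotation, "PDAC", "healthy")
        t = result.table
        assert ((t["raw_p"] <= t["adjusted_p"] + 1e-15).all())
        assert t["significant"].equals(t["adjusted_p"] < result.alpha)


# --- build_venn -------------------------------------------------------------

class TestVenn:
    def test_two_set_partition(self):
        venn = build_venn({"X": {"A", "B", "C"}, "Y": {"B", "C", "D"}})
        assert venn.regions["X"] == {"A"}
        assert venn.regions["X&Y"] == {"B", "C"}
        assert venn.regions["Y"] == {"D"}

    def test_identical_sets_share_everything(self):
        venn = build_venn({"X": {"A", "B"}, "Y": {"A", "B"}})
        assert venn.regions["X&Y"] == {"A", "B"}
        assert venn.regions["X"] == set() and venn.regions["Y"] == set()

    def test_three_sets_with_published_region_structure(self):
        """Exclusive regions of 87 (cancer-only), 18 (pancreatitis-only)
        and a 54-member shared disease signature — the region layout of a
        blood marker Venn."""
        shared = {f"s{i}" for i in range(54)}
        pdac_only = {f"p{i}" for i in range(87)}
        cp_only = {f"c{i}" for i in range(18)}
        venn = build_venn({"PDAC_vs_healthy": pdac_only | shared,
                           "CP_vs_healthy": cp_only | shared})
        sizes = venn.region_sizes
        assert sizes["PDAC_vs_healthy"] == 87
        assert sizes["CP_vs_healthy"] == 18
        assert sizes["PDAC_vs_healthy&CP_vs_healthy"] == 54

    def test_regions_partition_the_union(self, rng):
        universe = [f"m{i}" for i in range(60)]
        sets = {name: set(rng.choice(universe, size=rng.integers(5, 40),
                                     replace=False))
                for name in ("A", "B", "C")}
        venn = build_venn(sets)
        regions = list(venn.regions.values())
        union = set().union(*sets.values())
        assert set().union(*regions) == union
        assert sum(len(r) for r in regions) == len(union)

    def test_more_than_three_sets_unsupported(self):
        with pytest.raises(ValueError):
            build_venn({k: {k} for k in "ABCD"})
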