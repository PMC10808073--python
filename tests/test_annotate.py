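import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from exoatlas.annotate import (
    AnnotationResult,
    OverlapTable,
    annotate_clusters,
    build_overlap_table,
    chisq_overlap,
    group_clusters,
)
from exoatlas.core_io import MarkerReference
from oracles import chisq_oracle


def table_from(d):
    return OverlapTable(pd.DataFrame(d))


class TestOverlapTable:
    def test_set_intersection(self):
        ref = MarkerReference({"exo": {"g1", "g2"}})
        t = build_overlap_table({"c1": {"g1", "g3"}}, ref)
        assert t.table.loc["exo", "c1"] == 1

    def test_disjoint_cluster_gives_zero_column(self):
        ref = MarkerReference({"exo": {"g1"}, "endo": {"g2"}})
        t = build_overlap_table({"c1": {"x", "y"}}, ref)
        assert (t.table["c1"] == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(50)]
        cut = sorted(rng.choice(np.arange(1, 50), 3, replace=False))
        ref = MarkerReference(
            {
                "t0": set(genes[: cut[0]]),
                "t1": set(genes[cut[0] : cut[1]]),
                "t2": set(genes[cut[1] : cut[2]]),
            }
        )
        sets = {
            c: set(rng.choice(genes, rng.integers(1, 30), replace=False))
            for c in range(4)
        }
        t = build_overlap_table(sets, ref)
        for tissue in ref.sets:
            for c in sets:
                expected = sum(1 for g in sets[c] if g in ref.sets[tissue])
                assert t.table.loc[tissue, c] == expected
        # disjointness of reference bounds the column sum
        for c in sets:
            assert t.table[c].sum() <= len(sets[c])


class TestChisqOverlap:
    def test_uniform_column_is_null(self):
        for variant in ("standard", "as_printed"):
            r = chisq_overlap({"a": 5, "b": 5, "c": 5, "d": 5}, variant=variant)
            assert (r.O1, r.E1, r.O2, r.E2) == (5, 5, 15, 15)
            assert r.statistic == 0.0 and r.p == 1.0 and not r.significant

    def test_skewed_column_both_variants(self):
        col = {"a": 9, "b": 1, "c": 1, "d": 1}
        r = chisq_overlap(col, variant="standard")
        assert (r.O1, r.E1, r.O2, r.E2) == (9, 3, 3, 9)
        assert np.isclose(r.statistic, 36 / 3 + 36 / 9)  # 16.0
        r2 = chisq_overlap(col, variant="as_printed")
        assert np.isclose(r2.statistic, 36 / 9 + 36 / 81)  # ~4.444

    def test_concentrated_column_significant(self):
        r = chisq_overlap({"a": 10, "b": 0, "c": 0, "d": 0})
        assert np.isclose(r.statistic, 30.0)
        p = scipy.stats.chi2.sf(30.0, 1)
        assert np.isclose(r.p, p)
        assert r.p_corrected == min(1.0, 4 * p) and r.p_corrected < 0.01

    def test_zero_column(self):
        r = chisq_overlap({"a": 0, "b": 0}, n_tissues=2)
        assert r.p == 1.0 and not r.significant

    def test_small_family_rejected(self):
        with pytest.raises(ValueError, match="N >= 2"):
            chisq_overlap({"a": 3}, n_tissues=1)

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            chisq_overlap({"a": 1, "b": 2}, variant="bogus")

    @given(
        st.integers(2, 12),
        st.lists(st.integers(0, 500), min_size=2, max_size=12),
        st.sampled_from(["standard", "as_printed"]),
    )
    @settings(max_examples=200)
    def test_matches_arithmetic_oracle(self, n, counts, variant):
        counts = counts[:n] + [0] * max(0, n - len(counts))
        if sum(counts) == 0:
            counts[0] = 1
        col = {f"t{i}": v for i, v in enumerate(counts)}
        r = chisq_overlap(col, n_tissues=len(col), variant=variant)
        stat, p, pc = chisq_oracle(counts, len(col), variant)
        assert abs(r.statistic - stat) < 1e-12
        assert abs(r.p - p) < 1e-12
        assert abs(r.p_corrected - pc) < 1e-12
        # bookkeeping identities
        assert np.isclose(r.O1 + r.O2, sum(counts))
        assert np.isclose(r.E1 + r.E2, sum(counts))

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=8), st.integers(0, 100))
    @settings(max_examples=100)
    def test_invariant_to_non_max_permutation(self, counts, seed):
        if sum(counts) == 0:
            counts[0] = 1
        rng = np.random.default_rng(seed)
        shuffled = list(counts)
        rng.shuffle(shuffled)
        a = chisq_overlap({f"t{i}": v for i, v in enumerate(counts)})
        b = chisq_overlap({f"t{i}": v for i, v in enumerate(shuffled)})
        assert np.isclose(a.statistic, b.statistic)

    def test_statistic_increases_with_concentration(self):
        """Holding the total fixed, a larger maximum is more extreme."""
        total = 60
        prev = -1.0
        for o1 in range(30, 61, 10):
            col = {"a": o1, "b": total - o1, "c": 0, "d": 0}
            stat = chisq_overlap(col).statistic
            assert stat > prev
            prev = stat


class TestAnnotateClusters:
    def test_iterative_assignment_worked_example(self):
        t = table_from({"c": {"exo": 20, "endo": 15, "cortex": 1, "epi": 0}})
        ann = annotate_clusters(t)
        assert ann.labels["c"] == ["exo", "endo"]
        assert ann.primary("c") == "exo"
        r1, r2, r3 = ann.results["c"]
        assert (r1.O1, r1.E1, r1.O2, r1.E2) == (20, 9, 16, 27)
        assert np.isclose(r1.statistic, 11**2 / 9 + 11**2 / 27)
        assert np.isclose(r2.statistic, (15 - 16 / 3) ** 2 / (16 / 3)
                          + (1 - 32 / 3) ** 2 / (32 / 3))
        assert np.isclose(r3.statistic, 1.0)
        assert np.isclose(r3.p_corrected, 2 * scipy.stats.chi2.sf(1.0, 1))
        assert not r3.significant

    def test_all_zero_column_unassigned(self):
        t = table_from({"c": {"a": 0, "b": 0, "d": 0}})
        ann = annotate_clusters(t)
        assert ann.primary("c") == "unassigned"
        assert ann.labels["c"] == []

    def test_tie_flag_and_lexicographic_break(self):
        t = table_from({"c": {"b": 7, "a": 7, "z": 0}})
        ann = annotate_clusters(t, alpha=0.5)
        assert ann.results["c"][0].tie
        assert ann.results["c"][0].tissue == "a"

    def test_max_rank_caps_iteration(self):
        t = table_from({"c": {"a": 50, "b": 40, "d": 30, "e": 20, "f": 0}})
        ann = annotate_clusters(t, alpha=0.999999, max_rank=3)
        assert len(ann.labels["c"]) <= 3

    def test_family_size_decrements_between_ranks(self):
        t = table_from({"c": {"a": 30, "b": 20, "d": 1, "e": 0}})
        ann = annotate_clusters(t, alpha=0.9999)
        fams = [round(r.p_corrected / r.p, 6) for r in ann.results["c"]
                if r.p_corrected < 1.0]
        assert fams == sorted(fams, reverse=True)


class TestGroupClusters:
    def test_identity_grouping(self):
        out = group_clusters({"c1": "exo", "c2": "exo"}, {"exo": "exo"})
        assert out == {"c1": "exo", "c2": "exo"}

    def test_unassigned_passes_through(self):
        out = group_clusters({"c1": "unassigned"}, {})
        assert out["c1"] == "unassigned"

    def test_unmapped_label_is_error(self):
        with pytest.raises(KeyError, match="unmapped label endo"):
            group_clusters({"c3": "endo"}, {"exo": "ground"})
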