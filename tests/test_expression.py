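"""Differential calls, FDR, Venn intersections, contingency, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from hsfchip import expression as expr
from hsfchip import datasets


def records(*rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "system", "fold_change", "fdr_p"]
    )


class TestDifferentialCalls:
    def test_strongly_induced_gene_called_up(self):
        calls = expr.differential_calls(
            records(("Hsp70Bbb", "cells", 41.9, 2.00e-10))
        )
        assert calls["status"].iloc[0] == "up"

    def test_weak_fold_unchanged(self):
        calls = expr.differential_calls(records(("CG32850", "larvae", 1.2, 0.70)))
        assert calls["status"].iloc[0] == "unchanged"

    def test_boundaries_inclusive_fold_strict_alpha(self):
        calls = expr.differential_calls(
            records(
                ("at_alpha", "cells", 2.0, 0.01),   # p not < alpha
                ("at_fold", "cells", 2.0, 0.009),   # fold inclusive
                ("down", "cells", -2.0, 0.001),
            )
        )
        assert list(calls["status"]) == ["unchanged", "up", "down"]

    def test_duplicate_gene_system_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            expr.differential_calls(
                records(("g", "cells", 3.0, 0.001), ("g", "cells", 2.0, 0.001))
            )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert expr.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_textbook_step_up(self):
        np.testing.assert_allclose(expr.bh_fdr([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_order_invariance(self):
        p = np.array([0.4, 0.01, 0.2, 0.05])
        adjusted = expr.bh_fdr(p)
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(expr.bh_fdr(p[perm]), adjusted[perm])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, pvals):
        """Independent implementation of the Benjamini-Hochberg definition."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(expr.bh_fdr(p), oracle, atol=1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            expr.bh_fdr([0.5, 1.5])


class TestIntersections:
    def test_disjoint_inputs(self):
        counts = expr.intersect_lists({"a"}, {"b"}, {"c"})
        assert counts.all_three == 0
        assert counts.total_union == 3

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(60)]
        bound = set(rng.choice(universe, 25, replace=False))
        a = set(rng.choice(universe, 20, replace=False))
        b = set(rng.choice(universe, 30, replace=False))
        counts = expr.intersect_lists(bound, a, b)
        assert counts.total_union == len(bound | a | b)

    def test_published_one_system_fraction(self):
        """211 and 237 DE genes sharing 33 -> 92% single-system."""
        fraction = expr.one_system_fraction_from_counts(211, 237, 33)
        assert 100 * fraction == pytest.approx(92.0, abs=0.1)

    def test_fraction_matches_set_based_computation(self):
        a = {f"a{i}" for i in range(178)} | {f"s{i}" for i in range(33)}
        b = {f"b{i}" for i in range(204)} | {f"s{i}" for i in range(33)}
        counts = expr.intersect_lists(set(), a, b)
        assert counts.one_system_fraction == pytest.approx(
            expr.one_system_fraction_from_counts(211, 237, 33)
        )


class TestGeneSiteAssociation:
    def test_rules(self, simple_annotation):
        import pandas as pd
        from hsfchip.segments import BoundSegment

        def seg_at(center):
            probe = pd.DataFrame(
                [
                    {
                        "chrom": "chr1",
                        "start": center - 30,
                        "end": center + 30,
                        "fold": 10.0,
                        "pxbar": 1e-6,
                    }
                ]
            )
            return BoundSegment.from_probes(probe)

        # geneA spans 10_000..14_500 (TSS 10_000)
        inside_body = seg_at(13_900)     # rule (a): peak in transcribed span
        near_tss = seg_at(9_000)         # rule (b): TSS within 1250 of peak
        too_far = seg_at(8_600)          # 1 400 bp upstream, outside gene body
        assert expr.gene_site_association(simple_annotation, [inside_body]) == {"geneA"}
        assert "geneA" in expr.gene_site_association(simple_annotation, [near_tss])
        assert "geneA" not in expr.gene_site_association(simple_annotation, [too_far])
        assert expr.gene_site_association(simple_annotation, []) == set()


class TestDistances:
    def test_peak_at_tss_and_median(self):
        genes = {
            "g0": ("chr1", 1_000, "+"),
            "g1": ("chr1", 1_010, "+"),
            "g2": ("chr1", 1_020, "+"),
            "g3": ("chr1", 1_030, "+"),
        }
        peaks = [("chr1", 1_000)]
        frame, summary = expr.distance_to_nearest_site(genes, peaks)
        by_gene = dict(zip(frame["gene_id"], frame["distance"]))
        assert by_gene["g0"] == 0
        assert summary["median"] == pytest.approx(15.0)

    def test_masked_gap_pushes_distance_beyond_gap(self, small_study):
        """A gene behind the probe-free super-gap has no nearby callable site."""
        masks = small_study.masks.sort_values("end")
        gap = masks.iloc[(masks["end"] - masks["start"]).argmax()]
        peaks = [(s.chrom, s.peak) for s in small_study.truth.planted_segments]
        mid = int((gap["start"] + gap["end"]) // 2)
        frame, _ = expr.distance_to_nearest_site(
            {"gap_gene": (gap["chrom"], mid, "+")}, peaks
        )
        gap_half = int(gap["end"] - gap["start"]) // 2
        assert abs(frame["distance"].iloc[0]) >= gap_half

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError):
            expr.distance_to_nearest_site({"g": ("chr1", 0, "+")}, [])


class TestChi2:
    def test_published_contingency_table(self):
        """3/11 vs 66/104 BEAF-bound promoters: chi2 ~5.43, p ~0.0198."""
        result = expr.chi2_2x2([[3, 8], [66, 38]])
        assert result.chi2 == pytest.approx(5.43, abs=0.01)
        assert result.p_value == pytest.approx(0.0198, abs=0.0001)

    def test_balanced_table_null(self):
        result = expr.chi2_2x2([[10, 10], [10, 10]])
        assert result.chi2 == 0.0
        assert result.p_value == 1.0

    def test_matches_textbook_formula_on_random_tables(self):
        """chi2 = N(ad-bc)^2 / (row and column marginal product), df=1."""
        rng = np.random.default_rng(9)
        for _ in range(1_000):
            a, b, c, d = rng.integers(1, 60, 4)
            result = expr.chi2_2x2([[a, b], [c, d]])
            n = a + b + c + d
            oracle = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert result.chi2 == pytest.approx(oracle, rel=1e-9)
            assert result.p_value == pytest.approx(stats.chi2.sf(oracle, 1), rel=1e-9)

    def test_zero_marginal_flagged(self):
        result = expr.chi2_2x2([[0, 0], [5, 7]])
        assert result.undefined and result.p_value == 1.0


class TestMotifInductionReport:
    def test_published_counts_reproduced(self):
        sets_ = datasets.beaf_contingency_sets()
        report = expr.motif_induction_report(
            sets_["induced_promoters"],
            sets_["noninduced_promoters"],
            sets_["motif_positive"],
            sets_["externally_bound"],
        )
        assert report.motif_pct_induced == pytest.approx(100 * 3 / 11)
        assert report.motif_pct_noninduced == pytest.approx(100 * 69 / 104)
        assert report.binding_test.p_value == pytest.approx(0.0198, abs=0.0001)
        frame = report.to_frame()
        assert frame.loc["promoters_with_both", "non_induced"] == 48

    def test_no_motifs_flagged_undefined(self):
        report = expr.motif_induction_report({"a"}, {"b", "c"}, set(), set())
        assert report.motif_pct_induced == 0.0
        assert report.motif_test.undefined

    def test_overlapping_groups_error(self):
        with pytest.raises(ValueError, match="both groups"):
            expr.motif_induction_report({"a"}, {"a", "b"}, set(), set())


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [8.0, 9.0]], index=["a", "b", "c"]
        )
        result = expr.cluster_profiles(matrix)
        assert result.linkage[0, 2] == 0.0
        # the identical pair ends up adjacent in the leaf ordering
        ia, ib = result.leaf_order.index("a"), result.leaf_order.index("b")
        assert abs(ia - ib) == 1

    def test_average_linkage_heights_hand_computed(self):
        """1-D profiles 0, 1, 5: merge (0,1) at 1, then with 5 at 4.5."""
        matrix = pd.DataFrame([[0.0], [1.0], [5.0]], index=["x", "y", "z"])
        result = expr.cluster_profiles(matrix)
        np.testing.assert_allclose(result.linkage[:, 2], [1.0, 4.5])

    def test_permutation_preserves_heights(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(8, 4)), index=list("abcdefgh"))
        shuffled = matrix.sample(frac=1.0, random_state=1)
        h1 = np.sort(expr.cluster_profiles(matrix).linkage[:, 2])
        h2 = np.sort(expr.cluster_profiles(shuffled).linkage[:, 2])
        np.testing.assert_allclose(h1, h2)

    def test_newick_round_trips_through_scipy_leaf_count(self):
        matrix = pd.DataFrame(
            np.arange(12, dtype=float).reshape(4, 3), index=list("abcd")
        )
        result = expr.cluster_profiles(matrix)
        assert result.newick.endswith(";")
        assert all(name in result.newick for name in "abcd")

    def test_non_finite_entries_error_names_genes(self):
        matrix = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            expr.cluster_profiles(matrix)


class TestTermEnrichment:
    def test_universal_term_p_one(self):
        background = {f"g{i}" for i in range(20)}
        frame = expr.term_enrichment({"g0", "g1"}, background, {"all": set(background)})
        assert frame["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_tail_oracle_small_case(self):
        background = {f"g{i}" for i in range(12)}
        term = {"g0", "g1", "g2"}
        gene_list = {"g0", "g1", "g2", "g5"}
        frame = expr.term_enrichment(gene_list, background, {"t": term})
        # P(X >= 3), X ~ Hypergeom(N=12, K=3, n=4): only k=3 possible
        from math import comb

        oracle = comb(3, 3) * comb(9, 1) / comb(12, 4)
        assert frame["p"].iloc[0] == pytest.approx(oracle)

    def test_empty_gene_list_all_p_one(self):
        background = {"a", "b"}
        frame = expr.term_enrichment(set(), background, {"t": {"a"}})
        assert (frame["p"] == 1.0).all()

    def test_gene_outside_background_errors(self):
        with pytest.raises(ValueError, match="not in background"):
            expr.term_enrichment({"x"}, {"a"}, {})
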