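import math

import pytest
from hypothesis import given, strategies as st

import tcrkit as tk
from tcrkit.annotate import ChainAnnotation
from tcrkit.stats import UndefinedStatisticError, repertoire_from_counts

counts_lists = st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=40)


def _ann(cdr3_aa, v="V1", j="J1", chain="TRA", count=1, productive=True):
    return ChainAnnotation(
        molecule_id=f"m-{cdr3_aa}-{count}", chain=chain, v_call=v, j_call=j, c_call="C1",
        cdr3_nt="TGT", cdr3_aa=cdr3_aa, productive=productive, count=count,
    )


class TestAggregate:
    def test_counts_merge_by_key(self):
        rep = tk.aggregate([_ann("CAF", count=2), _ann("CAF"), _ann("CAF")])
        assert rep.richness == 1 and rep.records[0].n == 4 and rep.N == 4

    def test_empty(self):
        rep = tk.aggregate([])
        assert rep.N == 0 and rep.records == []

    def test_mixed_chains_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            tk.aggregate([_ann("CAF", chain="TRA"), _ann("CWF", chain="TRB")])

    def test_nonproductive_excluded_by_default(self):
        rep = tk.aggregate([_ann("CAF"), _ann("", productive=False)])
        assert rep.N == 1
        rep_all = tk.aggregate([_ann("CAF"), _ann("", productive=False)], productive_only=False)
        assert rep_all.N == 2

    def test_simulator_abundances_recovered(self, small_sim):
        truth_by_id = {t.read_id: t for t in small_sim["read_truth"]}
        clone = {c.clonotype_id: c for c in small_sim["clonotypes"]}
        for chain in ("TRA", "TRB"):
            rep = tk.aggregate([a for a in small_sim["annotations"] if a.chain == chain])
            truth = {}
            for c, k in zip(small_sim["clonotypes"], small_sim["abundances"]):
                if c.chain == chain and k > 0:
                    key = (c.v_name, c.j_name, c.cdr3_aa)
                    truth[key] = truth.get(key, 0) + int(k)
            assert {r.key: r.n for r in rep.records} == truth


class TestD50:
    def test_hand_computed_case(self):
        rep = repertoire_from_counts([5, 1, 1, 1, 1, 1])
        assert tk.d50(rep) == pytest.approx(100.0 / 6, abs=1e-9)

    def test_uniform_repertoire_is_50(self):
        assert tk.d50(repertoire_from_counts([7] * 10)) == pytest.approx(50.0, abs=1e-9)

    def test_single_clone_degenerate_case(self):
        # literal application of the formula: k = 1 of R = 1 records
        assert tk.d50(repertoire_from_counts([42])) == 100.0

    def test_cap_restricts_denominator(self):
        rep = repertoire_from_counts([10] + [1] * 99)
        assert tk.d50(rep, cap=10) == pytest.approx(100.0 / 10, abs=1e-9)

    def test_empty_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            tk.d50(repertoire_from_counts([]))

    @given(counts_lists)
    def test_dominant_clone_gives_100_over_richness(self, counts):
        dominant = sum(counts) + 1
        rep = repertoire_from_counts(counts + [dominant])
        assert tk.d50(rep) == pytest.approx(100.0 / rep.richness, abs=1e-9)


class TestDiversityIndex:
    def test_all_singletons_is_100(self):
        assert tk.diversity_index(repertoire_from_counts([1] * 20)) == 100.0

    def test_monoclonal_is_0(self):
        assert tk.diversity_index(repertoire_from_counts([37])) == 0.0

    def test_hand_computed_case(self):
        rep = repertoire_from_counts([2, 1, 1])
        assert tk.diversity_index(rep) == pytest.approx((1 - 2 / 12) * 100, abs=1e-9)

    def test_undefined_below_two_reads(self):
        with pytest.raises(UndefinedStatisticError):
            tk.diversity_index(repertoire_from_counts([1]))

    @given(counts_lists)
    def test_permutation_invariant(self, counts):
        a = tk.diversity_index(repertoire_from_counts(counts))
        b = tk.diversity_index(repertoire_from_counts(counts[::-1]))
        assert a == pytest.approx(b, abs=1e-12)

    @given(counts_lists)
    def test_evening_out_strictly_increases(self, counts):
        """Moving one read from the largest clone to a new singleton raises Di."""
        counts = sorted(counts, reverse=True)
        if counts[0] < 2:
            counts[0] = 2
        before = tk.diversity_index(repertoire_from_counts(counts))
        evened = [counts[0] - 1] + counts[1:] + [1]
        after = tk.diversity_index(repertoire_from_counts(evened))
        assert after > before


class TestDiversityCurve:
    def test_uniform_traces_diagonal(self):
        curve = tk.diversity_curve(repertoire_from_counts([5] * 4))
        assert curve == [(25.0, 25.0), (50.0, 50.0), (75.0, 75.0), (100.0, 100.0)]

    def test_hand_computed_case(self):
        assert tk.diversity_curve(repertoire_from_counts([9, 1])) == [(50.0, 90.0), (100.0, 100.0)]

    @given(counts_lists)
    def test_weakly_above_diagonal_and_ends_at_100(self, counts):
        curve = tk.diversity_curve(repertoire_from_counts(counts))
        assert curve[-1] == (100.0, 100.0)
        for x, y in curve:
            assert y >= x - 1e-9
        xs, ys = zip(*curve)
        assert list(xs) == sorted(xs) and list(ys) == sorted(ys)

    def test_subsampling_keeps_endpoint(self):
        curve = tk.diversity_curve(repertoire_from_counts([1] * 500), n_points=50)
        assert len(curve) == 50 and curve[-1] == (100.0, 100.0)


class TestTreemap:
    def test_single_clonotype_fills_canvas(self):
        layout = tk.treemap(repertoire_from_counts([5]), canvas=(10.0, 4.0))
        (r,) = layout.rectangles
        assert (r["x"], r["y"], r["w"], r["h"]) == (0.0, 0.0, 10.0, 4.0)

    def test_two_clone_areas(self):
        layout = tk.treemap(repertoire_from_counts([3, 1]), canvas=(1.0, 1.0))
        areas = sorted(r["w"] * r["h"] for r in layout.rectangles)
        assert areas == pytest.approx([0.25, 0.75], rel=1e-6)

    @given(counts_lists)
    def test_area_conservation_and_proportionality(self, counts):
        rep = repertoire_from_counts(counts)
        layout = tk.treemap(rep, canvas=(100.0, 60.0))
        total_area = sum(r["w"] * r["h"] for r in layout.rectangles)
        assert total_area == pytest.approx(100.0 * 60.0, rel=1e-6)
        for r in layout.rectangles:
            assert r["w"] * r["h"] == pytest.approx(r["n"] / rep.N * 6000.0, rel=1e-6)

    def test_no_overlap(self):
        layout = tk.treemap(repertoire_from_counts([8, 5, 4, 2, 1, 1]), canvas=(10.0, 10.0))
        rects = layout.rectangles
        for i, a in enumerate(rects):
            for b in rects[i + 1 :]:
                dx = min(a["x"] + a["w"], b["x"] + b["w"]) - max(a["x"], b["x"])
                dy = min(a["y"] + a["h"], b["y"] + b["h"]) - max(a["y"], b["y"])
                assert min(dx, dy) <= 1e-9  # touching edges allowed, area overlap not

    def test_bad_canvas_rejected(self):
        with pytest.raises(ValueError):
            tk.treemap(repertoire_from_counts([1]), canvas=(0.0, 5.0))


class TestVUsage:
    def test_single_v_is_100(self):
        rep = tk.aggregate([_ann("CAF", v="V1")])
        assert tk.v_usage(rep).rows == [("V1", pytest.approx(100.0))]

    def test_proportions(self):
        rep = tk.aggregate([_ann("CAF", v="V1", count=3), _ann("CWF", v="V2")])
        assert tk.v_usage(rep).rows == [("V1", pytest.approx(75.0)), ("V2", pytest.approx(25.0))]

    def test_other_row_completes_to_100(self):
        anns = [_ann(f"CA{i}F", v=f"V{i}", count=i + 1) for i in range(15)]
        usage = tk.v_usage(tk.aggregate(anns), top_n=10)
        assert usage.rows[-1][0] == "other"
        assert sum(p for _, p in usage.rows) == pytest.approx(100.0, abs=1e-9)
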