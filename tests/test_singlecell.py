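import numpy as np
import pytest

import tcrkit as tk
from tcrkit.singlecell import CellChain, CellChainSet, CellQCRecord, InputError

from conftest import expansion_histogram_oracle


def _chain(chain, cdr3, v="V1", j="J1", c="C1"):
    return CellChain(chain=chain, v_call=v, j_call=j, c_call=c, cdr3_aa=cdr3)


def _cell(bc, *specs):
    return CellChainSet(bc, [_chain(ch, aa) for ch, aa in specs])


A1, A2 = ("TRA", "CAF"), ("TRA", "CGF")
B1, B2 = ("TRB", "CASSF"), ("TRB", "CAWWF")


class TestBuildClonotypes:
    def test_matching_pairs_group(self):
        cells = [_cell("A", A1, B1), _cell("B", A1, B1), _cell("C", A2, B2)]
        cts = tk.build_clonotypes(cells)
        assert [ct.frequency for ct in cts] == [2, 1]
        assert sum(ct.frequency for ct in cts) == 3

    def test_multi_chain_key_uses_set_equality(self):
        triple = [A1, A2, B1]
        cells = [
            _cell("A", *triple),
            _cell("B", *triple[::-1]),  # order must not matter
            _cell("C", A1, B1),         # subset is a different clonotype
        ]
        cts = tk.build_clonotypes(cells)
        assert sorted(ct.frequency for ct in cts) == [1, 2]
        two = next(ct for ct in cts if ct.frequency == 2)
        assert set(two.member_cells) == {"A", "B"}

    def test_single_chain_cells_excluded_by_default(self):
        cells = [_cell("A", A1), _cell("B", A1, B1)]
        assert sum(ct.frequency for ct in tk.build_clonotypes(cells)) == 1
        kept = tk.build_clonotypes(cells, paired_only=False)
        assert sum(ct.frequency for ct in kept) == 2
        assert any(not ct.paired for ct in kept)

    def test_strict_mode_separates_by_genes(self):
        a = CellChainSet("A", [_chain("TRA", "CAF", v="V1"), _chain("TRB", "CASSF")])
        b = CellChainSet("B", [_chain("TRA", "CAF", v="V9"), _chain("TRB", "CASSF")])
        assert len(tk.build_clonotypes([a, b])) == 1
        assert len(tk.build_clonotypes([a, b], strict=True)) == 2

    def test_empty_input(self):
        assert tk.build_clonotypes([]) == []

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            tk.build_clonotypes([_cell("A", A1, B1), _cell("A", A2, B2)])


class TestLabelExpanded:
    def test_frequencies_2_1_1(self):
        cells = [_cell("A", A1, B1), _cell("B", A1, B1), _cell("C", A2, B2),
                 _cell("D", A2, B1)]
        labels, n_expanded = tk.label_expanded(tk.build_clonotypes(cells))
        assert n_expanded == 1
        expanded_cells = {l.cell_barcode for l in labels if l.expanded}
        assert expanded_cells == {"A", "B"}

    def test_all_singletons(self):
        cells = [_cell("A", A1, B1), _cell("B", A2, B2)]
        labels, n_expanded = tk.label_expanded(tk.build_clonotypes(cells))
        assert n_expanded == 0 and not any(l.expanded for l in labels)

    def test_matches_histogram_oracle_on_simulation(self, ref):
        cfg = tk.SimulationConfig(seed=21, n_cells=300, sc_richness=80)
        cells, _truth = tk.simulate_cells(ref, cfg)
        labels, n_expanded = tk.label_expanded(tk.build_clonotypes(cells))
        oracle_labels, oracle_n = expansion_histogram_oracle(cells)
        assert n_expanded == oracle_n
        assert {l.cell_barcode: l.expanded for l in labels} == oracle_labels

    def test_stable_under_reordering(self):
        cells = [_cell("A", A1, B1), _cell("B", A1, B1), _cell("C", A2, B2)]
        l1, _ = tk.label_expanded(tk.build_clonotypes(cells))
        l2, _ = tk.label_expanded(tk.build_clonotypes(cells[::-1]))
        assert l1 == l2


class TestClusterCalls:
    def _labels(self, n_expanded, n_total, cluster="c0"):
        labels = [tk.singlecell.ExpansionLabel(f"{cluster}-{i}", i < n_expanded) for i in range(n_total)]
        assignment = {l.cell_barcode: cluster for l in labels}
        return labels, assignment

    def test_exact_boundary_is_expanded(self):
        labels, assignment = self._labels(3, 20)
        (call,) = tk.call_expanded_clusters(labels, assignment)
        assert call.fraction_expanded == pytest.approx(0.15)
        assert call.phenotype == "Expanded"

    def test_below_boundary(self):
        labels, assignment = self._labels(2, 20)
        (call,) = tk.call_expanded_clusters(labels, assignment)
        assert call.phenotype == "NotExpanded"

    def test_missing_cluster_lists_barcodes(self):
        labels, assignment = self._labels(1, 3)
        del assignment["c0-1"]
        with pytest.raises(InputError, match="c0-1"):
            tk.call_expanded_clusters(labels, assignment)

    def test_invariant_to_cluster_relabeling(self):
        la, aa = self._labels(3, 10, "x")
        lb, ab = self._labels(5, 12, "y")
        calls = tk.call_expanded_clusters(la + lb, {**aa, **ab})
        renamed = {bc: {"x": "7", "y": "3"}[cl] for bc, cl in {**aa, **ab}.items()}
        calls2 = tk.call_expanded_clusters(la + lb, renamed)
        key = lambda c: (c.n_cells, c.n_expanded, c.phenotype)
        assert sorted(map(key, calls)) == sorted(map(key, calls2))


class TestTopClonotypeTable:
    def _clonotypes_with_total(self, freqs, total):
        cells = []
        i = 0
        for f in freqs:
            aa = f"CAX{i}F"
            for _ in range(f):
                cells.append(_cell(f"cell{len(cells)}", ("TRA", aa), ("TRB", "CB" + aa)))
            i += 1
        while len(cells) < total:
            aa = f"CS{len(cells)}F"
            cells.append(_cell(f"cell{len(cells)}", ("TRA", aa), ("TRB", "CB" + aa)))
        return tk.build_clonotypes(cells)

    def test_proportions_format_like_printed_table(self):
        # frequency 40 of 5731 cells → 0.698%; 20 → 0.349%
        cts = self._clonotypes_with_total([40, 20], 5731)
        rows = tk.top_clonotype_table(cts, n=2)
        assert rows[0]["frequency"] == 40 and rows[0]["proportion_pct"] == "0.698%"
        tra_rows = [r for r in rows if r["rank"] == 2]
        assert tra_rows[0]["frequency"] == 20 and tra_rows[0]["proportion_pct"] == "0.349%"

    def test_n_larger_than_count_returns_all(self):
        cts = self._clonotypes_with_total([2], 4)
        assert len(cts) == 3
        rows = tk.top_clonotype_table(cts, n=50)
        assert {r["rank"] for r in rows} == {1, 2, 3}

    def test_one_row_per_chain(self):
        cts = tk.build_clonotypes([_cell("A", A1, A2, B1)])
        rows = tk.top_clonotype_table(cts, n=1)
        assert [r["chain"] for r in rows] == ["TRA", "TRA", "TRB"]


class TestQCFilter:
    @pytest.mark.parametrize(
        "n_features, mito, expect",
        [
            (450, 0.01, False),   # too few features
            (500, 0.01, True),    # boundary passes
            (4000, 0.07, True),   # both boundaries pass
            (4001, 0.01, False),  # too many features
            (2000, 0.08, False),  # mitochondrial excess
            (2000, 0.07, True),
        ],
    )
    def test_rules(self, n_features, mito, expect):
        assert CellQCRecord("bc", n_features, mito).passes is expect

    def test_summary_counts_failing_both_once(self):
        cells = [
            CellQCRecord("a", 100, 0.5),   # fails both → counted under features
            CellQCRecord("b", 2000, 0.5),  # fails mito
            CellQCRecord("c", 2000, 0.01),
        ]
        passing, summary = tk.qc_filter(cells)
        assert [c.cell_barcode for c in passing] == ["c"]
        assert summary == {"input": 3, "passed": 1, "removed_by_features": 1, "removed_by_mito": 1}
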