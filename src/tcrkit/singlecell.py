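"""Paired single-cell αβ clonotypes, expansion labelling and cluster calls.

Cells are grouped into paired clonotypes by matching the CDR3 amino-acid
sequences of *all* their chains (both TCRα and TCRβ; cells carrying a second
TCRα keep it in the key).  A cell is *expanded* when its clonotype is found
in two or more cells; a transcriptome cluster has the *expanded phenotype*
when at least 15% of its cells are expanded (inclusive boundary).

Also included: the standard scRNA cell-quality filter used upstream of
clustering (500–4000 detected features, ≤7% mitochondrial reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class InputError(ValueError):
    pass


@dataclass
class CellChain:
    chain: str  # TRA or TRB
    v_call: str
    j_call: str
    c_call: str
    cdr3_aa: str
    umi_count: int = 1


@dataclass
class CellChainSet:
    cell_barcode: str
    chains: list[CellChain]


@dataclass
class PairedClonotype:
    key: tuple  # sorted unique (chain, cdr3_aa) pairs (strict mode adds V/J)
    member_cells: list[str]
    chains: list[CellChain]  # representative gene calls (first member cell)
    paired: bool = True  # has at least one TRA and one TRB

    @property
    def frequency(self) -> int:
        return len(self.member_cells)


@dataclass
class ExpansionLabel:
    cell_barcode: str
    expanded: bool


@dataclass
class ClusterExpansionCall:
    cluster_id: str
    n_cells: int
    n_expanded: int
    fraction_expanded: float
    phenotype: str  # "Expanded" | "NotExpanded"


@dataclass
class CellQCRecord:
    cell_barcode: str
    n_features: int
    mito_fraction: float

    @property
    def passes(self) -> bool:
        # strict reading of the printed rules: exclude < 500 or > 4000
        # features, exclude > 7% mitochondrial; boundary cells pass
        return 500 <= self.n_features <= 4000 and self.mito_fraction <= 0.07


def _cell_key(cell: CellChainSet, strict: bool) -> tuple:
    if strict:
        pairs = {(c.chain, c.v_call, c.j_call, c.cdr3_aa) for c in cell.chains}
    else:
        pairs = {(c.chain, c.cdr3_aa) for c in cell.chains}
    return tuple(sorted(pairs))


def build_clonotypes(
    cells: Sequence[CellChainSet],
    strict: bool = False,
    paired_only: bool = True,
) -> list[PairedClonotype]:
    """Group cells into clonotypes by matching the CDR3 amino acids of all chains.

    Two cells belong to one clonotype iff their chain key sets are identical
    (set semantics: a cell with chains α1, α2, β1 matches only cells with the
    same triple).  ``strict=True`` adds V/J genes to the key.  By default
    cells lacking either a TRA or a TRB (single-chain cells) are excluded
    from paired-clonotype counts; ``paired_only=False`` keeps them as
    flagged single-chain clonotypes.
    """
    seen: set[str] = set()
    for c in cells:
        if c.cell_barcode in seen:
            raise InputError(f"duplicate cell barcode {c.cell_barcode!r}")
        seen.add(c.cell_barcode)

    groups: dict[tuple, list[CellChainSet]] = {}
    for c in sorted(cells, key=lambda c: c.cell_barcode):
        if not c.chains:
            continue
        chains_present = {ch.chain for ch in c.chains}
        if paired_only and not {"TRA", "TRB"} <= chains_present:
            continue
        groups.setdefault(_cell_key(c, strict), []).append(c)

    out = []
    for key in sorted(groups):
        members = groups[key]
        rep = members[0]
        paired = {"TRA", "TRB"} <= {ch.chain for ch in rep.chains}
        out.append(
            PairedClonotype(
                key=key,
                member_cells=[m.cell_barcode for m in members],
                chains=sorted(rep.chains, key=lambda ch: (ch.chain, ch.cdr3_aa)),
                paired=paired,
            )
        )
    out.sort(key=lambda ct: (-ct.frequency, ct.key))
    return out


def label_expanded(
    clonotypes: Sequence[PairedClonotype], threshold: int = 2
) -> tuple[list[ExpansionLabel], int]:
    """Label every member cell; expanded ⇔ clonotype frequency ≥ threshold.

    Returns the per-cell labels plus the number of distinct expanded
    clonotypes.  The default threshold of 2 cells matches the study's
    definition ("found in 2 or more cells").
    """
    labels = []
    n_expanded_clonotypes = 0
    for ct in clonotypes:
        expanded = ct.frequency >= threshold
        n_expanded_clonotypes += int(expanded)
        labels.extend(ExpansionLabel(bc, expanded) for bc in ct.member_cells)
    labels.sort(key=lambda l: l.cell_barcode)
    return labels, n_expanded_clonotypes


def call_expanded_clusters(
    labels: Sequence[ExpansionLabel],
    cluster_assignment: Mapping[str, str],
    threshold: float = 0.15,
) -> list[ClusterExpansionCall]:
    """Call the expanded phenotype per cluster: ≥15% expanded cells (inclusive)."""
    missing = sorted(l.cell_barcode for l in labels if l.cell_barcode not in cluster_assignment)
    if missing:
        raise InputError(f"cells without cluster assignment: {', '.join(missing[:10])}")
    per: dict[str, list[bool]] = {}
    for l in labels:
        per.setdefault(str(cluster_assignment[l.cell_barcode]), []).append(l.expanded)
    out = []
    for cluster_id in sorted(per):
        flags = per[cluster_id]
        n, k = len(flags), sum(flags)
        frac = k / n
        out.append(
            ClusterExpansionCall(
                cluster_id=cluster_id,
                n_cells=n,
                n_expanded=k,
                fraction_expanded=frac,
                phenotype="Expanded" if frac >= threshold else "NotExpanded",
            )
        )
    return out


def top_clonotype_table(clonotypes: Sequence[PairedClonotype], n: int = 10) -> list[dict]:
    """Top-N clonotype table: one row per chain, with frequency and proportion.

    Proportions are over all cells carrying a clonotype and are additionally
    formatted as percent with three decimals (``0.698%`` style).
    """
    total = sum(ct.frequency for ct in clonotypes)
    rows = []
    for rank, ct in enumerate(clonotypes[:n], start=1):
        prop = ct.frequency / total if total else 0.0
        for ch in ct.chains:
            rows.append(
                {
                    "rank": rank,
                    "chain": ch.chain,
                    "v_call": ch.v_call,
                    "j_call": ch.j_call,
                    "c_call": ch.c_call,
                    "cdr3_aa": ch.cdr3_aa,
                    "frequency": ct.frequency,
                    "proportion": prop,
                    "proportion_pct": f"{100.0 * prop:.3f}%",
                }
            )
    return rows


def qc_filter(cells: Iterable[CellQCRecord]) -> tuple[list[CellQCRecord], dict]:
    """Apply the feature-count and mitochondrial-fraction cell filters.

    A cell failing both rules is counted once, under the feature rule.
    """
    passing = []
    summary = {"input": 0, "passed": 0, "removed_by_features": 0, "removed_by_mito": 0}
    for c in cells:
        summary["input"] += 1
        if not 500 <= c.n_features <= 4000:
            summary["removed_by_features"] += 1
        elif c.mito_fraction > 0.07:
            summary["removed_by_mito"] += 1
        else:
            summary["passed"] += 1
            passing.append(c)
    return passing, summary
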