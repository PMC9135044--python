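"""Clonotype aggregation and repertoire clonality/diversity statistics.

The two headline statistics follow immune-repertoire convention:

* **D50** — the percentage of unique CDR3 clonotypes (ranked by abundance,
  restricted to the top 10,000) whose cumulative count first reaches 50% of
  the total.  Low D50 = high clonality.
* **Diversity index (Di)** — a Simpson-type evenness statistic,
  ``Di = [1 − Σ n(n−1) / (N(N−1))] × 100`` over clone counts ``n`` with
  total ``N``; 100 for all-singleton repertoires, 0 for a monoclonal one.

Also provided: the diversity curve (cumulative % of reads vs % of unique
clonotypes; an even repertoire traces the diagonal), a two-level squarified
treemap layout (outer tiles per V gene, inner tiles per clonotype, areas
proportional to counts), and top-N V-usage tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .annotate import ChainAnnotation

KeyMode = Literal["vj_aa", "aa", "nt"]


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class ClonotypeRecord:
    key: tuple
    chain: str
    v_call: str
    j_call: str
    cdr3_aa: str
    n: int
    cdr3_nt_variants: set[str] = field(default_factory=set)


@dataclass
class Repertoire:
    chain: str
    records: list[ClonotypeRecord]

    @property
    def N(self) -> int:
        return sum(r.n for r in self.records)

    @property
    def richness(self) -> int:
        return len(self.records)

    def sorted_counts(self) -> list[int]:
        return [r.n for r in self.records]


def clonotype_key(a: ChainAnnotation, mode: KeyMode = "vj_aa") -> tuple:
    if mode == "vj_aa":
        return (a.v_call, a.j_call, a.cdr3_aa)
    if mode == "aa":
        return (a.cdr3_aa,)
    if mode == "nt":
        return (a.v_call, a.j_call, a.cdr3_nt)
    raise ValueError(f"unknown key mode {mode!r}")


def aggregate(
    annotations: Iterable[ChainAnnotation],
    key_mode: KeyMode = "vj_aa",
    productive_only: bool = True,
) -> Repertoire:
    """Aggregate single-chain annotations into a count-sorted Repertoire.

    Only productive annotations enter by default (standard repertoire
    practice).  Records are sorted descending by count with a lexicographic
    key tie-break, which fixes ranking-dependent statistics (D50, curves).
    """
    annotations = list(annotations)
    chains = {a.chain for a in annotations}
    if len(chains) > 1:
        raise ValueError(f"mixed chains in one repertoire: {sorted(chains)}; partition first")
    chain = chains.pop() if chains else "TRA"

    acc: dict[tuple, ClonotypeRecord] = {}
    for a in annotations:
        if productive_only and not a.productive:
            continue
        key = clonotype_key(a, key_mode)
        rec = acc.get(key)
        if rec is None:
            acc[key] = ClonotypeRecord(
                key=key, chain=a.chain, v_call=a.v_call, j_call=a.j_call,
                cdr3_aa=a.cdr3_aa, n=a.count, cdr3_nt_variants={a.cdr3_nt},
            )
        else:
            rec.n += a.count
            rec.cdr3_nt_variants.add(a.cdr3_nt)
    records = sorted(acc.values(), key=lambda r: (-r.n, r.key))
    return Repertoire(chain=chain, records=records)


def repertoire_from_counts(counts: Iterable[int], chain: str = "TRA") -> Repertoire:
    """Repertoire from a bare abundance vector (zeros dropped); for truth tables."""
    records = [
        ClonotypeRecord(key=(f"clone{i}",), chain=chain, v_call="", j_call="", cdr3_aa=f"clone{i}", n=int(n))
        for i, n in enumerate(counts) if n > 0
    ]
    records.sort(key=lambda r: (-r.n, r.key))
    return Repertoire(chain=chain, records=records)


def d50(rep: Repertoire, cap: int = 10000) -> float:
    """D50: % of unique clonotypes (top ``cap`` by count) cumulating to ≥50% of reads.

    Walking the count-sorted records, ``k`` is the minimal number of
    clonotypes whose cumulative count reaches at least half the restricted
    total; D50 = 100·k/R over R restricted records.  A monoclonal repertoire
    degenerately yields 100 (k = R = 1), documented rather than special-cased.
    """
    if not rep.records:
        raise UndefinedStatisticError("D50 undefined for an empty repertoire")
    counts = rep.sorted_counts()[: min(cap, len(rep.records))]
    total = sum(counts)
    half = total / 2
    cum = 0
    for k, n in enumerate(counts, start=1):
        cum += n
        if cum >= half:
            return 100.0 * k / len(counts)
    raise AssertionError("unreachable")


def diversity_index(rep: Repertoire) -> float:
    """Simpson-type diversity index ``[1 − Σ n(n−1)/(N(N−1))] × 100``."""
    N = rep.N
    if N < 2:
        raise UndefinedStatisticError("diversity index undefined for N < 2")
    s = sum(n * (n - 1) for n in rep.sorted_counts())
    return (1.0 - s / (N * (N - 1))) * 100.0


def diversity_curve(rep: Repertoire, n_points: int = 100) -> list[tuple[float, float]]:
    """Cumulative-share curve: point i = (100·i/R, 100·cum_i/N), clones count-sorted.

    Weakly above the diagonal by construction; ends at (100, 100).  When the
    repertoire holds more than ``n_points`` clonotypes the curve is evenly
    subsampled (always keeping the final point).
    """
    if not rep.records:
        raise UndefinedStatisticError("diversity curve undefined for an empty repertoire")
    N = rep.N
    R = rep.richness
    pts = []
    cum = 0
    for i, n in enumerate(rep.sorted_counts(), start=1):
        cum += n
        pts.append((100.0 * i / R, 100.0 * cum / N))
    if n_points and R > n_points:
        idx = sorted({round(j * (R - 1) / (n_points - 1)) for j in range(n_points)})
        pts = [pts[i] for i in idx]
    return pts


@dataclass
class TreemapLayout:
    canvas: tuple[float, float]
    rectangles: list[dict]  # x, y, w, h, v_group, key, n


def _squarify(sizes: list[float], x: float, y: float, w: float, h: float) -> list[tuple[float, float, float, float]]:
    """Squarified treemap layout (Bruls et al. style), sizes pre-sorted descending.

    Sizes must sum to w*h.  Deterministic; degenerate zero-area inputs are
    given zero-width slivers.
    """
    out: list[tuple[float, float, float, float]] = []
    sizes = list(sizes)
    while sizes:
        short = min(w, h)
        if short <= 0 or sum(sizes) <= 0:
            out.extend((x, y, 0.0, 0.0) for _ in sizes)
            break
        row = [sizes.pop(0)]
        while sizes:
            cur = _worst(row, short)
            nxt = _worst(row + [sizes[0]], short)
            if nxt <= cur:
                row.append(sizes.pop(0))
            else:
                break
        area = sum(row)
        if w >= h:  # lay the row vertically along the left edge
            rw = area / h
            yy = y
            for s in row:
                rh = s / rw if rw > 0 else 0.0
                out.append((x, yy, rw, rh))
                yy += rh
            x += rw
            w -= rw
        else:
            rh = area / w
            xx = x
            for s in row:
                rw = s / rh if rh > 0 else 0.0
                out.append((xx, y, rw, rh))
                xx += rw
            y += rh
            h -= rh
    return out


def _worst(row: list[float], short: float) -> float:
    """Worst aspect ratio of a row laid along a side of length ``short``."""
    total = sum(row)
    if total <= 0 or short <= 0 or min(row) <= 0:
        return float("inf")
    worst = 0.0
    for s in row:
        a = (short * short * s) / (total * total)
        worst = max(worst, a, 1.0 / a)
    return worst


def treemap(rep: Repertoire, canvas: tuple[float, float] = (100.0, 100.0)) -> TreemapLayout:
    """Two-level squarified treemap: outer tiles per V gene, inner per clonotype.

    Rectangle areas are proportional to clone counts; the union tiles the
    canvas exactly (up to float tolerance).
    """
    W, H = canvas
    if W <= 0 or H <= 0:
        raise ValueError("canvas dimensions must be positive")
    if not rep.records:
        raise UndefinedStatisticError("treemap undefined for an empty repertoire")
    N = rep.N
    groups: dict[str, list[ClonotypeRecord]] = {}
    for r in rep.records:  # records pre-sorted desc
        groups.setdefault(r.v_call, []).append(r)
    order = sorted(groups, key=lambda v: (-sum(r.n for r in groups[v]), v))
    outer_sizes = [sum(r.n for r in groups[v]) / N * W * H for v in order]
    outer = _squarify(outer_sizes, 0.0, 0.0, W, H)
    rects: list[dict] = []
    for v, (gx, gy, gw, gh) in zip(order, outer):
        members = groups[v]
        gn = sum(r.n for r in members)
        inner_sizes = [r.n / gn * gw * gh for r in members]
        for rec, (x, y, w, h) in zip(members, _squarify(inner_sizes, gx, gy, gw, gh)):
            rects.append({"x": x, "y": y, "w": w, "h": h, "v_group": v, "key": rec.key, "n": rec.n})
    return TreemapLayout(canvas=canvas, rectangles=rects)


@dataclass
class UsageTable:
    rows: list[tuple[str, float]]  # (segment or "other", percent of N)


def v_usage(rep: Repertoire, top_n: int = 10) -> UsageTable:
    """Percent of total count per V segment, descending; top-N plus an
    "other" remainder row when more segments exist."""
    if not rep.records:
        raise UndefinedStatisticError("usage undefined for an empty repertoire")
    N = rep.N
    totals: dict[str, int] = {}
    for r in rep.records:
        totals[r.v_call] = totals.get(r.v_call, 0) + r.n
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [(name, 100.0 * n / N) for name, n in ranked[:top_n]]
    if len(ranked) > top_n:
        rows.append(("other", 100.0 * sum(n for _, n in ranked[top_n:]) / N))
    return UsageTable(rows=rows)
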