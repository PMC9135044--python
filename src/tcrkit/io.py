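"""Readers and writers shared by all stages.

Formats: FASTQ (Phred+33, transparently gzipped by ``.gz`` suffix), FASTA +
anchor tables for germline references, AIRR-style rearrangement TSV for
annotations, CSV for statistics and suppression input, 10x-style contig CSV
for single-cell chains, and JSON for curves/treemaps/run summaries.  Minimal
SVG rendering of the diversity curve and treemap is included so no plotting
stack is required.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotate import ChainAnnotation
from .readproc import MergedRead, RawRead, ReadPair
from .singlecell import CellChain, CellChainSet
from .stats import Repertoire, TreemapLayout
from .suppression import ProliferationMeasurement


def _open(path: str | Path, mode: str = "rt"):
    path = str(path)
    if not path.endswith(".gz"):
        return open(path, mode)
    if "w" in mode:
        # mtime pinned to 0 and no FNAME header field, so identical content
        # gives identical bytes regardless of run time or file name
        import io as _io

        gz = gzip.GzipFile("", "wb", fileobj=open(path, "wb"), mtime=0)
        return _io.TextIOWrapper(gz) if "t" in mode else gz
    return gzip.open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ


def _phred_string(quals: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_fastq(reads: Iterable[RawRead | MergedRead], path: str | Path) -> int:
    n = 0
    with _open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{_phred_string(r.qualities)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> list[RawRead]:
    reads = []
    with _open(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            seq, plus, qual = fh.readline(), fh.readline(), fh.readline()
            lineno += 4
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"{path}: malformed FASTQ record ending at line {lineno}")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise ValueError(f"{path}: length mismatch in record ending at line {lineno}")
            reads.append(RawRead(header[1:].split()[0], seq.upper(), [ord(c) - 33 for c in qual]))
    return reads


def write_fastq_pairs(pairs: Sequence[ReadPair], fwd_path: str | Path, rev_path: str | Path) -> None:
    """Paired FASTQ; the dual index is carried in the header comment."""
    with _open(fwd_path, "wt") as f1, _open(rev_path, "wt") as f2:
        for p in pairs:
            tag = f" {p.dual_index}" if p.dual_index else ""
            f1.write(f"@{p.forward.read_id}{tag}\n{p.forward.sequence}\n+\n{_phred_string(p.forward.qualities)}\n")
            f2.write(f"@{p.reverse.read_id}{tag}\n{p.reverse.sequence}\n+\n{_phred_string(p.reverse.qualities)}\n")


def read_fastq_pairs(fwd_path: str | Path, rev_path: str | Path) -> list[ReadPair]:
    def parse(path):
        out = []
        with _open(path, "rt") as fh:
            recno = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                seq, plus, qual = fh.readline(), fh.readline(), fh.readline()
                recno += 1
                if not header.startswith("@") or not plus.startswith("+"):
                    raise ValueError(f"{path}: malformed FASTQ record {recno}")
                parts = header[1:].strip().split()
                dual = parts[1] if len(parts) > 1 else None
                seq, qual = seq.strip().upper(), qual.strip()
                if not seq or len(seq) != len(qual):
                    raise ValueError(f"{path}: malformed FASTQ record {recno} ({parts[0]})")
                out.append((parts[0], dual, RawRead(parts[0], seq, [ord(c) - 33 for c in qual])))
        return out

    fwd, rev = parse(fwd_path), parse(rev_path)
    if len(fwd) != len(rev):
        raise ValueError("forward/reverse FASTQ files differ in record count")
    pairs = []
    for (fid, dual, f), (rid, _, r) in zip(fwd, rev):
        if fid != rid:
            raise ValueError(f"read id mismatch between mates: {fid!r} vs {rid!r}")
        pairs.append(ReadPair(forward=f, reverse=r, dual_index=dual))
    return pairs


# ---------------------------------------------------------------------------
# barcode table


def write_barcode_table(table: dict[str, tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tdual_index\tinternal_barcode\n")
        for sample, (dual, bc) in table.items():
            fh.write(f"{sample}\t{dual}\t{bc}\n")


def read_barcode_table(path: str | Path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row["sample"]: (row["dual_index"], row["internal_barcode"]) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# AIRR-style rearrangement TSV

AIRR_COLUMNS = [
    "sequence_id", "locus", "v_call", "d_call", "j_call", "c_call",
    "junction", "junction_aa", "productive", "duplicate_count", "sample",
]


def write_airr(annotations: Sequence[ChainAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sequence_id": a.molecule_id,
            "locus": a.chain,
            "v_call": a.v_call,
            "d_call": a.d_call or "",
            "j_call": a.j_call,
            "c_call": a.c_call,
            "junction": a.cdr3_nt,
            "junction_aa": a.cdr3_aa,
            "productive": "T" if a.productive else "F",
            "duplicate_count": a.count,
            "sample": a.sample_key or "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> list[ChainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            ChainAnnotation(
                molecule_id=r["sequence_id"],
                chain=r["locus"],
                v_call=r["v_call"],
                j_call=r["j_call"],
                c_call=r["c_call"],
                d_call=r["d_call"] or None,
                cdr3_nt=r["junction"],
                cdr3_aa=r["junction_aa"],
                productive=r["productive"] == "T",
                count=int(r["duplicate_count"]),
                sample_key=r["sample"] or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# single-cell tables


def read_contigs(path: str | Path) -> list[CellChainSet]:
    """10x-style filtered-contig CSV: barcode, chain, v_gene, j_gene, c_gene, cdr3, umis."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cells: dict[str, CellChainSet] = {}
    for _, r in df.iterrows():
        cell = cells.setdefault(r["barcode"], CellChainSet(cell_barcode=r["barcode"], chains=[]))
        cell.chains.append(
            CellChain(
                chain=r["chain"], v_call=r["v_gene"], j_call=r["j_gene"],
                c_call=r["c_gene"], cdr3_aa=r["cdr3"], umi_count=int(r["umis"] or 1),
            )
        )
    return [cells[k] for k in sorted(cells)]


def write_contigs(cells: Sequence[CellChainSet], path: str | Path) -> None:
    rows = [
        {
            "barcode": c.cell_barcode, "chain": ch.chain, "v_gene": ch.v_call,
            "j_gene": ch.j_call, "c_gene": ch.c_call, "cdr3": ch.cdr3_aa, "umis": ch.umi_count,
        }
        for c in cells
        for ch in c.chains
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clusters(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    barcode_col, cluster_col = df.columns[:2]
    return dict(zip(df[barcode_col], df[cluster_col]))


# ---------------------------------------------------------------------------
# suppression CSV


def read_proliferation(path: str | Path) -> list[ProliferationMeasurement]:
    df = pd.read_csv(path, dtype={"condition": str, "replicate": str})
    return [
        ProliferationMeasurement(r["condition"], str(r["replicate"]), float(r["percent_proliferated"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# JSON / SVG


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def curve_svg(curve: Sequence[tuple[float, float]], path: str | Path, size: int = 400) -> None:
    """Diversity curve with the full-diversity diagonal, as standalone SVG."""
    s = size / 100.0
    pts = " ".join(f"{x * s:.2f},{(100 - y) * s:.2f}" for x, y in [(0.0, 0.0), *curve])
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">\n'
        f'<rect width="{size}" height="{size}" fill="white" stroke="black"/>\n'
        f'<line x1="0" y1="{size}" x2="{size}" y2="0" stroke="gray" stroke-dasharray="6,4"/>\n'
        f'<polyline points="{pts}" fill="none" stroke="crimson" stroke-width="2"/>\n'
        "</svg>\n"
    )
    Path(path).write_text(svg)


def treemap_svg(layout: TreemapLayout, path: str | Path, size: int = 400) -> None:
    W, H = layout.canvas
    sx, sy = size / W, size / H
    groups = sorted({r["v_group"] for r in layout.rectangles})
    palette = ["#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f", "#edc948",
               "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac"]
    color = {g: palette[i % len(palette)] for i, g in enumerate(groups)}
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    ]
    for r in layout.rectangles:
        parts.append(
            f'<rect x="{r["x"] * sx:.2f}" y="{r["y"] * sy:.2f}" width="{r["w"] * sx:.2f}" '
            f'height="{r["h"] * sy:.2f}" fill="{color[r["v_group"]]}" stroke="white" stroke-width="0.5"/>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")


def stats_row(sample: str, rep: Repertoire, d50_value: float, di_value: float) -> dict:
    return {
        "sample": sample,
        "chain": rep.chain,
        "N": rep.N,
        "richness": rep.richness,
        "D50": d50_value,
        "Di": di_value,
    }
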