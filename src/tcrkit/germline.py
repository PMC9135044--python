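"""Germline V/(D)/J/C segment reference model.

Segment annotation and CDR3 extraction are anchored on the conserved
CDR3-delimiting codons: the second cysteine of the V gene and the
phenylalanine/tryptophan of the J-gene FGxG motif.  The CDR3 convention is
IMGT-style and *inclusive* of both anchors, so productive junctions read
``C....F`` (or ``C....W``).

Coordinates are 0-based, half-open.  ``cdr3_anchor`` is the index of the
first base of the anchor codon within the segment sequence; ``frame_offset``
(0-2) gives the positions ``p`` with ``p % 3 == frame_offset`` at which
codons begin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHAINS = ("TRA", "TRB")
SEGMENT_CLASSES = ("V", "D", "J", "C")
_NT = set("ACGT")


class ReferenceError(ValueError):
    """Raised when a germline reference cannot be loaded or is invalid."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D, J or C reference sequence.

    ``cdr3_anchor`` is present exactly for V and J segments and must point at
    a codon translating to C (for V) or F/W (for J) in the declared frame.
    """

    name: str
    chain: str
    segment_class: str
    sequence: str
    cdr3_anchor: int | None = None
    frame_offset: int = 0

    def anchor_codon(self) -> str | None:
        if self.cdr3_anchor is None:
            return None
        return self.sequence[self.cdr3_anchor : self.cdr3_anchor + 3]


@dataclass
class GermlineReference:
    """Germline segments indexed by ``(chain, segment_class, name)``."""

    segments: dict[tuple[str, str, str], GermlineSegment] = field(default_factory=dict)

    @classmethod
    def from_segments(cls, segments: Iterable[GermlineSegment]) -> "GermlineReference":
        ref = cls()
        for seg in segments:
            key = (seg.chain, seg.segment_class, seg.name)
            if key in ref.segments:
                raise ReferenceError(f"duplicate segment {seg.name} ({seg.chain} {seg.segment_class})")
            ref.segments[key] = seg
        return ref

    def by_class(self, chain: str, segment_class: str) -> list[GermlineSegment]:
        """Segments of one chain and class, in deterministic name order."""
        out = [s for (c, k, _), s in self.segments.items() if c == chain and k == segment_class]
        return sorted(out, key=lambda s: s.name)

    def get(self, chain: str, segment_class: str, name: str) -> GermlineSegment:
        return self.segments[(chain, segment_class, name)]

    def __len__(self) -> int:
        return len(self.segments)


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def validate_segment(seg: GermlineSegment) -> list[str]:
    """Return one message per violated segment invariant (empty list = valid)."""
    problems: list[str] = []
    if seg.chain not in CHAINS:
        problems.append(f"{seg.name}: unknown chain {seg.chain!r}")
    if seg.segment_class not in SEGMENT_CLASSES:
        problems.append(f"{seg.name}: unknown segment class {seg.segment_class!r}")
    if not seg.sequence:
        problems.append(f"{seg.name}: empty sequence")
    elif not set(seg.sequence) <= _NT:
        problems.append(f"{seg.name}: sequence contains non-ACGT characters")
    if not 0 <= seg.frame_offset <= 2:
        problems.append(f"{seg.name}: frame_offset {seg.frame_offset} outside 0-2")

    needs_anchor = seg.segment_class in ("V", "J")
    if needs_anchor and seg.cdr3_anchor is None:
        problems.append(f"{seg.name}: {seg.segment_class} segment lacks cdr3_anchor")
    if not needs_anchor and seg.cdr3_anchor is not None:
        problems.append(f"{seg.name}: {seg.segment_class} segment must not carry cdr3_anchor")
    if needs_anchor and seg.cdr3_anchor is not None and seg.sequence:
        if not 0 <= seg.cdr3_anchor <= len(seg.sequence) - 3:
            problems.append(
                f"{seg.name}: cdr3_anchor {seg.cdr3_anchor} out of range for length {len(seg.sequence)}"
            )
        else:
            if seg.cdr3_anchor % 3 != seg.frame_offset:
                problems.append(f"{seg.name}: cdr3_anchor not on a codon boundary of the declared frame")
            codon = seg.anchor_codon()
            if set(codon) <= _NT:
                aa = _translate_codon(codon)
                want = ("C",) if seg.segment_class == "V" else ("F", "W")
                if aa not in want:
                    problems.append(
                        f"{seg.name}: anchor codon {codon} translates to {aa}, expected {'/'.join(want)}"
                    )
    return problems


def validate_reference(ref: GermlineReference) -> list[str]:
    """Validate every segment plus reference-level completeness invariants.

    Violations are returned as data (one description per problem), never
    raised; an empty list means the reference is well-formed.
    """
    problems: list[str] = []
    for seg in ref.segments.values():
        problems.extend(validate_segment(seg))
    for chain in CHAINS:
        for cls in ("V", "J", "C"):
            if not ref.by_class(chain, cls):
                problems.append(f"reference has no {chain} {cls} segment")
    return problems


def load_reference(fasta_path: str | Path, anchors_path: str | Path) -> GermlineReference:
    """Load a germline reference from a FASTA file plus an anchor table.

    The anchor table is tab-separated with header columns
    ``name  chain  class  cdr3_anchor  frame_offset`` (cdr3_anchor empty or
    ``-`` for D/C segments).  Every FASTA record must match exactly one
    anchor row and vice versa.
    """
    rows: dict[str, tuple[str, str, int | None, int]] = {}
    with open(anchors_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "chain", "class", "cdr3_anchor", "frame_offset"]
        if header != expected:
            raise ReferenceError(f"anchor table header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            name, chain, cls, anchor_s, frame_s = line.rstrip("\n").split("\t")
            if name in rows:
                raise ReferenceError(f"duplicate anchor-table row for {name}")
            anchor = None if anchor_s in ("", "-") else int(anchor_s)
            rows[name] = (chain, cls, anchor, int(frame_s))

    segments = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = rec.id
        if name not in rows:
            raise ReferenceError(f"FASTA record {name} absent from anchor table")
        chain, cls, anchor, frame = rows[name]
        seen.add(name)
        segments.append(
            GermlineSegment(
                name=name,
                chain=chain,
                segment_class=cls,
                sequence=str(rec.seq).upper(),
                cdr3_anchor=anchor,
                frame_offset=frame,
            )
        )
    missing = sorted(set(rows) - seen)
    if missing:
        raise ReferenceError(f"anchor-table rows without FASTA record: {', '.join(missing)}")

    ref = GermlineReference.from_segments(segments)
    # per-segment validity is enforced at load; chain completeness is a
    # reference-level property left to validate_reference (partial references
    # are legitimate inputs for focused analyses and tests)
    problems = [p for seg in ref.segments.values() for p in validate_segment(seg)]
    if problems:
        raise ReferenceError("invalid reference: " + "; ".join(problems))
    return ref


def write_reference(ref: GermlineReference, fasta_path: str | Path, anchors_path: str | Path) -> None:
    """Write a reference as FASTA + anchor table (inverse of load_reference)."""
    segs = sorted(ref.segments.values(), key=lambda s: (s.chain, s.segment_class, s.name))
    records = [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in segs]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(anchors_path, "w") as fh:
        fh.write("name\tchain\tclass\tcdr3_anchor\tframe_offset\n")
        for s in segs:
            anchor = "-" if s.cdr3_anchor is None else str(s.cdr3_anchor)
            fh.write(f"{s.name}\t{s.chain}\t{s.segment_class}\t{anchor}\t{s.frame_offset}\n")


def default_reference(seed: int = 20) -> GermlineReference:
    """The shipped desk-scale germline set (synthetic, deterministically generated).

    Eight V, four J and one C segment per chain plus two TRB D segments.
    Segment names carry an ``S`` suffix (``TRAVS1`` ...) to mark them as
    synthetic stand-ins, not IMGT genes.  Real IMGT references load through
    :func:`load_reference` the same way.
    """
    from .simulate import synthetic_reference  # local import: avoid cycle

    return synthetic_reference(seed=seed)
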