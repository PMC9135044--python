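"""Raw paired-read processing: demultiplexing, quality trimming, overlap
merging and UMI consensus collapsing.

The processing order mirrors amplicon repertoire practice: reads are
demultiplexed by exact dual-index + internal-barcode match (the 10-nt UMI and
8-nt internal barcode are excised from the forward read), both mates are
quality-trimmed with a 2-base sliding window, mates are merged through their
overlap requiring a *perfect* overlap match, and merged molecules sharing a
UMI are collapsed to a majority-vote consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    pass


@dataclass
class RawRead:
    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass
class ReadPair:
    forward: RawRead
    reverse: RawRead
    dual_index: str | None = None
    sample_key: str | None = None
    umi: str | None = None
    internal_barcode: str | None = None


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    qualities: list[int]
    overlap_length: int = 0
    source_pair_count: int = 1
    sample_key: str | None = None
    umi: str | None = None


@dataclass
class ProcessingSummary:
    """Stage-boundary molecule accounting; conservation is checked in tests."""

    input_pairs: int = 0
    demux_assigned: int = 0
    demux_unassigned: int = 0
    trim_rejected: int = 0
    merge_rejected: int = 0
    merged: int = 0
    consensus_molecules: int = 0
    extra: dict = field(default_factory=dict)


def demultiplex(
    pairs: Iterable[ReadPair],
    barcode_table: Mapping[str, tuple[str, str]],
    umi_length: int = 10,
    barcode_length: int = 8,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign read pairs to samples by exact dual-index + internal-barcode match.

    The forward read is laid out ``UMI (umi_length) + internal barcode
    (barcode_length) + insert``; UMI and barcode are excised from the
    sequence before downstream processing.  A pair is assigned only when both
    the dual index and the internal barcode match a table entry exactly
    (mismatch tolerance 0; N never matches).  Returns per-sample streams plus
    the unassigned stream; every input pair lands in exactly one stream.
    """
    seen: dict[tuple[str, str], str] = {}
    for sample, entry in barcode_table.items():
        if entry in seen:
            raise ConfigurationError(
                f"duplicate barcode-table entry {entry} for samples {seen[entry]!r} and {sample!r}"
            )
        seen[entry] = sample

    assigned: dict[str, list[ReadPair]] = {s: [] for s in barcode_table}
    unassigned: list[ReadPair] = []
    prefix = umi_length + barcode_length
    for pair in pairs:
        fwd = pair.forward
        umi = fwd.sequence[:umi_length]
        bc = fwd.sequence[umi_length:prefix]
        sample = seen.get((pair.dual_index, bc)) if pair.dual_index is not None else None
        if sample is None or len(fwd.sequence) <= prefix:
            unassigned.append(pair)
            continue
        trimmed_fwd = RawRead(fwd.read_id, fwd.sequence[prefix:], fwd.qualities[prefix:])
        assigned[sample].append(
            replace(pair, forward=trimmed_fwd, sample_key=sample, umi=umi, internal_barcode=bc)
        )
    return assigned, unassigned


def quality_trim(
    read: RawRead, window: int = 2, q_threshold: int = 20, min_length: int = 50
) -> RawRead | None:
    """3'-trim a read at the first low-quality sliding window.

    Windows of ``window`` bases are scanned 5'→3'; at the first window in
    which any quality is below ``q_threshold`` the read is truncated starting
    at that window's first position (the failing window and everything 3' of
    it is discarded).  Reads shorter than ``min_length`` after truncation are
    rejected (None).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(read.qualities)
    bad = np.flatnonzero(q < q_threshold)
    if bad.size == 0:
        keep = len(q)
    elif len(q) < window:
        keep = 0
    else:
        # first window containing the first low-quality base; clamp to the
        # last full window so trailing bases are still covered
        keep = min(max(0, int(bad[0]) - window + 1), len(q) - window)
    if keep < min_length:
        return None
    if keep == len(q):
        return read
    return RawRead(read.read_id, read.sequence[:keep], read.qualities[:keep])


def merge_pairs(pair: ReadPair, min_overlap: int = 10) -> MergedRead | None:
    """Merge a read pair through a perfect overlap, or reject it.

    The reverse mate is reverse-complemented and slid along the forward mate;
    a merge is accepted only for a gap-free overlap of at least
    ``min_overlap`` bases with *zero* mismatches — pairs disagreeing anywhere
    in the overlap are thrown out, which doubles as an error filter.  Under
    this perfect-match acceptance rule the overlap-alignment formulation and
    an exhaustive offset scan are provably identical, so the scan is used.
    Ties: largest overlap first, then smallest offset.  Merged qualities take
    the per-position maximum inside the overlap.
    """
    f, r = pair.forward, pair.reverse
    rc_seq = reverse_complement(r.sequence)
    rc_qual = r.qualities[::-1]
    lf, lr = len(f.sequence), len(rc_seq)
    best: tuple[int, int] | None = None  # (overlap, offset)
    for offset in range(0, lf - min_overlap + 1):
        o = min(lf - offset, lr)
        if o < min_overlap:
            break
        if f.sequence[offset : offset + o] == rc_seq[:o] and "N" not in rc_seq[:o]:
            if best is None or o > best[0]:
                best = (o, offset)
    if best is None:
        return None
    o, offset = best
    seq = f.sequence[:offset] + rc_seq if offset + lr >= lf else f.sequence
    qual = list(f.qualities[:offset])
    for k in range(o):
        fq = f.qualities[offset + k]
        qual.append(max(fq, rc_qual[k]))
    if offset + lr > lf:
        qual.extend(rc_qual[o:])
    else:
        qual.extend(f.qualities[offset + lr :])
    assert len(seq) == len(qual)
    return MergedRead(
        read_id=f.read_id,
        sequence=seq,
        qualities=qual,
        overlap_length=o,
        source_pair_count=1,
        sample_key=pair.sample_key,
        umi=pair.umi,
    )


def _consensus(group: list[MergedRead]) -> MergedRead:
    """Per-position majority among members of the modal length."""
    lengths = [len(m.sequence) for m in group]
    modal = max(set(lengths), key=lambda L: (lengths.count(L), -L))
    members = [m for m in group if len(m.sequence) == modal]
    if len(members) == 1:
        rep = members[0]
        seq = rep.sequence
    else:
        cols = []
        for i in range(modal):
            counts: dict[str, int] = {}
            for m in members:
                b = m.sequence[i]
                counts[b] = counts.get(b, 0) + 1
            # majority base; lexicographic tie-break for determinism
            cols.append(max(sorted(counts), key=lambda b: counts[b]))
        seq = "".join(cols)
        rep = members[0]
    qual = [max(m.qualities[i] for m in members) for i in range(modal)]
    return MergedRead(
        read_id=rep.read_id,
        sequence=seq,
        qualities=qual,
        overlap_length=rep.overlap_length,
        source_pair_count=sum(m.source_pair_count for m in group),
        sample_key=rep.sample_key,
        umi=rep.umi,
    )


def collapse_umi(molecules: Iterable[MergedRead]) -> list[MergedRead]:
    """Collapse merged molecules sharing (sample_key, UMI) to one consensus.

    ``source_pair_count`` totals are conserved: the consensus carries the
    summed counts of its group.  Output order is deterministic (by read_id of
    the group representative).
    """
    groups: dict[tuple[str | None, str | None], list[MergedRead]] = {}
    for m in molecules:
        groups.setdefault((m.sample_key, m.umi), []).append(m)
    out = [_consensus(g) for g in groups.values()]
    out.sort(key=lambda m: m.read_id)
    return out


def process_pairs(
    pairs: Iterable[ReadPair],
    barcode_table: Mapping[str, tuple[str, str]] | None = None,
    window: int = 2,
    q_threshold: int = 20,
    min_length: int = 50,
    min_overlap: int = 10,
    collapse: bool = True,
    umi_length: int = 10,
    barcode_length: int = 8,
) -> tuple[dict[str, list[MergedRead]], ProcessingSummary]:
    """Full raw-read stage: demultiplex → trim → merge → UMI collapse.

    With ``barcode_table=None`` all pairs are treated as one pre-demultiplexed
    sample keyed ``"sample"`` and no UMI/barcode excision is performed.
    """
    summary = ProcessingSummary()
    pairs = list(pairs)
    summary.input_pairs = len(pairs)
    if barcode_table is None:
        streams = {"sample": [replace(p, sample_key="sample") for p in pairs]}
        summary.demux_assigned = len(pairs)
    else:
        streams, unassigned = demultiplex(pairs, barcode_table, umi_length, barcode_length)
        summary.demux_unassigned = len(unassigned)
        summary.demux_assigned = sum(len(v) for v in streams.values())

    out: dict[str, list[MergedRead]] = {}
    for sample, sample_pairs in streams.items():
        merged: list[MergedRead] = []
        for pair in sample_pairs:
            f = quality_trim(pair.forward, window, q_threshold, min_length)
            r = quality_trim(pair.reverse, window, q_threshold, min_length)
            if f is None or r is None:
                summary.trim_rejected += 1
                continue
            m = merge_pairs(replace(pair, forward=f, reverse=r), min_overlap)
            if m is None:
                summary.merge_rejected += 1
                continue
            merged.append(m)
        merged.sort(key=lambda m: m.read_id)
        summary.merged += len(merged)
        out[sample] = collapse_umi(merged) if collapse else merged
        summary.consensus_molecules += len(out[sample])
    return out, summary
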