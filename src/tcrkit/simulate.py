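"""Synthetic repertoire, V(D)J-recombination and read simulation.

Everything the pipeline consumes can be generated here with known ground
truth: a germline segment set, clone-size distributions spanning the
oligoclonal-to-diverse range, recombined chains whose CDR3s are known by
construction, 250-bp paired reads carrying a 10-nt UMI and an 8-nt internal
barcode with per-base qualities and substitution errors, and per-cell paired
αβ chain tables for the single-cell stage.

All generators are deterministic functions of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .germline import GermlineReference, GermlineSegment
from .readproc import RawRead, ReadPair, reverse_complement
from .singlecell import CellChain, CellChainSet

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODON = {}


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# synthetic germline reference


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _strip_stops(seq: str, start: int, rng: np.random.Generator) -> str:
    """Resample in-frame stop codons in seq[start:] (frame anchored at start)."""
    s = list(seq)
    for p in range(start, len(seq) - 2, 3):
        while "".join(s[p : p + 3]) in _STOPS:
            s[p + 2] = "ACGT"[rng.integers(0, 4)]
    return "".join(s)


def synthetic_reference(seed: int = 20) -> GermlineReference:
    """Deterministic desk-scale germline set (synthetic stand-in, not IMGT).

    Eight V, four J and one C segment per chain plus two TRB D segments.
    V segments are 108 nt with the conserved Cys codon at position 96;
    J segments are 48 nt with the Phe codon at position 12; segment names
    carry an ``S`` to mark them synthetic (``TRAVS1``, ``TRBJS2``, ...).
    """
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    for chain in ("TRA", "TRB"):
        for i in range(1, 9):
            seq = _random_nt(rng, 108)
            seq = seq[:96] + "TGT" + seq[99:]
            seq = _strip_stops(seq, 96, rng)  # keep the V-encoded CDR3 stub stop-free
            segments.append(
                GermlineSegment(f"{chain}VS{i}", chain, "V", seq, cdr3_anchor=96, frame_offset=0)
            )
        for i in range(1, 5):
            seq = _random_nt(rng, 48)
            seq = seq[:12] + "TTT" + seq[15:]
            # codons at 0/3/6/9 sit in the CDR3 reading frame (end-anchored at
            # the Phe codon) for any trim; keep them stop-free
            seq = _strip_stops(seq, 0, rng)
            segments.append(
                GermlineSegment(f"{chain}JS{i}", chain, "J", seq, cdr3_anchor=12, frame_offset=0)
            )
        segments.append(GermlineSegment(f"{chain}CS", chain, "C", _random_nt(rng, 120)))
    for i, length in ((1, 12), (2, 14)):
        segments.append(GermlineSegment(f"TRBDS{i}", "TRB", "D", _random_nt(rng, length)))
    return GermlineReference.from_segments(segments)


# ---------------------------------------------------------------------------
# configuration and truth records


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate one oligoclonal bulk library.

    ``clone_distribution`` is ``"uniform"``, ``("geometric", p)`` or
    ``("power_law", alpha)`` over clonotype ranks.
    """

    seed: int = 0
    richness: int = 200
    clone_distribution: object = ("geometric", 0.05)
    n_molecules: int = 20000
    tra_fraction: float = 0.5
    v_trim_max: int = 6
    j_trim_max: int = 6
    d_trim_max: int = 4
    n_insert_max: int = 9
    productive_fraction: float = 1.0
    read_length: int = 250
    substitution_error_rate: float = 0.001
    quality_model: str = "constant"  # or "ramp"
    quality_constant: int = 35
    umi_length: int = 10
    barcode_length: int = 8
    samples: dict = field(
        default_factory=lambda: {"S1": ("ATTACTCG+TATAGCCT", "GATCGATC")}
    )
    sample_name: str = "S1"
    # single-cell generator
    n_cells: int = 1000
    sc_richness: int = 300
    second_tra_fraction: float = 0.1


@dataclass
class ClonotypeTruth:
    clonotype_id: int
    chain: str
    v_name: str
    j_name: str
    c_name: str
    d_name: str | None
    sequence: str  # full molecule nucleotide sequence (FR2 → constant prefix)
    cdr3_nt: str
    cdr3_aa: str
    productive: bool


@dataclass
class ReadTruth:
    read_id: str
    clonotype_id: int
    umi: str
    n_errors_fwd: int
    n_errors_rev: int


@dataclass
class CellTruth:
    cell_barcode: str
    clonotype_id: int
    expanded: bool


# ---------------------------------------------------------------------------
# clone-size distributions


def clone_weights(distribution, richness: int) -> np.ndarray:
    if distribution == "uniform":
        w = np.ones(richness)
    elif isinstance(distribution, tuple) and distribution[0] == "geometric":
        p = float(distribution[1])
        if not 0 < p < 1:
            raise ConfigError(f"geometric parameter p={p} outside (0, 1)")
        w = (1.0 - p) ** np.arange(richness)
    elif isinstance(distribution, tuple) and distribution[0] == "power_law":
        alpha = float(distribution[1])
        if alpha <= 0:
            raise ConfigError(f"power-law alpha={alpha} must be positive")
        w = (np.arange(richness) + 1.0) ** (-alpha)
    else:
        raise ConfigError(f"unknown clone distribution {distribution!r}")
    return w / w.sum()


def simulate_repertoire(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw true clonotype abundances: multinomial over the clone distribution.

    Returns an integer vector of length ``richness`` summing to
    ``n_molecules`` (zeros possible for rare clones).
    """
    if config.richness < 1:
        raise ConfigError("richness must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    w = clone_weights(config.clone_distribution, config.richness)
    return rng.multinomial(config.n_molecules, w)


# ---------------------------------------------------------------------------
# V(D)J recombination


def _recombine_one(
    ref: GermlineReference,
    chain: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    clonotype_id: int,
    productive: bool,
) -> ClonotypeTruth:
    vs = ref.by_class(chain, "V")
    js = ref.by_class(chain, "J")
    cs = ref.by_class(chain, "C")
    ds = ref.by_class(chain, "D")
    v = vs[rng.integers(0, len(vs))]
    j = js[rng.integers(0, len(js))]
    c = cs[rng.integers(0, len(cs))]

    if config.v_trim_max > len(v.sequence) - (v.cdr3_anchor + 3):
        raise ConfigError(f"v_trim_max {config.v_trim_max} cuts into the {v.name} anchor codon")
    if config.j_trim_max > j.cdr3_anchor:
        raise ConfigError(f"j_trim_max {config.j_trim_max} cuts into the {j.name} anchor codon")

    for _attempt in range(200):
        tv = int(rng.integers(0, config.v_trim_max + 1))
        tj = int(rng.integers(0, config.j_trim_max + 1))
        d_name = None
        d_part = ""
        if chain == "TRB" and ds:
            d = ds[rng.integers(0, len(ds))]
            d5 = int(rng.integers(0, config.d_trim_max + 1))
            d3 = int(rng.integers(0, config.d_trim_max + 1))
            if d5 + d3 < len(d.sequence):
                d_name = d.name
                d_part = d.sequence[d5 : len(d.sequence) - d3]
            ins1 = _random_nt(rng, int(rng.integers(0, config.n_insert_max + 1)))
            ins2 = _random_nt(rng, int(rng.integers(0, config.n_insert_max + 1)))
            junction_mid = ins1 + d_part + ins2
        else:
            junction_mid = _random_nt(rng, int(rng.integers(0, config.n_insert_max + 1)))

        v_part = v.sequence[v.cdr3_anchor : len(v.sequence) - tv]
        j_part = j.sequence[tj : j.cdr3_anchor + 3]
        cdr3_nt = v_part + junction_mid + j_part
        in_frame = len(cdr3_nt) % 3 == 0
        if productive:
            if not in_frame:
                continue
            aa = _translate(cdr3_nt)
            if "*" in aa:
                continue
        else:
            if in_frame:
                continue
            aa = ""
        sequence = (
            v.sequence[: len(v.sequence) - tv]
            + junction_mid
            + j.sequence[tj:]
            + c.sequence
        )
        return ClonotypeTruth(
            clonotype_id=clonotype_id,
            chain=chain,
            v_name=v.name,
            j_name=j.name,
            c_name=c.name,
            d_name=d_name,
            sequence=sequence,
            cdr3_nt=cdr3_nt,
            cdr3_aa=aa,
            productive=productive,
        )
    raise ConfigError("could not generate a junction satisfying the productivity constraint")


def simulate_recombination(
    ref: GermlineReference, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ClonotypeTruth]:
    """Generate ``richness`` recombined chains with ground-truth CDR3s.

    Each clonotype is one chain (TRA with probability ``tra_fraction``):
    sequence = V (3'-trimmed) + N-insert [+ D fragment + N-insert for TRB]
    + J (5'-trimmed) + constant prefix.  The truth CDR3 is read off from the
    anchor coordinates by construction; a ``productive_fraction`` of
    junctions is forced in-frame and stop-free.
    """
    rng = rng or np.random.default_rng(config.seed)
    out = []
    for i in range(config.richness):
        chain = "TRA" if rng.random() < config.tra_fraction else "TRB"
        productive = rng.random() < config.productive_fraction
        out.append(_recombine_one(ref, chain, config, rng, i, productive))
    return out


# ---------------------------------------------------------------------------
# paired reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for i in hit:
        choices = _NT[_NT != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode(), len(hit)


def _qualities(length: int, config: SimulationConfig) -> list[int]:
    if config.quality_model == "constant":
        return [config.quality_constant] * length
    if config.quality_model == "ramp":
        return [max(2, int(round(38 - 8 * i / max(1, length - 1)))) for i in range(length)]
    raise ConfigError(f"unknown quality model {config.quality_model!r}")


def simulate_reads(
    clonotypes: Sequence[ClonotypeTruth],
    abundances: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], list[ReadTruth]]:
    """Emit one 250-bp read pair per molecule with UMI/barcode layout.

    Forward read: 10-nt UMI + 8-nt internal barcode + 5' end of the
    molecule; reverse read: reverse complement of the molecule 3' end.
    UMIs are drawn without replacement (one molecule, one UMI).
    Substitution errors are i.i.d. per base at ``substitution_error_rate``
    on both mates (UMI and barcode bases included); counts are recorded in
    the truth table.
    """
    rng = rng or np.random.default_rng(config.seed)
    if len(abundances) != len(clonotypes):
        raise ConfigError("abundance vector and clonotype list differ in length")
    dual_index, barcode = config.samples[config.sample_name]
    L = config.read_length
    prefix = config.umi_length + config.barcode_length
    pairs: list[ReadPair] = []
    truth: list[ReadTruth] = []
    used_umis: set[str] = set()
    idx = 0
    for ct, k in zip(clonotypes, abundances):
        mol = ct.sequence
        if len(mol) < prefix + 20 or len(mol) > 2 * L - 10:
            raise ConfigError(f"clonotype {ct.clonotype_id} molecule length {len(mol)} unusable")
        for _ in range(int(k)):
            while True:
                umi = _random_nt(rng, config.umi_length)
                if umi not in used_umis:
                    used_umis.add(umi)
                    break
            read_id = f"r{idx:07d}"
            idx += 1
            fwd = umi + barcode + mol[: L - prefix]
            rev = reverse_complement(mol[-L:])
            fwd, ef = _apply_errors(fwd, config.substitution_error_rate, rng)
            rev, er = _apply_errors(rev, config.substitution_error_rate, rng)
            pairs.append(
                ReadPair(
                    forward=RawRead(read_id, fwd, _qualities(len(fwd), config)),
                    reverse=RawRead(read_id, rev, _qualities(len(rev), config)),
                    dual_index=dual_index,
                )
            )
            truth.append(ReadTruth(read_id, ct.clonotype_id, umi, ef, er))
    return pairs, truth


# ---------------------------------------------------------------------------
# single-cell tables


def simulate_cells(
    ref: GermlineReference, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[CellChainSet], list[CellTruth]]:
    """Per-cell paired αβ chain tables with known clonotype identity.

    A pool of ``sc_richness`` paired clonotypes (one TRA + one TRB, a
    ``second_tra_fraction`` of them carrying a second TRA chain, as real
    dual-α T cells do) is sampled ``n_cells`` times under the clone
    distribution.  Truth expansion labels follow from the drawn frequencies.
    """
    rng = rng or np.random.default_rng(config.seed)
    sc_conf = replace(config, productive_fraction=1.0)
    pool: list[list[CellChain]] = []
    for i in range(config.sc_richness):
        chains = []
        tra = _recombine_one(ref, "TRA", sc_conf, rng, i, True)
        trb = _recombine_one(ref, "TRB", sc_conf, rng, i, True)
        for t in (tra, trb):
            chains.append(
                CellChain(
                    chain=t.chain, v_call=t.v_name, j_call=t.j_name, c_call=t.c_name,
                    cdr3_aa=t.cdr3_aa, umi_count=int(rng.integers(1, 20)),
                )
            )
        if rng.random() < config.second_tra_fraction:
            tra2 = _recombine_one(ref, "TRA", sc_conf, rng, i, True)
            chains.append(
                CellChain(
                    chain="TRA", v_call=tra2.v_name, j_call=tra2.j_name, c_call=tra2.c_name,
                    cdr3_aa=tra2.cdr3_aa, umi_count=int(rng.integers(1, 20)),
                )
            )
        pool.append(chains)

    w = clone_weights(config.clone_distribution, config.sc_richness)
    draws = rng.choice(config.sc_richness, size=config.n_cells, p=w)
    counts = np.bincount(draws, minlength=config.sc_richness)
    cells, truth = [], []
    for i, clone_idx in enumerate(draws):
        bc = f"CELL{i:05d}-1"
        cells.append(CellChainSet(cell_barcode=bc, chains=list(pool[clone_idx])))
        truth.append(CellTruth(bc, int(clone_idx), bool(counts[clone_idx] >= 2)))
    return cells, truth
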