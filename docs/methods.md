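# Methods

This note documents the models and procedures implemented in tcrkit, the
defaults chosen where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Read processing

**Demultiplexing.** A read pair is assigned to a sample only on an exact
match of both the Illumina dual index and the 8-nt internal barcode carried
at the 5' end of the constant-region read; the 10-nt UMI and the barcode are
excised before any downstream step. Exact matching (0 mismatches, `N` never
matches) keeps assignment deterministic; a mismatch-tolerant mode was
deliberately not made the default because a single tolerant hit can be
ambiguous between barcodes at Hamming distance 2.

**Quality trimming.** A 2-base window slides 5'→3'; at the first window
containing any quality below 20 the read is truncated from that window's
first position (the conservative reading of "from the window to the 3'
end"). Reads shorter than `min_length = 50` nt after trimming are rejected —
shorter fragments cannot span the sequenced framework-2 → constant-region
amplicon. Trimming is idempotent (property-tested).

**Pair merging.** The reverse mate is reverse-complemented and slid along
the forward mate. A merge is accepted only for a gap-free overlap of
≥ 10 nt with zero mismatches; any disagreement rejects the pair. Under this
perfect-match acceptance rule an overlap alignment and an exhaustive offset
scan provably select the same merges, so the implementation scans offsets
and is tested for equality against an independently written scan oracle.
Ties take the largest overlap, then the smallest offset. Merged qualities
take the per-position maximum inside the overlap. Negative offsets
(read-through into adapter) are not modelled; the amplicon geometry this
pipeline targets cannot produce them after trimming.

The perfect-overlap rule doubles as the error filter: at a 0.1% per-base
substitution rate roughly a third of pairs are rejected (either mate erring
anywhere in a ~190-nt overlap), and the survivors are essentially error-free
across the overlap — which contains the CDR3. This is why CDR3 recovery on
surviving molecules stays at ~100% even with sequencing errors.

**UMI collapsing.** Molecules sharing (sample, UMI) are collapsed to one
consensus: per-position majority vote among members of the modal length
(lexicographic tie-break), qualities per-position maximum, with
`source_pair_count` conserved as the group-size sum.

## V(D)J annotation

**Alignment.** Local Smith–Waterman with affine gaps (numba kernel; defaults
match +2, mismatch −2, gap open −3, gap extend −1, a gap of length *k*
scoring `open + (k−1)·extend`). `N` mismatches everything, including `N`.
The published pipeline this follows does not state its scoring scheme, so
the defaults are fixed for reproducibility and the kernel is verified in
tests against an independent plain-Python DP oracle on random instances.
Tie-breaking among equally scoring alignments takes the first maximal cell
in row-major order with a diagonal-preferring traceback; this is
deterministic, and on non-degenerate data coincides with the
smallest-start convention.

**Candidate search.** Each candidate segment is first located on the read
with edlib's infix (bit-parallel edit distance) search and SW is computed
exactly within the located window padded by 30 nt; a hit touching the window
edge triggers a full-read realignment. V candidates are additionally
shortlisted to the top 3 by infix edit distance before SW scoring
(`v_prefilter_top_k`, 0 disables). Both devices change runtime only: a test
verifies that windowed+shortlisted calls equal exhaustive full-read SW calls
on simulated molecules.

**Segment assignment.** The chain (TRA/TRB) is decided by the best
constant-segment hit across chains; V and J are then the best hits of their
class on that chain, required to satisfy read-coordinate ordering
V < J ≤ C. Class score minima (V 30, J 15, C 15 score units — J and C are
short) mark weaker molecules unassigned. Equal-scoring segment calls tie by
name order and are counted in the run summary. The TRB D call is
annotational only (longest exact D substring of ≥ 5 nt inside the junction
window); it never affects CDR3 extraction.

**CDR3 extraction.** The germline CDR3 anchors — the index of the conserved
V-gene cysteine codon and J-gene phenylalanine/tryptophan codon — are
migrated through the alignment cigars onto the read;
`cdr3_nt = read[v_anchor : j_anchor + 3]`, inclusive of both anchor codons,
so productive junctions read `C…F/W`. An anchor falling at most 6 nt beyond
the aligned reference interval is linearly extrapolated; beyond that, or in
an alignment gap, the molecule is flagged cdr3-missing rather than guessed.
Productive requires length ≡ 0 (mod 3), no stop codon, first residue C,
last residue F or W, and no ambiguous base.

## Repertoire statistics

Clonotypes are keyed by `(v_call, j_call, cdr3_aa)` by default — amino-acid
identity stratified by gene calls, matching treemap grouping by V usage —
with `aa`-only and nucleotide keys available. Only productive clonotypes
enter statistics unless requested otherwise.

**D50** restricts to the top `min(10,000, R)` clonotypes by count, walks the
descending ranking, and returns `100·k/R` for the minimal *k* whose
cumulative count reaches ≥ 50% of the restricted total. Two documented
granularity consequences of this literal formula: a monoclonal repertoire
returns 100 (k = R = 1), and a uniform repertoire of odd richness returns
`100·⌈R/2⌉/R` rather than exactly 50 (half the reads is not attainable by
whole clones). Ranking ties (equal counts) break lexicographically by key,
which pins the value of *k* at 50% boundaries.

**Diversity index** is `[1 − Σ n(n−1)/(N(N−1))] × 100`, undefined for
N < 2. It is permutation-invariant and strictly increases when a read moves
from the largest clone to a new singleton (property-tested).

**Diversity curve**: point *i* is `(100·i/R, 100·cum_i/N)` over the
descending ranking — weakly above the diagonal, ending at (100, 100); an
even repertoire traces the diagonal. Curves longer than `n_points` (default
100) are evenly subsampled, always keeping the final point.

**Treemap**: two-level squarified layout (Bruls-style worst-aspect-ratio
rule) — outer tiles per V gene sized by summed counts, inner tiles per
clonotype — deterministic given the sorted input, areas proportional to
counts within 1e-6 relative tolerance.

## Single-cell expansion

Cells group into clonotypes by set equality of their `(chain, cdr3_aa)`
pairs — all chains participate, so dual-α cells match only cells with the
identical triple; a strict mode adds V/J genes to the key. Cells lacking
either a TRA or a TRB are excluded from paired-clonotype counts by default
(kept, flagged, with `paired_only=False`). A cell is expanded iff its
clonotype holds ≥ 2 cells (the threshold is a parameter; the stricter "> 2"
variant seen in some figure legends can be selected). A cluster is called
expanded-phenotype at ≥ 15% expanded cells, boundary inclusive. QC bounds
are applied exactly as printed — exclude features < 500 or > 4000, exclude
mitochondrial fraction > 7% — so boundary cells (500, 4000, exactly 7%)
pass; a cell failing both rules is counted once, under the feature rule.

## Suppression assay

`suppression% = 100 − (treated/control × 100)`; the Tconv-only control
defines 0%. Replicates are referenced to the pooled control mean by default
(a paired mode references same-id control replicates); per-ratio summaries
report mean and standard error. Values above the control give negative
suppression, reported as-is with a warning — clamping would hide assay
problems. Proliferation percentages outside [0, 100] are rejected as input
errors.

## Synthetic data generator

The generator emulates the structure of an RNA-based TCR amplicon library:
clone abundances drawn multinomially from a uniform, geometric(p) or
power-law(α) rank distribution; V(D)J junctions as
`V(3'-trimmed) + N-insert [+ D fragment + N-insert] + J(5'-trimmed)`
followed by a constant-region prefix, with trims uniform on [0, max]
(defaults: V/J 6 nt, D 4 nt per side, inserts ≤ 9 nt) and insert bases
uniform over ACGT — the simplest model carrying the junctional diversity
the annotator must handle. In-frame, stop-free junctions are enforced for a
configurable productive fraction (default 1.0). Reads are 250 bp paired,
the forward read prefixed by a 10-nt UMI (drawn without replacement — one
molecule, one UMI) and the 8-nt sample barcode; substitution errors are
i.i.d. per base at a configurable rate with counts recorded; qualities are
constant (35) or a ramp. Per-cell tables draw paired clonotypes from the
rank distribution, a configurable fraction of clonotypes carrying a second
TRA chain as real dual-α T cells do.

The shipped germline set is synthetic and named accordingly (`TRAVS1` …):
8 V (108 nt, Cys anchor at 96), 4 J (48 nt, Phe anchor at 12) and one C
(120 nt) per chain plus two TRB D segments, generated deterministically
with anchor-frame codons kept stop-free so that productive junctions are
always constructible. Real IMGT references load through the same
FASTA + anchor-table interface.

Not emulated: biologically calibrated V/J usage priors, indel sequencing
errors (substitution-only, since the perfect-overlap merge rejects
indel-bearing pairs anyway; an indel flag exists for robustness testing),
PCR amplification bias and chimeras, UMI collisions (excluded by
construction so molecule counts are exactly known), and quality-dependent
error profiles. Passing recovery tests therefore demonstrate correctness of
the pipeline's bookkeeping and alignment logic under a clean error model,
not robustness to every artefact of real libraries.

## Problem sizes and determinism

Recovery tests run at 200 clonotypes × 20,000 molecules per repertoire —
comfortably past the regime where the diversity statistics stabilise, while
keeping a full multi-seed sweep (3 error-free + 10 at 0.1% substitutions)
inside a few CPU-minutes. Every generator is a deterministic function of
(config, seed); gzip outputs pin mtime and omit the filename header so
fixed-seed reruns are byte-identical. All randomness flows through
`numpy.random.default_rng` seeded explicitly.

## Known limitations

- Allele-level (`*01`) resolution, pseudogene classification and CDR1/CDR2
  annotation are out of scope; anchors are the only IMGT coordinates used.
- The D-segment call is heuristic (exact substring) and should not be used
  for D-usage statistics.
- Chain assignment requires a constant-region hit; libraries truncated
  before the constant region will go unassigned rather than being rescued
  by V/J evidence alone.
- `smith_waterman` reports a single optimal alignment; co-optimal
  alignments are counted (tie counter) but not enumerated.
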