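import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tcrkit as tk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref():
    return tk.synthetic_reference()


@pytest.fixture(scope="session")
def small_sim(ref):
    """Small error-free end-to-end dataset with ground truth."""
    cfg = tk.SimulationConfig(seed=7, richness=30, n_molecules=400, substitution_error_rate=0.0)
    rng = np.random.default_rng(cfg.seed)
    abundances = tk.simulate_repertoire(cfg, rng)
    clonotypes = tk.simulate_recombination(ref, cfg, rng)
    pairs, read_truth = tk.simulate_reads(clonotypes, abundances, cfg, rng)
    streams, process_summary = tk.process_pairs(pairs, cfg.samples)
    molecules = streams["S1"]
    annotations, ann_summary = tk.annotate(molecules, ref)
    return {
        "config": cfg,
        "abundances": abundances,
        "clonotypes": clonotypes,
        "pairs": pairs,
        "read_truth": read_truth,
        "molecules": molecules,
        "annotations": annotations,
        "process_summary": process_summary,
        "ann_summary": ann_summary,
    }


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def affine_sw_score_oracle(q, r, match=2, mismatch=-2, gap_open=-3, gap_extend=-1):
    """Textbook affine-gap local-alignment DP, plain Python, score only."""
    n, m = len(q), len(r)
    NEG = float("-inf")
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == r[j - 1] and q[i - 1] != "N") else mismatch
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def merge_oracle(fwd_seq, rev_seq, min_overlap=10):
    """Exhaustive overlap scan: longest perfect overlap, smallest offset.

    Returns (merged_sequence, overlap_length) or None.
    """
    rc = tk.readproc.reverse_complement(rev_seq)
    lf, lr = len(fwd_seq), len(rc)
    candidates = []
    for offset in range(0, lf - min_overlap + 1):
        o = min(lf - offset, lr)
        if o < min_overlap:
            continue
        window_f = fwd_seq[offset : offset + o]
        window_r = rc[:o]
        if window_f == window_r and "N" not in window_f and "N" not in window_r:
            merged = fwd_seq[:offset] + rc if offset + lr >= lf else fwd_seq
            candidates.append((o, -offset, merged))
    if not candidates:
        return None
    o, neg_offset, merged = max(candidates)
    return merged, o


def expansion_histogram_oracle(cells, threshold=2):
    """Brute-force per-cell expansion from a raw frequency histogram."""
    from collections import Counter

    keys = {
        c.cell_barcode: tuple(sorted({(ch.chain, ch.cdr3_aa) for ch in c.chains}))
        for c in cells
        if {"TRA", "TRB"} <= {ch.chain for ch in c.chains}
    }
    hist = Counter(keys.values())
    labels = {bc: hist[k] >= threshold for bc, k in keys.items()}
    n_expanded_clonotypes = sum(1 for v in hist.values() if v >= threshold)
    return labels, n_expanded_clonotypes
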