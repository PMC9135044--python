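"""End-to-end pipeline orchestration: process → annotate → stats.

A run is configured by a YAML file (unknown keys rejected), executes each
stage with the module defaults unless overridden, writes stage outputs plus
a machine-readable JSON summary, and emits a provenance record (config
hash, package version, seed).  Count conservation is asserted at every
stage boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import AnnotationConfig, annotate
from .germline import default_reference, load_reference
from .io import (
    read_airr,
    read_barcode_table,
    read_fastq_pairs,
    stats_row,
    write_airr,
    write_json,
)
from .readproc import process_pairs
from .stats import aggregate, d50, diversity_curve, diversity_index, treemap


class PipelineError(RuntimeError):
    pass


_KNOWN_KEYS = {
    "seed": int,
    "input": dict,
    "process": dict,
    "annotate": dict,
    "stats": dict,
    "output_dir": str,
}
_KNOWN_SUBKEYS = {
    "input": {"fastq_forward", "fastq_reverse", "barcode_table", "germline_fasta", "germline_anchors"},
    "process": {"window", "q_threshold", "min_length", "min_overlap", "collapse_umi",
                "umi_length", "barcode_length"},
    "annotate": {"v_prefilter_top_k", "max_extrapolate", "min_score_v", "min_score_j", "min_score_c"},
    "stats": {"key_mode", "top_n", "productive_only"},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    input: dict = field(default_factory=dict)
    process: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    output_dir: str = "tcrkit_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_KNOWN_KEYS)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _KNOWN_SUBKEYS.items():
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise PipelineError(f"unknown keys in config section {section!r}: {sorted(extra)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run process → annotate → stats; returns the summary dict it also writes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    inp = config.input
    pairs = read_fastq_pairs(inp["fastq_forward"], inp["fastq_reverse"])
    barcode_table = read_barcode_table(inp["barcode_table"]) if inp.get("barcode_table") else None
    if inp.get("germline_fasta"):
        ref = load_reference(inp["germline_fasta"], inp["germline_anchors"])
    else:
        ref = default_reference()

    pconf = dict(config.process)
    collapse = pconf.pop("collapse_umi", True)
    streams, psummary = process_pairs(pairs, barcode_table, collapse=collapse, **pconf)
    if psummary.demux_assigned + psummary.demux_unassigned != psummary.input_pairs:
        raise PipelineError("demultiplex count conservation violated")
    if (psummary.demux_assigned - psummary.trim_rejected - psummary.merge_rejected
            != psummary.merged):
        raise PipelineError("trim/merge count conservation violated")

    aconf = AnnotationConfig()
    acfg = config.annotate
    if "v_prefilter_top_k" in acfg:
        aconf.v_prefilter_top_k = acfg["v_prefilter_top_k"]
    if "max_extrapolate" in acfg:
        aconf.max_extrapolate = acfg["max_extrapolate"]
    for cls in ("v", "j", "c"):
        if f"min_score_{cls}" in acfg:
            aconf.min_scores[cls.upper()] = acfg[f"min_score_{cls}"]

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "process": asdict(psummary),
        "samples": {},
    }
    stats_rows = []
    for sample in sorted(streams):
        molecules = streams[sample]
        annotations, asum = annotate(molecules, ref, aconf)
        if not asum.conserved():
            raise PipelineError(f"annotation count conservation violated for {sample}")
        write_airr(annotations, out / f"{sample}.rearrangements.tsv")
        sample_block = {"annotate": asdict(asum), "chains": {}}
        sconf = config.stats
        for chain in ("TRA", "TRB"):
            chain_ann = [a for a in annotations if a.chain == chain]
            if not chain_ann:
                continue
            rep = aggregate(
                chain_ann,
                key_mode=sconf.get("key_mode", "vj_aa"),
                productive_only=sconf.get("productive_only", True),
            )
            if rep.N < 2:
                continue
            d = d50(rep)
            di = diversity_index(rep)
            stats_rows.append(stats_row(sample, rep, d, di))
            write_json(
                {"curve": diversity_curve(rep)},
                out / f"{sample}.{chain}.curve.json",
            )
            layout = treemap(rep)
            write_json(
                {"canvas": layout.canvas,
                 "rectangles": [dict(r, key=list(r["key"])) for r in layout.rectangles]},
                out / f"{sample}.{chain}.treemap.json",
            )
            sample_block["chains"][chain] = {"N": rep.N, "richness": rep.richness, "D50": d, "Di": di}
        summary["samples"][sample] = sample_block

    import pandas as pd

    pd.DataFrame(stats_rows, columns=["sample", "chain", "N", "richness", "D50", "Di"]).to_csv(
        out / "stats.csv", index=False
    )
    write_json(summary, out / "run_summary.json")
    return summary
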