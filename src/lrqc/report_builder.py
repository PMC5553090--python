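"""Aggregate statistics into report surfaces and render TSV/JSON + HTML.

The analysis runs in up to three layers, mirroring what inputs are
available:

1. basic statistics (always): read counts, mappable-length statistics,
   alignment classification fractions, binned mappability, BED12 export;
2. error-pattern analysis (needs the reference genome): per-type rates,
   context matrices, homopolymer statistics;
3. transcript statistics (needs an annotation): assignments, isoform
   identification, splice-site accuracy.

Every number shown in the HTML lives in the machine-readable
``report.json``; with fixed seeds the JSON is byte-identical across runs
(no clock, no hostnames).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CLASS_LABELS,
    GenomeSequence,
    ReadAlignment,
    TranscriptModel,
    write_bed,
)
from .path_combiner import (
    CombinationPolicy,
    classification_summary,
    classification_table,
    classify_reads,
)


@dataclass
class LengthStats:
    """Moments of the mappable-length distribution of aligned reads."""

    count: int
    mean: float
    median: float
    sd: float
    maximum: int

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "LengthStats | None":
        if not lengths:
            return None
        arr = np.asarray(lengths, dtype=float)
        # single observation: sd reported as 0 by convention
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return cls(
            count=len(arr),
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            sd=sd,
            maximum=int(arr.max()),
        )

    def as_dict(self) -> dict:
        return {
            "count": self.count,
            "mean": round(self.mean, 4),
            "median": self.median,
            "sd": round(self.sd, 4),
            "maximum": self.maximum,
        }


def length_statistics(reads: Sequence[ReadAlignment]) -> LengthStats | None:
    """Mappable-length statistics over aligned reads (unaligned excluded;
    their count is reported separately by the caller).  Returns None — an
    explicit empty-stats sentinel — when nothing aligned."""
    return LengthStats.from_lengths(
        [r.mappable_length for r in reads if r.aligned]
    )


@dataclass
class BinSpec:
    """Left-closed right-open read-length bins, 500 bp steps to 4 kb plus
    a >4 kb bin by default."""

    edges: tuple[float, ...] = tuple(range(0, 4001, 500))

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    def labels(self) -> list[str]:
        out = [
            f"[{int(a)},{int(b)})" for a, b in zip(self.edges, self.edges[1:])
        ]
        out.append(f">={int(self.edges[-1])}")
        return out

    def bin_of(self, length: float) -> int:
        for i in range(len(self.edges) - 1):
            if self.edges[i] <= length < self.edges[i + 1]:
                return i
        return len(self.edges) - 1


def binned_mappability(
    reads: Sequence[ReadAlignment], bins: BinSpec | None = None
) -> pd.DataFrame:
    """Distribution of mappable-length / read-length per read-length bin.

    Each aligned read contributes one ratio in [0,1] to the bin of its
    total read length.
    """
    bins = bins or BinSpec()
    labels = bins.labels()
    per_bin: list[list[float]] = [[] for _ in labels]
    for r in reads:
        if not r.aligned or r.read_length <= 0:
            continue
        ratio = min(1.0, r.mappable_length / r.read_length)
        per_bin[bins.bin_of(r.read_length)].append(ratio)
    rows = []
    for lab, vals in zip(labels, per_bin):
        rows.append(
            {
                "bin": lab,
                "n_reads": len(vals),
                "mean_mappable_fraction": float(np.mean(vals)) if vals else float("nan"),
                "median_mappable_fraction": float(np.median(vals)) if vals else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline + report
# ---------------------------------------------------------------------------

def analyze(
    reads: Sequence[ReadAlignment],
    genome: GenomeSequence | None = None,
    transcripts: Sequence[TranscriptModel] | None = None,
    policy: CombinationPolicy | None = None,
    sample_target: int = 1_000_000,
    min_context_obs: int = 10_000,
    seed: int = 0,
    bins: BinSpec | None = None,
) -> dict:
    """Run all applicable analysis layers; returns the report payload dict.

    Layer 2 runs iff a genome is given, layer 3 iff an annotation is given.
    The payload is JSON-serialisable and deterministic for fixed inputs and
    seed.
    """
    from . import error_profiler as ep

    reads = classify_reads(list(reads), policy)
    payload: dict = {"layers": ["basic"]}

    n_total = len(reads)
    n_aligned = sum(1 for r in reads if r.aligned)
    stats = length_statistics(reads)
    summary = classification_summary(reads)
    payload["basic"] = {
        "n_reads": n_total,
        "n_aligned": n_aligned,
        "n_unaligned": n_total - n_aligned,
        "mappable_length": stats.as_dict() if stats else None,
        "classification": _df_records(summary),
        "binned_mappability": _df_records(binned_mappability(reads, bins)),
    }

    if genome is not None:
        payload["layers"].append("error")
        rates = ep.overall_error_rates(
            reads, genome, sample_target=sample_target, seed=seed
        )
        ctx = ep.context_error_matrices(
            reads, genome, min_context_obs=min_context_obs, seed=seed
        )
        hp = ep.homopolymer_stats(reads, genome)
        prop = rates.proportions
        payload["error"] = {
            "sampled_reads": rates.sampled_reads,
            "sampled_columns": rates.total_columns,
            "overall_pct": _r(100 * rates.total_rate),
            "mismatch_pct": _r(100 * rates.mismatch_rate),
            "insertion_pct": _r(100 * rates.insertion_rate),
            "deletion_pct": _r(100 * rates.deletion_rate),
            "proportions_pct": {k: _r(100 * v) for k, v in prop.items()},
            "context_undersampled": any(m.undersampled for m in ctx.matrices()),
            "context_top_cells": {
                m.focal: "".join(m.max_cell())
                for m in ctx.mismatch.values()
                if m.counts.sum() > 0
            },
            "homopolymer": {
                "indels_total": hp.indels_total,
                "loose_fraction": _r(hp.loose_fraction),
                "tight_fraction": _r(hp.tight_fraction),
            },
        }
        payload["_context_profile"] = ctx  # not serialised; used by callers

    if transcripts is not None:
        payload["layers"].append("transcript")
        from . import quantifier as qt
        from . import transcript_annotator as ta

        assignments = ta.assign_reads(reads, transcripts)
        ident = ta.identify_isoforms(assignments, transcripts)
        _, splice = ta.splice_offsets(reads, transcripts)
        counts = qt.count_isoform_reads(
            assignments, universe=[t.transcript_id for t in transcripts]
        )
        payload["transcript"] = {
            "n_transcripts": len(transcripts),
            "n_identified": int((ident["status"] != "not-identified").sum()),
            "identification": _df_records(
                ident[["transcript_id", "status", "supporting_reads", "unique_reads"]]
            ),
            "splice": {
                k: (_r(v) if isinstance(v, float) else v)
                for k, v in splice.items()
                if k != "offset_histogram"
            },
            "splice_offset_histogram": {
                str(k): v for k, v in splice["offset_histogram"].items()
            },
            "unique_counts": counts,
        }
    payload["_reads"] = reads  # classified reads, for writers; not serialised
    return payload


def _r(x: float, nd: int = 6) -> float:
    return round(x, nd) if not math.isnan(x) else float("nan")


def _df_records(df: pd.DataFrame) -> list[dict]:
    recs = df.to_dict(orient="records")
    for rec in recs:
        for k, v in rec.items():
            if isinstance(v, (np.integer,)):
                rec[k] = int(v)
            elif isinstance(v, (np.floating, float)):
                rec[k] = _r(float(v))
    return recs


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not serialisable: {type(o)}")


def build_report(payload: dict, out_dir: str | Path) -> dict[str, str]:
    """Write report.json, data TSVs, mappings.bed and a self-contained
    report.html from an :func:`analyze` payload.  Returns written paths."""
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    reads = payload.get("_reads", [])
    serialisable = {
        k: v for k, v in payload.items() if not k.startswith("_")
    }
    paths: dict[str, str] = {}

    jpath = out / "data" / "report.json"
    with open(jpath, "w") as fh:
        json.dump(serialisable, fh, indent=1, sort_keys=True, default=_json_default, allow_nan=True)
        fh.write("\n")
    paths["json"] = str(jpath)

    bed = out / "mappings.bed"
    write_bed(reads, bed)
    paths["bed"] = str(bed)

    if reads:
        classification_table(reads).to_csv(
            out / "data" / "classification.tsv", sep="\t", index=False
        )
        paths["classification"] = str(out / "data" / "classification.tsv")
    ctx = payload.get("_context_profile")
    if ctx is not None:
        ctx.as_long_table().to_csv(
            out / "data" / "context_matrices.tsv", sep="\t", index=False
        )
        paths["context"] = str(out / "data" / "context_matrices.tsv")

    hpath = out / "report.html"
    with open(hpath, "w") as fh:
        fh.write(_render_html(serialisable))
    paths["html"] = str(hpath)
    return paths


def _html_table(records: list[dict]) -> str:
    if not records:
        return "<p>(empty)</p>"
    cols = list(records[0])
    head = "".join(f"<th>{c}</th>" for c in cols)
    body = "".join(
        "<tr>" + "".join(f"<td>{rec.get(c, '')}</td>" for c in cols) + "</tr>"
        for rec in records
    )
    return f"<table><tr>{head}</tr>{body}</table>"


def _render_html(p: dict) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>long-read alignment QC</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
        "collapse}td,th{border:1px solid #999;padding:3px 8px}h2{margin-top:2em}"
        "</style></head><body>",
        "<h1>Long-read alignment QC report</h1>",
        f"<p>Layers run: {', '.join(p['layers'])}</p>",
    ]
    b = p["basic"]
    parts.append("<h2>Basic statistics</h2>")
    parts.append(
        f"<p>{b['n_reads']} reads, {b['n_aligned']} aligned, "
        f"{b['n_unaligned']} unaligned.</p>"
    )
    if b["mappable_length"]:
        parts.append(_html_table([b["mappable_length"]]))
    parts.append("<h3>Alignment classification</h3>")
    parts.append(_html_table(b["classification"]))
    parts.append("<h3>Mappable fraction by read length</h3>")
    parts.append(_html_table(b["binned_mappability"]))
    if "error" in p:
        e = p["error"]
        parts.append("<h2>Error pattern</h2>")
        parts.append(
            _html_table(
                [
                    {
                        k: e[k]
                        for k in (
                            "sampled_reads",
                            "sampled_columns",
                            "overall_pct",
                            "insertion_pct",
                            "deletion_pct",
                            "mismatch_pct",
                        )
                    }
                ]
            )
        )
        parts.append(
            f"<p>Homopolymer indels: loose {e['homopolymer']['loose_fraction']}, "
            f"tight {e['homopolymer']['tight_fraction']} of "
            f"{e['homopolymer']['indels_total']} indels.</p>"
        )
    if "transcript" in p:
        t = p["transcript"]
        parts.append("<h2>Transcript statistics</h2>")
        parts.append(
            f"<p>{t['n_identified']} of {t['n_transcripts']} annotated "
            f"isoforms identified.</p>"
        )
        parts.append(_html_table(t["identification"][:200]))
    parts.append("</body></html>")
    return "".join(parts)
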