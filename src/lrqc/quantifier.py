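"""Long-read isoform counting and spike-in abundance evaluation.

For a spike-in mixture with known composition (e.g. a SIRV E0 mix of 68
isoforms at identical concentration), reads are counted per isoform, the
relative expression percentage REP_i = count_i / Σ counts is formed, and
estimation quality is the Euclidean distance between the estimated and the
expected REP vector (uniform 1/68 for an equimolar mix).  REP is exposed
both as a fraction and as a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .transcript_annotator import MatchResult

UNIQUE_ONLY = "unique_only"
BEST = "best"


@dataclass
class AbundanceVector:
    """Per-isoform counts and relative expression (fractions summing to 1)."""

    counts: dict[str, int]
    rep: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rep_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.rep.items()}


def count_isoform_reads(
    assignments: Mapping[str, Sequence[MatchResult]],
    mode: str = UNIQUE_ONLY,
    universe: Sequence[str] | None = None,
) -> dict[str, int]:
    """Per-isoform read counts.

    ``unique_only`` counts a read only when its best assignment is unique;
    ``best`` gives every assigned read to its single best isoform, breaking
    exact ties deterministically by transcript id.  Unassigned reads are
    not counted.  ``universe`` forces zero entries for listed isoforms.
    """
    counts: dict[str, int] = {t: 0 for t in (universe or [])}
    for matches in assignments.values():
        if not matches:
            continue
        top = matches[0]  # assign_read sorts best-first
        if mode == UNIQUE_ONLY:
            if not top.unique:
                continue
        elif mode != BEST:
            raise ValueError(f"unknown counting mode {mode!r}")
        counts[top.transcript_id] = counts.get(top.transcript_id, 0) + 1
    return counts


def rep(counts: Mapping[str, int]) -> AbundanceVector:
    """Relative expression percentage: REP_i = count_i / Σ counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero counts: REP undefined")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    return AbundanceVector(
        counts=dict(counts), rep={k: c / total for k, c in counts.items()}
    )


def uniform_expected(isoforms: Sequence[str]) -> AbundanceVector:
    """The expected vector for an equimolar mix: every isoform at 1/n."""
    n = len(isoforms)
    return AbundanceVector(
        counts={t: 1 for t in isoforms}, rep={t: 1.0 / n for t in isoforms}
    )


def estimation_error(
    estimated: AbundanceVector, expected: AbundanceVector, scale: str = "fraction"
) -> float:
    """Euclidean distance between estimated and expected REP vectors.

    Isoform universes must agree exactly; zero-count isoforms contribute as
    zeros.  ``scale`` selects fractions (default) or percentages — the same
    distance multiplied by 100.
    """
    a, b = set(estimated.rep), set(expected.rep)
    if a != b:
        missing = sorted(b - a)
        extra = sorted(a - b)
        raise ValueError(
            f"isoform universes differ: missing={missing} extra={extra}"
        )
    d = math.sqrt(
        sum((estimated.rep[k] - expected.rep[k]) ** 2 for k in expected.rep)
    )
    if scale == "percent":
        return 100.0 * d
    if scale != "fraction":
        raise ValueError(f"unknown scale {scale!r}")
    return d
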