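"""Reduce multi-read molecules to one best read per molecule.

PacBio sequences one circular template molecule many times: the same ZMW
(well) can yield subreads and a CCS consensus.  ONT can report a 2D
consensus alongside the 1D template and complement strand reads of one
molecule.  Transcriptome analyses want each molecule represented once and
only once, so reads are grouped by molecule and a platform-specific
priority ladder picks the representative:

* PacBio, long-read-only: best aligned CCS, else best aligned subread.
* PacBio, hybrid: best aligned CCS with > 2 passes and predicted accuracy
  > 95 (both reported by upstream SMRT software, carried as metadata),
  else best aligned short-read-corrected CCS, else best aligned subread.
* ONT (both strategies): best aligned 2D, else 1D template, else 1D
  complement; for hybrid the members are the corrected reads.

"Best aligned" = most mapped read bases of the read's best path, with the
same deterministic tie-break as path selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ReadAlignment

PACBIO = "pacbio"
ONT = "ont"

KIND_CCS = "ccs"
KIND_SUBREAD = "subread"
KIND_2D = "2d"
KIND_1D_TEMPLATE = "1d_template"
KIND_1D_COMPLEMENT = "1d_complement"

_PACBIO_NAME = re.compile(r"^(?P<movie>[^/]+)/(?P<zmw>\d+)(?:/(?P<rest>.*))?$")
# ONT molecule identity: channel + read number when present in the name
_ONT_NAME = re.compile(r"(?P<mol>ch\d+_read\d+|channel_\d+_read_\d+)", re.IGNORECASE)


@dataclass
class ReadMeta:
    """Per-read selection metadata (from a metadata TSV or name parsing)."""

    kind: str
    passes: int | None = None
    accuracy: float | None = None  # percent, 0-100 scale, upstream estimate
    corrected: bool = False


@dataclass
class MemberRead:
    read: ReadAlignment
    meta: ReadMeta

    @property
    def mapped_bases(self) -> int:
        return self.read.best_path.aligned_read_bases if self.read.best_path else 0

    @property
    def aligned(self) -> bool:
        return self.read.best_path is not None

    def sort_key(self) -> tuple:
        p = self.read.best_path
        tie = p.sort_key() if p else ("", 0, "")
        return (-self.mapped_bases,) + tie + (self.read.read_id,)


@dataclass
class MoleculeGroup:
    molecule_id: str
    members: list[MemberRead] = field(default_factory=list)


def read_metadata_tsv(path: str | Path) -> dict[str, ReadMeta]:
    """Load a read-metadata table: read_id, kind, passes, accuracy, corrected."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.read_id)] = ReadMeta(
            kind=str(row.kind),
            passes=int(row.passes) if pd.notna(getattr(row, "passes", None)) else None,
            accuracy=float(row.accuracy) if pd.notna(getattr(row, "accuracy", None)) else None,
            corrected=bool(getattr(row, "corrected", False)),
        )
    return out


def _infer_pacbio(read_id: str) -> tuple[str, str] | None:
    m = _PACBIO_NAME.match(read_id)
    if not m:
        return None
    rest = m.group("rest") or ""
    kind = KIND_CCS if rest.strip().lower() == "ccs" else KIND_SUBREAD
    return f"{m.group('movie')}/{m.group('zmw')}", kind


def _infer_ont(read_id: str) -> tuple[str, str]:
    m = _ONT_NAME.search(read_id)
    mol = m.group("mol") if m else read_id.split()[0].rsplit("_", 1)[0]
    low = read_id.lower()
    if "2d" in low or "twodir" in low:
        kind = KIND_2D
    elif "complement" in low:
        kind = KIND_1D_COMPLEMENT
    else:
        kind = KIND_1D_TEMPLATE
    return mol, kind


def group_molecules(
    reads: Iterable[ReadAlignment],
    platform: str,
    metadata: dict[str, ReadMeta] | None = None,
) -> list[MoleculeGroup]:
    """Group reads by source molecule (PacBio: movie/ZMW; ONT: channel/read).

    Metadata, when provided, overrides name-derived read kinds.  Reads with
    unparsable names fall back to a singleton group.  A read whose name
    parses under the *other* platform's convention but not this one raises
    ``ValueError`` naming the read.
    """
    if platform not in (PACBIO, ONT):
        raise ValueError(f"unknown platform {platform!r}")
    groups: dict[str, MoleculeGroup] = {}
    for r in reads:
        if platform == PACBIO:
            parsed = _infer_pacbio(r.read_id)
            if parsed is None:
                if _ONT_NAME.search(r.read_id):
                    raise ValueError(
                        f"read {r.read_id!r} looks like ONT naming in a pacbio run"
                    )
                parsed = (r.read_id, KIND_SUBREAD)
        else:
            if _PACBIO_NAME.match(r.read_id) and "/" in r.read_id:
                raise ValueError(
                    f"read {r.read_id!r} looks like PacBio naming in an ont run"
                )
            parsed = _infer_ont(r.read_id)
        mol, kind = parsed
        meta = (metadata or {}).get(r.read_id) or ReadMeta(kind=kind)
        groups.setdefault(mol, MoleculeGroup(mol)).members.append(MemberRead(r, meta))
    return list(groups.values())


LONG_ONLY = "long_only"
HYBRID = "hybrid"


def _best_in(members: list[MemberRead]) -> MemberRead | None:
    aligned = [m for m in members if m.aligned]
    if not aligned:
        return None
    return min(aligned, key=MemberRead.sort_key)


def select_best(group: MoleculeGroup, platform: str, strategy: str = LONG_ONLY) -> MemberRead | None:
    """Walk the platform/strategy priority ladder; None when nothing aligned."""
    ms = group.members
    if platform == PACBIO:
        if strategy == HYBRID:
            tiers = [
                [
                    m
                    for m in ms
                    if m.meta.kind == KIND_CCS
                    and not m.meta.corrected
                    and (m.meta.passes or 0) > 2
                    and (m.meta.accuracy or 0.0) > 95.0
                ],
                [m for m in ms if m.meta.kind == KIND_CCS and m.meta.corrected],
                [m for m in ms if m.meta.kind == KIND_SUBREAD],
            ]
        else:
            tiers = [
                [m for m in ms if m.meta.kind == KIND_CCS],
                [m for m in ms if m.meta.kind == KIND_SUBREAD],
            ]
    elif platform == ONT:
        # hybrid uses the same ladder over corrected members
        tiers = [
            [m for m in ms if m.meta.kind == KIND_2D],
            [m for m in ms if m.meta.kind == KIND_1D_TEMPLATE],
            [m for m in ms if m.meta.kind == KIND_1D_COMPLEMENT],
        ]
    else:
        raise ValueError(f"unknown platform {platform!r}")
    for tier in tiers:
        best = _best_in(tier)
        if best is not None:
            return best
    return None


def select_best_reads(
    reads: Iterable[ReadAlignment],
    platform: str,
    strategy: str = LONG_ONLY,
    metadata: dict[str, ReadMeta] | None = None,
) -> list[ReadAlignment]:
    """One best read per molecule with >= 1 aligned member."""
    chosen = []
    for g in group_molecules(reads, platform, metadata):
        best = select_best(g, platform, strategy)
        if best is not None:
            chosen.append(best.read)
    return chosen
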