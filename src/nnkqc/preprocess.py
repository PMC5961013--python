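"""Read-to-insert filtering for fixed-layout amplicon sequencing.

Filters apply in a fixed order, each read counted under exactly the first
reason that fails:

1. ``barcode_mismatch`` — the barcode substring must match with 100%
   fidelity at its fixed offset.
2. ``flank_mismatch`` — zero mismatches tolerated anywhere in the non-insert
   region: the upstream flank anchored at the read start and the downstream
   flank anchored at the read end.
3. ``wrong_length`` / ``non_nnk`` / ``missing_cys`` / ``ambiguous_base`` —
   insert-level NNK validation (see :func:`nnkqc.design.is_valid_nnk_insert`).

Anchoring the downstream flank at the 3' end means a 1-nt indel inside the
insert leaves both flanks intact and is rejected as ``wrong_length`` — the
insert-length criterion — rather than masquerading as a flank defect.
Reads are assumed in forward orientation; base qualities are ignored
(filtering is purely sequence-based) unless ``min_mean_q`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .design import (
    LibraryDesign,
    REASON_AMBIGUOUS,
    REASON_MISSING_CYS,
    REASON_NON_NNK,
    REASON_WRONG_LENGTH,
    is_valid_nnk_insert,
)

REASON_BARCODE = "barcode_mismatch"
REASON_FLANK = "flank_mismatch"
ALL_REASONS = (
    REASON_BARCODE,
    REASON_FLANK,
    REASON_WRONG_LENGTH,
    REASON_NON_NNK,
    REASON_MISSING_CYS,
    REASON_AMBIGUOUS,
)


@dataclass
class FilterReport:
    """Tally of accepted reads and per-reason rejections."""

    total_reads: int = 0
    accepted: int = 0
    rejected_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in ALL_REASONS}
    )

    def check_conservation(self) -> bool:
        return self.accepted + sum(self.rejected_by_reason.values()) == self.total_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "accepted": self.accepted,
            "rejected_by_reason": dict(self.rejected_by_reason),
        }


@dataclass
class InsertTable:
    """Accepted nucleotide inserts with read counts plus the filter report."""

    counts: dict[str, int]
    design: LibraryDesign
    report: FilterReport

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["insert", "count"]
        )


def match_barcode(read: str, design: LibraryDesign) -> bool:
    """Exact barcode match at the fixed offset; empty barcode matches all."""
    if not design.barcode:
        return True
    end = design.barcode_offset + len(design.barcode)
    return read[design.barcode_offset : end] == design.barcode


def extract_insert(read: str, design: LibraryDesign) -> Tuple[Optional[str], Optional[str]]:
    """Return (insert, None) or (None, 'flank_mismatch').

    The upstream flank must match exactly at the read start and the
    downstream flank exactly at the read end; the spanned middle (fixed
    cysteines included for constrained designs) is the insert, validated
    separately.
    """
    up, down = design.upstream_flank, design.downstream_flank
    if len(read) < len(up) + len(down):
        return None, REASON_FLANK
    if up and not read.startswith(up):
        return None, REASON_FLANK
    if down and not read.endswith(down):
        return None, REASON_FLANK
    insert = read[len(up) : len(read) - len(down)]
    return insert, None


def classify_read(read: str, design: LibraryDesign) -> Tuple[Optional[str], Optional[str]]:
    """Full filter cascade for one read: (insert, None) or (None, reason)."""
    if not match_barcode(read, design):
        return None, REASON_BARCODE
    insert, reason = extract_insert(read, design)
    if reason is not None:
        return None, reason
    ok, reason = is_valid_nnk_insert(insert, design)
    if not ok:
        return None, reason
    return insert, None


def _iter_reads(fastq, min_mean_q: Optional[float]):
    """Yield (sequence, mean_quality_or_None) from a FASTQ path/handle or an
    iterable of plain sequences."""
    if isinstance(fastq, (str, Path)) or hasattr(fastq, "read"):
        for idx, rec in enumerate(SeqIO.parse(fastq, "fastq")):
            quals = rec.letter_annotations.get("phred_quality")
            mean_q = sum(quals) / len(quals) if quals else None
            yield str(rec.seq).upper(), mean_q
    else:
        for seq in fastq:
            yield str(seq).upper(), None


def run_preprocess(
    fastq: Union[str, Path, Iterable[str]],
    design: LibraryDesign,
    min_mean_q: Optional[float] = None,
) -> InsertTable:
    """Filter a FASTQ down to an InsertTable of validated NNK inserts.

    ``fastq`` may be a path/handle to a FASTQ file or any iterable of read
    sequences.  ``min_mean_q``, if set, drops reads with mean Phred quality
    below the threshold before the sequence filters; such reads are tallied
    under their own ``low_quality`` key so count conservation still holds.
    The option defaults off — the canonical filters are purely sequence-based.
    """
    report = FilterReport()
    if min_mean_q is not None:
        report.rejected_by_reason.setdefault("low_quality", 0)
    counts: dict[str, int] = {}
    for seq, mean_q in _iter_reads(fastq, min_mean_q):
        report.total_reads += 1
        if min_mean_q is not None and mean_q is not None and mean_q < min_mean_q:
            report.rejected_by_reason["low_quality"] += 1
            continue
        insert, reason = classify_read(seq, design)
        if reason is not None:
            report.rejected_by_reason[reason] += 1
            continue
        report.accepted += 1
        counts[insert] = counts.get(insert, 0) + 1
    return InsertTable(counts=counts, design=design, report=report)
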