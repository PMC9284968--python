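"""Per-read pileup consensus over the hotspot.

Each extracted sub-read is aligned back to the target reference; the
base (or deletion) its edit path places over the hotspot becomes one
pileup entry.  The read's call is the plurality of its pileup, with
ties broken uniformly at random from a seeded generator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._align import _aligner, sanitize
from .assay import LampAssay
from .chaining import SubRead

DEFAULT_MIN_ALIGN_IDENTITY = 0.70
DEFAULT_MIN_ALIGN_COLUMNS = 50

NOCALL = "NOCALL"
DEL = "DEL"

__all__ = [
    "SubAlignment",
    "Pileup",
    "ConsensusCall",
    "align_subread",
    "consensus_call",
    "polish_stats",
]


@dataclass(frozen=True)
class SubAlignment:
    subread: SubRead | None
    aligned: bool
    ref_interval: tuple[int, int] | None
    identity: float
    score: int
    locus_call: str  # A/C/G/T/DEL/NOCALL
    cigar: str = ""


@dataclass(frozen=True)
class Pileup:
    """Multiset of hotspot calls from one read's sub-alignments."""

    calls: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.calls)

    @classmethod
    def from_alignments(cls, alignments) -> "Pileup":
        return cls(
            calls=tuple(
                a.locus_call for a in alignments if a.locus_call != NOCALL
            )
        )


@dataclass(frozen=True)
class ConsensusCall:
    call: str  # A/C/G/T/DEL/NOCALL
    support: int
    tie_broken: bool


def _cigar_and_locus(alignment_blocks, query: str, hotspot: int) -> tuple[str, str]:
    """Read the hotspot call (and a CIGAR string) off aligned block pairs."""
    tblocks, qblocks = alignment_blocks
    ops: list[str] = []
    call = NOCALL
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        t0, t1, q0, q1 = int(t0), int(t1), int(q0), int(q1)
        if prev_t is not None:
            if t0 > prev_t:  # deletion in query relative to reference
                ops.append(f"{t0 - prev_t}D")
                if prev_t <= hotspot < t0:
                    call = DEL
            if q0 > prev_q:
                ops.append(f"{q0 - prev_q}I")
        ops.append(f"{t1 - t0}M")
        if t0 <= hotspot < t1:
            call = query[q0 + (hotspot - t0)]
        prev_t, prev_q = t1, q1
    return "".join(ops), call


def align_subread(
    seq: str,
    assay: LampAssay,
    min_identity: float = DEFAULT_MIN_ALIGN_IDENTITY,
    min_columns: int = DEFAULT_MIN_ALIGN_COLUMNS,
    subread: SubRead | None = None,
) -> SubAlignment:
    """Align one target-forward sub-read sequence to the target reference.

    The alignment is accepted when identity >= ``min_identity`` over at
    least ``min_columns`` aligned columns; otherwise the sub-read
    contributes nothing (aligned=False, NOCALL).
    """
    if not seq:
        raise ValueError("empty sub-read sequence")
    seq = sanitize(seq)
    failed = SubAlignment(
        subread=subread, aligned=False, ref_interval=None,
        identity=0.0, score=0, locus_call=NOCALL,
    )
    alignments = _aligner().align(assay.target_ref, seq)
    try:
        if alignments.score <= 0:
            return failed
        best = alignments[0]
    except (IndexError, OverflowError):
        return failed
    counts = best.counts()
    aligned_cols = counts.identities + counts.mismatches
    n_columns = aligned_cols + counts.internal_gaps
    if n_columns < min_columns:
        return failed
    identity = counts.identities / n_columns
    if identity < min_identity:
        return failed
    tblocks, qblocks = best.aligned
    ref_interval = (int(tblocks[0][0]), int(tblocks[-1][1]))
    cigar, call = _cigar_and_locus(best.aligned, seq, assay.hotspot_pos)
    clip_left = int(qblocks[0][0])
    clip_right = len(seq) - int(qblocks[-1][1])
    if clip_left:
        cigar = f"{clip_left}S{cigar}"
    if clip_right:
        cigar = f"{cigar}{clip_right}S"
    return SubAlignment(
        subread=subread,
        aligned=True,
        ref_interval=ref_interval,
        identity=identity,
        score=int(best.score),
        locus_call=call,
        cigar=cigar,
    )


def consensus_call(pileup: Pileup, rng: np.random.Generator) -> ConsensusCall:
    """Plurality call over the pileup; ties broken uniformly via ``rng``."""
    if len(pileup) == 0:
        return ConsensusCall(call=NOCALL, support=0, tie_broken=False)
    counts = Counter(pileup.calls)
    top = max(counts.values())
    winners = sorted(b for b, c in counts.items() if c == top)
    if len(winners) == 1:
        return ConsensusCall(call=winners[0], support=top, tie_broken=False)
    pick = winners[int(rng.integers(len(winners)))]
    return ConsensusCall(call=pick, support=top, tie_broken=True)


def subalignments_to_sam(assay: LampAssay, alignments) -> str:
    """Minimal SAM text of aligned sub-reads against target_ref."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{assay.name}\tLN:{len(assay.target_ref)}",
    ]
    for i, a in enumerate(alignments):
        if not a.aligned:
            continue
        name = (
            f"{a.subread.source_read_id}/{i}" if a.subread is not None else f"sub/{i}"
        )
        seq = a.subread.sequence if a.subread is not None else "*"
        lines.append(
            f"{name}\t0\t{assay.name}\t{a.ref_interval[0] + 1}\t60\t"
            f"{a.cigar or '*'}\t*\t0\t0\t{seq}\t*"
        )
    return "\n".join(lines) + "\n"


def polish_stats(alignments, consensus: ConsensusCall) -> dict:
    """Per-read error-correction summary from the pileup vote."""
    calls = [a.locus_call for a in alignments if a.locus_call != NOCALL]
    overridden = sum(1 for c in calls if c != consensus.call)
    return {
        "n_subreads": len(list(alignments)),
        "n_calls": len(calls),
        "n_overridden": overridden,
        "polished": overridden > 0,
    }
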