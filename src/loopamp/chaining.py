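"""Sub-read extraction: chain design hits around each target hit.

For every TARGET hit on a read, walk outward through neighboring hits
in both directions, accepting a neighbor only when the adjacency
grammar allows it and it sits within the configured gap/overlap
tolerances.  The chained span is extracted (reverse-complemented for
minus-orientation targets) as one concatemer sub-read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from ._align import revcomp, sanitize
from .assay import TARGET, AdjacencyGrammar
from .seeding import SeedHit

DEFAULT_MAX_GAP = 25
DEFAULT_MAX_OVERLAP = 5

__all__ = ["SubRead", "build_subreads", "extract"]


@dataclass(frozen=True)
class SubRead:
    """A chained concatemer unit presumed to contain the target.

    ``sequence`` is the extracted read slice, reverse-complemented when
    ``orientation`` is "-" so that every sub-read is target-forward.
    """

    source_read_id: str
    interval: tuple[int, int]
    constituent_hits: tuple[SeedHit, ...]
    orientation: str
    sequence: str


def _flip_node(node: tuple[str, str]) -> tuple[str, str]:
    label, strand = node
    return (label, "-" if strand == "+" else "+")


def _extend(
    hits: list[SeedHit],
    start_idx: int,
    grammar: AdjacencyGrammar,
    direction: int,
    max_gap: int,
    max_overlap: int,
) -> list[SeedHit]:
    """Greedy walk from hits[start_idx] in ``direction`` (+1 right / -1 left)."""
    chain: list[SeedHit] = []
    current = hits[start_idx]
    idx = start_idx
    while True:
        nxt = None
        j = idx + direction
        while 0 <= j < len(hits):
            cand = hits[j]
            if direction > 0:
                offset = cand.start - current.end
            else:
                offset = current.start - cand.end
            if offset > max_gap:
                j = None  # nothing closer can follow in sorted order
                break
            if offset < -max_overlap:
                j += direction  # contained/deep-overlap hit: skip, keep looking
                continue
            nxt = cand
            break
        if nxt is None:
            break
        if nxt.label == TARGET:
            break  # never absorb a second target
        if direction > 0:
            ok = grammar.allows(current.node(), nxt.node())
        else:
            ok = grammar.allows(nxt.node(), current.node())
        if not ok:
            break
        chain.append(nxt)
        current = nxt
        idx = j
    return chain


def build_subreads(
    read: str,
    hits: list[SeedHit],
    grammar: AdjacencyGrammar,
    read_id: str = "read",
    max_gap: int = DEFAULT_MAX_GAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[SubRead]:
    """One SubRead per TARGET hit; flanking hits may be shared.

    ``hits`` must be sorted by read position (find_hits output).
    Extension stops at the first grammar-violating neighbor, at another
    TARGET hit, or at the read end.
    """
    subreads: list[SubRead] = []
    n = 0
    for i, hit in enumerate(hits):
        if hit.label != TARGET:
            continue
        left = _extend(hits, i, grammar, -1, max_gap, max_overlap)
        right = _extend(hits, i, grammar, +1, max_gap, max_overlap)
        members = tuple(sorted(left + [hit] + right, key=lambda h: h.interval))
        lo = min(h.start for h in members)
        hi = max(h.end for h in members)
        sub = SubRead(
            source_read_id=read_id,
            interval=(lo, hi),
            constituent_hits=members,
            orientation=hit.strand,
            sequence="",
        )
        sub = dataclasses.replace(sub, sequence=extract(read, sub))
        subreads.append(sub)
        n += 1
    return subreads


def extract(read: str, subread: SubRead) -> str:
    """Extract the sub-read slice, target-forward.

    Minus-orientation sub-reads are reverse-complemented so they align
    forward to the target reference.
    """
    lo, hi = subread.interval
    if not (0 <= lo < hi <= len(read)):
        raise RuntimeError(f"sub-read interval {subread.interval} outside read")
    piece = sanitize(read[lo:hi])
    return revcomp(piece) if subread.orientation == "-" else piece


def subreads_to_fasta(subreads) -> str:
    out = []
    for i, s in enumerate(subreads):
        out.append(f">{s.source_read_id}/{i}\n{s.sequence}\n")
    return "".join(out)
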