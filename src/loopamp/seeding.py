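"""Read marking: locate the target seed and design sequences on a read.

Every query (target seed + each design sequence) is aligned locally to
the read on both strands; matches with identity >= ``min_identity`` and
query coverage >= ``min_query_coverage`` are kept.  Multiple copies per
query are found by iterated best-hit extraction: after each accepted
hit its read span is masked with N (which cannot align) and the search
repeats until the best remaining alignment fails the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _align
from ._align import best_local, revcomp
from .assay import TARGET, LampAssay

DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_QUERY_COVERAGE = 0.80

__all__ = ["SeedHit", "local_align", "find_hits", "hits_to_bed"]


@dataclass(frozen=True)
class SeedHit:
    """A located design-sequence (or target-seed) match on a read."""

    label: str
    interval: tuple[int, int]
    strand: str
    identity: float
    score: int

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    def node(self) -> tuple[str, str]:
        return (self.label, self.strand)


def local_align(query: str, read: str):
    """Best stranded local alignment of query against read.

    Returns a LocalHit (score, identity, read interval, strand) or None
    when nothing scores above zero.  Strand is chosen as the better of
    the query and its reverse complement; forward wins ties.
    """
    if not query or not read:
        raise ValueError("local_align requires non-empty sequences")
    return _align.best_local_stranded(read, query)


def _iter_query_hits(
    read: str,
    label: str,
    query: str,
    min_identity: float,
    min_query_coverage: float,
) -> list[SeedHit]:
    masked = list(read)
    qrc = revcomp(query)
    hits: list[SeedHit] = []
    # exact full-query occurrences are provably score-maximal local
    # alignments, so they can be extracted and masked up front, saving a
    # DP round each (fast path for low-error reads)
    exact_score = 2 * len(query)
    for strand, q in (("+", query), ("-", qrc)):
        pos = 0
        while True:
            idx = "".join(masked).find(q, pos)
            if idx < 0:
                break
            hits.append(
                SeedHit(
                    label=label,
                    interval=(idx, idx + len(q)),
                    strand=strand,
                    identity=1.0,
                    score=exact_score,
                )
            )
            for i in range(idx, idx + len(q)):
                masked[i] = _align.MASK_CHAR
            pos = idx + len(q)
    max_rounds = 2 + 2 * (len(read) // max(1, len(query)))
    for _ in range(max_rounds):
        current = "".join(masked)
        fwd = best_local(current, query)
        rev = best_local(current, qrc)
        if rev is not None and (fwd is None or rev.score > fwd.score):
            hit, strand = rev, "-"
        else:
            hit, strand = fwd, "+"
        if hit is None or hit.score <= 0:
            break
        covered = (hit.query_span[1] - hit.query_span[0]) / len(query)
        if hit.identity < min_identity or covered < min_query_coverage:
            break
        hits.append(
            SeedHit(
                label=label,
                interval=hit.interval,
                strand=strand,
                identity=hit.identity,
                score=hit.score,
            )
        )
        for i in range(hit.interval[0], hit.interval[1]):
            masked[i] = _align.MASK_CHAR
    return hits


def find_hits(
    read: str,
    assay: LampAssay,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE,
    include_loops: bool = True,
) -> list[SeedHit]:
    """All seed hits on a read, sorted by read position.

    Hits of one query never overlap each other (masking); hits of
    different queries may.  An empty list is a valid result.
    """
    if not read:
        raise ValueError("find_hits requires a non-empty read")
    read = _align.sanitize(read)
    hits: list[SeedHit] = []
    for label, query in assay.queries(include_loops=include_loops).items():
        hits.extend(
            _iter_query_hits(read, label, query, min_identity, min_query_coverage)
        )
    hits.sort(key=lambda h: (h.interval, h.label, h.strand))
    return hits


def hits_to_bed(read_id: str, hits) -> str:
    """BED lines for a read's hits (identity scaled to 0-1000)."""
    lines = []
    for h in hits:
        lines.append(
            f"{read_id}\t{h.start}\t{h.end}\t{h.label}\t"
            f"{int(round(h.identity * 1000))}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
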