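"""Shared pairwise local-alignment machinery.

All seeding and consensus alignment in this package runs through one
affine-gap local aligner (Biopython's C implementation) with a single
scoring scheme: match +2, mismatch -4, gap open -4, gap extend -2,
where a gap of length L costs open + (L - 1) * extend.  The sentinel
base ``N`` scores heavily negative against everything so that masked
read regions can never be re-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

MATCH = 2
MISMATCH = -4
GAP_OPEN = -4
GAP_EXTEND = -2
MASK_SCORE = -16  # N vs anything; < any achievable column score

MASK_CHAR = "N"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "LocalHit",
    "revcomp",
    "sanitize",
    "best_local",
    "best_local_stranded",
]


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize(seq: str) -> str:
    """Uppercase and replace any non-ACGT character with the mask base."""
    seq = seq.upper()
    if all(c in "ACGT" for c in seq):
        return seq
    return "".join(c if c in "ACGT" else MASK_CHAR for c in seq)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = MATCH if a == b else MISMATCH
    for a in "ACGTN":
        matrix[a, MASK_CHAR] = MASK_SCORE
        matrix[MASK_CHAR, a] = MASK_SCORE
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query against a read.

    ``interval`` is the 0-based half-open span on the read; ``query_span``
    the span on the query *as given* (for strand "-" the reverse
    complement of the query was aligned, and the span refers to it).
    ``identity`` counts matches over aligned columns including internal
    gap columns.
    """

    score: int
    identity: float
    interval: tuple[int, int]
    strand: str
    query_span: tuple[int, int]
    n_columns: int

    @property
    def query_coverage(self) -> float:
        return (self.query_span[1] - self.query_span[0]) / max(
            1, self._query_len
        )

    # set post-hoc by best_local; dataclass frozen so stash via object.__setattr__
    _query_len: int = 0


def _score_alignment(alignment) -> LocalHit | None:
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    if aligned_cols == 0:
        return None
    n_columns = aligned_cols + counts.internal_gaps
    identity = counts.identities / n_columns
    tblocks, qblocks = alignment.aligned
    interval = (int(tblocks[0][0]), int(tblocks[-1][1]))
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    return LocalHit(
        score=int(alignment.score),
        identity=identity,
        interval=interval,
        strand="+",
        query_span=qspan,
        n_columns=n_columns,
    )


def best_local(read: str, query: str) -> LocalHit | None:
    """Best local alignment of ``query`` (as given) against ``read``.

    Returns None when no positive-scoring alignment exists.
    """
    if not read or not query:
        raise ValueError("empty sequence passed to local alignment")
    alignments = _aligner().align(read, query)
    try:
        if alignments.score <= 0:
            return None
        best = alignments[0]
    except (IndexError, OverflowError):
        return None
    hit = _score_alignment(best)
    if hit is None:
        return None
    object.__setattr__(hit, "_query_len", len(query))
    return hit


def best_local_stranded(read: str, query: str) -> LocalHit | None:
    """Best local alignment of query or its reverse complement vs read.

    The forward strand wins ties.  The returned hit's ``strand`` records
    which orientation aligned.
    """
    fwd = best_local(read, query)
    rev = best_local(read, revcomp(query))
    if rev is not None and (fwd is None or rev.score > fwd.score):
        hit = LocalHit(
            score=rev.score,
            identity=rev.identity,
            interval=rev.interval,
            strand="-",
            query_span=rev.query_span,
            n_columns=rev.n_columns,
        )
        object.__setattr__(hit, "_query_len", len(query))
        return hit
    return fwd
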