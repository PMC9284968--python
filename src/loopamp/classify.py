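"""Read classification heuristics.

Every read receives exactly one class, assigned by a fixed precedence
chain: SHORT -> ONT -> TARGET -> FRAGMENT -> SPURIOUS -> BACKGROUND ->
UNKNOWN.  Length and adapter checks are cheap and unambiguous; TARGET
outranks SPURIOUS because genuine concatemers also carry many design
hits.  A simple alignment-position classifier for plain PCR amplicon
runs is provided separately (``classify_amplicon``).

Background detection is a k-mer voting index over a supplied genome
FASTA rather than an external long-read mapper: a read is background
when a sufficient fraction of its k-mers vote consistently for one
reference diagonal.  Without a background index the BACKGROUND test is
skipped and such reads degrade to UNKNOWN.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum

from ._align import best_local_stranded, revcomp, sanitize
from .assay import LampAssay, TARGET
from .consensus import NOCALL, ConsensusCall

SHORT_READ_LENGTH = 60
SPURIOUS_MIN_DESIGN_HITS = 3
ONT_MIN_IDENTITY = 0.80
ONT_MIN_READ_COVERAGE = 0.50
FRAGMENT_MIN_IDENTITY = 0.70
FRAGMENT_MIN_COLUMNS = 50
FRAGMENT_MIN_READ_FRACTION = 0.80


class ReadClass(str, Enum):
    TARGET = "TARGET"
    FRAGMENT = "FRAGMENT"
    SPURIOUS = "SPURIOUS"
    BACKGROUND = "BACKGROUND"
    ONT = "ONT"
    SHORT = "SHORT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ReadDiagnosis:
    read_id: str
    read_class: ReadClass
    consensus: ConsensusCall | None
    n_subreads: int
    n_design_hits: int
    start_time: float | None


class KmerBackgroundIndex:
    """Diagonal-voting k-mer index over a background genome.

    Stand-in for a minimap2-style primary alignment test at desk scale:
    a read maps to background when >= ``min_vote_fraction`` of its
    k-mers land on one (contig, strand) with consistent diagonals.
    """

    def __init__(self, sequences: dict[str, str], k: int = 13,
                 min_vote_fraction: float = 0.10, band: int = 100):
        self.k = k
        self.min_vote_fraction = min_vote_fraction
        self.band = band
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in sequences.items():
            seq = sanitize(seq)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index[kmer].append((name, i))

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "KmerBackgroundIndex":
        from Bio import SeqIO

        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(seqs, **kwargs)

    def maps(self, read: str) -> bool:
        read = sanitize(read)
        k = self.k
        n_kmers = len(read) - k + 1
        if n_kmers < 1:
            return False
        votes: Counter = Counter()
        for strand, seq in (("+", read), ("-", revcomp(read))):
            for i in range(len(seq) - k + 1):
                for name, pos in self._index.get(seq[i : i + k], ()):
                    diag = (pos - i) // self.band
                    votes[(name, strand, diag)] += 1
        if not votes:
            return False
        best = max(votes.values())
        return best / n_kmers >= self.min_vote_fraction


def _matches_adapter(read: str, adapters, min_identity: float,
                     min_coverage: float) -> bool:
    for adapter in adapters:
        try:
            hit = best_local_stranded(read, adapter)
        except ValueError:
            continue
        if hit is None:
            continue
        covered = (hit.interval[1] - hit.interval[0]) / len(read)
        if hit.identity >= min_identity and covered >= min_coverage:
            return True
    return False


def _overlaps_target_region(read: str, assay: LampAssay) -> bool:
    """Does the whole read align acceptably somewhere on target_ref?

    Besides the identity/column floors, the alignment must cover most
    of the read: genuine amplicon fragments align near full-length,
    while chance bridges between design-sequence sites do not.
    """
    from ._align import _aligner

    alignments = _aligner().align(assay.target_ref, sanitize(read))
    try:
        if alignments.score <= 0:
            return False
        best = alignments[0]
    except (IndexError, OverflowError):
        return False
    counts = best.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    if cols < FRAGMENT_MIN_COLUMNS:
        return False
    if counts.identities / cols < FRAGMENT_MIN_IDENTITY:
        return False
    _, qblocks = best.aligned
    covered = int(qblocks[-1][1]) - int(qblocks[0][0])
    if covered / len(read) < FRAGMENT_MIN_READ_FRACTION:
        return False
    return True


def _overlaps_either_strand(read: str, assay: LampAssay) -> bool:
    return _overlaps_target_region(read, assay) or _overlaps_target_region(
        revcomp(sanitize(read)), assay
    )


def classify(
    read: str,
    read_id: str,
    hits,
    subreads,
    subalignments,
    consensus: ConsensusCall | None,
    assay: LampAssay,
    background_index: KmerBackgroundIndex | None = None,
    ont_sequences=(),
    start_time: float | None = None,
    short_length: int = SHORT_READ_LENGTH,
    spurious_min_hits: int = SPURIOUS_MIN_DESIGN_HITS,
) -> ReadDiagnosis:
    """Assign exactly one class to a fully processed read."""
    n_design_hits = sum(1 for h in hits if h.label != TARGET)
    has_locatable_target = any(
        a.aligned and a.locus_call != NOCALL for a in subalignments
    )

    if len(read) < short_length:
        cls = ReadClass.SHORT
    elif ont_sequences and _matches_adapter(
        read, ont_sequences, ONT_MIN_IDENTITY, ONT_MIN_READ_COVERAGE
    ):
        cls = ReadClass.ONT
    elif has_locatable_target:
        cls = ReadClass.TARGET
    elif (
        any(a.aligned for a in subalignments)
        or _overlaps_either_strand(read, assay)
    ):
        cls = ReadClass.FRAGMENT
    elif n_design_hits >= spurious_min_hits:
        cls = ReadClass.SPURIOUS
    elif background_index is not None and background_index.maps(read):
        cls = ReadClass.BACKGROUND
    else:
        cls = ReadClass.UNKNOWN

    return ReadDiagnosis(
        read_id=read_id,
        read_class=cls,
        consensus=consensus if cls is ReadClass.TARGET else None,
        n_subreads=len(list(subreads)),
        n_design_hits=n_design_hits,
        start_time=start_time,
    )


def classify_amplicon(
    read: str,
    assay: LampAssay,
    background_index: KmerBackgroundIndex | None = None,
    short_length: int = SHORT_READ_LENGTH,
) -> ReadClass:
    """Alignment-position classifier for plain (non-concatemer) amplicons.

    The single best (primary) local alignment of the read against the
    amplicon reference decides: TARGET when it covers the hotspot,
    FRAGMENT when it overlaps the amplicon but misses the hotspot,
    BACKGROUND when the read maps to the background genome instead.
    """
    if len(read) < short_length:
        return ReadClass.SHORT
    from ._align import _aligner

    best_hit = None
    seq = sanitize(read)
    for oriented in (seq, revcomp(seq)):
        alignments = _aligner().align(assay.target_ref, oriented)
        try:
            if alignments.score <= 0:
                continue
            best = alignments[0]
        except (IndexError, OverflowError):
            continue
        counts = best.counts()
        cols = counts.identities + counts.mismatches + counts.internal_gaps
        if cols < FRAGMENT_MIN_COLUMNS:
            continue
        if counts.identities / cols < FRAGMENT_MIN_IDENTITY:
            continue
        if best_hit is None or best.score > best_hit[0]:
            tblocks, _ = best.aligned
            best_hit = (best.score, int(tblocks[0][0]), int(tblocks[-1][1]))
    if best_hit is not None:
        _, lo, hi = best_hit
        if lo <= assay.hotspot_pos < hi:
            return ReadClass.TARGET
        return ReadClass.FRAGMENT
    if background_index is not None and background_index.maps(read):
        return ReadClass.BACKGROUND
    return ReadClass.UNKNOWN


def amplicon_locus_call(read: str, assay: LampAssay) -> str:
    """Hotspot base under the primary alignment (amplicon mode)."""
    from ._align import _aligner
    from .consensus import _cigar_and_locus

    best_call = NOCALL
    best_score = 0
    seq = sanitize(read)
    for oriented in (seq, revcomp(seq)):
        alignments = _aligner().align(assay.target_ref, oriented)
        try:
            if alignments.score <= 0:
                continue
            best = alignments[0]
        except (IndexError, OverflowError):
            continue
        if best.score <= best_score:
            continue
        counts = best.counts()
        cols = counts.identities + counts.mismatches + counts.internal_gaps
        if cols < FRAGMENT_MIN_COLUMNS or counts.identities / cols < FRAGMENT_MIN_IDENTITY:
            continue
        _, call = _cigar_and_locus(best.aligned, oriented, assay.hotspot_pos)
        best_score = best.score
        best_call = call
    return best_call
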