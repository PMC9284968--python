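"""FASTQ streaming (batch and follow mode) and pipeline orchestration.

Batch mode sorts reads by their ``start_time`` header field before
emission; follow mode tails a directory, emitting reads as new FASTQ
files appear.  The pipeline itself is strictly incremental — per-read
state updates, no global re-pass — so follow-mode reports are available
continuously and the final report is identical to a batch run.
"""

from __future__ import annotations

import glob
import json
import logging
import math
import os
import time as _time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from . import __version__
from .assay import LampAssay, build_grammar
from .chaining import DEFAULT_MAX_GAP, DEFAULT_MAX_OVERLAP, build_subreads
from .classify import (
    KmerBackgroundIndex,
    ReadClass,
    ReadDiagnosis,
    SHORT_READ_LENGTH,
    SPURIOUS_MIN_DESIGN_HITS,
    classify,
)
from .consensus import (
    DEFAULT_MIN_ALIGN_COLUMNS,
    DEFAULT_MIN_ALIGN_IDENTITY,
    Pileup,
    align_subread,
    consensus_call,
)
from .report import (
    DEFAULT_SUPPORT_TARGET,
    NOT_REACHED,
    SupportTimeline,
    VafReport,
    proportion_ci,
)
from .seeding import DEFAULT_MIN_IDENTITY, DEFAULT_MIN_QUERY_COVERAGE, find_hits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str
    start_time: float | None  # absolute seconds (POSIX or plain float field)


def _parse_start_time(description: str) -> float | None:
    for token in description.split():
        if token.startswith("start_time="):
            value = token[len("start_time=") :]
            try:
                return float(value)
            except ValueError:
                pass
            try:
                if value.endswith("Z"):
                    value = value[:-1] + "+00:00"
                return datetime.fromisoformat(value).timestamp()
            except ValueError:
                logger.warning("unparseable start_time %r", value)
                return None
    return None


def parse_fastq(path) -> tuple[list[ReadRecord], int]:
    """Tolerant FASTQ parse; returns (records, n_skipped_malformed)."""
    records: list[ReadRecord] = []
    skipped = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    for i in range(0, len(lines), 4):
        chunk = lines[i : i + 4]
        if len(chunk) < 4:
            skipped += 1
            logger.warning("%s: truncated record at line %d", path, i + 1)
            break
        header, seq, sep, qual = chunk
        if (
            not header.startswith("@")
            or not sep.startswith("+")
            or not seq
            or len(seq) != len(qual)
        ):
            skipped += 1
            logger.warning("%s: malformed record at line %d", path, i + 1)
            continue
        fields = header[1:].split(None, 1)
        read_id = fields[0] if fields else f"read{i // 4}"
        desc = fields[1] if len(fields) > 1 else ""
        records.append(
            ReadRecord(
                read_id=read_id,
                sequence=seq.upper(),
                quality=qual,
                start_time=_parse_start_time(desc),
            )
        )
    return records, skipped


def _sorted_by_time(records: list[ReadRecord]) -> list[ReadRecord]:
    timed = [r for r in records if r.start_time is not None]
    untimed = [r for r in records if r.start_time is None]
    timed.sort(key=lambda r: r.start_time)
    return timed + untimed


def stream_reads(source, follow: bool = False, poll_interval: float = 0.2,
                 idle_timeout: float | None = None):
    """Yield ReadRecords from a FASTQ file, list of files, or directory.

    Batch mode (follow=False) emits all reads sorted by start_time.
    Follow mode watches a directory, emitting each new file's reads
    (time-sorted within the file) as it appears, and stops after
    ``idle_timeout`` seconds without new files (None = run forever).
    """
    if follow:
        yield from _follow(source, poll_interval, idle_timeout)
        return
    if isinstance(source, (str, Path)) and os.path.isdir(source):
        paths = sorted(glob.glob(os.path.join(str(source), "*.fastq")))
    elif isinstance(source, (list, tuple)):
        paths = [str(p) for p in source]
    else:
        paths = [str(source)]
    records: list[ReadRecord] = []
    for p in paths:
        recs, _ = parse_fastq(p)
        records.extend(recs)
    yield from _sorted_by_time(records)


def _follow(directory, poll_interval, idle_timeout):
    seen: set[str] = set()
    idle = 0.0
    last_time = -math.inf
    while True:
        paths = sorted(glob.glob(os.path.join(str(directory), "*.fastq")))
        new = [p for p in paths if p not in seen]
        if not new:
            if idle_timeout is not None and idle >= idle_timeout:
                return
            _time.sleep(poll_interval)
            idle += poll_interval
            continue
        idle = 0.0
        for p in new:
            seen.add(p)
            recs, _ = parse_fastq(p)
            for r in _sorted_by_time(recs):
                if r.start_time is not None:
                    if r.start_time < last_time:
                        logger.warning(
                            "out-of-order start_time in follow mode: %s", r.read_id
                        )
                    last_time = max(last_time, r.start_time)
                yield r


@dataclass
class PipelineConfig:
    """All thresholds for a pipeline run (echoed in the report)."""

    min_identity: float = DEFAULT_MIN_IDENTITY
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE
    include_loops: bool = True
    max_gap: int = DEFAULT_MAX_GAP
    max_overlap: int = DEFAULT_MAX_OVERLAP
    min_align_identity: float = DEFAULT_MIN_ALIGN_IDENTITY
    min_align_columns: int = DEFAULT_MIN_ALIGN_COLUMNS
    short_length: int = SHORT_READ_LENGTH
    spurious_min_hits: int = SPURIOUS_MIN_DESIGN_HITS
    adapters: tuple = ()
    support_target: int = DEFAULT_SUPPORT_TARGET
    ci_level: float = 0.95
    ci_method: str = "wald"
    seed: int = 0


class Pipeline:
    """Incremental seed -> chain -> consensus -> classify -> tally engine."""

    def __init__(
        self,
        assay: LampAssay,
        config: PipelineConfig | None = None,
        background_index: KmerBackgroundIndex | None = None,
    ):
        self.assay = assay
        self.config = config or PipelineConfig()
        self.grammar = build_grammar(assay)
        self.background_index = background_index
        self.rng = np.random.default_rng(self.config.seed)
        self.class_counts: dict[str, int] = {c.value: 0 for c in ReadClass}
        self.n_mut = 0
        self.n_wt = 0
        self.n_other = 0
        self.supporting: list[tuple[float, bool]] = []  # (abs time, is_mutant)
        self.n_untimed_support = 0
        self.diagnoses: list[ReadDiagnosis] = []

    def process_read(self, record: ReadRecord) -> ReadDiagnosis:
        cfg = self.config
        seq = record.sequence
        if len(seq) < cfg.short_length:
            hits, subreads, subalignments = [], [], []
        else:
            hits = find_hits(
                seq,
                self.assay,
                min_identity=cfg.min_identity,
                min_query_coverage=cfg.min_query_coverage,
                include_loops=cfg.include_loops,
            )
            subreads = build_subreads(
                seq, hits, self.grammar, read_id=record.read_id,
                max_gap=cfg.max_gap, max_overlap=cfg.max_overlap,
            )
            subalignments = [
                align_subread(
                    s.sequence, self.assay,
                    min_identity=cfg.min_align_identity,
                    min_columns=cfg.min_align_columns,
                    subread=s,
                )
                for s in subreads
            ]
        consensus = consensus_call(
            Pileup.from_alignments(subalignments), self.rng
        )
        diagnosis = classify(
            seq,
            record.read_id,
            hits,
            subreads,
            subalignments,
            consensus,
            self.assay,
            background_index=self.background_index,
            ont_sequences=cfg.adapters,
            start_time=record.start_time,
            short_length=cfg.short_length,
            spurious_min_hits=cfg.spurious_min_hits,
        )
        self._tally(diagnosis)
        return diagnosis

    def _tally(self, d: ReadDiagnosis) -> None:
        self.class_counts[d.read_class.value] += 1
        self.diagnoses.append(d)
        if d.read_class is not ReadClass.TARGET or d.consensus is None:
            return
        call = d.consensus.call
        if call == self.assay.wildtype_allele:
            self.n_wt += 1
            is_mut = False
        elif call in self.assay.mutant_alleles:
            self.n_mut += 1
            is_mut = True
        else:
            self.n_other += 1
            return
        if d.start_time is None:
            self.n_untimed_support += 1
        else:
            self.supporting.append((d.start_time, is_mut))

    # -- reporting ---------------------------------------------------------

    def vaf_report(self) -> VafReport:
        support = self.n_mut + self.n_wt
        ci = (
            proportion_ci(self.n_mut, support, self.config.ci_level,
                          self.config.ci_method)
            if support
            else None
        )
        return VafReport(
            n_mut=self.n_mut, n_wt=self.n_wt, n_other=self.n_other,
            ci=ci, confidence=self.config.ci_level,
        )

    def timeline(self) -> SupportTimeline:
        """Support timeline with times relative to the earliest read seen."""
        times = [t for t, _ in self.supporting]
        if self.diagnoses:
            all_times = [
                d.start_time for d in self.diagnoses if d.start_time is not None
            ]
        else:
            all_times = []
        t0 = min(all_times) if all_times else 0.0
        tl = SupportTimeline()
        mut = 0
        for i, (t, is_mut) in enumerate(sorted(self.supporting), start=1):
            mut += int(is_mut)
            tl.points.append((t - t0, i, mut / i))
        return tl

    def report(self) -> dict:
        from dataclasses import asdict

        from .report import time_to_support

        vaf = self.vaf_report()
        tl = self.timeline()
        tts = time_to_support(tl, self.config.support_target)
        return {
            "tool": "loopamp",
            "version": __version__,
            "assay": self.assay.name,
            "seed": self.config.seed,
            "config": asdict(self.config) | {"adapters": list(self.config.adapters)},
            "n_reads": len(self.diagnoses),
            "counts": dict(self.class_counts),
            "vaf": {
                "n_mut": vaf.n_mut,
                "n_wt": vaf.n_wt,
                "n_other": vaf.n_other,
                "support": vaf.support,
                "vaf": vaf.vaf,
                "ci": list(vaf.ci) if vaf.ci else None,
                "confidence": vaf.confidence,
            },
            "support_target": self.config.support_target,
            "time_to_support": None if tts == NOT_REACHED else tts,
        }

    def per_read_tsv(self) -> str:
        lines = ["read_id\tclass\tcall\tsupport\tn_subreads\tn_design_hits\tstart_time"]
        for d in self.diagnoses:
            call = d.consensus.call if d.consensus else "."
            support = d.consensus.support if d.consensus else 0
            t = f"{d.start_time:.6f}" if d.start_time is not None else "."
            lines.append(
                f"{d.read_id}\t{d.read_class.value}\t{call}\t{support}\t"
                f"{d.n_subreads}\t{d.n_design_hits}\t{t}"
            )
        return "\n".join(lines) + "\n"

    def timeline_tsv(self) -> str:
        lines = ["time_s\tcumulative_support\trunning_vaf"]
        for t, n, v in self.timeline().points:
            lines.append(f"{t:.6f}\t{n}\t{v:.6f}")
        return "\n".join(lines) + "\n"

    def to_vcf(self) -> str:
        """Minimal single-record VCF at the hotspot (1-based position)."""
        vaf = self.vaf_report()
        header = (
            "##fileformat=VCFv4.2\n"
            f"##source=loopamp {__version__}\n"
            f"##contig=<ID={self.assay.name},length={len(self.assay.target_ref)}>\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Support">\n'
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        if vaf.support == 0:
            return header
        alt = self.assay.mutant_alleles[0]
        line = (
            f"{self.assay.name}\t{self.assay.hotspot_pos + 1}\t.\t"
            f"{self.assay.wildtype_allele}\t{alt}\t.\t.\t"
            f"DP={vaf.support};AF={vaf.vaf:.6f}\n"
        )
        return header + line


def run_pipeline(
    assay: LampAssay,
    source,
    config: PipelineConfig | None = None,
    background_fasta=None,
    follow: bool = False,
    idle_timeout: float | None = None,
) -> tuple[dict, Pipeline]:
    """Execute the full per-read pipeline over a FASTQ source."""
    bg = (
        KmerBackgroundIndex.from_fasta(background_fasta)
        if background_fasta
        else None
    )
    pipe = Pipeline(assay, config=config, background_index=bg)
    for record in stream_reads(source, follow=follow, idle_timeout=idle_timeout):
        pipe.process_read(record)
    return pipe.report(), pipe


def write_outputs(pipe: Pipeline, out_dir, vcf: bool = False) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = pipe.report()
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out_dir / "reads.tsv").write_text(pipe.per_read_tsv())
    (out_dir / "timeline.tsv").write_text(pipe.timeline_tsv())
    if vcf:
        (out_dir / "call.vcf").write_text(pipe.to_vcf())
    return report
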