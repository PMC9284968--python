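"""Synthetic LAMP sequencing libraries with truth labels.

Generates proper concatemers (alternating-orientation repeats of the
core amplicon unit), fragments, spurious primer products, background
genomic slices, adapter reads and short junk, under an independent
per-base substitution/insertion/deletion error model with Poisson read
arrivals.  Every read carries a truth record so the whole pipeline can
be validated without external data.

The module also ships demo assays: a fully synthetic one whose
reference is built from random design sequences, and assays built
around the published H3F3A/HIST1H3B K27M LAMP primer sets (their
genomic flanks are synthetic filler; they exercise primer parsing and
the pipeline, not the real genome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from functools import lru_cache

import numpy as np

from ._align import revcomp
from .assay import LampAssay, make_assay

BASES = "ACGT"
RUN_EPOCH = datetime(2022, 1, 1, tzinfo=timezone.utc)

#: published LAMP primer sets (poly-T linker joins the inner-primer halves)
H3F3A_PRIMERS = {
    "F3": "GTTTGGTAGTTGCATATGGTG",
    "B3": "ATACCTGTAACGATGAGGTTTC",
    "FIP": "GCGGGCAGTCTGCTTTGTATTTTATGCTGGTAGGTAAGTAAGGA",
    "BIP": "CGACCGGTGGTAAAGCACCTTTTCACCCCTCCAGTAGAG",
    "FLP": "CGAGCCATGGTACAGAGAC",
    "BLP": "CAGGAAGCAACTGGCTACA",
}
HIST1H3B_PRIMERS = {
    "F3": "GATCGGTCTTGAAGTCTTGG",
    "B3": "ATAGTTGGTGGTCTGACTCTAT",
    "FIP": "AAAGCCTCACCGTTACCGTTTTCCGAATCAGCAACTCG",
    "BIP": "GAGCAGCCTTGGTAGCCAGTTTTGGCTCGTACTAAACAGACAG",
    "FLP": "GAGATCCGCCGCTACCAA",
    "BLP": "TTACCGCCGGTGGATTTC",
}
LINKER = "TTTT"

#: demo sequencing-adapter sequence used by simulator and CLI defaults
DEMO_ADAPTER = (
    "GGTGCTGTTCCAGGTACGTACTTCGAACCTGAAGGCATCATCGTAGACCTTGAGGTCAAC"
)

DEFAULT_MIXTURE = {
    "target": 0.40,
    "fragment": 0.10,
    "spurious": 0.15,
    "background": 0.15,
    "ont": 0.08,
    "short": 0.07,
    "unknown": 0.05,
}

_FILL = 20  # bp of filler between design sites on synthetic references
_SEED_FILL = 5


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def synthetic_reference(designs: dict[str, str], center: str,
                        rng: np.random.Generator) -> str:
    """Assemble a forward-strand amplicon reference around design sites."""
    fill = lambda n: _random_dna(rng, n)  # noqa: E731
    parts = [designs["F3"], fill(_FILL), designs["F2"], fill(_FILL)]
    if "FLP" in designs:
        parts += [revcomp(designs["FLP"]), fill(_FILL)]
    parts += [designs["F1"], fill(_SEED_FILL), center, fill(_SEED_FILL),
              revcomp(designs["B1"]), fill(_FILL)]
    if "BLP" in designs:
        parts += [designs["BLP"], fill(_FILL)]
    parts += [revcomp(designs["B2"]), fill(_FILL), revcomp(designs["B3"])]
    return "".join(parts)


@lru_cache(maxsize=8)
def demo_assay(kind: str = "synthetic") -> LampAssay:
    """A deterministic, fully specified demo assay.

    ``synthetic`` uses random design sequences; ``h3f3a``/``hist1h3b``
    use the published primer sets with synthetic genomic filler.
    """
    rng = np.random.default_rng(271828)
    if kind == "synthetic":
        designs = {
            label: _random_dna(rng, 20)
            for label in ("F3", "F2", "F1", "B1", "B2", "B3", "FLP", "BLP")
        }
        linker = None
    elif kind == "h3f3a":
        designs, linker = dict(H3F3A_PRIMERS), LINKER
    elif kind == "hist1h3b":
        designs, linker = dict(HIST1H3B_PRIMERS), LINKER
    else:
        raise ValueError(f"unknown demo assay {kind!r}")

    center = _random_dna(rng, 41)
    mid = len(center) // 2
    center = center[:mid] + "A" + center[mid + 1 :]  # wildtype hotspot base

    if linker:  # resolve F1/F2/B1/B2 from the inner primers for ref assembly
        from .assay import split_inner_primers

        (f1c, f2), (b1c, b2) = split_inner_primers(
            designs["FIP"], designs["BIP"], linker
        )
        site_designs = {
            **{k: v for k, v in designs.items() if k not in ("FIP", "BIP")},
            "F1": revcomp(f1c), "F2": f2, "B1": revcomp(b1c), "B2": b2,
        }
    else:
        site_designs = designs
    ref = synthetic_reference(site_designs, center, rng)
    hotspot = ref.find(center) + mid
    return make_assay(
        name=f"demo-{kind}",
        target_ref=ref,
        hotspot_pos=hotspot,
        mutant_alleles=("T",),
        designs=designs,
        linker=linker,
    )


@lru_cache(maxsize=2)
def background_contig(length: int = 100_000, seed: int = 20220101) -> str:
    """Deterministic synthetic background 'genome' contig."""
    return _random_dna(np.random.default_rng(seed), length)


@dataclass(frozen=True)
class SimulationConfig:
    assay: LampAssay
    n_reads: int = 1000
    true_vaf: float = 0.5
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    unit_geom_p: float = 0.45
    max_units: int = 8
    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    arrival_rate: float = 20.0  # reads / second
    seed: int = 0
    adapter: str = DEMO_ADAPTER
    quality_char: str = "I"
    imbalanced_target_fraction: float = 0.0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0 <= self.true_vaf <= 1:
            raise ValueError("true_vaf must lie in [0, 1]")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        unknown = set(self.mixture) - set(DEFAULT_MIXTURE)
        if unknown:
            raise ValueError(f"unknown mixture classes {sorted(unknown)}")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r < 0.5:
                raise ValueError(f"{name}={r} outside [0, 0.5)")
        if self.arrival_rate <= 0:
            raise ValueError("arrival_rate must be positive")
        if not 0 <= self.imbalanced_target_fraction <= 1:
            raise ValueError("imbalanced_target_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    true_class: str
    allele: str | None
    n_units: int
    unit_spans: tuple[tuple[int, int], ...]  # target-seed spans on the CLEAN read
    start_time: float  # seconds since run start
    clean_sequence: str

    @property
    def iso_time(self) -> str:
        return (RUN_EPOCH + timedelta(seconds=self.start_time)).isoformat()


def _sites(assay: LampAssay) -> dict[str, tuple[int, int]]:
    out = {}
    for label in assay.designs:
        site = assay.design_site(label)
        if site is None:
            raise ValueError(f"design {label} not locatable on target_ref")
        out[label] = site
    return out


def simulate_concatemer(
    assay: LampAssay,
    n_units: int,
    allele: str,
    rng: np.random.Generator,
    with_terminals: bool | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Clean concatemer DNA plus the target-seed span of every unit.

    Units are alternating-orientation copies of the core amplicon slice
    (F2 site through B2 site); terminal F3/B3 flanks are optionally
    attached at the read extremities.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    ref = assay.target_ref
    if allele != ref[assay.hotspot_pos]:
        ref = ref[: assay.hotspot_pos] + allele + ref[assay.hotspot_pos + 1 :]
    sites = _sites(assay)
    f3s, f2s = sites["F3"], sites["F2"]
    b2s, b3s = sites["B2"], sites["B3"]
    unit = ref[f2s[0] : b2s[1]]
    span_lo, span_hi = assay.target_span
    off = (span_lo - f2s[0], span_hi - f2s[0])

    first_forward = bool(rng.integers(2))
    if with_terminals is None:
        with_terminals = bool(rng.integers(2))

    pieces: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    if with_terminals:
        left = ref[f3s[0] : f2s[0]] if first_forward else revcomp(ref[b2s[1] : b3s[1]])
        pieces.append(left)
        pos += len(left)
    forward = first_forward
    for _ in range(n_units):
        if forward:
            pieces.append(unit)
            spans.append((pos + off[0], pos + off[1]))
        else:
            pieces.append(revcomp(unit))
            spans.append((pos + len(unit) - off[1], pos + len(unit) - off[0]))
        pos += len(unit)
        forward = not forward
    if with_terminals:
        last_forward = not forward  # orientation of the final unit
        right = ref[b2s[1] : b3s[1]] if last_forward else revcomp(ref[f3s[0] : f2s[0]])
        pieces.append(right)
    return "".join(pieces), spans


def simulate_imbalanced_read(
    assay: LampAssay, allele: str, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """A concatemer whose long section misses the hotspot.

    Mimics reads whose longer, non-target concatemer section wins the
    primary alignment under a standard aligner while a short flanked
    target copy carries the diagnostic base.
    """
    ref = assay.target_ref
    if allele != ref[assay.hotspot_pos]:
        ref = ref[: assay.hotspot_pos] + allele + ref[assay.hotspot_pos + 1 :]
    sites = _sites(assay)
    f1s, b1s = sites["F1"], sites["B1"]
    span_lo, span_hi = assay.target_span
    # short target section: F1 site through B1 site
    short = ref[f1s[0] : b1s[1]]
    short_off = (span_lo - f1s[0], span_hi - f1s[0])
    # long non-target section: alternating-orientation copies of the
    # pre-hotspot reference, so no single monotone alignment can chain
    # the long section into the short target section
    frag = ref[: assay.hotspot_pos - 10]
    n_copies = 2 * (1 + int(rng.integers(2)))  # even: rc(frag) abuts short
    pieces = [frag if i % 2 == 0 else revcomp(frag) for i in range(n_copies)]
    long_len = len(frag) * n_copies
    seq = "".join(pieces) + short
    spans = [(long_len + short_off[0], long_len + short_off[1])]
    return seq, spans


def corrupt(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> str:
    """Independent per-base substitution / insertion / deletion noise."""
    for name, r in (("sub_rate", sub_rate), ("ins_rate", ins_rate),
                    ("del_rate", del_rate)):
        if not 0 <= r < 0.5:
            raise ValueError(f"{name}={r} outside [0, 0.5)")
    if not seq or (sub_rate == 0 and ins_rate == 0 and del_rate == 0):
        return seq
    n = len(seq)
    dels = rng.random(n) < del_rate
    subs = rng.random(n) < sub_rate
    inserts = rng.random(n + 1) < ins_rate
    out: list[str] = []
    for i, base in enumerate(seq):
        if inserts[i]:
            out.append(BASES[int(rng.integers(4))])
        if dels[i]:
            continue
        if subs[i]:
            alts = BASES.replace(base, "") if base in BASES else BASES
            out.append(alts[int(rng.integers(len(alts)))])
        else:
            out.append(base)
    if inserts[n]:
        out.append(BASES[int(rng.integers(4))])
    return "".join(out)


@dataclass(frozen=True)
class SimulatedRun:
    config: SimulationConfig
    reads: tuple[SimulatedRead, ...]

    def to_fastq(self) -> str:
        chunks = []
        for r in self.reads:
            qual = self.config.quality_char * len(r.sequence)
            chunks.append(
                f"@{r.read_id} start_time={r.iso_time}\n{r.sequence}\n+\n{qual}\n"
            )
        return "".join(chunks)

    def to_truth_tsv(self) -> str:
        lines = ["read_id\tclass\tallele\tn_units\tunit_spans\tstart_time"]
        for r in self.reads:
            spans = ";".join(f"{a}-{b}" for a, b in r.unit_spans)
            lines.append(
                f"{r.read_id}\t{r.true_class}\t{r.allele or '.'}\t"
                f"{r.n_units}\t{spans or '.'}\t{r.start_time:.6f}"
            )
        return "\n".join(lines) + "\n"

    def write(self, fastq_path, truth_path=None) -> None:
        with open(fastq_path, "w") as fh:
            fh.write(self.to_fastq())
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                fh.write(self.to_truth_tsv())


def _noisy(cfg: SimulationConfig, seq: str, rng) -> str:
    return corrupt(seq, cfg.sub_rate, cfg.ins_rate, cfg.del_rate, rng)


def simulate_run(config: SimulationConfig) -> SimulatedRun:
    """Draw a full library from the class mixture (seeded, deterministic)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    assay = cfg.assay
    contig = background_contig()
    classes = sorted(cfg.mixture)
    probs = np.array([cfg.mixture[c] for c in classes])

    gaps = rng.exponential(1.0 / cfg.arrival_rate, size=cfg.n_reads)
    times = np.cumsum(gaps)

    reads: list[SimulatedRead] = []
    for i in range(cfg.n_reads):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        allele = None
        n_units = 0
        spans: list[tuple[int, int]] = []
        if cls == "target":
            allele = (
                assay.mutant_alleles[0]
                if rng.random() < cfg.true_vaf
                else assay.wildtype_allele
            )
            if rng.random() < cfg.imbalanced_target_fraction:
                clean, spans = simulate_imbalanced_read(assay, allele, rng)
                n_units = 1
            else:
                n_units = min(int(rng.geometric(cfg.unit_geom_p)), cfg.max_units)
                clean, spans = simulate_concatemer(assay, n_units, allele, rng)
        elif cls == "fragment":
            hp = assay.hotspot_pos
            left_room = hp - 10
            right_room = len(assay.target_ref) - (hp + 11)
            if left_room >= 60 and (right_room < 60 or rng.random() < 0.5):
                hi = left_room
                length = int(rng.integers(60, hi + 1))
                start = int(rng.integers(0, hi - length + 1))
                clean = assay.target_ref[start : start + length]
            else:
                lo = hp + 11
                length = int(rng.integers(60, right_room + 1))
                start = lo + int(rng.integers(0, right_room - length + 1))
                clean = assay.target_ref[start : start + length]
            if rng.integers(2):
                clean = revcomp(clean)
        elif cls == "spurious":
            n_pieces = int(rng.integers(4, 9))
            labels = list(assay.designs)
            pieces = []
            for _ in range(n_pieces):
                seq = assay.designs[labels[int(rng.integers(len(labels)))]].sequence
                if rng.integers(2):
                    seq = revcomp(seq)
                pieces.append(seq)
            clean = "".join(pieces)
        elif cls == "background":
            length = int(rng.integers(100, 1001))
            start = int(rng.integers(0, len(contig) - length))
            clean = contig[start : start + length]
            if rng.integers(2):
                clean = revcomp(clean)
        elif cls == "ont":
            clean = cfg.adapter + _random_dna(rng, 15)
        elif cls == "short":
            clean = _random_dna(rng, int(rng.integers(20, 51)))
        else:  # unknown
            clean = _random_dna(rng, int(rng.integers(150, 401)))

        noisy = clean if cls == "short" else _noisy(cfg, clean, rng)
        if not noisy:
            noisy = clean
        reads.append(
            SimulatedRead(
                read_id=f"sim{i:06d}",
                sequence=noisy,
                true_class=cls.upper(),
                allele=allele,
                n_units=n_units,
                unit_spans=tuple(spans),
                start_time=float(times[i]),
                clean_sequence=clean,
            )
        )
    return SimulatedRun(config=cfg, reads=tuple(reads))
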