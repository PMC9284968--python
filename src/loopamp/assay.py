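"""LAMP assay schema: design sequences, target reference, hotspot, grammar.

An assay bundles the six core design sequences (F3/F2/F1/B1/B2/B3, loop
primers FLP/BLP optional), the amplicon-region reference, the hotspot
position with its wildtype/mutant alleles, and the span of the target
seed used for read marking.  ``build_grammar`` derives the adjacency
rules a properly formed concatemer must follow.

Orientation convention: F-side design sequences (F3, F2, F1) are stored
in the forward orientation of ``target_ref``; B-side sequences (B1, B2,
B3) and FLP are reverse-strand; BLP is forward-strand.  On the forward
strand of the reference the layout is therefore::

    F3  F2  rc(FLP)  F1  ...target...  rc(B1)  BLP  rc(B2)  rc(B3)

Inner primers FIP/BIP are accepted in the assay file and split on their
poly-T linker into F1c+F2 / B1c+B2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._align import revcomp

CORE_LABELS = ("F3", "F2", "F1", "B1", "B2", "B3")
LOOP_LABELS = ("FLP", "BLP")
ALL_LABELS = CORE_LABELS + LOOP_LABELS
TARGET = "TARGET"

#: strand each design label is expected on for a forward amplicon copy
FORWARD_STRAND_OF = {
    "F3": "+", "F2": "+", "F1": "+", "FLP": "-",
    "B1": "-", "B2": "-", "B3": "-", "BLP": "+",
    TARGET: "+",
}

#: default extension of the inter-F1/B1 region when deriving target_span
SEED_PAD = 5


class AssayValidationError(ValueError):
    """Raised when an assay definition violates a schema invariant."""


@dataclass(frozen=True)
class DesignSequence:
    label: str
    sequence: str

    def __post_init__(self):
        if self.label not in ALL_LABELS:
            raise AssayValidationError(f"unknown design label {self.label!r}")
        if not self.sequence:
            raise AssayValidationError(f"design {self.label}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise AssayValidationError(
                f"design {self.label}: non-DNA characters {sorted(bad)}"
            )


def _flip(node: tuple[str, str]) -> tuple[str, str]:
    label, strand = node
    return (label, "-" if strand == "+" else "+")


@dataclass(frozen=True)
class AdjacencyGrammar:
    """Legal right-neighbor sets for design hits in a proper concatemer.

    ``allowed_right[(label, strand)]`` is the frozenset of (label, strand)
    pairs that may legally follow it (left to right on the read).  The
    relation is symmetric under reverse complementation of the whole
    read: a -> b implies flip(b) -> flip(a).
    """

    allowed_right: dict[tuple[str, str], frozenset[tuple[str, str]]]

    def allows(self, left: tuple[str, str], right: tuple[str, str]) -> bool:
        return right in self.allowed_right.get(left, frozenset())

    def left_neighbors(self, node: tuple[str, str]) -> frozenset[tuple[str, str]]:
        return frozenset(
            a for a, rights in self.allowed_right.items() if node in rights
        )


@dataclass(frozen=True)
class LampAssay:
    name: str
    target_ref: str
    hotspot_pos: int
    wildtype_allele: str
    mutant_alleles: tuple[str, ...]
    designs: dict[str, DesignSequence]
    target_span: tuple[int, int]
    linker: str | None = None

    def __post_init__(self):
        ref = self.target_ref
        if not ref or set(ref) - set("ACGT"):
            raise AssayValidationError("target_ref: empty or non-DNA")
        for label in CORE_LABELS:
            if label not in self.designs:
                raise AssayValidationError(f"missing required design {label}")
        lo, hi = self.target_span
        if not (0 <= lo < hi <= len(ref)):
            raise AssayValidationError(
                f"target_span {self.target_span} outside target_ref[0,{len(ref)})"
            )
        if not (lo <= self.hotspot_pos < hi):
            raise AssayValidationError(
                f"hotspot_pos {self.hotspot_pos} outside target_span {self.target_span}"
            )
        if self.wildtype_allele != ref[self.hotspot_pos]:
            raise AssayValidationError(
                f"wildtype_allele {self.wildtype_allele!r} != "
                f"target_ref[{self.hotspot_pos}] ({ref[self.hotspot_pos]!r})"
            )
        for m in self.mutant_alleles:
            if m not in "ACGT" or len(m) != 1:
                raise AssayValidationError(f"bad mutant allele {m!r}")
            if m == self.wildtype_allele:
                raise AssayValidationError("mutant allele equals wildtype")

    @property
    def target_seed(self) -> str:
        lo, hi = self.target_span
        return self.target_ref[lo:hi]

    def design_site(self, label: str) -> tuple[int, int] | None:
        """Locate a design sequence on the forward strand of target_ref.

        B-side and FLP sequences are searched as reverse complements per
        the orientation convention.  Returns None when absent.
        """
        d = self.designs.get(label)
        if d is None:
            return None
        probe = d.sequence if FORWARD_STRAND_OF[label] == "+" else revcomp(d.sequence)
        idx = self.target_ref.find(probe)
        if idx < 0:
            return None
        return (idx, idx + len(probe))

    def queries(self, include_loops: bool = True) -> dict[str, str]:
        """Seeding queries: target seed plus each design sequence."""
        out = {TARGET: self.target_seed}
        for label, d in self.designs.items():
            if not include_loops and label in LOOP_LABELS:
                continue
            out[label] = d.sequence
        return out


def split_inner_primers(
    fip: str, bip: str, linker: str
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Split FIP/BIP on their single linker occurrence.

    Returns ((F1c, F2), (B1c, B2)) halves with the linker removed.
    Raises AssayValidationError when the linker occurs zero or multiple
    times in either primer.
    """
    if not linker:
        raise AssayValidationError("empty linker")
    halves = []
    for name, primer in (("FIP", fip), ("BIP", bip)):
        n = primer.count(linker)
        if n != 1:
            raise AssayValidationError(
                f"{name}: linker {linker!r} occurs {n} times (need exactly 1)"
            )
        left, right = primer.split(linker)
        if not left or not right:
            raise AssayValidationError(f"{name}: linker at primer end")
        halves.append((left, right))
    return halves[0], halves[1]


def _derive_target_span(
    ref: str, designs: dict[str, DesignSequence]
) -> tuple[int, int]:
    f1 = designs["F1"].sequence
    b1c = revcomp(designs["B1"].sequence)
    f1_idx = ref.find(f1)
    b1_idx = ref.find(b1c)
    if f1_idx < 0 or b1_idx < 0:
        raise AssayValidationError(
            "cannot derive target_span: F1/B1 sites not found on target_ref; "
            "set target_span explicitly"
        )
    lo = f1_idx + len(f1) - SEED_PAD
    hi = b1_idx + SEED_PAD
    if lo >= hi:
        raise AssayValidationError("derived target_span is empty; check F1/B1 sites")
    return (max(0, lo), min(len(ref), hi))


def make_assay(
    name: str,
    target_ref: str,
    hotspot_pos: int,
    mutant_alleles,
    designs: dict[str, str],
    target_span: tuple[int, int] | None = None,
    linker: str | None = None,
    wildtype_allele: str | None = None,
) -> LampAssay:
    """Assemble and validate a LampAssay from plain values.

    FIP/BIP entries in ``designs`` are split on ``linker`` into
    F1/F2/B1/B2 (F1 = rc(F1c), B1 = rc(B1c)).
    """
    designs = dict(designs)
    if "FIP" in designs or "BIP" in designs:
        if linker is None:
            raise AssayValidationError("FIP/BIP given but no linker defined")
        if "FIP" not in designs or "BIP" not in designs:
            raise AssayValidationError("FIP and BIP must be given together")
        (f1c, f2), (b1c, b2) = split_inner_primers(
            designs.pop("FIP"), designs.pop("BIP"), linker
        )
        for label, seq in (("F1", revcomp(f1c)), ("F2", f2),
                           ("B1", revcomp(b1c)), ("B2", b2)):
            if label in designs and designs[label] != seq:
                raise AssayValidationError(
                    f"{label} given explicitly but disagrees with inner-primer split"
                )
            designs[label] = seq
    objs = {}
    for label, seq in designs.items():
        objs[label] = DesignSequence(label=label, sequence=seq)
    if target_span is None:
        for label in ("F1", "B1"):
            if label not in objs:
                raise AssayValidationError(f"missing required design {label}")
        target_span = _derive_target_span(target_ref, objs)
    wt = target_ref[hotspot_pos] if 0 <= hotspot_pos < len(target_ref) else "?"
    if wildtype_allele is not None and wildtype_allele != wt:
        raise AssayValidationError(
            f"declared wildtype_allele {wildtype_allele!r} != reference base {wt!r}"
        )
    mutants = tuple(mutant_alleles) if not isinstance(mutant_alleles, str) else (mutant_alleles,)
    return LampAssay(
        name=name,
        target_ref=target_ref,
        hotspot_pos=hotspot_pos,
        wildtype_allele=wt,
        mutant_alleles=mutants,
        designs=objs,
        target_span=(int(target_span[0]), int(target_span[1])),
        linker=linker,
    )


def load_assay(path) -> LampAssay:
    """Load and validate an assay definition (YAML key/value text).

    Recognised keys: name, target_ref (inline string or FASTA path),
    hotspot, wildtype (optional cross-check), mutants, linker,
    target_span (optional [lo, hi)), designs (label: sequence mapping;
    FIP/BIP allowed).
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise AssayValidationError(f"{path}: invalid YAML ({e})") from None
    if not isinstance(doc, dict):
        raise AssayValidationError(f"{path}: not a key/value document")
    try:
        target_ref = doc["target_ref"]
        hotspot = int(doc["hotspot"])
        designs = doc["designs"]
    except KeyError as e:
        raise AssayValidationError(f"{path}: missing required key {e}") from None
    if isinstance(target_ref, str) and (
        target_ref.endswith(".fa") or target_ref.endswith(".fasta")
    ):
        from Bio import SeqIO

        ref_path = path.parent / target_ref
        record = next(SeqIO.parse(str(ref_path), "fasta"))
        target_ref = str(record.seq).upper()
    span = doc.get("target_span")
    mutants = doc.get("mutants", [])
    if isinstance(mutants, str):
        mutants = [mutants]
    return make_assay(
        name=str(doc.get("name", path.stem)),
        target_ref=str(target_ref).upper(),
        hotspot_pos=hotspot,
        mutant_alleles=[str(m).upper() for m in mutants],
        designs={str(k).upper(): str(v).upper() for k, v in designs.items()},
        target_span=tuple(span) if span else None,
        linker=str(doc["linker"]).upper() if doc.get("linker") else None,
        wildtype_allele=str(doc["wildtype"]).upper() if doc.get("wildtype") else None,
    )


def write_assay(assay: LampAssay, path) -> None:
    """Serialise an assay so that load_assay round-trips it."""
    doc = {
        "name": assay.name,
        "target_ref": assay.target_ref,
        "hotspot": assay.hotspot_pos,
        "wildtype": assay.wildtype_allele,
        "mutants": list(assay.mutant_alleles),
        "target_span": list(assay.target_span),
        "designs": {label: d.sequence for label, d in sorted(assay.designs.items())},
    }
    if assay.linker:
        doc["linker"] = assay.linker
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def build_grammar(assay: LampAssay) -> AdjacencyGrammar:
    """Adjacency rules for hits of a properly formed concatemer.

    Concatemer units alternate orientation; within a forward unit the
    hit order is F2+ [FLP-] F1+ TARGET+ B1- [BLP+] B2-, with F3/B3 only
    at read extremities and inverted-repeat junctions (B2- -> B2+,
    F2- -> F2+) between units.
    """
    has_flp = "FLP" in assay.designs
    has_blp = "BLP" in assay.designs

    forward_chain: list[tuple[str, str]] = [("F3", "+"), ("F2", "+")]
    if has_flp:
        forward_chain.append(("FLP", "-"))
    forward_chain += [("F1", "+"), (TARGET, "+"), ("B1", "-")]
    if has_blp:
        forward_chain.append(("BLP", "+"))
    forward_chain += [("B2", "-"), ("B3", "-")]

    edges: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    # consecutive, plus skip edges over optional loop-primer nodes
    for i in range(len(forward_chain) - 1):
        edges.add((forward_chain[i], forward_chain[i + 1]))
    for i, node in enumerate(forward_chain):
        if node[0] in LOOP_LABELS and 0 < i < len(forward_chain) - 1:
            edges.add((forward_chain[i - 1], forward_chain[i + 1]))
    # inverted-repeat junctions between alternating units
    edges.add((("B2", "-"), ("B2", "+")))
    edges.add((("F2", "-"), ("F2", "+")))
    # close under reverse-complement symmetry: a -> b implies rc(b) -> rc(a)
    closed = set(edges)
    for a, b in edges:
        closed.add((_flip(b), _flip(a)))

    allowed: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for a, b in closed:
        allowed.setdefault(a, set()).add(b)
    return AdjacencyGrammar(
        allowed_right={k: frozenset(v) for k, v in sorted(allowed.items())}
    )


def assay_equal(a: LampAssay, b: LampAssay) -> bool:
    return dataclasses.asdict(a) == dataclasses.asdict(b)
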