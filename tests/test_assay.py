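import pytest
import yaml

from loopamp.assay import (
    AssayValidationError,
    TARGET,
    build_grammar,
    load_assay,
    make_assay,
    split_inner_primers,
    write_assay,
)
from loopamp.simulate import H3F3A_PRIMERS, LINKER, demo_assay

H3F3A_FIP = "GCGGGCAGTCTGCTTTGTATTTTATGCTGGTAGGTAAGTAAGGA"
H3F3A_BIP = "CGACCGGTGGTAAAGCACCTTTTCACCCCTCCAGTAGAG"


class TestSplitInnerPrimers:
    def test_published_fip_splits_on_polyT_linker(self):
        (f1c, f2), (b1c, b2) = split_inner_primers(H3F3A_FIP, H3F3A_BIP, "TTTT")
        assert f1c == "GCGGGCAGTCTGCTTTGTA"
        assert f2 == "ATGCTGGTAGGTAAGTAAGGA"
        assert b1c == "CGACCGGTGGTAAAGCACC"
        assert b2 == "CACCCCTCCAGTAGAG"

    def test_single_occurrence(self):
        (f1c, f2), _ = split_inner_primers("AAAATTTTCCCC", "GGGGTTTTAAAA", "TTTT")
        assert (f1c, f2) == ("AAAA", "CCCC")

    def test_multiple_occurrences_ambiguous(self):
        # brute-force scan: "TTTTAATTTT".count("TTTT") == 2
        assert "TTTTAATTTT".count("TTTT") == 2
        with pytest.raises(AssayValidationError, match="2 times"):
            split_inner_primers("TTTTAATTTT", H3F3A_BIP, "TTTT")

    def test_zero_occurrences(self):
        with pytest.raises(AssayValidationError, match="0 times"):
            split_inner_primers("ACGTACGT", H3F3A_BIP, "TTTT")

    def test_partition_roundtrip(self):
        (f1c, f2), (b1c, b2) = split_inner_primers(H3F3A_FIP, H3F3A_BIP, "TTTT")
        assert f1c + "TTTT" + f2 == H3F3A_FIP
        assert b1c + "TTTT" + b2 == H3F3A_BIP


class TestLoadAssay:
    def test_h3f3a_demo_assay_is_valid(self, h3f3a_assay):
        assert h3f3a_assay.designs["F3"].sequence == "GTTTGGTAGTTGCATATGGTG"
        assert h3f3a_assay.designs["B3"].sequence == "ATACCTGTAACGATGAGGTTTC"
        assert h3f3a_assay.wildtype_allele == "A"
        lo, hi = h3f3a_assay.target_span
        assert lo <= h3f3a_assay.hotspot_pos < hi

    def test_roundtrip_write_load(self, tmp_path, h3f3a_assay):
        path = tmp_path / "assay.yaml"
        write_assay(h3f3a_assay, path)
        reloaded = load_assay(path)
        assert reloaded.target_ref == h3f3a_assay.target_ref
        assert reloaded.target_span == h3f3a_assay.target_span
        assert reloaded.hotspot_pos == h3f3a_assay.hotspot_pos
        assert {k: d.sequence for k, d in reloaded.designs.items()} == {
            k: d.sequence for k, d in h3f3a_assay.designs.items()
        }

    def test_load_from_raw_yaml_with_inner_primers(self, tmp_path, h3f3a_assay):
        doc = {
            "name": "h3f3a-file",
            "target_ref": h3f3a_assay.target_ref,
            "hotspot": h3f3a_assay.hotspot_pos,
            "mutants": ["T"],
            "linker": LINKER,
            "designs": dict(H3F3A_PRIMERS),
        }
        path = tmp_path / "h3f3a.yaml"
        path.write_text(yaml.safe_dump(doc))
        assay = load_assay(path)
        # FIP/BIP were split into the four inner design roles
        assert assay.designs["F2"].sequence == "ATGCTGGTAGGTAAGTAAGGA"
        assert assay.designs["B1"].sequence  # rc of the BIP left half
        assert assay.target_span == h3f3a_assay.target_span

    def test_hotspot_outside_span_rejected(self, assay):
        with pytest.raises(AssayValidationError, match="hotspot"):
            make_assay(
                name="bad",
                target_ref=assay.target_ref,
                hotspot_pos=1,  # inside ref, outside derived span
                mutant_alleles=("T",),
                designs={k: d.sequence for k, d in assay.designs.items()},
            )

    def test_wildtype_mismatch_rejected(self, assay):
        wrong = "A" if assay.wildtype_allele != "A" else "C"
        with pytest.raises(AssayValidationError, match="wildtype"):
            make_assay(
                name="bad",
                target_ref=assay.target_ref,
                hotspot_pos=assay.hotspot_pos,
                mutant_alleles=("T",),
                designs={k: d.sequence for k, d in assay.designs.items()},
                wildtype_allele=wrong,
            )

    def test_missing_design_rejected(self, assay):
        designs = {k: d.sequence for k, d in assay.designs.items()}
        designs.pop("B2")
        with pytest.raises(AssayValidationError, match="B2"):
            make_assay(
                name="bad",
                target_ref=assay.target_ref,
                hotspot_pos=assay.hotspot_pos,
                mutant_alleles=("T",),
                designs=designs,
                target_span=assay.target_span,
            )

    def test_non_dna_characters_rejected(self, assay):
        designs = {k: d.sequence for k, d in assay.designs.items()}
        designs["F3"] = "ACGTX"
        with pytest.raises(AssayValidationError, match="F3"):
            make_assay(
                name="bad",
                target_ref=assay.target_ref,
                hotspot_pos=assay.hotspot_pos,
                mutant_alleles=("T",),
                designs=designs,
                target_span=assay.target_span,
            )


class TestGrammar:
    def test_target_neighbors(self, grammar):
        # derived by enumerating an error-free simulated concatemer:
        # forward target follows F1+, is followed by B1-; the rc copy mirrors.
        assert grammar.allows(("F1", "+"), (TARGET, "+"))
        assert grammar.allows((TARGET, "+"), ("B1", "-"))
        assert grammar.allows(("B1", "+"), (TARGET, "-"))
        assert grammar.allows((TARGET, "-"), ("F1", "-"))
        assert grammar.left_neighbors((TARGET, "+"))
        assert grammar.allowed_right[(TARGET, "+")]

    def test_junctions_are_inverted_repeats(self, grammar):
        assert grammar.allows(("B2", "-"), ("B2", "+"))
        assert grammar.allows(("F2", "-"), ("F2", "+"))

    def test_no_loop_entries_without_loop_primers(self, assay):
        designs = {
            k: d.sequence for k, d in assay.designs.items() if k not in ("FLP", "BLP")
        }
        a = make_assay(
            name="noloop",
            target_ref=assay.target_ref,
            hotspot_pos=assay.hotspot_pos,
            mutant_alleles=("T",),
            designs=designs,
            target_span=assay.target_span,
        )
        g = build_grammar(a)
        labels = {n[0] for n in g.allowed_right} | {
            n[0] for rights in g.allowed_right.values() for n in rights
        }
        assert "FLP" not in labels and "BLP" not in labels
        # chain skips straight across the removed loop nodes
        assert g.allows(("F2", "+"), ("F1", "+"))
        assert g.allows(("B1", "-"), ("B2", "-"))

    def test_deterministic(self, assay):
        g1 = build_grammar(assay)
        g2 = build_grammar(demo_assay("synthetic"))
        assert g1.allowed_right == g2.allowed_right

    def test_revcomp_symmetry(self, grammar):
        def flip(node):
            return (node[0], "-" if node[1] == "+" else "+")

        for a, rights in grammar.allowed_right.items():
            for b in rights:
                assert grammar.allows(flip(b), flip(a)), (a, b)

    def test_error_free_concatemer_fully_parseable(self, assay, grammar, rng):
        """No adjacent hit pair of a clean concatemer violates the grammar."""
        from loopamp.seeding import find_hits
        from loopamp.simulate import simulate_concatemer

        for n_units in (1, 2, 4):
            seq, _ = simulate_concatemer(
                assay, n_units, assay.wildtype_allele, rng, with_terminals=True
            )
            hits = find_hits(seq, assay)
            assert hits
            for left, right in zip(hits, hits[1:]):
                if right.start < left.end - 5:
                    continue  # deep overlap (seed/design hit sharing)
                assert grammar.allows(left.node(), right.node()), (
                    left.node(), right.node(), n_units,
                )
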