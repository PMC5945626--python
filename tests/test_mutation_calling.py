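import itertools

import pytest

from tagmute.mutation_calling import (
    BOUNDARY,
    FRAMESHIFT,
    IN_FRAME,
    NONSENSE,
    WILD_TYPE,
    Allele,
    CdnaVariant,
    annotate_protein,
    apply_variants,
    call_variants,
    classify_frame,
    collapse_alleles,
    filter_alleles,
    parse_allele_hgvs,
    parse_hgvs_c,
    render_allele_hgvs,
    render_hgvs_c,
)
from tagmute.read_alignment import AlnOp, PairwiseAlignment, align_read, shift_indels_3prime
from tagmute.reference_model import CodingTranscript

from .conftest import build_toy_cds
from .oracles import translate_to_stop


def mkaln(ref_start, ops, read_id="r"):
    width = sum(op.length for op in ops if op.kind in ("match", "mismatch", "deletion"))
    return PairwiseAlignment(read_id, (ref_start, ref_start + width - 1), tuple(ops), 0.0)


class TestCallVariants:
    def test_three_base_deletion_names_127_129(self, toy_transcript):
        seq = toy_transcript.sequence
        aln = mkaln(81, [AlnOp("match", 46), AlnOp("deletion", 3, seq[126:129]), AlnOp("match", 40)])
        allele = call_variants(aln, toy_transcript)
        assert allele.hgvs_c_allele == "c.127_129delATG"
        assert allele.frame_class == IN_FRAME

    def test_deletion_plus_substitution_phased(self, toy_transcript):
        # compound allele: 3-nt deletion plus adjacent substitution, kept
        # as two phased variants in one bracketed allele
        seq = toy_transcript.sequence
        assert seq[129] == "T"
        aln = mkaln(
            81,
            [
                AlnOp("match", 46),
                AlnOp("deletion", 3, seq[126:129]),
                AlnOp("mismatch", 1, "A"),
                AlnOp("match", 39),
            ],
        )
        allele = call_variants(aln, toy_transcript)
        assert allele.hgvs_c_allele == "c.[127_129delATG;130T>A]"
        assert allele.frame_class == IN_FRAME

    def test_perfect_alignment_is_wild_type(self, toy_transcript):
        aln = mkaln(81, [AlnOp("match", 60)])
        allele = call_variants(aln, toy_transcript)
        assert allele.frame_class == WILD_TYPE and not allele.variants

    def test_noncoding_variants_dropped(self, utr_transcript):
        # mismatch entirely in the 5' UTR
        t = utr_transcript
        aln = mkaln(2, [AlnOp("match", 5), AlnOp("mismatch", 1, "A" if t.sequence[7] != "A" else "C"), AlnOp("match", 40)])
        allele = call_variants(aln, t)
        assert allele.frame_class == WILD_TYPE

    def test_cds_boundary_deletion_flagged(self, utr_transcript):
        t = utr_transcript
        # deletion straddling the CDS start
        aln = mkaln(
            t.cds_start - 4,
            [AlnOp("match", 2), AlnOp("deletion", 4, t.sequence[t.cds_start - 2 : t.cds_start + 2]), AlnOp("match", 30)],
        )
        allele = call_variants(aln, t)
        assert allele.frame_class == BOUNDARY


class TestClassifyFrame:
    def test_examples(self, toy_transcript):
        seq = toy_transcript.sequence
        del3 = Allele(variants=(CdnaVariant("deletion", 127, 129, seq[126:129], ""),))
        assert classify_frame(del3, toy_transcript).frame_class == IN_FRAME
        del4 = Allele(variants=(CdnaVariant("deletion", 130, 133, seq[129:133], ""),))
        assert classify_frame(del4, toy_transcript).frame_class == FRAMESHIFT
        assert classify_frame(Allele(variants=()), toy_transcript).frame_class == WILD_TYPE

    def test_stop_gain_is_nonsense(self):
        # codon 3 -> TAA by substitution
        seq = "ATG" + "AAA" + "CAA" + "GGG" * 5 + "TAA"
        t = CodingTranscript("n", seq, 1, len(seq))
        sub = Allele(variants=(CdnaVariant("substitution", 7, 7, "C", "T"),))
        out = classify_frame(sub, t)
        assert out.frame_class == NONSENSE
        assert out.protein_change.hgvs_p_compact == "p.3Q>*"

    def test_net_length_invariant(self, toy_transcript):
        seq = toy_transcript.sequence
        for start, length in [(100, 1), (100, 2), (100, 3), (100, 4), (100, 6), (100, 7)]:
            a = classify_frame(
                Allele(variants=(CdnaVariant("deletion", start, start + length - 1, seq[start - 1 : start + length - 1], ""),)),
                toy_transcript,
            )
            if a.net_length_change % 3 == 0:
                assert a.frame_class in (IN_FRAME, NONSENSE)
            else:
                assert a.frame_class == FRAMESHIFT


class TestAnnotateProtein:
    def test_missense_F44I(self, toy_transcript):
        a = classify_frame(
            Allele(variants=(CdnaVariant("substitution", 130, 130, "T", "A"),)), toy_transcript
        )
        assert a.protein_change.hgvs_p_compact == "p.44F>I"
        assert a.protein_change.hgvs_p == "p.Phe44Ile"
        assert a.protein_change.affected_residues == {44}

    def test_single_codon_deletion_M43(self, toy_transcript):
        a = classify_frame(
            Allele(variants=(CdnaVariant("deletion", 127, 129, "ATG", ""),)), toy_transcript
        )
        assert a.protein_change.hgvs_p_compact == "p.43delM"
        assert a.protein_change.hgvs_p == "p.Met43del"

    def test_synonymous_substitution(self, toy_transcript):
        # codon 44 TTT -> TTC is still Phe
        a = classify_frame(
            Allele(variants=(CdnaVariant("substitution", 132, 132, "T", "C"),)), toy_transcript
        )
        assert a.frame_class == IN_FRAME
        assert a.protein_change.hgvs_p == "p.(=)"

    def test_frameshift_novel_residue_count(self, toy_transcript):
        seq = toy_transcript.sequence
        a = classify_frame(
            Allele(variants=(CdnaVariant("deletion", 130, 133, seq[129:133], ""),)), toy_transcript
        )
        pc = a.protein_change
        assert a.frame_class == FRAMESHIFT
        # oracle: edit + translate directly
        mutant = seq[:129] + seq[133:]
        mut_p, stopped = translate_to_stop(mutant)
        ref_p = translate_to_stop(seq)[0]
        prefix = 0
        while prefix < min(len(ref_p), len(mut_p)) and ref_p[prefix] == mut_p[prefix]:
            prefix += 1
        if stopped:
            assert pc.novel_residues_before_stop == len(mut_p) - prefix
            assert pc.hgvs_p_compact == f"p.{prefix + 1}{ref_p[prefix]}>fs{len(mut_p) - prefix}*"
        else:
            assert pc.novel_residues_before_stop is None and "no_stop_found" in pc.flags

    def test_exhaustive_single_edits_vs_translate_diff_oracle(self):
        """Pipeline annotation of every single edit of a 36-nt toy CDS agrees
        with a direct edit-translate-diff oracle (class, protein sequence,
        frameshift novel-residue count)."""
        cds = build_toy_cds(12, seed=5)  # 36 nt + stop
        tail = "ACCGTTACCGTTAAGGTTACCGGTAGGATC"  # downstream context for fs stops
        seq = cds + tail
        t = CodingTranscript("tiny", seq, 1, len(cds))
        ref_p = translate_to_stop(cds)[0]
        n = len(cds)

        def oracle(mutseq):
            mut_p, stopped = translate_to_stop(mutseq)
            return mut_p, stopped

        cases = []
        # all single-base substitutions
        for pos in range(1, n + 1):
            for alt in "ACGT":
                if alt != seq[pos - 1]:
                    cases.append((CdnaVariant("substitution", pos, pos, seq[pos - 1], alt),))
        # all deletions length 1..7 fully inside the CDS
        for length in range(1, 8):
            for pos in range(1, n - length + 2):
                cases.append((CdnaVariant("deletion", pos, pos + length - 1, seq[pos - 1 : pos + length - 1], ""),))
        # insertions of AC and ACG at every flank
        for ins in ("AC", "ACG", "T"):
            for pos in range(1, n):
                cases.append((CdnaVariant("insertion", pos, pos + 1, "", ins),))

        for variants in cases:
            allele = classify_frame(Allele(variants=variants), t)
            mutant_tail = apply_variants(seq, variants)
            mut_p, stopped = oracle(mutant_tail)
            net = allele.net_length_change
            if net % 3 != 0:
                assert allele.frame_class == FRAMESHIFT, variants
                pc = allele.protein_change
                prefix = 0
                while prefix < min(len(ref_p), len(mut_p)) and ref_p[prefix] == mut_p[prefix]:
                    prefix += 1
                if stopped:
                    assert pc.novel_residues_before_stop == len(mut_p) - prefix, variants
                else:
                    assert pc.novel_residues_before_stop is None
            else:
                expected_len = len(ref_p) + net // 3
                if stopped and len(mut_p) < expected_len:
                    assert allele.frame_class == NONSENSE, variants
                else:
                    assert allele.frame_class == IN_FRAME, variants
                    # reconstruct the mutant protein from the annotation
                    pc = allele.protein_change
                    assert _apply_protein_change(ref_p, pc) == mut_p, (variants, pc)


def _apply_protein_change(ref_p, pc):
    """Replay a protein annotation on the reference peptide (oracle check)."""
    s = pc.hgvs_p_compact
    if s == "p.(=)":
        return ref_p
    body = s[2:]
    if "ins" in body and "del" not in body:
        left, ins = body.split("ins")
        p = int(left.split("_")[0])
        return ref_p[:p] + ins + ref_p[p:]
    if "del" in body:
        left, deleted = body.split("del")
        parts = left.split("_")
        start = int(parts[0])
        end = int(parts[1]) if len(parts) > 1 else start
        assert ref_p[start - 1 : end] == deleted
        return ref_p[: start - 1] + ref_p[end:]
    if ">" in body:
        left, alt = body.split(">")
        # forms: 44F>I or 43_44MF>I
        import re

        m = re.match(r"^(\d+)(?:_(\d+))?([A-Z*]+)$", left)
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        assert ref_p[start - 1 : end] == m.group(3)
        return ref_p[: start - 1] + alt + ref_p[end:]
    raise AssertionError(f"unrecognised compact-style annotation {s!r}")


class TestHgvsRoundTrip:
    FIXTURE_STRINGS = [
        "c.127_129delATG",
        "c.130T>A",
        "c.[127_129delATG;130T>A]",
        "c.130_133delTTTG",
        "c.130_131delTT",
        "c.129_130delGT",
        "c.129_130insC",
        "c.129delG",
        "c.1771C>T",
        "c.2288delT",
    ]

    @pytest.mark.parametrize("s", FIXTURE_STRINGS)
    def test_parse_render_round_trip(self, s):
        variants = parse_allele_hgvs(s)
        assert render_allele_hgvs(variants) == s

    def test_delins_round_trip(self):
        v = parse_hgvs_c("c.10_12delinsAAAA")
        assert v.kind == "delins"
        assert "c." + render_hgvs_c(v) == "c.10_12delinsAAAA"

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            parse_hgvs_c("c.banana")


class TestCollapseAndFilter:
    def _alleles(self, toy_transcript, spec):
        out = []
        for hgvs, count in spec:
            variants = tuple(parse_allele_hgvs(hgvs, toy_transcript))
            for _ in range(count):
                out.append(classify_frame(Allele(variants=variants), toy_transcript))
        return out

    def test_identical_alleles_grouped(self, toy_transcript):
        table = collapse_alleles(self._alleles(toy_transcript, [("c.127_129delATG", 3)]))
        assert len(table) == 1
        assert table.iloc[0]["read_count"] == 3

    def test_counts_conserved_and_sorted(self, toy_transcript):
        table = collapse_alleles(
            self._alleles(toy_transcript, [("c.127_129delATG", 2), ("c.130T>A", 5), ("c.=", 1)])
        )
        assert table["read_count"].sum() == 8
        assert list(table["read_count"]) == sorted(table["read_count"], reverse=True)
        assert table.iloc[0]["hgvs_c"] == "c.130T>A"

    def test_filter_removes_singletons(self, toy_transcript):
        table = collapse_alleles(
            self._alleles(toy_transcript, [("c.127_129delATG", 5), ("c.131T>G", 1)])
        )
        kept = filter_alleles(table, min_reads=2)
        assert list(kept["hgvs_c"]) == ["c.127_129delATG"]
        assert filter_alleles(table, 0, 0.0).equals(table)

    def test_negative_threshold_rejected(self, toy_transcript):
        table = collapse_alleles(self._alleles(toy_transcript, [("c.130T>A", 1)]))
        with pytest.raises(ValueError):
            filter_alleles(table, min_reads=-1)
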