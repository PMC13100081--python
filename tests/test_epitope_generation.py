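import random

import pytest
from Bio.Seq import Seq

from neorank.epitope_generation import (
    AnnotationMismatchError,
    MutantProteinContext,
    build_frameshift_context,
    build_inframe_context,
    build_missense_context,
    enumerate_peptides,
    fusion_peptides,
    select_epitope_variants,
    translate_cds,
)
from neorank.io_formats import EffectAnnotation, FusionRecord, SomaticVariant

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_windows(ctx, lengths=(8, 9, 10, 11)):
    """Independent enumeration: every 8-11 substring intersecting the altered
    span (or straddling it), minus stop/ambiguous windows, de-duplicated."""
    seq = ctx.mutant_sequence
    a, b = ctx.altered_span
    seen, out = set(), []
    for length in sorted(lengths):
        for s in range(len(seq) - length + 1):
            first, last = s + 1, s + length
            if ctx.requires_straddle:
                ok = first <= a and last >= b
            else:
                ok = first <= b and last >= a
            if not ok:
                continue
            pep = seq[s : s + length]
            if "*" in pep or "X" in pep or pep in seen:
                continue
            seen.add(pep)
            out.append(pep)
    return out


def _missense_variant(protein_pos, ref_aa, alt_aa, tx="TX"):
    return SomaticVariant(
        chrom="chr1", pos=100, ref_allele="A", alt_allele="G",
        filter_status=frozenset({"PASS"}), tumor_depth=30, vaf=0.5,
        effect=EffectAnnotation(
            gene_symbol="G", transcript_id=tx, consequence_class="missense",
            protein_position=protein_pos, ref_aa=ref_aa, alt_aa=alt_aa,
        ),
    )


def _indel_variant(consequence, cds_pos, cds_ref, cds_alt, tx="TX"):
    return SomaticVariant(
        chrom="chr1", pos=100, ref_allele=cds_ref, alt_allele=cds_alt,
        filter_status=frozenset({"PASS"}), tumor_depth=30, vaf=0.5,
        effect=EffectAnnotation(
            gene_symbol="G", transcript_id=tx, consequence_class=consequence,
            cds_position=cds_pos, cds_ref=cds_ref, cds_alt=cds_alt,
        ),
    )


class TestTranslateCds:
    def test_basic(self):
        assert translate_cds("ATGGCC") == "MA"

    def test_stops_at_first_stop_codon(self):
        assert translate_cds("ATGTAAGCC") == "M"

    def test_trailing_partial_codon_ignored(self):
        assert translate_cds("ATGGC") == "M"

    def test_ambiguous_base_yields_x(self):
        assert translate_cds("ATGANT") == "MX"

    def test_agrees_with_independent_codon_table(self):
        rng = random.Random(17)
        for _ in range(200):
            n = rng.randrange(0, 60)
            cds = "".join(rng.choice("ACGT") for _ in range(n))
            trimmed = cds[: len(cds) - len(cds) % 3]
            expected = str(Seq(trimmed).translate(to_stop=True))
            assert translate_cds(cds) == expected, cds


class TestSelectEpitopeVariants:
    def test_stop_gain_excluded(self):
        v = _indel_variant("frameshift", 1, "AT", "A")
        stop = SomaticVariant(
            chrom="chr1", pos=1, ref_allele="A", alt_allele="T",
            filter_status=frozenset({"PASS"}), tumor_depth=30, vaf=0.5,
            effect=EffectAnnotation(consequence_class="stop_gain"),
        )
        assert select_epitope_variants([v, stop]) == [v]

    def test_depth_nine_excluded(self):
        v = SomaticVariant(
            chrom="chr1", pos=1, ref_allele="A", alt_allele="T",
            filter_status=frozenset({"PASS"}), tumor_depth=9, vaf=0.5,
            effect=EffectAnnotation(consequence_class="missense", protein_position=1,
                                    ref_aa="M", alt_aa="K"),
        )
        assert select_epitope_variants([v]) == []

    def test_mixed_fixture_two_of_six(self):
        def make(consequence, filters=frozenset({"PASS"}), depth=30):
            return SomaticVariant(
                chrom="chr1", pos=1, ref_allele="A", alt_allele="T",
                filter_status=filters, tumor_depth=depth, vaf=0.5,
                effect=EffectAnnotation(consequence_class=consequence),
            )

        variants = [
            make("missense"),                                   # eligible
            make("inframe_indel"),                              # eligible
            make("synonymous"),
            make("stop_gain"),
            make("missense", filters=frozenset({"germline"})),
            make("frameshift", depth=5),
        ]
        assert select_epitope_variants(variants) == variants[:2]


class TestMissenseContext:
    def test_construction(self):
        v = _missense_variant(5, "F", "L")
        ctx = build_missense_context(v, {"TX": "ACDEFGHIK"})
        assert ctx.mutant_sequence == "ACDELGHIK"
        assert ctx.altered_span == (5, 5)
        assert ctx.wildtype_sequence == "ACDEFGHIK"

    def test_reference_mismatch_is_hard_error(self):
        v = _missense_variant(5, "W", "L")
        with pytest.raises(AnnotationMismatchError):
            build_missense_context(v, {"TX": "ACDEFGHIK"})

    def test_exactly_one_residue_differs_random(self):
        rng = random.Random(23)
        for _ in range(100):
            protein = "".join(rng.choice(AA20) for _ in range(rng.randrange(10, 80)))
            pos = rng.randrange(1, len(protein) + 1)
            alt = rng.choice([a for a in AA20 if a != protein[pos - 1]])
            ctx = build_missense_context(
                _missense_variant(pos, protein[pos - 1], alt), {"TX": protein}
            )
            diffs = [i for i, (x, y) in enumerate(zip(ctx.wildtype_sequence, ctx.mutant_sequence)) if x != y]
            assert diffs == [pos - 1]


class TestFrameshiftContext:
    def test_planted_novel_tail(self, toy_cohort):
        ref = toy_cohort.reference
        sample = toy_cohort.spec.sample_name(0)
        frameshifts = [
            v for v in toy_cohort.variants[sample]
            if v.effect.consequence_class == "frameshift"
        ]
        assert frameshifts
        for v in frameshifts:
            ctx = build_frameshift_context(v, ref.cds)
            assert ctx is not None
            a, b = ctx.altered_span
            assert b == len(ctx.mutant_sequence)  # span runs to the new terminus
            wt = translate_cds(ref.cds[v.effect.transcript_id])
            assert ctx.mutant_sequence[: a - 1] == wt[: a - 1]
            if a <= len(wt):
                assert ctx.mutant_sequence[a - 1] != wt[a - 1]

    def test_inframe_indel_routed_here_is_error(self):
        v = _indel_variant("inframe_indel", 3, "G", "GAAA")
        with pytest.raises(ValueError, match="frame"):
            build_frameshift_context(v, {"TX": "ATGGGGCCC"})

    def test_no_novel_residue_gives_empty_context(self):
        # deleting the 8th base: ATGAAACCC -> ATGAAACC translates to the same prefix
        v = _indel_variant("frameshift", 7, "CC", "C")
        assert build_frameshift_context(v, {"TX": "ATGAAACCC"}) is None

    def test_cds_mismatch_is_hard_error(self):
        v = _indel_variant("frameshift", 1, "TT", "T")
        with pytest.raises(AnnotationMismatchError):
            build_frameshift_context(v, {"TX": "ATGAAACCC"})


class TestInframeContext:
    def test_insertion_span_length_two(self):
        # insert 6 nt (two codons) after codon 1 of ATG AAA CCC
        v = _indel_variant("inframe_indel", 3, "G", "GGATTCT")
        ctx = build_inframe_context(v, {"TX": "ATGAAACCC"})
        assert ctx is not None
        a, b = ctx.altered_span
        assert b - a + 1 == 2
        assert not ctx.requires_straddle

    def test_deletion_requires_straddle(self):
        # delete codon 2 from ATG AAA CCC GGG
        v = _indel_variant("inframe_indel", 3, "GAAA", "G")
        ctx = build_inframe_context(v, {"TX": "ATGAAACCCGGG"})
        assert ctx is not None
        assert ctx.requires_straddle
        assert ctx.mutant_sequence == "MPG"

    def test_frameshift_routed_here_is_error(self):
        v = _indel_variant("frameshift", 3, "GA", "G")
        with pytest.raises(ValueError, match="frame"):
            build_inframe_context(v, {"TX": "ATGAAACCC"})

    def test_length_arithmetic_random(self):
        rng = random.Random(29)
        codons = [c for c in
                  ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
                  if translate_cds(c)]
        for _ in range(50):
            n = rng.randrange(8, 30)
            cds = "".join(rng.choice(codons) for _ in range(n))
            k = rng.choice([1, 2]) * 3  # indel size in nt
            if rng.random() < 0.5:  # insertion after a codon boundary
                p = 3 * rng.randrange(1, n)
                ins = "".join(rng.choice(codons) for _ in range(k // 3))
                v = _indel_variant("inframe_indel", p, cds[p - 1], cds[p - 1] + ins)
                delta = k // 3
            else:  # deletion of k nt after an anchor base
                p = 3 * rng.randrange(1, n - 2)
                v = _indel_variant("inframe_indel", p, cds[p - 1 : p + k], cds[p - 1])
                delta = -(k // 3)
            ctx = build_inframe_context(v, {"TX": cds})
            if ctx is None:
                continue
            wt_len = len(translate_cds(cds))
            assert len(ctx.mutant_sequence) - wt_len == delta


class TestEnumeratePeptides:
    def _ctx(self, seq, span, straddle=False, source="snv", wildtype=None):
        return MutantProteinContext(
            mutant_sequence=seq, altered_span=span, source_type=source,
            gene_label="G", variant_key="k", wildtype_sequence=wildtype,
            requires_straddle=straddle,
        )

    def test_interior_missense_38_peptides(self):
        rng = random.Random(1)
        seq = "".join(rng.choice(AA20) for _ in range(31))
        ctx = self._ctx(seq, (16, 16))  # >= 15 residues flanking both sides
        assert len(enumerate_peptides(ctx)) == 38  # 8 + 9 + 10 + 11 windows

    def test_n_terminal_missense_4_peptides(self):
        rng = random.Random(2)
        seq = "".join(rng.choice(AA20) for _ in range(40))
        ctx = self._ctx(seq, (1, 1))
        peptides = enumerate_peptides(ctx)
        assert len(peptides) == 4
        assert sorted(len(p.sequence) for p in peptides) == [8, 9, 10, 11]

    def test_every_window_covers_altered_span(self):
        rng = random.Random(3)
        seq = "".join(rng.choice(AA20) for _ in range(60))
        ctx = self._ctx(seq, (30, 33), source="inframe_indel")
        for p in enumerate_peptides(ctx):
            start, end = p.window_start, p.window_start + len(p.sequence) - 1
            assert start <= 33 and end >= 30
            assert p.contains_positions

    def test_missense_wildtype_differs_in_one_residue(self):
        rng = random.Random(4)
        wt = "".join(rng.choice(AA20) for _ in range(50))
        pos = 25
        alt = rng.choice([a for a in AA20 if a != wt[pos - 1]])
        mut = wt[: pos - 1] + alt + wt[pos:]
        ctx = self._ctx(mut, (pos, pos), wildtype=wt)
        peptides = enumerate_peptides(ctx)
        assert peptides
        for p in peptides:
            assert p.wildtype_counterpart is not None
            diffs = sum(x != y for x, y in zip(p.sequence, p.wildtype_counterpart))
            assert diffs == 1

    def test_matches_brute_force_on_random_contexts(self):
        rng = random.Random(5)
        for _ in range(250):
            n = rng.randrange(8, 80)
            seq = "".join(rng.choice(AA20) for _ in range(n))
            a = rng.randrange(1, n + 1)
            b = min(n, a + rng.randrange(0, 6))
            straddle = rng.random() < 0.3 and b > a
            ctx = self._ctx(seq, (a, b), straddle=straddle,
                            source="inframe_indel" if (straddle or b > a) else "snv")
            got = [p.sequence for p in enumerate_peptides(ctx)]
            assert got == brute_force_windows(ctx)

    def test_peptides_with_stop_or_x_suppressed(self):
        ctx = self._ctx("AAAAAAAAXAAAAAAAA", (9, 9), source="frameshift")
        assert enumerate_peptides(ctx) == []


def _fusion(junction_cds, offset, **kwargs):
    defaults = dict(
        gene5="AAA", gene3="BBB", junction_reads=9, discordant_pairs=2,
        confidence="high", frame_status="in_frame",
        junction_cds=junction_cds, junction_offset=offset,
    )
    defaults.update(kwargs)
    return FusionRecord(**defaults)


class TestFusionPeptides:
    CODONS = ["GCT", "TGC", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "TTG",
              "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT", "TGG", "TAT"]

    def _junction(self, n5=10, n3=11, rng_seed=0):
        rng = random.Random(rng_seed)
        five = "".join(rng.choice(self.CODONS) for _ in range(n5))
        three = "".join(rng.choice(self.CODONS) for _ in range(n3))
        return five + three, len(five)

    def test_full_flank_junction_yields_34(self):
        cds, offset = self._junction()
        peptides = fusion_peptides(_fusion(cds, offset))
        assert len(peptides) == 34  # 7 + 8 + 9 + 10 junction-spanning windows

    def test_every_peptide_contains_both_partners(self):
        cds, offset = self._junction(rng_seed=7)
        n5 = offset // 3
        for p in fusion_peptides(_fusion(cds, offset)):
            start, end = p.window_start, p.window_start + len(p.sequence) - 1
            assert start <= n5 < end  # at least one residue each side

    def test_stop_before_junction_yields_nothing(self):
        cds, offset = self._junction()
        cds = cds[:9] + "TAA" + cds[12:]
        assert fusion_peptides(_fusion(cds, offset)) == []

    def test_offset_not_multiple_of_three_still_spans(self):
        cds, offset = self._junction()
        # shift: 5' contributes 31 nt; junction falls to a codon boundary after
        # dropping the leading out-of-frame base
        rec = _fusion("G" + cds, offset + 1)
        peptides = fusion_peptides(rec)
        assert peptides
        n5 = (rec.junction_offset - rec.junction_offset % 3) // 3
        for p in peptides:
            assert p.window_start <= n5 < p.window_start + len(p.sequence) - 1

    def test_inconsistent_offset_is_hard_error(self):
        with pytest.raises(ValueError):
            FusionRecord(gene5="A", gene3="B", junction_cds="ATG", junction_offset=7)

    def test_matches_brute_force(self):
        for seed in range(40):
            rng = random.Random(seed)
            cds, offset = self._junction(
                n5=rng.randrange(1, 15), n3=rng.randrange(1, 15), rng_seed=seed
            )
            peptides = fusion_peptides(_fusion(cds, offset))
            protein = translate_cds(cds)
            n5 = offset // 3
            if n5 < 1 or len(protein) <= n5:
                assert peptides == []
                continue
            ctx = MutantProteinContext(
                mutant_sequence=protein, altered_span=(n5, n5 + 1),
                source_type="fusion", gene_label="A::B", variant_key="k",
                requires_straddle=True,
            )
            assert [p.sequence for p in peptides] == brute_force_windows(ctx)
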