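"""Effect classification, splice windows, mutation spectrum, region summaries."""

import numpy as np
import pytest

from somatrio.annotate import (
    SPECTRUM_CLASSES,
    AnnotatedVariant,
    TranscriptModel,
    classify_effect,
    load_gene_model,
    purine_first_label,
    region_summary,
    spectrum_class,
    spectrum_counts,
    spectrum_table,
)
from somatrio.casestudy import CASE_VARIANTS

# chrT (plus strand):  1-10 upstream, CDS 11-19 (ATG GAG CTG),
# intron 20-29, CDS 30-38 (TTT CAG TAA), 39-48 downstream.
CHR_T = "GATTACAGGC" + "ATGGAGCTG" + "GTAAGTTTAG" + "TTTCAGTAA" + "CCATTGAACT"
# chrM (minus strand): CDS 11-22 whose reverse complement is ATG GAA CTG TAA.
CHR_M = "GATTACAGGC" + "TTACAGTTCCAT" + "CCATTGAACT"

GTF = "\n".join(
    [
        'chrT\ttest\ttranscript\t3\t45\t.\t+\t.\tgene_name "GENEA"; transcript_id "txA";',
        'chrT\ttest\tCDS\t11\t19\t.\t+\t0\tgene_name "GENEA"; transcript_id "txA";',
        'chrT\ttest\tCDS\t30\t38\t.\t+\t0\tgene_name "GENEA"; transcript_id "txA";',
        'chrM\ttest\tCDS\t11\t22\t.\t-\t0\tgene_name "GENEB"; transcript_id "txB";',
    ]
)


@pytest.fixture(scope="module")
def setup():
    reference = {"chrT": CHR_T, "chrM": CHR_M}
    models = load_gene_model(GTF)
    return reference, models


class TestGeneModel:
    def test_gtf_text_parsed(self, setup):
        _, models = setup
        assert {m.gene for m in models} == {"GENEA", "GENEB"}
        tx_a = next(m for m in models if m.gene == "GENEA")
        assert tx_a.cds == [(11, 19), (30, 38)]
        assert tx_a.transcript_span == (3, 45)

    def test_cds_sequence_is_strand_resolved(self, setup):
        reference, models = setup
        tx_b = next(m for m in models if m.gene == "GENEB")
        assert tx_b.cds_sequence(reference) == "ATGGAACTGTAA"

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            TranscriptModel("G", "tx", "chrT", "+", [(11, 20)])

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            TranscriptModel("G", "tx", "chrT", "+", [(11, 19), (15, 23)])


class TestClassifyCoding:
    def test_stopgain_renders_empty_destination(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 14, "G", "T", models, reference)  # GAG -> TAG
        assert ann.effect == "stopgain" and ann.aa_change == "Glu->"
        assert ann.gene == "GENEA"

    def test_missense_in_start_codon(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 13, "G", "A", models, reference)  # ATG -> ATA
        assert ann.effect == "nonsynonymous" and ann.aa_change == "Met->Ile"

    def test_synonymous_leucine(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 17, "C", "T", models, reference)  # CTG -> TTG
        assert ann.effect == "synonymous" and ann.aa_change == "Leu->Leu"

    def test_stoploss(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 36, "T", "C", models, reference)  # TAA -> CAA
        assert ann.effect == "stoploss" and ann.aa_change == "->Gln"

    def test_second_exon_frame_carries_over(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 34, "A", "T", models, reference)  # CAG -> CTG
        assert ann.effect == "nonsynonymous" and ann.aa_change == "Gln->Leu"

    def test_minus_strand_codon_resolved(self, setup):
        reference, models = setup
        # genomic C>T at chrM:20 is coding G>A in the ATG: Met->Ile
        ann = classify_effect("chrM", 20, "C", "T", models, reference)
        assert ann.gene == "GENEB"
        assert ann.effect == "nonsynonymous" and ann.aa_change == "Met->Ile"

    def test_reference_mismatch_rejected(self, setup):
        reference, models = setup
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_effect("chrT", 14, "C", "T", models, reference)

    def test_identity_substitution_rejected(self, setup):
        reference, models = setup
        with pytest.raises(ValueError, match="alt equals ref"):
            classify_effect("chrT", 14, "G", "G", models, reference)


class TestClassifyNonCoding:
    def test_splice_window_two_bp(self, setup):
        reference, models = setup
        for pos in (20, 21, 28, 29):  # within 2 bp of a CDS boundary, intron side
            ann = classify_effect("chrT", pos, CHR_T[pos - 1], "C" if CHR_T[pos - 1] != "C" else "A",
                                  models, reference)
            assert ann.effect == "splice", pos

    def test_deep_intron_is_intronic(self, setup):
        reference, models = setup
        for pos in (23, 24, 25, 26):
            ann = classify_effect("chrT", pos, CHR_T[pos - 1], "C" if CHR_T[pos - 1] != "C" else "A",
                                  models, reference)
            assert ann.effect == "intronic", pos

    def test_transcript_flank_is_utr(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 5, "A", "G", models, reference)
        assert ann.effect == "utr" and ann.gene == "GENEA"

    def test_outside_any_transcript_is_intergenic(self, setup):
        reference, models = setup
        ann = classify_effect("chrT", 47, "C", "T", models, reference)
        assert ann.effect == "intergenic" and ann.gene is None
        # chrM has no transcript feature: positions outside its CDS are intergenic
        assert classify_effect("chrM", 5, "A", "G", models, reference).effect == "intergenic"


class TestSpectrum:
    def test_strand_collapse_symmetry(self):
        assert spectrum_class("C", "T") == spectrum_class("G", "A") == "C:G>T:A"
        assert spectrum_class("A", "G") == spectrum_class("T", "C") == "T:A>C:G"

    def test_all_twelve_substitutions_map_onto_six_classes(self):
        classes = {
            spectrum_class(r, a) for r in "ACGT" for a in "ACGT" if r != a
        }
        assert classes == set(SPECTRUM_CLASSES)

    def test_purine_first_labels_are_involutive(self):
        for cls in SPECTRUM_CLASSES:
            flipped = purine_first_label(cls)
            assert flipped != cls
            assert purine_first_label(flipped) == cls

    def test_counts_example(self):
        variants = [("c", 1, "C", "T"), ("c", 2, "G", "A"), ("c", 3, "A", "G")]
        counts = spectrum_counts(variants)
        assert counts["C:G>T:A"] == 2 and counts["T:A>C:G"] == 1
        assert sum(counts.values()) == 3

    def test_invalid_substitutions_rejected(self):
        with pytest.raises(ValueError):
            spectrum_class("C", "C")
        with pytest.raises(ValueError):
            spectrum_class("N", "A")

    def test_table_carries_both_conventions(self):
        table = spectrum_table([("c", 1, "C", "T")])
        assert list(table.columns) == ["class_pyrimidine_first", "class_purine_first", "count"]
        row = table[table.class_pyrimidine_first == "C:G>T:A"].iloc[0]
        assert row.class_purine_first == "G:C>A:T" and row["count"] == 1

    def test_uniform_substitutions_split_evenly(self):
        rng = np.random.default_rng(29)
        variants = []
        for i in range(1200):
            ref = "ACGT"[rng.integers(4)]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(("c", i, ref, str(alt)))
        counts = spectrum_counts(variants)
        sd = np.sqrt(1200 * (1 / 6) * (5 / 6))
        for cls in SPECTRUM_CLASSES:
            assert abs(counts[cls] - 200) <= 3 * sd


class TestRegionSummary:
    def test_sums_to_input_size(self):
        anns = [
            AnnotatedVariant("c", 1, "A", "G", "G1", "nonsynonymous", "Met->Ile"),
            AnnotatedVariant("c", 2, "A", "G", None, "intergenic"),
            AnnotatedVariant("c", 3, "A", "G", "G1", "intronic"),
        ]
        summary = region_summary(anns)
        assert summary["nonsynonymous"] == 1 and summary["intergenic"] == 1
        assert sum(summary.values()) == 3

    def test_empty_input_all_zero(self):
        assert sum(region_summary([]).values()) == 0


class TestCaseStudyAnnotations:
    def test_nine_case_variants_reproduce_reported_changes(self, case):
        aa3 = {"M": "Met", "I": "Ile", "E": "Glu", "D": "Asp", "H": "His",
               "G": "Gly", "C": "Cys", "F": "Phe", "L": "Leu", "R": "Arg",
               "Q": "Gln", "S": "Ser", "*": ""}
        for key, expected in zip(case.case_keys, CASE_VARIANTS):
            chrom, pos, ref, alt = key
            ann = classify_effect(chrom, pos, ref, alt, case.models, case.reference)
            assert ann.gene == expected.gene
            assert ann.effect == expected.effect
            assert ann.aa_change == f"{aa3[expected.ref_aa]}->{aa3[expected.alt_aa]}"

    def test_emergent_region_summary(self, case, case_result):
        post_keys = {s.key for s in case_result.comparison.post_only}
        anns = [case_result.annotations[k] for k in post_keys]
        summary = region_summary(anns)
        assert summary["nonsynonymous"] == 8
        assert summary["stopgain"] == 1
        assert sum(summary.values()) == 12
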