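"""Seven-criterion cascade: per-criterion boundaries, frozen examples, composition."""

import pandas as pd
import pytest

from somatrio.caller import CandidateSNV
from somatrio.evidence import EVIDENCE_COLUMNS, EvidenceStore, ReadObservation, SiteEvidence
from somatrio.filters import (
    CRITERIA,
    FilterConfig,
    apply_cascade,
    f1_adjacent_distance,
    f2_mapping_quality,
    f3_base_quality,
    f4_allele_freq_change,
    f5_gap_region,
    f6_read_end_bias,
    f7_simple_repeat,
)

from _oracles import ranksum_oracle


def make_candidate(pos=100, chrom="chr1", ref="A", alt="G",
                   t_alt=15, t_ref=15, n_alt=0, n_ref=30):
    return CandidateSNV(
        chrom, pos, ref, alt, t_ref, t_alt, n_ref, n_alt,
        t_alt / (t_alt + t_ref), n_alt / max(1, n_alt + n_ref), 1e-4,
    )


def make_site(var_obs, ref_obs, pos=100, ref="A", alt="G"):
    """Build a tumor SiteEvidence from (baseq, mapq, end_dist) triples."""
    obs = [ReadObservation(alt, bq, mq, ed, False) for bq, mq, ed in var_obs]
    obs += [ReadObservation(ref, bq, mq, ed, False) for bq, mq, ed in ref_obs]
    return SiteEvidence("chr1", pos, ref, "pre", obs)


def quality_site(var_baseqs=(35, 36, 38), var_mapqs=None, var_ends=None, n_ref=20):
    n_var = max(map(len, (x for x in (var_baseqs, var_mapqs or [], var_ends or []) if x)))
    var_mapqs = var_mapqs or [60] * n_var
    var_ends = var_ends or [20 + i for i in range(n_var)]
    var_baseqs = list(var_baseqs) or [35] * n_var
    var = list(zip(var_baseqs, var_mapqs, var_ends))
    ref = [(34, 60, 15 + (i % 20)) for i in range(n_ref)]
    return make_site(var, ref)


class TestAdjacentDistance:
    def test_pair_at_nine_bp_both_fail(self):
        pair = [make_candidate(pos=100), make_candidate(pos=109)]
        verdicts = f1_adjacent_distance(pair)
        assert all(not v.passed for v in verdicts.values())

    def test_pair_at_ten_bp_both_pass(self):
        pair = [make_candidate(pos=100), make_candidate(pos=110)]
        verdicts = f1_adjacent_distance(pair)
        assert all(v.passed for v in verdicts.values())

    def test_lone_candidate_passes(self):
        verdicts = f1_adjacent_distance([make_candidate()])
        assert all(v.passed for v in verdicts.values())

    def test_neighbors_on_other_chromosomes_ignored(self):
        pair = [make_candidate(pos=100, chrom="chr1"), make_candidate(pos=105, chrom="chr2")]
        verdicts = f1_adjacent_distance(pair)
        assert all(v.passed for v in verdicts.values())

    def test_middle_of_cluster_fails_with_distant_third(self):
        cands = [make_candidate(pos=100), make_candidate(pos=105), make_candidate(pos=500)]
        verdicts = f1_adjacent_distance(cands)
        assert not verdicts[cands[0].key].passed
        assert not verdicts[cands[1].key].passed
        assert verdicts[cands[2].key].passed


class TestMappingQuality:
    def test_high_mapqs_pass(self):
        site = quality_site(var_mapqs=[40, 45, 50, 60], var_baseqs=[35] * 4)
        assert f2_mapping_quality(make_candidate(), site).passed

    def test_uniformly_low_mapqs_fail(self):
        site = quality_site(
            var_mapqs=[10, 12, 11, 13, 9, 8, 14, 12], var_baseqs=[35] * 8
        )
        verdict = f2_mapping_quality(make_candidate(), site)
        assert not verdict.passed
        assert verdict.p_value == pytest.approx(1 / 256)

    def test_mapqs_equal_to_reference_value_pass(self):
        site = quality_site(var_mapqs=[30, 30, 30], var_baseqs=[35] * 3)
        verdict = f2_mapping_quality(make_candidate(), site)
        assert verdict.passed and verdict.p_value == 1.0

    def test_two_sample_mode_compares_against_reference_reads(self):
        config = FilterConfig(quality_test_mode="two_sample")
        var = [(35, 10, 20), (35, 11, 21), (35, 12, 22), (35, 9, 23)]
        ref = [(34, 60, 15 + i) for i in range(8)]
        verdict = f2_mapping_quality(make_candidate(), make_site(var, ref), config)
        assert not verdict.passed

    def test_missing_variant_reads_violate_contract(self):
        site = make_site([], [(34, 60, 15)])
        with pytest.raises(ValueError, match="caller contract"):
            f2_mapping_quality(make_candidate(), site)


class TestBaseQuality:
    def test_high_baseqs_pass(self):
        assert f3_base_quality(make_candidate(), quality_site((35, 36, 38))).passed

    def test_uniformly_low_baseqs_fail(self):
        site = quality_site((8, 9, 10, 11, 12, 9, 8, 10))
        verdict = f3_base_quality(make_candidate(), site)
        assert not verdict.passed and verdict.p_value < 0.05

    def test_one_low_value_among_high_passes(self):
        verdict = f3_base_quality(make_candidate(), quality_site((35, 36, 18)))
        assert verdict.passed
        assert verdict.p_value == pytest.approx(0.875)


class TestAlleleFreqChange:
    def test_strong_change_passes(self):
        cand = make_candidate(t_alt=8, t_ref=12, n_alt=0, n_ref=20)
        verdict = f4_allele_freq_change(cand)
        assert verdict.passed and verdict.p_value == pytest.approx(0.003276003276003276)

    def test_identical_frequencies_fail(self):
        cand = make_candidate(t_alt=5, t_ref=45, n_alt=5, n_ref=45)
        assert not f4_allele_freq_change(cand).passed

    def test_weak_change_fails_with_frozen_p(self):
        cand = make_candidate(t_alt=3, t_ref=57, n_alt=1, n_ref=59)
        verdict = f4_allele_freq_change(cand)
        assert not verdict.passed
        assert verdict.p_value == pytest.approx(0.6186166774402068)


class TestGapRegion:
    def _store(self, gap_positions, center=100):
        rows = [("chr1", center, "A", "pre", "G", 30, 60, 20, False, "+")]
        rows += [
            ("chr1", p, "A", "pre", "A", 30, 60, 20, True, "+") for p in gap_positions
        ]
        return EvidenceStore(pd.DataFrame(rows, columns=EVIDENCE_COLUMNS), "pre")

    def test_nine_gap_flags_pass(self):
        store = self._store([90] * 4 + [110] * 5)
        assert f5_gap_region(make_candidate(), store).passed

    def test_ten_gap_flags_fail(self):
        store = self._store([90] * 5 + [110] * 5)
        verdict = f5_gap_region(make_candidate(), store)
        assert not verdict.passed and verdict.statistic == 10.0

    def test_flags_outside_flank_not_counted(self):
        store = self._store([79] * 10 + [121] * 10)  # just outside +/- 20
        assert f5_gap_region(make_candidate(), store).passed

    def test_flank_boundaries_inclusive(self):
        store = self._store([80] * 5 + [120] * 5)
        assert not f5_gap_region(make_candidate(), store).passed


class TestReadEndBias:
    def test_variant_reads_at_ends_fail(self):
        var = [(35, 60, e) for e in (1, 2, 3, 4)]
        ref = [(34, 60, e) for e in (10, 11, 12, 13, 14)]
        verdict = f6_read_end_bias(make_candidate(), make_site(var, ref))
        assert not verdict.passed
        assert verdict.p_value == pytest.approx(1 / 126)

    def test_matched_end_distributions_pass(self):
        var = [(35, 60, e) for e in (5, 15, 25, 35)]
        ref = [(34, 60, e) for e in (5, 15, 25, 35)]
        assert f6_read_end_bias(make_candidate(), make_site(var, ref)).passed

    def test_interleaved_distances_pass_with_oracle_p(self):
        var_ends = [8.0, 12.0, 20.0, 30.0]
        ref_ends = [1.0, 5.0, 9.0, 15.0, 22.0, 40.0]
        var = [(35, 60, int(e)) for e in var_ends]
        ref = [(34, 60, int(e)) for e in ref_ends]
        verdict = f6_read_end_bias(make_candidate(), make_site(var, ref))
        assert verdict.passed
        assert verdict.p_value == pytest.approx(ranksum_oracle(var_ends, ref_ends, "less"))

    def test_no_reference_reads_is_untestable_pass(self):
        site = make_site([(35, 60, 2)], [])
        verdict = f6_read_end_bias(make_candidate(), site)
        assert verdict.passed and "untestable" in verdict.detail

    def test_hard_cutoff_mode(self):
        config = FilterConfig(end_bias_mode="hard_cutoff")
        near = make_site([(35, 60, e) for e in (0, 1, 2, 30)], [])
        far = make_site([(35, 60, e) for e in (30, 31, 2, 33)], [])
        assert not f6_read_end_bias(make_candidate(), near, config).passed
        assert f6_read_end_bias(make_candidate(), far, config).passed


LEFT = "GATTACAGGCATCGTAGCTAACGGT"
RIGHT = "TCGGATCCATTGAACTGATCGGTAC"


class TestSimpleRepeat:
    def test_six_copies_fail(self):
        reference = {"chr1": LEFT + "CAG" * 6 + RIGHT}
        verdict = f7_simple_repeat(make_candidate(pos=len(LEFT) + 2), reference)
        assert not verdict.passed and verdict.statistic == 6.0

    def test_five_copies_pass(self):
        reference = {"chr1": LEFT + "CAG" * 5 + RIGHT}
        verdict = f7_simple_repeat(make_candidate(pos=len(LEFT) + 2), reference)
        assert verdict.passed and verdict.statistic == 5.0

    def test_homopolymer_run_fails(self):
        reference = {"chr1": LEFT + "A" * 8 + RIGHT}
        assert not f7_simple_repeat(make_candidate(pos=len(LEFT) + 4), reference).passed

    def test_repeat_beyond_scan_flank_ignored(self):
        reference = {"chr1": LEFT + RIGHT + "CAG" * 10 + LEFT + RIGHT}
        assert f7_simple_repeat(make_candidate(pos=10), reference).passed


class TestCascadeComposition:
    def _fixture(self):
        reference = {"chr1": (LEFT + RIGHT) * 40}
        cand = make_candidate(pos=100, ref=reference["chr1"][99],
                              alt="G" if reference["chr1"][99] != "G" else "T")
        rows = [
            ("chr1", 100, cand.ref, "pre", cand.alt, 35, 60, 20 + i, False, "+")
            for i in range(15)
        ] + [
            ("chr1", 100, cand.ref, "pre", cand.ref, 34, 60, 10 + i, False, "+")
            for i in range(15)
        ]
        store = EvidenceStore(pd.DataFrame(rows, columns=EVIDENCE_COLUMNS), "pre")
        return [cand], store, reference

    def test_every_call_carries_all_seven_verdicts(self):
        cands, store, reference = self._fixture()
        calls = apply_cascade(cands, store, reference)
        assert len(calls) == len(cands)
        for call in calls:
            assert set(call.verdicts) == set(CRITERIA)

    def test_clean_candidate_passes_and_reports_pass(self):
        cands, store, reference = self._fixture()
        call = apply_cascade(cands, store, reference)[0]
        assert call.passed and call.filter_field == "PASS"

    def test_result_independent_of_input_order(self):
        cands, store, reference = self._fixture()
        extra = make_candidate(pos=500, ref=reference["chr1"][499],
                               alt="G" if reference["chr1"][499] != "G" else "T")
        rows = [
            ("chr1", 500, extra.ref, "pre", b, 35, 60, 20, False, "+")
            for b in [extra.alt] * 10 + [extra.ref] * 10
        ]
        store2 = EvidenceStore(
            pd.concat([store.frame, pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)]),
            "pre",
        )
        forward = apply_cascade(cands + [extra], store2, reference)
        backward = apply_cascade([extra] + cands, store2, reference)
        assert [c.key for c in forward] == [c.key for c in backward]
        assert [c.filter_field for c in forward] == [c.filter_field for c in backward]

    def test_missing_tumor_evidence_is_an_error(self):
        cands, store, reference = self._fixture()
        orphan = make_candidate(pos=900, ref=reference["chr1"][899],
                                alt="G" if reference["chr1"][899] != "G" else "T")
        with pytest.raises(KeyError, match="900"):
            apply_cascade([orphan], store, reference)


ARTIFACT_TARGET = {
    "end_biased": "read_end_bias",
    "gap_proximal": "gap_region",
    "low_mapq_cluster": "low_mapq",
    "repeat_hotspot": "repeat_region",
    "adjacent_cluster": "adj_dist",
}


class TestArtifactTargeting:
    def test_each_artifact_class_fails_its_intended_criterion(self, sim_trio, sim_result):
        _, _, truth, _ = sim_trio
        found = set()
        for sample in ("pre", "post"):
            by_pos = {(c.candidate.chrom, c.candidate.pos): c for c in sim_result.calls[sample]}
            for site in truth.artifact_sites:
                call = by_pos.get((site.chrom, site.pos))
                if call is None:
                    continue
                found.add(site.artifact_class)
                assert ARTIFACT_TARGET[site.artifact_class] in call.failed_criteria, (
                    site.artifact_class, call.filter_field)
        assert found == set(ARTIFACT_TARGET)

    def test_most_true_somatic_calls_pass_all_criteria(self, sim_trio, sim_result):
        _, _, truth, _ = sim_trio
        truth_pos = {(s.chrom, s.pos): s for s in truth.somatic_sites}
        n_true = n_pass = 0
        for sample in ("pre", "post"):
            for call in sim_result.calls[sample]:
                site = truth_pos.get((call.candidate.chrom, call.candidate.pos))
                if site is None:
                    continue
                n_true += 1
                n_pass += call.passed
        assert n_true > 0 and n_pass / n_true >= 0.85
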