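"""Filter-cascade semantics and the temporal induction filter."""

import copy

import numpy as np
import pytest

from lincscreen.io_formats import GenomicInterval
from lincscreen.selection import (
    CandidateRecord,
    TimecoursePair,
    filter_annotation_overlap,
    filter_boolean_criteria,
    filter_csf,
    filter_masspec,
    filter_rrs,
    run_selection_pipeline,
    temporal_induction_filter,
)


def cand(gene_id="c1", chrom="chr1", start=100, end=200, **kw):
    defaults = dict(
        csf_score=-500.0,
        masspec_tags=0,
        max_rrs=0.5,
        has_human_synteny=True,
        has_k4me3_k36me3=True,
    )
    defaults.update(kw)
    return CandidateRecord(
        gene_id=gene_id, locus=GenomicInterval(chrom, start, end), **defaults
    )


class TestAnnotationOverlap:
    def test_overlapping_coding_exon_excludes(self):
        kept, excluded = filter_annotation_overlap(
            [cand()], [(GenomicInterval("chr1", 150, 160), "coding")]
        )
        assert not kept and excluded[0].filter_trace == [("annotation_overlap", "fail")]

    def test_half_open_abutment_keeps(self):
        kept, _ = filter_annotation_overlap(
            [cand()], [(GenomicInterval("chr1", 200, 300), "coding")]
        )
        assert len(kept) == 1

    def test_lncrna_annotations_never_exclude(self):
        kept, _ = filter_annotation_overlap(
            [cand()], [(GenomicInterval("chr1", 100, 200), "lincRNA")]
        )
        assert len(kept) == 1

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            filter_annotation_overlap(
                [cand(chrom="chrX")], [(GenomicInterval("chr1", 0, 10), "coding")]
            )

    def test_matches_all_pairs_oracle(self, rng):
        annotations = []
        for i in range(40):
            s = int(rng.integers(0, 50_000))
            annotations.append(
                (GenomicInterval("chr1", s, s + int(rng.integers(1, 3_000))), "coding")
            )
        candidates = []
        for i in range(50):
            s = int(rng.integers(0, 50_000))
            candidates.append(cand(gene_id=f"c{i}", start=s, end=s + int(rng.integers(1, 2_000))))
        kept, excluded = filter_annotation_overlap(candidates, annotations)
        # O(n^2) oracle
        expected_excluded = {
            c.gene_id
            for c in candidates
            if any(c.locus.overlaps(a) for a, _ in annotations)
        }
        assert {c.gene_id for c in excluded} == expected_excluded
        assert {c.gene_id for c in kept} == {
            c.gene_id for c in candidates
        } - expected_excluded


class TestScalarFilters:
    @pytest.mark.parametrize(
        "csf,expected_kept", [(-205.0, True), (-14771.0, True), (-200.0, False), (-14.0, False)]
    )
    def test_csf_strict_threshold(self, csf, expected_kept):
        kept, _ = filter_csf([cand(csf_score=csf)])
        assert bool(kept) is expected_kept

    def test_csf_missing_score_excluded_not_error(self):
        kept, excluded = filter_csf([cand(csf_score=None)])
        assert not kept and len(excluded) == 1

    @pytest.mark.parametrize("tags,expected_kept", [(0, True), (2, True), (3, False)])
    def test_masspec_threshold(self, tags, expected_kept):
        kept, _ = filter_masspec([cand(masspec_tags=tags)])
        assert bool(kept) is expected_kept

    def test_masspec_negative_count_errors(self):
        with pytest.raises(ValueError, match="negative"):
            filter_masspec([cand(masspec_tags=-1)])

    def test_rrs_screen_uses_coding_percentile(self):
        coding = np.linspace(1.0, 10.0, 100)  # 5th percentile ~1.45
        kept, _ = filter_rrs([cand(max_rrs=1.0)], coding)
        assert len(kept) == 1
        kept, excluded = filter_rrs([cand(max_rrs=5.0)], coding)
        assert not kept and len(excluded) == 1

    def test_rrs_undefined_score_kept(self):
        kept, _ = filter_rrs([cand(max_rrs=None)], [1.0, 2.0, 3.0])
        assert len(kept) == 1

    def test_boolean_criteria(self):
        kept, _ = filter_boolean_criteria([cand(has_human_synteny=False)])
        assert not kept
        kept, _ = filter_boolean_criteria(
            [cand(has_human_synteny=False)], require_synteny=False
        )
        assert len(kept) == 1


class TestPipeline:
    def build_cohort(self):
        annotations = [(GenomicInterval("chr1", 5_000, 6_000), "coding")]
        cohort = [
            cand(gene_id="all_pass"),
            cand(gene_id="fails_annotation", start=5_500, end=5_900),
            cand(gene_id="fails_csf", csf_score=-50.0),
            cand(gene_id="fails_masspec", masspec_tags=9),
            cand(gene_id="fails_rrs", max_rrs=99.0),
            cand(gene_id="fails_flags", has_k4me3_k36me3=False),
        ]
        rrs_results = {c.gene_id: c.max_rrs for c in cohort}
        coding_rrs = list(np.linspace(2.0, 20.0, 50))
        return cohort, annotations, rrs_results, coding_rrs

    def test_planted_pass_fail_labels_recovered(self):
        cohort, annotations, rrs_results, coding = self.build_cohort()
        kept, attrition = run_selection_pipeline(cohort, annotations, rrs_results, coding)
        assert [c.gene_id for c in kept] == ["all_pass"]
        # attrition bookkeeping: kept + excluded = stage input at every stage
        for row in attrition.itertuples(index=False):
            assert row.n_kept + row.n_excluded == row.n_in
        assert attrition["n_in"].iloc[0] == len(cohort)

    def test_short_circuit_trace(self):
        cohort, annotations, rrs_results, coding = self.build_cohort()
        run_selection_pipeline(cohort, annotations, rrs_results, coding)
        by_id = {c.gene_id: c for c in cohort}
        assert by_id["all_pass"].filter_trace == [
            ("annotation_overlap", "pass"),
            ("csf", "pass"),
            ("masspec", "pass"),
            ("rrs", "pass"),
            ("boolean_criteria", "pass"),
        ]
        assert by_id["fails_csf"].filter_trace == [
            ("annotation_overlap", "pass"),
            ("csf", "fail"),
        ]

    def test_cascade_equals_intersection_of_individual_keeps(self):
        cohort, annotations, rrs_results, coding = self.build_cohort()
        cascade_kept, _ = run_selection_pipeline(
            copy.deepcopy(cohort), annotations, rrs_results, coding
        )
        keeps = []
        for filt in (
            lambda cs: filter_annotation_overlap(cs, annotations)[0],
            lambda cs: filter_csf(cs)[0],
            lambda cs: filter_masspec(cs)[0],
            lambda cs: filter_rrs(cs, coding)[0],
            lambda cs: filter_boolean_criteria(cs)[0],
        ):
            keeps.append({c.gene_id for c in filt(copy.deepcopy(cohort))})
        assert {c.gene_id for c in cascade_kept} == set.intersection(*keeps)

    def test_missing_rrs_id_errors(self):
        cohort, annotations, rrs_results, coding = self.build_cohort()
        del rrs_results["all_pass"]
        with pytest.raises(ValueError, match="all_pass"):
            run_selection_pipeline(cohort, annotations, rrs_results, coding)


class TestTemporalInduction:
    def test_significant_and_induced_lands_in_both_sets(self):
        pairs = [
            TimecoursePair("g1", "adjacent", 0.005, 1),
            TimecoursePair("g1", "vs_day0", 0.005, 1),
        ]
        de, induced = temporal_induction_filter(pairs)
        assert de == {"g1"} and induced == {"g1"}

    def test_downregulated_gene_only_in_first_set(self):
        pairs = [
            TimecoursePair("g1", "adjacent", 0.005, 1),
            TimecoursePair("g1", "vs_day0", 0.005, -1),
        ]
        de, induced = temporal_induction_filter(pairs)
        assert de == {"g1"} and induced == set()

    def test_unlabelled_contrast_errors(self):
        with pytest.raises(ValueError, match="unlabelled"):
            TimecoursePair("g1", "day3_vs_day4", 0.005, 1)

    def test_toy_table_matches_manual_evaluation(self):
        """6 genes x 3 contrasts, evaluated exhaustively by hand."""
        q, Q = 0.001, 0.5  # clearly below / above the 0.01 threshold
        rows = [
            # gene, adjacent q, vs_day0 q, vs_day0 direction
            ("a", q, q, +1),   # de + induced
            ("b", q, q, -1),   # de, not induced (down)
            ("c", q, Q, +1),   # de, vs-day0 not significant
            ("d", Q, q, +1),   # induced vs day0 but never adjacent-DE
            ("e", Q, Q, +1),   # nothing
            ("f", q, q, +1),   # de + induced
        ]
        pairs = []
        for gene, qa, q0, d0 in rows:
            pairs.append(TimecoursePair(gene, "adjacent", qa, 1))
            pairs.append(TimecoursePair(gene, "vs_day0", q0, d0))
        de, induced = temporal_induction_filter(pairs, q_threshold=0.01)
        assert de == {"a", "b", "c", "f"}
        assert induced == {"a", "f"}
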