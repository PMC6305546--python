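"""ROI hit rules, batch annotation, clinical tiering and diagnostic yield."""

import pytest

from cnvburden import (
    Gene,
    GenomicInterval,
    RoiLocus,
    annotate_events,
    classify_clinical,
    diagnostic_yield,
    gene_hit,
    locus_hit,
    overlap_length,
)
from cnvburden import datasets
from cnvburden.roi import (
    BASIS_HR_LOSS,
    BASIS_LISTED,
    BASIS_LOCUS,
    GAIN_BREAKPOINT,
    LOSS_INTERSECT,
    RoiAnnotation,
    classify_all,
)

from conftest import make_event

LOCUS_DEL = RoiLocus("del_locus", GenomicInterval("chr1", 1_000_000, 2_000_000), "del")
LOCUS_DUP = RoiLocus("dup_locus", GenomicInterval("chr1", 1_000_000, 2_000_000), "dup")
GENE = Gene("G1", GenomicInterval("chr1", 1_000_000, 2_000_000), high_risk=True)


class TestLocusHit:
    def test_identical_loss_hits_deletion_locus(self):
        assert locus_hit(make_event(start=1_000_000, end=2_000_000), LOCUS_DEL)

    def test_dosage_correspondence_required(self):
        gain = make_event(start=1_000_000, end=2_000_000, dosage="gain")
        assert not locus_hit(gain, LOCUS_DEL)
        assert locus_hit(gain, LOCUS_DUP)
        both = RoiLocus("b", LOCUS_DEL.interval, "both")
        assert locus_hit(gain, both)

    def test_eighty_percent_boundary_inclusive(self):
        # 1 Mb event, locus covers 790 kb vs 800 kb of it
        ev = make_event(start=1_500_000, end=2_500_000)
        locus_79 = RoiLocus("x", GenomicInterval("chr1", 0, 2_290_000), "del")
        locus_80 = RoiLocus("x", GenomicInterval("chr1", 0, 2_300_000), "del")
        assert not locus_hit(ev, locus_79)
        assert locus_hit(ev, locus_80)

    def test_hit_implies_overlap(self):
        ev = make_event(start=1_200_000, end=1_400_000)
        assert locus_hit(ev, LOCUS_DEL)
        assert overlap_length(ev.interval, LOCUS_DEL.interval) > 0

    def test_shrinking_inside_locus_preserves_hit(self):
        for start, end in [(1_000_000, 2_000_000), (1_200_000, 1_800_000),
                           (1_499_000, 1_501_000)]:
            assert locus_hit(make_event(start=start, end=end), LOCUS_DEL)


class TestGeneHit:
    def test_loss_counts_on_any_intersection(self):
        graze = make_event(start=999_000, end=1_000_001)  # 1 bp of gene
        assert gene_hit(graze, GENE) == LOSS_INTERSECT

    def test_loss_without_overlap_is_none(self):
        assert gene_hit(make_event(start=0, end=999_999), GENE) is None

    def test_gain_spanning_whole_gene_is_none(self):
        spanning = make_event(start=500_000, end=2_500_000, dosage="gain")
        assert gene_hit(spanning, GENE) is None

    def test_gain_breakpoint_inside_counts(self):
        partial = make_event(start=1_500_000, end=2_500_000, dosage="gain")
        assert gene_hit(partial, GENE) == GAIN_BREAKPOINT

    def test_gain_fully_inside_gene_counts(self):
        inside = make_event(start=1_200_000, end=1_400_000, dosage="gain")
        assert gene_hit(inside, GENE) == GAIN_BREAKPOINT

    def test_boundary_touching_breakpoint_does_not_count(self):
        # both breakpoints exactly at gene boundaries: not strictly inside
        at_bounds = make_event(start=1_000_000, end=2_000_000, dosage="gain")
        assert gene_hit(at_bounds, GENE) is None

    def test_modes_are_dosage_specific(self):
        loss = make_event(start=1_200_000, end=1_400_000)
        gain = make_event(start=1_200_000, end=1_400_000, dosage="gain")
        assert gene_hit(loss, GENE) == LOSS_INTERSECT
        assert gene_hit(gain, GENE) == GAIN_BREAKPOINT


class TestAnnotateEvents:
    def test_worked_example_dual_hit(self):
        """The chr16:29580021-30178406 loss hits both the 16p11.2 deletion
        locus and the TAOK2 high-risk gene inside it."""
        ev = make_event(chrom="chr16", start=29_580_021, end=30_178_406,
                        sample_id="ASD386")
        [ann] = annotate_events([ev], datasets.asd_loci(), datasets.roi_genes())
        assert [name for name, _ in ann.asd_locus_hits] == ["16p11.2"]
        assert ("TAOK2", LOSS_INTERSECT) in ann.hr_gene_hits

    def test_event_off_all_rois_gets_empty_annotation(self):
        ev = make_event(chrom="chr9", start=1_000_000, end=1_500_000)
        [ann] = annotate_events([ev], datasets.asd_loci(), datasets.roi_genes())
        assert not (ann.asd_locus_hits or ann.hr_gene_hits or ann.lofi_gene_hits)

    def test_deterministic_and_ordered(self):
        evs = [
            make_event(chrom="chr16", start=29_580_021, end=30_178_406, sample_id="b"),
            make_event(chrom="chr2", start=51_057_960, end=51_433_041, sample_id="a"),
        ]
        first = annotate_events(evs, datasets.asd_loci(), datasets.roi_genes())
        second = annotate_events(evs, datasets.asd_loci(), datasets.roi_genes())
        assert [(a.event.sample_id, a.asd_locus_hits, a.hr_gene_hits) for a in first] == [
            (a.event.sample_id, a.asd_locus_hits, a.hr_gene_hits) for a in second
        ]
        assert [a.event.interval.chrom for a in first] == ["chr16", "chr2"]


class TestClassifyClinical:
    def test_high_risk_gene_loss_is_pathogenic(self):
        ev = make_event(chrom="chr2", start=51_057_960, end=51_433_041)
        [ann] = annotate_events([ev], [], datasets.roi_genes())
        call = classify_clinical(ann)
        assert (call.tier, call.basis) == ("pathogenic", BASIS_HR_LOSS)

    def test_high_risk_gene_gain_is_uncertain(self):
        ev = make_event(chrom="chr20", start=49_531_228, end=49_685_636, dosage="gain")
        [ann] = annotate_events([ev], [], datasets.roi_genes())
        assert classify_clinical(ann).tier == "uncertain"

    def test_listed_region_takes_priority(self):
        ev = make_event(chrom="chr17", start=14_087_934, end=15_484_859)
        [ann] = annotate_events([ev], datasets.asd_loci(), datasets.roi_genes())
        call = classify_clinical(ann, datasets.listed_regions())
        assert (call.tier, call.basis) == ("pathogenic", BASIS_LISTED)

    def test_locus_hit_outranks_gene_basis(self):
        ev = make_event(chrom="chr16", start=29_580_021, end=30_178_406)
        [ann] = annotate_events([ev], datasets.asd_loci(), datasets.roi_genes())
        call = classify_clinical(ann, datasets.listed_regions())
        assert (call.tier, call.basis) == ("pathogenic", BASIS_LOCUS)

    def test_no_hits_untiered(self):
        call = classify_clinical(RoiAnnotation(event=make_event()))
        assert (call.tier, call.basis) == ("none", "none")

    def test_pure_function_of_annotation(self):
        ev = make_event(chrom="chr2", start=51_057_960, end=51_433_041)
        [ann] = annotate_events([ev], [], datasets.roi_genes())
        assert classify_clinical(ann) == classify_clinical(ann)


class TestDiagnosticYield:
    def test_worked_example_yield(self):
        events = datasets.example_events()
        anns = annotate_events(events, datasets.asd_loci(), datasets.roi_genes())
        calls = classify_all(anns, datasets.listed_regions())
        pathogenic = [c for c in calls if c.tier == "pathogenic"]
        assert len(pathogenic) == 17
        assert diagnostic_yield(calls, 405) == 4.2

    def test_degenerate_yields(self):
        events = datasets.example_events()
        anns = annotate_events(events, datasets.asd_loci(), datasets.roi_genes())
        calls = classify_all(anns, datasets.listed_regions())
        assert diagnostic_yield([], 100) == 0.0
        carriers = {c.event.sample_id for c in calls if c.tier == "pathogenic"}
        assert diagnostic_yield(calls, len(carriers)) == 100.0
        with pytest.raises(ValueError):
            diagnostic_yield(calls, 0)
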