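"""Rare-event filtering: call thresholds, autosome gate, frequency matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvburden import (
    FrequencyReference,
    GenomicInterval,
    ReferenceRecord,
    apply_call_thresholds,
    autosomes_only,
    filter_rare,
    fraction_of_query,
    reference_frequency,
    run_filter_chain,
)
from cnvburden.core import ConfigError

from conftest import make_event


class TestCallThresholds:
    def test_size_boundary_inclusive_at_100kb(self):
        small = make_event(start=0, end=99_000)
        exact = make_event(start=0, end=100_000)
        assert apply_call_thresholds([small, exact]) == [exact]

    def test_probe_threshold_strictly_greater(self):
        at = make_event(probe_count=25)
        above = make_event(probe_count=26)
        absent = make_event()
        assert apply_call_thresholds([at, above, absent]) == [above, absent]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            apply_call_thresholds([], min_size_kb=-1)

    def test_order_preserved_and_idempotent(self):
        events = [make_event(sample_id=f"s{i}", start=0, end=(i + 1) * 90_000)
                  for i in range(5)]
        once = apply_call_thresholds(events)
        assert apply_call_thresholds(once) == once
        assert once == [ev for ev in events if ev.size_kb >= 100]


def test_autosomes_only():
    evs = [make_event(chrom=c) for c in ("chr1", "chrX", "chr22", "chrY")]
    kept = autosomes_only(evs)
    assert [e.interval.chrom for e in kept] == ["chr1", "chr22"]
    assert autosomes_only(kept) == kept
    assert autosomes_only([]) == []


def _carrier_ref(records, ref_n=1000, name="ref"):
    return FrequencyReference(name=name, ref_n=ref_n, events=records)


class TestReferenceFrequency:
    def test_no_overlap_gives_zero(self):
        ref = _carrier_ref([ReferenceRecord(GenomicInterval("chr2", 0, 100_000),
                                            "loss", carrier_id="c1")])
        assert reference_frequency(make_event(), ref) == 0.0

    def test_half_overlap_rule_with_carrier_count(self):
        # 30 carriers of a 60,001 bp deletion covering 60.001% of a 100 kb query
        records = [
            ReferenceRecord(GenomicInterval("chr1", 0, 60_001), "loss",
                            carrier_id=f"c{i}")
            for i in range(30)
        ]
        event = make_event(start=0, end=100_000)
        assert reference_frequency(event, _carrier_ref(records)) == pytest.approx(0.03)

    def test_half_overlap_is_strict(self):
        # exactly 50% coverage does not match
        records = [ReferenceRecord(GenomicInterval("chr1", 0, 50_000), "loss",
                                   carrier_id="c1")]
        assert reference_frequency(make_event(start=0, end=100_000),
                                   _carrier_ref(records)) == 0.0

    def test_dosage_mismatch_ignored(self):
        records = [ReferenceRecord(GenomicInterval("chr1", 0, 60_001), "gain",
                                   carrier_id=f"c{i}") for i in range(30)]
        assert reference_frequency(make_event(start=0, end=100_000),
                                   _carrier_ref(records)) == 0.0

    def test_frequency_encoding_takes_max(self):
        records = [
            ReferenceRecord(GenomicInterval("chr1", 900_000, 1_300_000), "loss", freq=0.004),
            ReferenceRecord(GenomicInterval("chr1", 950_000, 1_250_000), "loss", freq=0.02),
        ]
        assert reference_frequency(make_event(), _carrier_ref(records)) == 0.02

    def test_monotone_in_carriers(self):
        event = make_event(start=0, end=100_000)
        base = [ReferenceRecord(GenomicInterval("chr1", 0, 80_000), "loss",
                                carrier_id=f"c{i}") for i in range(5)]
        extra = base + [ReferenceRecord(GenomicInterval("chr1", 0, 80_000), "loss",
                                        carrier_id="c99")]
        assert (reference_frequency(event, _carrier_ref(extra))
                >= reference_frequency(event, _carrier_ref(base)))

    def test_reciprocal_flag_requires_mutual_coverage(self):
        # huge reference event covers the query fully but not vice versa
        records = [ReferenceRecord(GenomicInterval("chr1", 0, 10_000_000), "loss",
                                   carrier_id=f"c{i}") for i in range(100)]
        event = make_event(start=1_000_000, end=1_200_000)
        assert reference_frequency(event, _carrier_ref(records)) == 0.1
        assert reference_frequency(event, _carrier_ref(records), reciprocal=True) == 0.0


class TestFilterRare:
    def test_rare_in_all_rule(self):
        event = make_event(start=0, end=100_000)
        common = _carrier_ref(
            [ReferenceRecord(GenomicInterval("chr1", 0, 80_000), "loss",
                             carrier_id=f"c{i}") for i in range(20)],
            name="common_in_here")  # frequency 0.02
        empty = _carrier_ref([], name="empty")
        kept, report = filter_rare([event], [common, empty])
        assert kept == []
        assert report.dispositions[0][1] == "frequency"
        assert report.dispositions[0][2] == pytest.approx(0.02)
        kept2, _ = filter_rare([event], [empty])
        assert kept2 == [event]

    def test_below_threshold_retained(self):
        event = make_event(start=0, end=100_000)
        ref = _carrier_ref([ReferenceRecord(GenomicInterval("chr1", 0, 80_000), "loss",
                                            carrier_id=f"c{i}") for i in range(9)])
        kept, _ = filter_rare([event], [ref])  # frequency 0.009 < 0.01
        assert kept == [event]

    def test_idempotent(self):
        events = [make_event(sample_id=f"s{i}", start=i * 1_000_000,
                             end=i * 1_000_000 + 150_000) for i in range(1, 6)]
        ref = _carrier_ref([ReferenceRecord(GenomicInterval("chr1", 1_000_000, 1_150_000),
                                            "loss", carrier_id=f"c{i}") for i in range(50)])
        once, _ = filter_rare(events, [ref])
        twice, _ = filter_rare(once, [ref])
        assert twice == once

    def test_requires_a_reference(self):
        with pytest.raises(ConfigError):
            filter_rare([make_event()], [])


def test_filter_chain_counts_non_increasing():
    events = [
        make_event(start=0, end=50_000),              # size
        make_event(probe_count=10),                   # probes
        make_event(chrom="chrX"),                     # autosome
        make_event(sample_id="keep"),
    ]
    kept, report = run_filter_chain(events, [])
    assert kept == [events[3]]
    counts = list(report.counts().values())
    assert counts == sorted(counts, reverse=True)
    assert counts == [4, 3, 2, 1, 1]
    removed_stages = [d[1] for d in report.dispositions]
    assert removed_stages == ["size", "probes", "autosome", None]


# --- indexed lookup vs brute force ---------------------------------------

_record = st.builds(
    lambda chrom, start, length, dosage, cid: ReferenceRecord(
        GenomicInterval(chrom, start, start + length), dosage, carrier_id=f"c{cid}"
    ),
    chrom=st.sampled_from(["chr1", "chr2"]),
    start=st.integers(0, 500_000),
    length=st.integers(50_000, 400_000),
    dosage=st.sampled_from(["loss", "gain"]),
    cid=st.integers(0, 40),
)


def _brute_force_frequency(event, ref):
    carriers = set()
    for rec in ref.events:
        if rec.dosage != event.dosage:
            continue
        if fraction_of_query(event.interval, rec.interval) > 0.5:
            carriers.add(rec.carrier_id)
    return len(carriers) / ref.ref_n


@settings(derandomize=True, max_examples=100)
@given(records=st.lists(_record, max_size=50),
       start=st.integers(0, 500_000),
       length=st.integers(50_000, 400_000),
       dosage=st.sampled_from(["loss", "gain"]))
def test_indexed_frequency_matches_brute_force(records, start, length, dosage):
    ref = FrequencyReference(name="rand", ref_n=100, events=records)
    event = make_event(start=start, end=start + length, dosage=dosage)
    assert reference_frequency(event, ref) == pytest.approx(
        _brute_force_frequency(event, ref)
    )
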