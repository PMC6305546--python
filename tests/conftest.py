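import pytest

from cnvburden import CnvEvent, GenomicInterval, Sample


def make_event(chrom="chr1", start=1_000_000, end=1_200_000, dosage="loss",
               sample_id="s1", probe_count=None):
    return CnvEvent(sample_id, GenomicInterval(chrom, start, end), dosage,
                    probe_count=probe_count)


@pytest.fixture
def tiny_cohort():
    """Four cases + four controls with hand-countable events."""
    samples = [Sample(f"case{i}", "case") for i in range(1, 5)] + [
        Sample(f"ctl{i}", "control") for i in range(1, 5)
    ]
    events = [
        make_event(sample_id="case1"),
        make_event(sample_id="case1", start=5_000_000, end=5_300_000),
        make_event(sample_id="case2"),
        make_event(sample_id="case3", dosage="gain"),
        make_event(sample_id="ctl1"),
        make_event(sample_id="ctl2", dosage="gain"),
    ]
    return samples, events
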