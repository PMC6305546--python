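"""Packaged worked-example data.

The example models a chromosomal-microarray study of a Chinese ASD cohort
(401 probands, of whom 177 mildly/moderately and 224 severely affected,
plus 197 ancestry-matched controls): the clinically significant CNVs and
candidate-gene CNVs it reported, hg19 spans for the recurrent risk loci
and curated pathogenic regions they match, approximate genic spans for
the implicated genes, and the published stratified event counts used to
reconstruct a count-matched cohort.

Locus spans are derived from the example CNV coordinates (stand-ins for a
curated locus list; real analyses should supply their own locus BED), and
gene spans are approximate hg19 coordinates.
"""

from __future__ import annotations

from pathlib import Path

from .core import BOTH, CnvEvent, DEL, DUP, Gene, GenomicInterval, RoiLocus, Sample
from .rare_filter import FrequencyReference, ReferenceRecord

# ---------------------------------------------------------------------------
# Clinically significant / candidate-gene CNVs of the example cohort.
# Fields: (label, region, dosage, sample_id, severity, dgv_freq or None)
# The chr16:29580021-30178406 loss hits both the 16p11.2 locus and TAOK2;
# it is a single event and is stored once.

_EXAMPLE_CNVS: tuple[tuple[str, str, str, str, str, float | None], ...] = (
    # curated pathogenic regions
    ("8p23.3p23.1", "chr8:158049-10137194", "loss", "ASD425", "mild", None),
    ("10q11.2", "chr10:46206776-51812795", "gain", "ASD106", "severe", None),
    ("4q31.21q33", "chr4:145149738-170414221", "gain", "ASD215", "mild", None),
    ("3p14.1", "chr3:66066409-69273190", "gain", "ASD343", "severe", None),
    ("17p12", "chr17:14087934-15484859", "loss", "ASD445", "severe", None),
    ("17p12", "chr17:14087934-15491532", "loss", "ASD381", "mild", None),
    # recurrent risk loci
    ("1q21.1", "chr1:146106724-147926347", "loss", "ASD227", "mild", None),
    ("7q11.23", "chr7:72624167-74136633", "loss", "ASD309", "severe", None),
    ("16p13.11", "chr16:15449697-16294705", "loss", "ASD443", "mild", None),
    ("16p11.2", "chr16:29580021-30178406", "loss", "ASD386", "severe", None),
    ("22q11.2", "chr22:18644791-19899146", "loss", "ASD419", "mild", None),
    ("22q11.2", "chr22:18916843-21798907", "loss", "ASD017", "mild", None),
    ("1q21.1", "chr1:146498360-147399145", "gain", "ASD278", "severe", None),
    ("15q11q13", "chr15:22770422-28545355", "gain", "ASD050", "severe", None),
    ("15q11q13", "chr15:23284500-28534245", "gain", "ASD061", "severe", None),
    ("15q11q13", "chr15:22770422-28560664", "gain", "ASD317", "severe", None),
    # high-risk genes
    ("NRXN1", "chr2:51057960-51433041", "loss", "ASD287", "mild", None),
    ("CNTNAP2", "chr7:144519741-145950454", "gain", "ASD406", "severe", None),
    ("ADNP", "chr20:49531228-49685636", "gain", "ASD094", "severe", None),
    # LoF-intolerant candidate genes
    ("RIMS2", "chr8:105008757-105127783", "loss", "ASD380", "severe", 0.000169),
    ("RIMS2", "chr8:104218356-104552138", "gain", "ASD024", "severe", 0.0),
    ("PTPRT", "chr20:41153385-41326127", "loss", "ASD114", "severe", 0.0),
    ("FRMD4A/HSPA14", "chr10:13219451-15005442", "loss", "ASD265", "severe", 0.0),
    ("CCZ1", "chr7:5838735-5982759", "loss", "ASD289", "severe", 0.000676),
)

EXAMPLE_COHORT_SIZE = 405  # tested individuals in the worked example


def example_events() -> list[CnvEvent]:
    """The worked-example CNV calls (one event per table entry)."""
    from .core import parse_region_string

    return [
        CnvEvent(
            sample_id=sample_id,
            interval=parse_region_string(region),
            dosage=dosage,
            source_tag=label,
        )
        for label, region, dosage, sample_id, severity, _ in _EXAMPLE_CNVS
    ]


def example_manifest(n_individuals: int = EXAMPLE_COHORT_SIZE) -> list[Sample]:
    """Case manifest for the worked example: the listed carriers plus
    unaffected-by-CNV filler probands up to ``n_individuals``."""
    samples: list[Sample] = []
    seen: set[str] = set()
    for _, _, _, sample_id, severity, _ in _EXAMPLE_CNVS:
        if sample_id in seen:
            continue
        seen.add(sample_id)
        samples.append(Sample(sample_id=sample_id, group="case", severity=severity))
    i = 0
    while len(samples) < n_individuals:
        i += 1
        sid = f"ASDF{i:03d}"
        if sid not in seen:
            samples.append(Sample(sample_id=sid, group="case"))
    return samples


def asd_loci() -> list[RoiLocus]:
    """Recurrent risk loci (hg19 spans derived from the example CNVs)."""
    return [
        RoiLocus("1q21.1", GenomicInterval("chr1", 146106724, 147926347), BOTH),
        RoiLocus("7q11.23", GenomicInterval("chr7", 72624167, 74136633), DEL),
        RoiLocus("16p13.11", GenomicInterval("chr16", 15449697, 16294705), DEL),
        RoiLocus("16p11.2", GenomicInterval("chr16", 29580021, 30178406), DEL),
        RoiLocus("22q11.2", GenomicInterval("chr22", 18644791, 21798907), DEL),
        RoiLocus("15q11q13", GenomicInterval("chr15", 22770422, 28560664), DUP),
    ]


def listed_regions() -> list[RoiLocus]:
    """Curated pathogenic regions of the worked example."""
    return [
        RoiLocus("8p23.3p23.1", GenomicInterval("chr8", 158049, 10137194), BOTH),
        RoiLocus("10q11.2", GenomicInterval("chr10", 46206776, 51812795), BOTH),
        RoiLocus("4q31.21q33", GenomicInterval("chr4", 145149738, 170414221), BOTH),
        RoiLocus("3p14.1", GenomicInterval("chr3", 66066409, 69273190), BOTH),
        RoiLocus("17p12", GenomicInterval("chr17", 14087934, 15491532), BOTH),
    ]


def roi_genes() -> list[Gene]:
    """High-risk and LoF-intolerant gene spans (approximate hg19)."""
    return [
        Gene("NRXN1", GenomicInterval("chr2", 50145643, 51259674), high_risk=True, lof_intolerant=True),
        Gene("TAOK2", GenomicInterval("chr16", 29985189, 30003582), high_risk=True),
        Gene("CNTNAP2", GenomicInterval("chr7", 145813453, 148118090), high_risk=True),
        Gene("ADNP", GenomicInterval("chr20", 49505454, 49547527), high_risk=True, lof_intolerant=True),
        Gene("RIMS2", GenomicInterval("chr8", 104310656, 105118580), lof_intolerant=True),
        Gene("PTPRT", GenomicInterval("chr20", 40701376, 41819974), lof_intolerant=True),
        Gene("FRMD4A", GenomicInterval("chr10", 13685704, 14372894), lof_intolerant=True),
        Gene("HSPA14", GenomicInterval("chr10", 14880043, 14913660), lof_intolerant=True),
        Gene("CCZ1", GenomicInterval("chr7", 5869788, 5929576), lof_intolerant=True),
    ]


def example_reference(ref_n: int = 54946) -> FrequencyReference:
    """DGV-style frequency-encoded reference carrying the example events'
    recorded population frequencies (all rare)."""
    from .core import parse_region_string

    records = [
        ReferenceRecord(parse_region_string(region), dosage, freq=freq)
        for _, region, dosage, _, _, freq in _EXAMPLE_CNVS
        if freq is not None and freq > 0.0
    ]
    return FrequencyReference(name="dgv_example", ref_n=ref_n, events=records)


# ---------------------------------------------------------------------------
# Published stratified event counts of the example cohort (per group):
# group sizes, event counts per (dosage, size bin) and per (dosage, ROI
# category, all sizes). Used by cohort_from_margins to reconstruct a
# count-matched cohort for deterministic rate/ratio arithmetic.

BURDEN_MARGINS: dict = {
    "n": {"control": 197, "mild": 177, "severe": 224},
    "bins": {
        ("loss", ">3M"): {"control": 0, "mild": 1, "severe": 0},
        ("loss", "1M-3M"): {"control": 1, "mild": 7, "severe": 4},
        ("loss", "400k-1M"): {"control": 4, "mild": 9, "severe": 4},
        ("loss", "100k-400k"): {"control": 46, "mild": 55, "severe": 68},
        ("gain", ">3M"): {"control": 0, "mild": 1, "severe": 5},
        ("gain", "1M-3M"): {"control": 7, "mild": 3, "severe": 7},
        ("gain", "400k-1M"): {"control": 23, "mild": 19, "severe": 31},
        ("gain", "100k-400k"): {"control": 146, "mild": 74, "severe": 132},
    },
    "categories": {
        ("loss", "asd_loci"): {"control": 0, "mild": 4, "severe": 2},
        ("gain", "asd_loci"): {"control": 0, "mild": 0, "severe": 4},
        ("loss", "hr_genes"): {"control": 0, "mild": 1, "severe": 1},
        ("gain", "hr_genes"): {"control": 4, "mild": 0, "severe": 2},
        ("loss", "lofi_genes"): {"control": 2, "mild": 5, "severe": 7},
        ("gain", "lofi_genes"): {"control": 16, "mild": 10, "severe": 22},
    },
}


# ---------------------------------------------------------------------------
# Materialization


def write_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the worked-example inputs as files and return their paths."""
    from .io import write_events, write_gene_bed, write_manifest, write_roi_bed
    from .rare_filter import write_frequency_reference

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out / "calls.tsv",
        "manifest": out / "samples.tsv",
        "loci": out / "asd_loci.bed",
        "listed": out / "listed_regions.bed",
        "genes": out / "genes.bed",
        "reference": out / "reference.tsv",
    }
    write_events(paths["calls"], example_events())
    write_manifest(paths["manifest"], example_manifest())
    write_roi_bed(paths["loci"], asd_loci())
    write_roi_bed(paths["listed"], listed_regions())
    write_gene_bed(paths["genes"], roi_genes())
    write_frequency_reference(paths["reference"], example_reference())
    return paths
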