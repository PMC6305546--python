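"""Region-of-interest annotation and rule-based clinical tiering.

Three ROI categories are annotated per event: recurrent risk loci
(requiring at least 80% of the CNV covered and dosage correspondence),
high-risk genes, and LoF-intolerant genes. Gene hits follow asymmetric
dosage rules: any overlapping loss disrupts a gene, while a gain counts
only when a breakpoint falls inside the gene body (a partial duplication);
a gain cleanly spanning the whole gene leaves an intact extra copy and
does not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    BOTH,
    CnvEvent,
    GAIN,
    Gene,
    LOSS,
    RoiLocus,
    fraction_of_query,
    overlap_length,
)
from .index import IntervalIndex

LOSS_INTERSECT = "loss_intersect"
GAIN_BREAKPOINT = "gain_breakpoint"

PATHOGENIC = "pathogenic"
UNCERTAIN = "uncertain"
NONE = "none"

BASIS_LISTED = "listed_region"
BASIS_LOCUS = "asd_locus"
BASIS_HR_LOSS = "high_risk_gene_loss"


def _locus_fraction(event: CnvEvent, locus: RoiLocus, fraction_of: str) -> float:
    """Overlap fraction under the configured direction convention."""
    if fraction_of == "cnv":
        return fraction_of_query(event.interval, locus.interval)
    if fraction_of == "locus":
        return fraction_of_query(locus.interval, event.interval)
    if fraction_of == "either":
        return max(
            fraction_of_query(event.interval, locus.interval),
            fraction_of_query(locus.interval, event.interval),
        )
    raise ValueError(f"fraction_of must be cnv/locus/either, got {fraction_of!r}")


def locus_hit(
    event: CnvEvent,
    locus: RoiLocus,
    min_fraction: float = 0.8,
    fraction_of: str = "cnv",
) -> bool:
    """Does the event match a recurrent locus?

    Requires at least ``min_fraction`` of the CNV's length covered by the
    locus (direction configurable) and dosage correspondence
    (loss<->deletion, gain<->duplication, or a ``both`` locus).
    """
    if not locus.dosage_matches(event.dosage):
        return False
    return _locus_fraction(event, locus, fraction_of) >= min_fraction


def gene_hit(event: CnvEvent, gene: Gene) -> Optional[str]:
    """Hit mode of an event against a genic span, or ``None``.

    Losses count on any overlap (``loss_intersect``). Gains count only when
    a breakpoint lies strictly inside the open genic span
    (``gain_breakpoint``); boundary-touching breakpoints do not interrupt
    the gene body, and a gain entirely inside the gene still partially
    duplicates it and counts.
    """
    if event.interval.chrom != gene.interval.chrom:
        return None
    if event.dosage == LOSS:
        return LOSS_INTERSECT if overlap_length(event.interval, gene.interval) > 0 else None
    g = gene.interval
    for breakpoint in (event.interval.start, event.interval.end):
        if g.start < breakpoint < g.end:
            return GAIN_BREAKPOINT
    return None


@dataclass
class RoiAnnotation:
    """ROI hits of one event: loci (with overlap fraction) and genes (with mode)."""

    event: CnvEvent
    asd_locus_hits: list[tuple[str, float]] = field(default_factory=list)
    hr_gene_hits: list[tuple[str, str]] = field(default_factory=list)
    lofi_gene_hits: list[tuple[str, str]] = field(default_factory=list)

    @property
    def has_locus_hit(self) -> bool:
        return bool(self.asd_locus_hits)

    @property
    def has_hr_hit(self) -> bool:
        return bool(self.hr_gene_hits)

    @property
    def has_lofi_hit(self) -> bool:
        return bool(self.lofi_gene_hits)


def annotate_event(
    event: CnvEvent,
    locus_index: IntervalIndex[RoiLocus],
    gene_index: IntervalIndex[Gene],
    min_fraction: float = 0.8,
    fraction_of: str = "cnv",
) -> RoiAnnotation:
    ann = RoiAnnotation(event=event)
    for locus in locus_index.overlapping(event.interval):
        if locus_hit(event, locus, min_fraction=min_fraction, fraction_of=fraction_of):
            ann.asd_locus_hits.append(
                (locus.name, _locus_fraction(event, locus, fraction_of))
            )
    for gene in gene_index.overlapping(event.interval):
        mode = gene_hit(event, gene)
        if mode is None:
            continue
        if gene.high_risk:
            ann.hr_gene_hits.append((gene.symbol, mode))
        if gene.lof_intolerant:
            ann.lofi_gene_hits.append((gene.symbol, mode))
    return ann


def annotate_events(
    events: Sequence[CnvEvent],
    loci: Sequence[RoiLocus],
    genes: Sequence[Gene],
    min_fraction: float = 0.8,
    fraction_of: str = "cnv",
) -> list[RoiAnnotation]:
    """Annotate every event; output ordered by (chrom, start, sample_id)."""
    locus_index: IntervalIndex[RoiLocus] = IntervalIndex((l.interval, l) for l in loci)
    gene_index: IntervalIndex[Gene] = IntervalIndex((g.interval, g) for g in genes)
    ordered = sorted(
        events, key=lambda ev: (ev.interval.chrom, ev.interval.start, ev.sample_id)
    )
    return [
        annotate_event(ev, locus_index, gene_index, min_fraction, fraction_of)
        for ev in ordered
    ]


@dataclass(frozen=True)
class ClinicalCall:
    """Rule-based clinical tier for one event."""

    event: CnvEvent
    tier: str
    basis: str


def classify_clinical(
    annotation: RoiAnnotation,
    listed_regions: Sequence[RoiLocus] = (),
    min_fraction: float = 0.8,
    fraction_of: str = "cnv",
) -> ClinicalCall:
    """Assign a clinical tier from ROI hits.

    Pathogenic bases, in priority order: (1) the event covers a curated
    pathogenic region at >=80%; (2) it matches a recurrent risk locus;
    (3) it is a loss hitting a high-risk gene. A gain hitting a high-risk
    gene is of uncertain significance; anything else is untiered. Pure in
    the annotation: repeated calls agree.
    """
    ev = annotation.event
    for region in listed_regions:
        if locus_hit(ev, region, min_fraction=min_fraction, fraction_of=fraction_of):
            return ClinicalCall(ev, PATHOGENIC, BASIS_LISTED)
    if annotation.has_locus_hit:
        return ClinicalCall(ev, PATHOGENIC, BASIS_LOCUS)
    if annotation.has_hr_hit:
        if ev.dosage == LOSS:
            return ClinicalCall(ev, PATHOGENIC, BASIS_HR_LOSS)
        return ClinicalCall(ev, UNCERTAIN, NONE)
    return ClinicalCall(ev, NONE, NONE)


def classify_all(
    annotations: Sequence[RoiAnnotation],
    listed_regions: Sequence[RoiLocus] = (),
    min_fraction: float = 0.8,
    fraction_of: str = "cnv",
) -> list[ClinicalCall]:
    return [
        classify_clinical(ann, listed_regions, min_fraction, fraction_of)
        for ann in annotations
    ]


def diagnostic_yield(calls: Sequence[ClinicalCall], n_individuals: int) -> float:
    """Percent of individuals with at least one pathogenic call, to 1 dp."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    carriers = {c.event.sample_id for c in calls if c.tier == PATHOGENIC}
    return round(100.0 * len(carriers) / n_individuals, 1)
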