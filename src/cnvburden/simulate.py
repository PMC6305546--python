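"""Synthetic case/control CNV cohorts.

Two generators are provided. :func:`simulate_cohort` draws stochastic
cohorts with the statistical structure the burden analysis assumes:
per-individual Poisson event counts (optionally negative-binomial for
overdispersion robustness checks), group-dependent rate multipliers,
log-uniform event sizes within the four analysis bins, uniform placement
over the hg19 autosomes, a common-CNV pool shared with the frequency
reference so the rarity filter has work to do, and optional placement on
region-of-interest fixtures. :func:`cohort_from_margins` deterministically
reconstructs a cohort matching published stratified event counts, for
exact rate/ratio arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    CASE,
    CONTROL,
    CnvEvent,
    ConfigError,
    GAIN,
    Gene,
    GenomicInterval,
    LOSS,
    MILD,
    RoiLocus,
    SEVERE,
    Sample,
)
from .genome import AUTOSOMES, HG19_LENGTHS
from .rare_filter import FrequencyReference, ReferenceRecord

# kb bounds of the four analysis size bins (upper bound of the open-ended
# top bin capped at 10 Mb for simulation)
_BIN_BOUNDS_KB: tuple[tuple[float, float], ...] = (
    (100, 400),
    (400, 1000),
    (1000, 3000),
    (3000, 10000),
)

# default size-bin mixtures: the empirical bin proportions of the example
# cohort's rare events (losses concentrate heavily below 400 kb)
DEFAULT_SIZE_MIX: dict[str, tuple[float, ...]] = {
    LOSS: (169 / 199, 17 / 199, 12 / 199, 1 / 199),
    GAIN: (352 / 448, 73 / 448, 17 / 448, 6 / 448),
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the example study: 197 controls, 177 mild and 224
    severe cases; control rates of 0.259 rare losses and 0.893 rare gains
    per individual; a case/control rate ratio of 1.43 for losses and 0.76
    for gains; and a severe/mild multiplier of 1.43 for gains (losses are
    severity-independent). The mild-case gain rate is derived so the
    cohort-wide case rate honours ``rr_case_gain`` while severe cases sit
    at ``rr_severe_gain`` times the mild rate.
    """

    n_control: int = 197
    n_case_mild: int = 177
    n_case_severe: int = 224
    base_rate_loss: float = 0.259
    base_rate_gain: float = 0.893
    rr_case_loss: float = 1.43
    rr_case_gain: float = 0.76
    rr_severe_gain: float = 1.43
    size_mix: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_MIX))
    common_pool_size: int = 20
    common_pool_freq: float = 0.05
    roi_hit_prob: float = 0.05
    ref_n: int = 2691
    n_private_ref: int = 200
    dispersion: Optional[float] = None  # negative-binomial shape; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_rate_loss", "base_rate_gain", "rr_case_loss",
                     "rr_case_gain", "rr_severe_gain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("common_pool_freq", "roi_hit_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for dosage, mix in self.size_mix.items():
            if len(mix) != 4 or not math.isclose(sum(mix), 1.0, abs_tol=1e-9):
                raise ConfigError(f"size_mix[{dosage!r}] must be 4 probabilities summing to 1")

    def group_rates(self) -> dict[str, dict[str, float]]:
        """Expected rare-event rates per individual by group and dosage."""
        case_loss = self.base_rate_loss * self.rr_case_loss
        case_gain = self.base_rate_gain * self.rr_case_gain
        n_cases = self.n_case_mild + self.n_case_severe
        denom = self.n_case_mild + self.n_case_severe * self.rr_severe_gain
        mild_gain = case_gain * n_cases / denom if denom > 0 else 0.0
        return {
            "control": {LOSS: self.base_rate_loss, GAIN: self.base_rate_gain},
            "mild": {LOSS: case_loss, GAIN: mild_gain},
            "severe": {LOSS: case_loss, GAIN: mild_gain * self.rr_severe_gain},
        }


@dataclass
class SimOutput:
    """A simulated cohort plus the truth record backing recovery tests."""

    samples: list[Sample]
    events: list[CnvEvent]
    reference: FrequencyReference
    loci: list[RoiLocus]
    genes: list[Gene]
    truth: dict


_AUTOSOME_LENGTHS = np.array([HG19_LENGTHS[c] for c in AUTOSOMES], dtype=float)
_AUTOSOME_P = _AUTOSOME_LENGTHS / _AUTOSOME_LENGTHS.sum()


def _draw_count(rng: np.random.Generator, rate: float, dispersion: Optional[float]) -> int:
    if rate <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(rate))
    # negative binomial with mean `rate` and shape `dispersion`
    p = dispersion / (dispersion + rate)
    return int(rng.negative_binomial(dispersion, p))


def _draw_interval(
    rng: np.random.Generator, size_mix: Sequence[float], max_retries: int = 1000
) -> GenomicInterval:
    """Size from the bin mixture (log-uniform within bin), position uniform
    over the autosomes; placements crossing a chromosome end are resampled."""
    bin_idx = int(rng.choice(4, p=np.asarray(size_mix)))
    lo, hi = _BIN_BOUNDS_KB[bin_idx]
    size_bp = int(round(math.exp(rng.uniform(math.log(lo * 1000), math.log(hi * 1000)))))
    size_bp = max(size_bp, int(lo * 1000))
    for _ in range(max_retries):
        chrom = AUTOSOMES[int(rng.choice(len(AUTOSOMES), p=_AUTOSOME_P))]
        length = HG19_LENGTHS[chrom]
        start = int(rng.integers(0, length))
        if start + size_bp <= length:
            return GenomicInterval(chrom, start, start + size_bp)
    raise ConfigError(f"could not place a {size_bp} bp event after {max_retries} tries")


def _draw_roi_interval(
    rng: np.random.Generator,
    size_mix: Sequence[float],
    dosage: str,
    loci: Sequence[RoiLocus],
    genes: Sequence[Gene],
) -> Optional[GenomicInterval]:
    """Place an event overlapping a randomly chosen ROI fixture."""
    regions: list[GenomicInterval] = [
        l.interval for l in loci if l.dosage_matches(dosage)
    ] + [g.interval for g in genes]
    if not regions:
        return None
    roi = regions[int(rng.integers(0, len(regions)))]
    bin_idx = int(rng.choice(4, p=np.asarray(size_mix)))
    lo, hi = _BIN_BOUNDS_KB[bin_idx]
    size_bp = int(round(math.exp(rng.uniform(math.log(lo * 1000), math.log(hi * 1000)))))
    length = HG19_LENGTHS[roi.chrom]
    anchor = int(rng.integers(roi.start, roi.end))
    start = max(0, min(anchor - size_bp // 2, length - size_bp))
    return GenomicInterval(roi.chrom, start, start + size_bp)


def _build_common_pool(rng: np.random.Generator, config: SimConfig) -> list[GenomicInterval]:
    pool = []
    for _ in range(config.common_pool_size):
        pool.append(_draw_interval(rng, (0.7, 0.2, 0.08, 0.02)))
    return pool


def simulate_cohort(
    config: SimConfig,
    loci: Optional[Sequence[RoiLocus]] = None,
    genes: Optional[Sequence[Gene]] = None,
) -> SimOutput:
    """Draw a full synthetic cohort; byte-reproducible from ``config.seed``.

    ROI fixtures default to the packaged worked-example loci and genes.
    Common-pool events alternate dosage and are shared verbatim with the
    simulated frequency reference, so they exceed the 1% rarity threshold
    and are removed by the frequency filter.
    """
    from . import datasets

    if loci is None:
        loci = datasets.asd_loci()
    if genes is None:
        genes = datasets.roi_genes()
    rng = np.random.default_rng(config.seed)
    rates = config.group_rates()

    pool = _build_common_pool(rng, config)
    pool_dosage = [LOSS if i % 2 == 0 else GAIN for i in range(len(pool))]

    samples: list[Sample] = []
    groups: list[str] = (
        ["control"] * config.n_control
        + ["mild"] * config.n_case_mild
        + ["severe"] * config.n_case_severe
    )
    for i, grp in enumerate(groups):
        sid = f"S{i + 1:05d}"
        if grp == "control":
            samples.append(Sample(sid, CONTROL, sex="female" if rng.random() < 0.43 else "male"))
        else:
            # CARS back-filled from the matching range so the severity label
            # round-trips through severity_from_cars
            if grp == "mild":
                cars = round(float(rng.uniform(30.0, 37.0)), 1)
            else:
                cars = round(float(rng.uniform(37.1, 60.0)), 1)
            samples.append(
                Sample(sid, CASE, severity=grp if grp != "mild" else MILD,
                       cars_score=cars, sex="female" if rng.random() < 0.16 else "male")
            )

    events: list[CnvEvent] = []
    for sample, grp in zip(samples, groups):
        for dosage in (LOSS, GAIN):
            n_events = _draw_count(rng, rates[grp][dosage], config.dispersion)
            for _ in range(n_events):
                interval = None
                if config.roi_hit_prob > 0 and rng.random() < config.roi_hit_prob:
                    interval = _draw_roi_interval(
                        rng, config.size_mix[dosage], dosage, loci, genes
                    )
                if interval is None:
                    interval = _draw_interval(rng, config.size_mix[dosage])
                events.append(
                    CnvEvent(sample.sample_id, interval, dosage, source_tag="rare_sim")
                )
        # common events: each pool CNV carried independently at pool frequency
        for interval, dosage in zip(pool, pool_dosage):
            if rng.random() < config.common_pool_freq:
                events.append(
                    CnvEvent(sample.sample_id, interval, dosage, source_tag="common_sim")
                )

    reference = simulate_reference(config, pool, pool_dosage, rng=rng)
    truth = {
        "rates": rates,
        "rr_case_loss": config.rr_case_loss,
        "rr_case_gain": config.rr_case_gain,
        "rr_severe_gain": config.rr_severe_gain,
        "n": {
            "control": config.n_control,
            "mild": config.n_case_mild,
            "severe": config.n_case_severe,
        },
        "common_pool_freq": config.common_pool_freq,
        "seed": config.seed,
    }
    return SimOutput(samples=samples, events=events, reference=reference,
                     loci=list(loci), genes=list(genes), truth=truth)


def simulate_reference(
    config: SimConfig,
    pool: Optional[Sequence[GenomicInterval]] = None,
    pool_dosage: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> FrequencyReference:
    """A carrier-encoded reference: the common pool at its configured
    frequency (Binomial(ref_n, freq) carriers per pool event) plus private
    noise events at frequency ~1/ref_n."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if pool is None:
        pool = _build_common_pool(rng, config)
        pool_dosage = [LOSS if i % 2 == 0 else GAIN for i in range(len(pool))]
    assert pool_dosage is not None
    records: list[ReferenceRecord] = []
    for interval, dosage in zip(pool, pool_dosage):
        n_carriers = int(rng.binomial(config.ref_n, config.common_pool_freq))
        carriers = rng.choice(config.ref_n, size=n_carriers, replace=False)
        for c in carriers:
            records.append(ReferenceRecord(interval, dosage, carrier_id=f"R{c + 1:05d}"))
    for _ in range(config.n_private_ref):
        dosage = LOSS if rng.random() < 0.5 else GAIN
        interval = _draw_interval(rng, (0.7, 0.2, 0.08, 0.02))
        carrier = int(rng.integers(0, config.ref_n))
        records.append(ReferenceRecord(interval, dosage, carrier_id=f"R{carrier + 1:05d}"))
    return FrequencyReference(name="sim_controls", ref_n=config.ref_n, events=records)


def recover_parameters(sim: SimOutput, burden_rows: Sequence) -> dict:
    """Compare rate ratios estimated by the pipeline against the truth record.

    Reports, per (contrast, dosage, all-sizes, any) stratum, the estimated
    ratio, the true multiplier, and the relative error (None when either
    is undefined).
    """
    true_of = {
        ("case_vs_control", LOSS): sim.truth["rr_case_loss"],
        ("case_vs_control", GAIN): sim.truth["rr_case_gain"],
        ("severe_vs_mild", GAIN): sim.truth["rr_severe_gain"],
        ("severe_vs_mild", LOSS): 1.0,
    }
    report: dict = {}
    for row in burden_rows:
        if row.size_bin != "all" or row.category != "any":
            continue
        key = (row.contrast, row.dosage)
        truth = true_of.get(key)
        est = row.rate_ratio
        rel = None
        if truth and est not in (None, math.inf) and truth > 0:
            rel = est / truth - 1.0
        report[f"{row.contrast}:{row.dosage}"] = {
            "estimated": est,
            "truth": truth,
            "relative_error": rel,
        }
    return report


# ---------------------------------------------------------------------------
# Deterministic count-matched cohort


def cohort_from_margins(
    margins: Optional[dict] = None,
) -> tuple[list[Sample], list[CnvEvent], list[RoiLocus], list[Gene]]:
    """Reconstruct a cohort exactly matching stratified event counts.

    ``margins`` follows the structure of
    :data:`cnvburden.datasets.BURDEN_MARGINS` (the default): group sizes,
    per-(dosage, size-bin) event counts and per-(dosage, ROI-category)
    all-size counts for control / mild-case / severe-case groups.
    ROI-category events are carved out of the 100k-400k bin and placed on
    dedicated synthetic ROI intervals (a deletion locus, a duplication
    locus, a high-risk gene and a LoF-intolerant gene on otherwise unused
    chromosomes), so category membership is exact and categories are
    mutually disjoint. Remaining events are tiled deterministically over
    free autosomes at bin-representative sizes. Events are assigned
    round-robin to the samples of their group.
    """
    from . import datasets

    if margins is None:
        margins = datasets.BURDEN_MARGINS

    locus_del = RoiLocus("synthetic_del_locus", GenomicInterval("chr11", 10_000_000, 22_000_000), "del")
    locus_dup = RoiLocus("synthetic_dup_locus", GenomicInterval("chr11", 40_000_000, 52_000_000), "dup")
    hr_gene = Gene("SYN_HR1", GenomicInterval("chr12", 10_000_000, 11_000_000), high_risk=True)
    lofi_gene = Gene("SYN_LOFI1", GenomicInterval("chr13", 30_000_000, 31_000_000), lof_intolerant=True)

    n = margins["n"]
    samples: list[Sample] = []
    group_samples: dict[str, list[str]] = {}
    for grp, prefix, kwargs in (
        ("control", "CTL", {"group": CONTROL}),
        ("mild", "MLD", {"group": CASE, "severity": MILD}),
        ("severe", "SVR", {"group": CASE, "severity": SEVERE}),
    ):
        ids = [f"{prefix}{i + 1:04d}" for i in range(n[grp])]
        group_samples[grp] = ids
        samples.extend(Sample(sid, **kwargs) for sid in ids)

    # representative event size (kb) per bin; category events use 200 kb
    rep_size_kb = {"100k-400k": 200, "400k-1M": 600, "1M-3M": 1800, ">3M": 5000}
    free_chroms = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr6", "chr9", "chr10"]
    cursor = {c: 1_000_000 for c in free_chroms}
    chrom_cycle = 0

    def generic_interval(size_kb: int) -> GenomicInterval:
        nonlocal chrom_cycle
        size_bp = size_kb * 1000
        for _ in range(len(free_chroms)):
            chrom = free_chroms[chrom_cycle % len(free_chroms)]
            chrom_cycle += 1
            start = cursor[chrom]
            if start + size_bp + 1000 < HG19_LENGTHS[chrom]:
                cursor[chrom] = start + size_bp + 1000
                return GenomicInterval(chrom, start, start + size_bp)
        raise ConfigError("ran out of genome while tiling the count-matched cohort")

    # category events sit fully inside their ROI so the >=80% locus rule and
    # the gene hit rules are met regardless of exact placement
    roi_cursor = {"del": locus_del.interval.start, "dup": locus_dup.interval.start,
                  "hr": hr_gene.interval.start + 1000, "lofi": lofi_gene.interval.start + 1000}
    roi_span_end = {"del": locus_del.interval.end, "dup": locus_dup.interval.end,
                    "hr": hr_gene.interval.end, "lofi": lofi_gene.interval.end}

    def roi_interval(kind: str, size_kb: int = 200) -> GenomicInterval:
        size_bp = size_kb * 1000
        start = roi_cursor[kind]
        if start + size_bp > roi_span_end[kind]:
            start = roi_span_end[kind] - size_bp  # overlap is harmless
            roi_cursor[kind] = start
        roi_cursor[kind] = min(start + 10_000, roi_span_end[kind] - size_bp)
        return GenomicInterval(locus_del.interval.chrom if kind in ("del", "dup")
                               else hr_gene.interval.chrom if kind == "hr"
                               else lofi_gene.interval.chrom,
                               start, start + size_bp)

    events: list[CnvEvent] = []
    assign_idx = {grp: 0 for grp in group_samples}

    def emit(grp: str, dosage: str, interval: GenomicInterval, tag: str) -> None:
        ids = group_samples[grp]
        sid = ids[assign_idx[grp] % len(ids)]
        assign_idx[grp] += 1
        events.append(CnvEvent(sid, interval, dosage, source_tag=tag))

    # category events first, carved from the 100k-400k bin counts
    carved = {key: {g: 0 for g in n} for key in margins["bins"]}
    kind_of = {"asd_loci": {"loss": "del", "gain": "dup"},
               "hr_genes": {"loss": "hr", "gain": "hr"},
               "lofi_genes": {"loss": "lofi", "gain": "lofi"}}
    for (dosage, category), counts in margins["categories"].items():
        for grp, count in counts.items():
            for _ in range(count):
                kind = kind_of[category][dosage]
                emit(grp, dosage, roi_interval(kind), f"margin_{category}")
                carved[(dosage, "100k-400k")][grp] += 1

    for (dosage, size_bin), counts in margins["bins"].items():
        for grp, count in counts.items():
            remaining = count - carved[(dosage, size_bin)][grp]
            if remaining < 0:
                raise ConfigError(
                    f"margins inconsistent: {dosage}/{size_bin}/{grp} has more "
                    "category events than the bin holds"
                )
            for _ in range(remaining):
                emit(grp, dosage, generic_interval(rep_size_kb[size_bin]), "margin_any")

    return samples, events, [locus_del, locus_dup], [hr_gene, lofi_gene]
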