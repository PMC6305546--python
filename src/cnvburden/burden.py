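"""Stratified burden table with one-sided permutation p-values.

Burden is summarized per stratum (dosage type x size bin x ROI category)
for two contrasts: cases vs controls, and severely vs mildly affected
cases. Three per-sample burden measures are supported as permutation
statistics: the event count (rate), the total event size, and the
carrier indicator (proportion with at least one event). Significance is
assessed by label permutation: group labels are reshuffled preserving
group sizes, each sample's events travelling with it, and the one-sided
add-one estimator p = (1 + #{T_b >= T_obs}) / (B + 1) guarantees a valid
p-value in [1/(B+1), 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .core import CASE, CnvEvent, ConfigError, DOSAGES, MILD, SEVERE, Sample
from .roi import RoiAnnotation

SIZE_BIN_ALL = "all"
SIZE_BINS: tuple[tuple[str, float, float], ...] = (
    ("100k-400k", 100, 400),
    ("400k-1M", 400, 1000),
    ("1M-3M", 1000, 3000),
    (">3M", 3000, math.inf),
)
SIZE_BIN_LABELS = tuple(label for label, _, _ in SIZE_BINS)

CATEGORY_ANY = "any"
CATEGORY_LOCI = "asd_loci"
CATEGORY_HR = "hr_genes"
CATEGORY_LOFI = "lofi_genes"
CATEGORIES = (CATEGORY_ANY, CATEGORY_LOCI, CATEGORY_HR, CATEGORY_LOFI)

CONTRAST_CASE_CONTROL = "case_vs_control"
CONTRAST_SEVERE_MILD = "severe_vs_mild"
CONTRASTS = (CONTRAST_CASE_CONTROL, CONTRAST_SEVERE_MILD)

STATISTICS = ("rate_diff", "total_size_diff", "carrier_prop_diff")


def assign_size_bin(event: CnvEvent) -> str:
    """Bin an event by size: half-open, lower-inclusive bins partitioning
    [100 kb, inf). Events below 100 kb should have been filtered out."""
    s = event.size_kb
    if s < 100:
        raise ConfigError(f"event of {s} kb reached binning (filter below 100 kb first)")
    for label, lo, hi in SIZE_BINS:
        if lo <= s < hi:
            return label
    raise AssertionError("unreachable: bins partition [100, inf)")


def event_rate(k: int, n: int) -> float:
    """Events per individual."""
    if n <= 0:
        raise ConfigError("event_rate requires a positive group size")
    return k / n


def rate_ratio(k1: int, n1: int, k2: int, n2: int) -> Optional[float]:
    """Ratio of per-individual rates; ``inf`` when only the numerator group
    has events, ``None`` (printed NA) when neither does."""
    r1, r2 = event_rate(k1, n1), event_rate(k2, n2)
    if r2 == 0.0:
        return None if r1 == 0.0 else math.inf
    return r1 / r2


def carrier_proportion(events: Sequence[CnvEvent], samples: Sequence[Sample]) -> float:
    """Proportion of individuals harboring at least one event."""
    ids = {s.sample_id for s in samples}
    carriers = set()
    for ev in events:
        if ev.sample_id not in ids:
            raise ConfigError(f"event references unknown sample {ev.sample_id!r}")
        carriers.add(ev.sample_id)
    return len(carriers) / len(ids) if ids else 0.0


def total_size_per_individual(
    events: Sequence[CnvEvent], samples: Sequence[Sample]
) -> dict[str, int]:
    """Per-sample total event size in kb (0 for non-carriers)."""
    totals = {s.sample_id: 0 for s in samples}
    for ev in events:
        if ev.sample_id not in totals:
            raise ConfigError(f"event references unknown sample {ev.sample_id!r}")
        totals[ev.sample_id] += ev.size_kb
    return totals


@dataclass(frozen=True)
class PermutationPlan:
    """Settings of the label-permutation test (one-sided, group-1-enriched).

    ``n_permutations=0`` disables p-value computation (rows carry NA);
    the same seed and inputs always give identical p-values, and each
    burden row draws from a substream derived from (seed, row identity)
    so row order never changes results.
    """

    n_permutations: int = 100_000
    seed: int = 0
    statistic: str = "rate_diff"

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ConfigError(f"statistic must be one of {STATISTICS}")
        if self.n_permutations < 0:
            raise ConfigError("n_permutations must be >= 0")


def _per_sample_values(
    events: Sequence[CnvEvent], sample_ids: Sequence[str], statistic: str
) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(sample_ids)}
    values = np.zeros(len(sample_ids))
    for ev in events:
        if ev.sample_id not in pos:
            raise ConfigError(f"event references unknown sample {ev.sample_id!r}")
        if statistic == "rate_diff":
            values[pos[ev.sample_id]] += 1.0
        elif statistic == "total_size_diff":
            values[pos[ev.sample_id]] += ev.size_kb
        else:  # carrier_prop_diff
            values[pos[ev.sample_id]] = 1.0
    return values


def permutation_pvalue(
    values: np.ndarray,
    n_group1: int,
    n_permutations: int,
    rng: np.random.Generator,
    chunk: int = 2_000,
) -> float:
    """One-sided add-one permutation p for T = mean(group1) - mean(group2).

    ``values`` holds the per-sample statistic with the first ``n_group1``
    entries belonging to group 1. Because group sizes are fixed, T is a
    strictly increasing function of the group-1 sum, so permuted T's are
    compared via group-1 sums (exact for integer-valued statistics; ties
    count toward the null).
    """
    n = len(values)
    if not 0 < n_group1 < n:
        raise ConfigError("both groups must be non-empty")
    observed = float(np.sum(values[:n_group1]))
    hits = 0
    remaining = n_permutations
    tol = 1e-9
    while remaining > 0:
        b = min(chunk, remaining)
        mat = np.tile(values, (b, 1))
        mat = rng.permuted(mat, axis=1)
        sums = mat[:, :n_group1].sum(axis=1)
        hits += int(np.sum(sums >= observed - tol))
        remaining -= b
    return (1 + hits) / (n_permutations + 1)


def permutation_test(
    events: Sequence[CnvEvent],
    samples: Sequence[Sample],
    group1: Callable[[Sample], bool],
    plan: PermutationPlan,
    selector: Optional[Callable[[CnvEvent], bool]] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Permutation p-value for enrichment of a stratum in group 1.

    ``group1`` splits ``samples`` into the enrichment group and the rest;
    ``selector`` restricts the events entering the statistic. Each sample's
    full event list travels with it under label shuffling.
    """
    g1 = [s for s in samples if group1(s)]
    g2 = [s for s in samples if not group1(s)]
    if not g1 or not g2:
        raise ConfigError("both groups must be non-empty")
    chosen = [ev for ev in events if selector is None or selector(ev)]
    ordered_ids = [s.sample_id for s in g1] + [s.sample_id for s in g2]
    values = _per_sample_values(chosen, ordered_ids, plan.statistic)
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    return permutation_pvalue(values, len(g1), plan.n_permutations, rng)


@dataclass(frozen=True)
class BurdenRow:
    """One stratum of the burden table."""

    contrast: str
    dosage: str
    size_bin: str
    category: str
    n1: int
    n2: int
    k1: int
    k2: int
    r1: float
    r2: float
    rate_ratio: Optional[float]
    p_value: Optional[float]


def _category_member(ann: RoiAnnotation, category: str) -> bool:
    if category == CATEGORY_ANY:
        return True
    if category == CATEGORY_LOCI:
        return ann.has_locus_hit
    if category == CATEGORY_HR:
        return ann.has_hr_hit
    if category == CATEGORY_LOFI:
        return ann.has_lofi_hit
    raise ConfigError(f"unknown category {category!r}")


def build_burden_table(
    events: Sequence[CnvEvent],
    annotations: Optional[Sequence[RoiAnnotation]],
    samples: Sequence[Sample],
    plan: PermutationPlan,
    contrasts: Sequence[str] = CONTRASTS,
    categories: Sequence[str] = CATEGORIES,
) -> list[BurdenRow]:
    """Assemble the stratified burden table.

    Rows: per contrast and dosage, one row per size bin plus an ``all``
    row (category ``any``), and one all-sizes row per requested ROI
    category. Pass only the categories whose ROI inputs exist; an omitted
    category produces no rows. The severity contrast is restricted to case
    samples and requires both severity labels to be present. Within each
    dosage the four size-bin counts sum to the ``all`` count by
    construction.
    """
    if annotations is None:
        annotations = [RoiAnnotation(event=ev) for ev in events]
        categories = [c for c in categories if c == CATEGORY_ANY]
    ann_of = {id(a.event): a for a in annotations}
    if len(ann_of) != len(events) or any(id(ev) not in ann_of for ev in events):
        raise ConfigError("annotations must cover exactly the supplied events")

    sample_by_id = {s.sample_id: s for s in samples}
    for ev in events:
        if ev.sample_id not in sample_by_id:
            raise ConfigError(f"event references unknown sample {ev.sample_id!r}")

    rows: list[BurdenRow] = []
    for ci, contrast in enumerate(contrasts):
        if contrast == CONTRAST_CASE_CONTROL:
            pool = list(samples)
            in_g1 = lambda s: s.group == CASE  # noqa: E731
        elif contrast == CONTRAST_SEVERE_MILD:
            pool = [s for s in samples if s.group == CASE and s.severity in (MILD, SEVERE)]
            if not any(s.severity == SEVERE for s in pool) or not any(
                s.severity == MILD for s in pool
            ):
                raise ConfigError(
                    "severity contrast requires case samples labelled mild and severe"
                )
            in_g1 = lambda s: s.severity == SEVERE  # noqa: E731
        else:
            raise ConfigError(f"unknown contrast {contrast!r}")

        pool_ids = {s.sample_id for s in pool}
        g1 = [s for s in pool if in_g1(s)]
        g2 = [s for s in pool if not in_g1(s)]
        pool_events = [ev for ev in events if ev.sample_id in pool_ids]

        strata: list[tuple[str, str, str]] = []
        for dosage in DOSAGES:
            if CATEGORY_ANY in categories:
                strata.append((dosage, SIZE_BIN_ALL, CATEGORY_ANY))
                strata.extend((dosage, b, CATEGORY_ANY) for b in SIZE_BIN_LABELS)
            for category in categories:
                if category != CATEGORY_ANY:
                    strata.append((dosage, SIZE_BIN_ALL, category))

        for si, (dosage, size_bin, category) in enumerate(strata):
            def selected(ev: CnvEvent) -> bool:
                if ev.dosage != dosage:
                    return False
                if size_bin != SIZE_BIN_ALL and assign_size_bin(ev) != size_bin:
                    return False
                return _category_member(ann_of[id(ev)], category)

            chosen = [ev for ev in pool_events if selected(ev)]
            k1 = sum(1 for ev in chosen if in_g1(sample_by_id[ev.sample_id]))
            k2 = len(chosen) - k1
            p: Optional[float] = None
            if plan.n_permutations > 0:
                rng = np.random.default_rng([plan.seed, ci, si])
                p = permutation_test(
                    pool_events, pool, in_g1, plan, selector=selected, rng=rng
                )
            rows.append(
                BurdenRow(
                    contrast=contrast,
                    dosage=dosage,
                    size_bin=size_bin,
                    category=category,
                    n1=len(g1),
                    n2=len(g2),
                    k1=k1,
                    k2=k2,
                    r1=event_rate(k1, len(g1)),
                    r2=event_rate(k2, len(g2)),
                    rate_ratio=rate_ratio(k1, len(g1), k2, len(g2)),
                    p_value=p,
                )
            )
    return rows
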