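"""Core domain types and interval arithmetic.

Coordinate convention: intervals are stored as ``(start, end)`` with
``length = end - start`` (half-open). Printed 1-based inclusive region
strings such as ``chr8:105008757-105127783`` are stored with their numbers
unchanged; the +/- 1 bp ambiguity between the two conventions is below kb
resolution, and BED inputs (0-based half-open) map to the same internal
representation without shifting.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

from .genome import is_autosome, normalize_chrom


class CnvBurdenError(Exception):
    """Base class for all package errors."""


class ParseError(CnvBurdenError, ValueError):
    """Malformed input file or region string."""


class ConfigError(CnvBurdenError, ValueError):
    """Invalid threshold or configuration value."""


LOSS = "loss"
GAIN = "gain"
DOSAGES = (LOSS, GAIN)

# expected dosage of a region-of-interest locus
DEL = "del"
DUP = "dup"
BOTH = "both"
EXPECTED_DOSAGES = (DEL, DUP, BOTH)

MILD = "mild"
SEVERE = "severe"
UNKNOWN = "unknown"

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span on a canonical human chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ParseError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ParseError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


_REGION_RE = re.compile(r"^\s*(?P<chrom>chr)?(?P<name>[0-9XYxy]{1,2})\s*:\s*(?P<start>[\d,]+)\s*-\s*(?P<end>[\d,]+)\s*$")


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a ``chrN:start-end`` region string into a :class:`GenomicInterval`.

    Thousands separators in the coordinates are stripped (tables often print
    ``2,882``-style numbers). Raises :class:`ParseError` naming the offending
    token for malformed strings, unknown chromosomes, and empty intervals.
    """
    m = _REGION_RE.match(text)
    if not m:
        raise ParseError(f"malformed region string: {text!r}")
    chrom = ("chr" if m.group("chrom") is None else m.group("chrom")) + m.group("name")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    try:
        return GenomicInterval(chrom, start, end)
    except ValueError as exc:
        raise ParseError(f"invalid region {text!r}: {exc}") from exc


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def fraction_of_query(query: GenomicInterval, subject: GenomicInterval) -> float:
    """Fraction of ``query``'s length covered by ``subject``.

    Deliberately asymmetric: the query is the CNV under evaluation. Raises
    :class:`ConfigError` for a zero-length query (cannot arise from a
    validated :class:`GenomicInterval`, but guards raw callers).
    """
    if query.length <= 0:
        raise ConfigError("fraction_of_query requires a positive-length query")
    return overlap_length(query, subject) / query.length


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CnvEvent:
    """One CNV call: an interval plus dosage type, owned by a sample.

    ``probe_count`` may be absent (simulated data has no probes); ``extra``
    preserves unrecognized input columns opaquely through IO round trips.
    """

    sample_id: str
    interval: GenomicInterval
    dosage: str
    probe_count: Optional[int] = None
    source_tag: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosage not in DOSAGES:
            raise ParseError(
                f"dosage must be one of {DOSAGES}, got {self.dosage!r} "
                f"(copy-neutral or unknown states are rejected)"
            )
        if self.probe_count is not None and self.probe_count <= 0:
            raise ParseError(f"probe_count must be positive, got {self.probe_count}")

    @property
    def size_kb(self) -> int:
        """Event size in kb, rounded to nearest (ties away from zero)."""
        return round_half_away(self.interval.length / 1000)

    @property
    def is_autosomal(self) -> bool:
        return is_autosome(self.interval.chrom)


def size_kb(event: CnvEvent) -> int:
    return event.size_kb


@dataclass(frozen=True)
class RoiLocus:
    """A recurrent risk locus with the dosage type it is associated with."""

    name: str
    interval: GenomicInterval
    expected_dosage: str = BOTH

    def __post_init__(self) -> None:
        if self.expected_dosage not in EXPECTED_DOSAGES:
            raise ParseError(
                f"expected_dosage must be one of {EXPECTED_DOSAGES}, "
                f"got {self.expected_dosage!r}"
            )

    def dosage_matches(self, dosage: str) -> bool:
        """Does a CNV dosage correspond to this locus (loss<->del, gain<->dup)?"""
        if self.expected_dosage == BOTH:
            return True
        return (self.expected_dosage == DEL) == (dosage == LOSS)


@dataclass(frozen=True)
class Gene:
    """A genic span flagged as high-risk and/or loss-of-function intolerant.

    ``high_risk`` marks curated strong-evidence risk genes; ``lof_intolerant``
    marks genes with pLI > 0.99 in population exome data.
    """

    symbol: str
    interval: GenomicInterval
    high_risk: bool = False
    lof_intolerant: bool = False


CARS_MIN = 30.0
CARS_MAX = 60.0
CARS_MILD_MAX = 37.0


def severity_from_cars(score: float, mild_max: float = CARS_MILD_MAX) -> str:
    """Map a CARS score to a severity label.

    Scores in [30, ``mild_max``] are ``mild`` (mild/moderate), scores in
    (``mild_max``, 60] are ``severe``. The shared boundary (37 by default)
    is assigned to mild: a severity claim requires a score strictly above
    the boundary. Scores outside [30, 60] are rejected (below the scale's
    ASD range or above its maximum).
    """
    if not CARS_MIN <= score <= CARS_MAX:
        raise ConfigError(
            f"CARS score {score} outside the ASD range [{CARS_MIN}, {CARS_MAX}]"
        )
    return MILD if score <= mild_max else SEVERE


@dataclass
class Sample:
    """One individual: case/control label, optional severity and CARS score."""

    sample_id: str
    group: str
    severity: str = UNKNOWN
    cars_score: Optional[float] = None
    sex: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise ParseError(f"group must be case or control, got {self.group!r}")
        if self.severity not in (MILD, SEVERE, UNKNOWN):
            raise ParseError(f"invalid severity {self.severity!r}")
        if self.sex not in ("male", "female", UNKNOWN):
            raise ParseError(f"invalid sex {self.sex!r}")
        if self.group == CONTROL and self.severity != UNKNOWN:
            raise ParseError(
                f"sample {self.sample_id}: severity labels apply to cases only"
            )
        if self.cars_score is not None and self.group == CASE:
            derived = severity_from_cars(self.cars_score)
            if self.severity == UNKNOWN:
                self.severity = derived
            elif self.severity != derived:
                raise ParseError(
                    f"sample {self.sample_id}: severity {self.severity!r} "
                    f"inconsistent with CARS score {self.cars_score} ({derived})"
                )
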