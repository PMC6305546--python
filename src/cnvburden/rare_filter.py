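"""Reduce raw CNV calls to the rare analysis set.

The filter chain retains autosomal events of at least 100 kb supported by
more than 25 probes whose population frequency is below 1% in every
supplied reference, frequency being the share of reference individuals
carrying a same-dosage event that covers more than half of the query
event's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .core import (
    CnvEvent,
    ConfigError,
    DOSAGES,
    GenomicInterval,
    ParseError,
    fraction_of_query,
)
from .index import IntervalIndex


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference CNV: carrier encoding (``carrier_id``) or frequency
    encoding (``freq``); exactly one of the two is set."""

    interval: GenomicInterval
    dosage: str
    carrier_id: Optional[str] = None
    freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dosage not in DOSAGES:
            raise ParseError(f"reference dosage must be loss/gain, got {self.dosage!r}")
        if (self.carrier_id is None) == (self.freq is None):
            raise ParseError("reference record needs exactly one of carrier_id / freq")
        if self.freq is not None and not 0.0 <= self.freq <= 1.0:
            raise ParseError(f"reference freq outside [0,1]: {self.freq}")


@dataclass
class FrequencyReference:
    """A reference cohort of CNVs supporting the >50%-overlap frequency query."""

    name: str
    ref_n: int
    events: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_n <= 0:
            raise ConfigError(f"reference {self.name!r}: ref_n must be positive")
        carriers = {r.carrier_id for r in self.events if r.carrier_id is not None}
        if len(carriers) > self.ref_n:
            raise ParseError(
                f"reference {self.name!r}: {len(carriers)} distinct carriers "
                f"exceed ref_n={self.ref_n}"
            )
        self._index: Optional[IntervalIndex[list[ReferenceRecord]]] = None

    def _get_index(self) -> IntervalIndex[list[ReferenceRecord]]:
        # records sharing an interval (e.g. many carriers of one common CNV)
        # are grouped so the tree holds each distinct interval once
        if self._index is None:
            groups: dict[GenomicInterval, list[ReferenceRecord]] = {}
            for rec in self.events:
                groups.setdefault(rec.interval, []).append(rec)
            self._index = IntervalIndex(groups.items())
        return self._index

    def matching_records(
        self, event: CnvEvent, min_overlap: float = 0.5, reciprocal: bool = False
    ) -> list[ReferenceRecord]:
        """Reference records of the event's dosage covering more than
        ``min_overlap`` of the event's length (optionally also reciprocally)."""
        out = []
        for group in self._get_index().overlapping(event.interval):
            ref_interval = group[0].interval
            if fraction_of_query(event.interval, ref_interval) <= min_overlap:
                continue
            if reciprocal and fraction_of_query(ref_interval, event.interval) <= min_overlap:
                continue
            out.extend(rec for rec in group if rec.dosage == event.dosage)
        return out


def reference_frequency(
    event: CnvEvent,
    ref: FrequencyReference,
    min_overlap: float = 0.5,
    reciprocal: bool = False,
) -> float:
    """Frequency of an event in a reference cohort.

    Carrier encoding: distinct reference individuals with at least one
    matching record, divided by ``ref_n``. Frequency encoding: the maximum
    recorded frequency over matching records. Events matching nothing have
    frequency 0 (not missing).
    """
    matches = ref.matching_records(event, min_overlap=min_overlap, reciprocal=reciprocal)
    if not matches:
        return 0.0
    carriers = {r.carrier_id for r in matches if r.carrier_id is not None}
    freqs = [r.freq for r in matches if r.freq is not None]
    return max(len(carriers) / ref.ref_n, max(freqs, default=0.0))


@dataclass
class FilterReport:
    """Per-stage survivor counts plus a per-event disposition log.

    Counts are non-increasing along the chain; ``dispositions`` holds one
    ``(event, stage_removed_or_None, max_reference_frequency)`` record per
    input event, in input order.
    """

    n_input: int = 0
    n_after_size: int = 0
    n_after_probes: int = 0
    n_after_autosome: int = 0
    n_after_frequency: int = 0
    dispositions: list[tuple[CnvEvent, Optional[str], Optional[float]]] = field(
        default_factory=list
    )

    def counts(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_after_size": self.n_after_size,
            "n_after_probes": self.n_after_probes,
            "n_after_autosome": self.n_after_autosome,
            "n_after_frequency": self.n_after_frequency,
        }


def apply_call_thresholds(
    events: Sequence[CnvEvent], min_size_kb: int = 100, min_probes: int = 25
) -> list[CnvEvent]:
    """Keep events of at least ``min_size_kb`` supported by more than
    ``min_probes`` probes; events without a probe count pass the probe gate
    (simulated calls carry none). Order is preserved."""
    if min_size_kb < 0 or min_probes < 0:
        raise ConfigError("size/probe thresholds must be non-negative")
    return [
        ev
        for ev in events
        if ev.size_kb >= min_size_kb
        and (ev.probe_count is None or ev.probe_count > min_probes)
    ]


def autosomes_only(events: Sequence[CnvEvent]) -> list[CnvEvent]:
    """Drop sex-chromosome events (burden is assessed on autosomes only)."""
    return [ev for ev in events if ev.is_autosomal]


def filter_rare(
    events: Sequence[CnvEvent],
    refs: Sequence[FrequencyReference],
    max_freq: float = 0.01,
    min_overlap: float = 0.5,
    reciprocal: bool = False,
) -> tuple[list[CnvEvent], FilterReport]:
    """Keep events rare (frequency strictly below ``max_freq``) in EVERY
    supplied reference; the report records each event's maximal frequency."""
    if not refs:
        raise ConfigError("filter_rare requires at least one frequency reference")
    if max_freq < 0:
        raise ConfigError("max_freq must be non-negative")
    report = FilterReport(n_input=len(events))
    kept: list[CnvEvent] = []
    for ev in events:
        fmax = max(
            reference_frequency(ev, ref, min_overlap=min_overlap, reciprocal=reciprocal)
            for ref in refs
        )
        if fmax < max_freq:
            kept.append(ev)
            report.dispositions.append((ev, None, fmax))
        else:
            report.dispositions.append((ev, "frequency", fmax))
    report.n_after_size = report.n_after_probes = report.n_after_autosome = len(events)
    report.n_after_frequency = len(kept)
    return kept, report


def run_filter_chain(
    events: Sequence[CnvEvent],
    refs: Sequence[FrequencyReference],
    min_size_kb: int = 100,
    min_probes: int = 25,
    max_freq: float = 0.01,
    min_overlap: float = 0.5,
    reciprocal: bool = False,
) -> tuple[list[CnvEvent], FilterReport]:
    """Full chain: size -> probes -> autosomes -> frequency, with audit log.

    With no references supplied the frequency stage passes everything
    (every event has frequency 0 against an empty reference set).
    """
    if min_size_kb < 0 or min_probes < 0:
        raise ConfigError("size/probe thresholds must be non-negative")
    report = FilterReport(n_input=len(events))
    survivors: list[CnvEvent] = []
    stage_of: dict[int, Optional[str]] = {}
    for ev in events:
        if ev.size_kb < min_size_kb:
            stage_of[id(ev)] = "size"
        elif ev.probe_count is not None and ev.probe_count <= min_probes:
            stage_of[id(ev)] = "probes"
        elif not ev.is_autosomal:
            stage_of[id(ev)] = "autosome"
        else:
            stage_of[id(ev)] = None
            survivors.append(ev)
    report.n_after_size = sum(
        1 for ev in events if stage_of[id(ev)] != "size"
    )
    report.n_after_probes = sum(
        1 for ev in events if stage_of[id(ev)] not in ("size", "probes")
    )
    report.n_after_autosome = len(survivors)

    kept: list[CnvEvent] = []
    freq_of: dict[int, Optional[float]] = {id(ev): None for ev in events}
    for ev in survivors:
        fmax = max(
            (
                reference_frequency(ev, ref, min_overlap=min_overlap, reciprocal=reciprocal)
                for ref in refs
            ),
            default=0.0,
        )
        freq_of[id(ev)] = fmax
        if fmax < max_freq:
            kept.append(ev)
        else:
            stage_of[id(ev)] = "frequency"
    report.n_after_frequency = len(kept)
    report.dispositions = [(ev, stage_of[id(ev)], freq_of[id(ev)]) for ev in events]
    return kept, report


# ---------------------------------------------------------------------------
# Frequency reference IO


def read_frequency_reference(path: str | Path, name: Optional[str] = None) -> FrequencyReference:
    """Read a frequency reference TSV.

    Header columns are ``chrom start end dosage carrier_id`` (carrier
    encoding) or ``chrom start end dosage freq`` (frequency encoding); the
    reference cohort size comes from a ``#ref_n=<int>`` sidecar line.
    """
    path = Path(path)
    ref_n: Optional[int] = None
    ref_name = name or path.stem
    rows: list[tuple[int, list[str]]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("ref_n="):
                    ref_n = int(stripped.split("=", 1)[1])
                elif stripped.startswith("name="):
                    ref_name = stripped.split("=", 1)[1]
                continue
            rows.append((lineno, [f.strip() for f in line.split("\t")]))
    if ref_n is None:
        raise ParseError(f"{path}: missing '#ref_n=<int>' sidecar line")
    if not rows:
        return FrequencyReference(name=ref_name, ref_n=ref_n)
    lineno, header = rows[0]
    needed = {"chrom", "start", "end", "dosage"}
    if not needed.issubset(header) or not ({"carrier_id", "freq"} & set(header)):
        raise ParseError(
            f"{path}:{lineno}: reference header must contain chrom/start/end/dosage "
            "plus carrier_id or freq"
        )
    col = {c: i for i, c in enumerate(header)}
    records: list[ReferenceRecord] = []
    for lineno, row in rows[1:]:
        where = f"{path}:{lineno}"
        try:
            interval = GenomicInterval(row[col["chrom"]], int(row[col["start"]]), int(row[col["end"]]))
            if "carrier_id" in col:
                records.append(
                    ReferenceRecord(interval, row[col["dosage"]], carrier_id=row[col["carrier_id"]])
                )
            else:
                records.append(
                    ReferenceRecord(interval, row[col["dosage"]], freq=float(row[col["freq"]]))
                )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return FrequencyReference(name=ref_name, ref_n=ref_n, events=records)


def write_frequency_reference(path: str | Path, ref: FrequencyReference) -> None:
    carrier_encoded = any(r.carrier_id is not None for r in ref.events)
    with open(path, "w", newline="") as handle:
        handle.write(f"#ref_n={ref.ref_n}\n#name={ref.name}\n")
        value_col = "carrier_id" if carrier_encoded or not ref.events else "freq"
        handle.write("\t".join(["chrom", "start", "end", "dosage", value_col]) + "\n")
        for r in ref.events:
            value = r.carrier_id if value_col == "carrier_id" else f"{r.freq:.6g}"
            handle.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.dosage}\t{value}\n"
            )
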