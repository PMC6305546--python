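"""Readers and writers for every file the pipeline touches.

All tabular formats are plain TSV. Output files begin with commented
header lines recording the tool version and (when a pipeline run) the
configuration hash, so artifacts are self-describing. Parse errors name
the offending file, line and token.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .core import (
    BOTH,
    CnvEvent,
    Gene,
    GenomicInterval,
    ParseError,
    RoiLocus,
    Sample,
)

_EVENT_COLUMNS = ("sample_id", "chrom", "start", "end", "dosage", "probe_count")
_NA_TOKENS = {"", "na", "NA", "nan", "None", "."}


def _comment_lines(config_hash: Optional[str] = None) -> list[str]:
    lines = [f"# cnvburden v{__version__}"]
    if config_hash:
        lines.append(f"# config_hash={config_hash}")
    return lines


def _open_rows(path: Path) -> list[tuple[int, list[str]]]:
    """Read a TSV as (1-based line number, fields), skipping comments/blanks."""
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or not row[0].strip() and len(row) == 1 or row[0].startswith("#"):
                continue
            rows.append((lineno, [f.strip() for f in row]))
    return rows


def _opt_int(token: str, where: str) -> Optional[int]:
    if token in _NA_TOKENS:
        return None
    try:
        return int(token.replace(",", ""))
    except ValueError as exc:
        raise ParseError(f"{where}: not an integer: {token!r}") from exc


def _opt_float(token: str) -> Optional[float]:
    if token in _NA_TOKENS:
        return None
    return float(token)


# ---------------------------------------------------------------------------
# CNV event tables


def read_cnv_table(
    path: str | Path,
    dialect: str = "auto",
    samples: Optional[Sequence[Sample]] = None,
) -> list[CnvEvent]:
    """Read CNV calls from a headered TSV or a 5-column BED.

    TSV columns: ``sample_id chrom start end dosage [probe_count] [...]``;
    unknown columns are preserved on ``event.extra``. BED columns:
    ``chrom start end name score`` with ``name = sample_id:dosage`` and
    ``score`` the probe count (``.`` when absent). ``dialect`` is one of
    ``auto``/``tsv``/``bed``. When ``samples`` is given, events referencing
    an unknown sample raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    rows = _open_rows(path)
    if not rows:
        return []
    if dialect == "auto":
        dialect = "tsv" if "sample_id" in rows[0][1] else "bed"
    known = None if samples is None else {s.sample_id for s in samples}
    events: list[CnvEvent] = []

    if dialect == "tsv":
        lineno, header = rows[0]
        missing = [c for c in _EVENT_COLUMNS[:5] if c not in header]
        if missing:
            raise ParseError(f"{path}:{lineno}: missing mandatory column(s) {missing}")
        col = {name: i for i, name in enumerate(header)}
        extra_cols = [c for c in header if c not in _EVENT_COLUMNS and c != "source_tag"]
        for lineno, row in rows[1:]:
            where = f"{path}:{lineno}"
            if len(row) < len(header):
                row = row + [""] * (len(header) - len(row))
            try:
                interval = GenomicInterval(
                    row[col["chrom"]],
                    int(row[col["start"]].replace(",", "")),
                    int(row[col["end"]].replace(",", "")),
                )
                event = CnvEvent(
                    sample_id=row[col["sample_id"]],
                    interval=interval,
                    dosage=row[col["dosage"]],
                    probe_count=(
                        _opt_int(row[col["probe_count"]], where)
                        if "probe_count" in col
                        else None
                    ),
                    source_tag=row[col["source_tag"]] if "source_tag" in col else "",
                    extra={c: row[col[c]] for c in extra_cols if row[col[c]] != ""},
                )
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from exc
            if known is not None and event.sample_id not in known:
                raise ParseError(f"{where}: unknown sample {event.sample_id!r}")
            events.append(event)
        return events

    if dialect == "bed":
        for lineno, row in rows:
            where = f"{path}:{lineno}"
            if len(row) < 4:
                raise ParseError(f"{where}: BED needs >=4 columns, got {len(row)}")
            name = row[3]
            if ":" not in name:
                raise ParseError(f"{where}: BED name must be sample_id:dosage, got {name!r}")
            sample_id, dosage = name.rsplit(":", 1)
            score = row[4] if len(row) > 4 else "."
            try:
                event = CnvEvent(
                    sample_id=sample_id,
                    interval=GenomicInterval(row[0], int(row[1]), int(row[2])),
                    dosage=dosage,
                    probe_count=_opt_int(score, where),
                )
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from exc
            if known is not None and event.sample_id not in known:
                raise ParseError(f"{where}: unknown sample {event.sample_id!r}")
            events.append(event)
        return events

    raise ParseError(f"unknown CNV table dialect {dialect!r}")


def write_events(
    path: str | Path,
    events: Sequence[CnvEvent],
    annotations: Optional[Sequence] = None,
    clinical: Optional[Sequence] = None,
    config_hash: Optional[str] = None,
) -> None:
    """Write events (optionally with ROI annotations and clinical calls) as TSV.

    ``annotations``/``clinical`` must align 1:1 with ``events`` when given
    (as produced by :func:`cnvburden.roi.annotate_events` and
    :func:`cnvburden.roi.classify_clinical`).
    """
    extra_cols: list[str] = []
    for ev in events:
        for c in ev.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    header = list(_EVENT_COLUMNS) + ["source_tag"] + extra_cols
    if annotations is not None:
        header += ["asd_loci", "hr_genes", "lofi_genes"]
    if clinical is not None:
        header += ["tier", "basis"]

    with open(path, "w", newline="") as handle:
        for line in _comment_lines(config_hash):
            handle.write(line + "\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for i, ev in enumerate(events):
            row = [
                ev.sample_id,
                ev.interval.chrom,
                ev.interval.start,
                ev.interval.end,
                ev.dosage,
                "" if ev.probe_count is None else ev.probe_count,
                ev.source_tag,
            ] + [ev.extra.get(c, "") for c in extra_cols]
            if annotations is not None:
                ann = annotations[i]
                row.append(";".join(f"{n}:{f:.4f}" for n, f in ann.asd_locus_hits))
                row.append(";".join(f"{s}:{m}" for s, m in ann.hr_gene_hits))
                row.append(";".join(f"{s}:{m}" for s, m in ann.lofi_gene_hits))
            if clinical is not None:
                call = clinical[i]
                row += [call.tier, call.basis]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Sample manifest


def read_manifest(path: str | Path) -> list[Sample]:
    """Read the sample manifest TSV.

    Columns: ``sample_id group severity cars_score sex`` (``severity`` may be
    ``NA``; ``cars_score`` optional). A duplicate ``sample_id`` raises
    :class:`ParseError` at its second occurrence.
    """
    path = Path(path)
    rows = _open_rows(path)
    if not rows:
        return []
    lineno, header = rows[0]
    for required in ("sample_id", "group"):
        if required not in header:
            raise ParseError(f"{path}:{lineno}: missing mandatory column {required!r}")
    col = {name: i for i, name in enumerate(header)}
    samples: list[Sample] = []
    seen: set[str] = set()
    for lineno, row in rows[1:]:
        where = f"{path}:{lineno}"
        if len(row) < len(header):
            row = row + [""] * (len(header) - len(row))
        sid = row[col["sample_id"]]
        if sid in seen:
            raise ParseError(f"{where}: duplicate sample_id {sid!r}")
        seen.add(sid)
        severity = row[col["severity"]] if "severity" in col else ""
        try:
            samples.append(
                Sample(
                    sample_id=sid,
                    group=row[col["group"]],
                    severity="unknown" if severity in _NA_TOKENS else severity,
                    cars_score=(
                        _opt_float(row[col["cars_score"]]) if "cars_score" in col else None
                    ),
                    sex=(
                        "unknown"
                        if "sex" not in col or row[col["sex"]] in _NA_TOKENS
                        else row[col["sex"]]
                    ),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return samples


def write_manifest(path: str | Path, samples: Sequence[Sample]) -> None:
    with open(path, "w", newline="") as handle:
        for line in _comment_lines():
            handle.write(line + "\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "group", "severity", "cars_score", "sex"])
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.group,
                    "NA" if s.severity == "unknown" else s.severity,
                    "" if s.cars_score is None else s.cars_score,
                    s.sex,
                ]
            )


# ---------------------------------------------------------------------------
# Region-of-interest files (BED-like, headerless)


def read_roi_bed(path: str | Path) -> list[RoiLocus]:
    """Read recurrent-locus intervals: ``chrom start end name expected_dosage``."""
    path = Path(path)
    loci: list[RoiLocus] = []
    for lineno, row in _open_rows(path):
        where = f"{path}:{lineno}"
        if len(row) < 4:
            raise ParseError(f"{where}: locus BED needs >=4 columns")
        try:
            loci.append(
                RoiLocus(
                    name=row[3],
                    interval=GenomicInterval(row[0], int(row[1]), int(row[2])),
                    expected_dosage=row[4] if len(row) > 4 else BOTH,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return loci


def write_roi_bed(path: str | Path, loci: Sequence[RoiLocus]) -> None:
    with open(path, "w", newline="") as handle:
        for line in _comment_lines():
            handle.write(line + "\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for locus in loci:
            writer.writerow(
                [locus.interval.chrom, locus.interval.start, locus.interval.end,
                 locus.name, locus.expected_dosage]
            )


def read_gene_bed(path: str | Path) -> list[Gene]:
    """Read gene spans: ``chrom start end symbol high_risk lof_intolerant``.

    Each loaded gene must carry at least one of the two flags.
    """
    path = Path(path)
    genes: list[Gene] = []
    for lineno, row in _open_rows(path):
        where = f"{path}:{lineno}"
        if len(row) < 6:
            raise ParseError(f"{where}: gene BED needs 6 columns")
        try:
            gene = Gene(
                symbol=row[3],
                interval=GenomicInterval(row[0], int(row[1]), int(row[2])),
                high_risk=bool(int(row[4])),
                lof_intolerant=bool(int(row[5])),
            )
        except ValueError as exc:
            raise ParseError(f"{where}: {exc}") from exc
        if not (gene.high_risk or gene.lof_intolerant):
            raise ParseError(f"{where}: gene {gene.symbol} carries neither ROI flag")
        genes.append(gene)
    return genes


def write_gene_bed(path: str | Path, genes: Sequence[Gene]) -> None:
    with open(path, "w", newline="") as handle:
        for line in _comment_lines():
            handle.write(line + "\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for g in genes:
            writer.writerow(
                [g.interval.chrom, g.interval.start, g.interval.end, g.symbol,
                 int(g.high_risk), int(g.lof_intolerant)]
            )


# ---------------------------------------------------------------------------
# Burden table


def write_burden_table(path: str | Path, rows: Sequence, config_hash: Optional[str] = None) -> None:
    """Write burden rows as TSV (``inf`` for infinite ratios, ``NA`` for 0/0).

    P-values are nominal (no multiple-testing correction), which the header
    comment records.
    """
    with open(path, "w", newline="") as handle:
        for line in _comment_lines(config_hash):
            handle.write(line + "\n")
        handle.write("# p_values: one-sided permutation, nominal (uncorrected)\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["contrast", "dosage", "size_bin", "category", "n1", "n2", "k1", "k2",
             "r1", "r2", "rate_ratio", "p_value"]
        )
        for r in rows:
            if r.rate_ratio is None:
                ratio = "NA"
            elif r.rate_ratio == float("inf"):
                ratio = "inf"
            else:
                ratio = f"{r.rate_ratio:.6g}"
            writer.writerow(
                [r.contrast, r.dosage, r.size_bin, r.category, r.n1, r.n2, r.k1, r.k2,
                 f"{r.r1:.6g}", f"{r.r2:.6g}", ratio,
                 "NA" if r.p_value is None else f"{r.p_value:.6g}"]
            )
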