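"""End-to-end orchestration: filter -> annotate -> burden.

Stages communicate only through files so each is independently testable;
a run is fully determined by its configuration and seed, and every
artifact carries the tool version and the configuration hash in its
header. One structured log line per stage records input/output counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .burden import (
    CATEGORY_ANY,
    CATEGORY_HR,
    CATEGORY_LOCI,
    CATEGORY_LOFI,
    CONTRASTS,
    PermutationPlan,
    build_burden_table,
)
from .core import CASE, CnvBurdenError
from .io import (
    read_cnv_table,
    read_gene_bed,
    read_manifest,
    read_roi_bed,
    write_burden_table,
    write_events,
)
from .rare_filter import read_frequency_reference, run_filter_chain
from .roi import annotate_events, classify_all, diagnostic_yield

logger = logging.getLogger("cnvburden")


@dataclass
class RunConfig:
    """All inputs, outputs and thresholds of one pipeline run.

    Threshold defaults are the analysis defaults throughout the package:
    100 kb minimum size, >25 probes, 1% frequency at >50% overlap, 80%
    locus overlap, 100,000 one-sided permutations.
    """

    calls: str
    manifest: str
    out_dir: str
    loci: Optional[str] = None
    genes: Optional[str] = None
    listed: Optional[str] = None
    refs: list[str] = field(default_factory=list)
    min_size_kb: int = 100
    min_probes: int = 25
    max_freq: float = 0.01
    min_overlap: float = 0.5
    reciprocal: bool = False
    locus_fraction: float = 0.8
    fraction_of: str = "cnv"
    permutations: int = 100_000
    seed: int = 0
    contrasts: list[str] = field(default_factory=lambda: list(CONTRASTS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise CnvBurdenError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Short content hash of the analysis configuration.

        Stable under key reordering; the output location is excluded so
        identical analyses written to different directories share a hash.
        """
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute filter -> annotate -> burden, writing all artifacts.

    Produces ``rare.tsv``, ``filter_report.tsv``, ``annotated.tsv``,
    ``burden.tsv`` and ``report.json`` under ``config.out_dir`` and returns
    the report dict. Any stage error raises :class:`CnvBurdenError` naming
    the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    def stage(name: str):
        def wrap(exc: Exception) -> CnvBurdenError:
            return CnvBurdenError(f"pipeline stage {name!r} failed: {exc}")
        return wrap

    # --- load ---------------------------------------------------------
    try:
        samples = read_manifest(config.manifest)
        events = read_cnv_table(config.calls, samples=samples)
        refs = [read_frequency_reference(p) for p in config.refs]
        loci = read_roi_bed(config.loci) if config.loci else []
        genes = read_gene_bed(config.genes) if config.genes else []
        listed = read_roi_bed(config.listed) if config.listed else []
    except Exception as exc:
        raise stage("load")(exc) from exc
    logger.info("load: %d samples, %d events, %d references", len(samples),
                len(events), len(refs))

    # --- rare filter --------------------------------------------------
    try:
        rare, report = run_filter_chain(
            events, refs,
            min_size_kb=config.min_size_kb, min_probes=config.min_probes,
            max_freq=config.max_freq, min_overlap=config.min_overlap,
            reciprocal=config.reciprocal,
        )
        write_events(out / "rare.tsv", rare, config_hash=chash)
        with open(out / "filter_report.tsv", "w") as handle:
            handle.write(f"# cnvburden v{__version__}\n# config_hash={chash}\n")
            handle.write("stage\tn_events\n")
            for k, v in report.counts().items():
                handle.write(f"{k}\t{v}\n")
    except Exception as exc:
        raise stage("filter")(exc) from exc
    logger.info("filter: %s", report.counts())

    # --- annotate + classify ------------------------------------------
    try:
        annotations = annotate_events(
            rare, loci, genes,
            min_fraction=config.locus_fraction, fraction_of=config.fraction_of,
        )
        calls = classify_all(
            annotations, listed,
            min_fraction=config.locus_fraction, fraction_of=config.fraction_of,
        )
        ordered = [ann.event for ann in annotations]
        write_events(out / "annotated.tsv", ordered, annotations=annotations,
                     clinical=calls, config_hash=chash)
    except Exception as exc:
        raise stage("annotate")(exc) from exc
    n_tier = {tier: sum(1 for c in calls if c.tier == tier)
              for tier in ("pathogenic", "uncertain", "none")}
    logger.info("annotate: tiers %s", n_tier)

    # --- burden -------------------------------------------------------
    try:
        categories = [CATEGORY_ANY]
        if loci:
            categories.append(CATEGORY_LOCI)
        if genes:
            categories += [CATEGORY_HR, CATEGORY_LOFI]
        plan = PermutationPlan(n_permutations=config.permutations, seed=config.seed)
        rows = build_burden_table(
            ordered, annotations, samples, plan,
            contrasts=config.contrasts, categories=categories,
        )
        write_burden_table(out / "burden.tsv", rows, config_hash=chash)
    except Exception as exc:
        raise stage("burden")(exc) from exc
    logger.info("burden: %d rows", len(rows))

    # --- report -------------------------------------------------------
    n_cases = sum(1 for s in samples if s.group == CASE)
    case_ids = {s.sample_id for s in samples if s.group == CASE}
    case_calls = [c for c in calls if c.event.sample_id in case_ids]
    report_dict = {
        "version": __version__,
        "config_hash": chash,
        "n_samples": len(samples),
        "n_cases": n_cases,
        "filter": report.counts(),
        "tiers": n_tier,
        "n_pathogenic_events": sum(1 for c in case_calls if c.tier == "pathogenic"),
        "diagnostic_yield_pct": (
            diagnostic_yield(case_calls, n_cases) if n_cases else None
        ),
        "n_burden_rows": len(rows),
    }
    with open(out / "report.json", "w") as handle:
        json.dump(report_dict, handle, indent=2)
        handle.write("\n")
    logger.info("report: yield %s%%", report_dict["diagnostic_yield_pct"])
    return report_dict
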