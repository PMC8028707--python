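"""One reproducible cross-species comparative analysis (CSCA) run.

Fixed stage order: parse the DEG table → partition into up/down →
harmonize the significant genes to one-to-one human orthologues → build
(or load) the evidence compendium and apply the WR and
expression-evidence filters → exact overlap tests of the harmonized
DEGs against each filtered target at every configured universe size →
optional multi-list scan with family correction.

The report logs N, K, n and k for every test, so any p-value in it can
be re-derived by hand from the log alone, and embeds the resolved
configuration plus a hash for provenance.
"""

from __future__ import annotations

import contextlib
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import yaml

from . import __version__
from .compendium import (
    CompendiumEntry,
    WeightConfig,
    build_compendium,
    filter_by_wr,
    filter_expression_evidence,
)
from .deg_partition import PartitionConfig, partition_degs, \
    summarize_partition
from .errors import CscaError, ConfigError
from .io_formats import read_cuffdiff_diff, read_gmt, read_ortholog_table
from .compendium import read_compendium_tsv
from .ortholog_harmonize import DEFAULT_DB_PRIORITY, HarmonizeReport, harmonize
from .overlap_stats import OverlapResult, multi_list_scan, overlap_test

__all__ = ["RunConfig", "RunReport", "run_csca", "render_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    deg_path: str
    ortholog_path: str
    compendium_path: str            # GMT (build) or TSV (precomputed WR)
    scan_targets_path: str | None = None
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    min_wr: float = 1.0
    universes: tuple[int, ...] = (22000, 18700)
    db_priority: tuple[str, ...] = DEFAULT_DB_PRIORITY
    correction: str = "bonferroni"
    alpha: float = 0.05
    seed: int = 0
    default_category: str | None = None

    def __post_init__(self) -> None:
        if not self.universes:
            raise ConfigError("at least one universe size is required")
        if any(u < 1 for u in self.universes):
            raise ConfigError("universe sizes must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_wr < 0:
            raise ConfigError(f"min_wr must be >= 0, got {self.min_wr}")
        if self.correction not in ("bonferroni", "bh"):
            raise ConfigError(f"unknown correction {self.correction!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        if "partition" in raw and isinstance(raw["partition"], dict):
            raw["partition"] = PartitionConfig(**raw["partition"])
        if "weights" in raw and isinstance(raw["weights"], dict):
            raw["weights"] = WeightConfig(**raw["weights"])
        for key in ("universes", "db_priority"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["partition"] = dataclasses.asdict(self.partition)
        d["weights"] = {
            "category_weights": dict(self.weights.category_weights),
            "aggregation": self.weights.aggregation,
        }
        d["universes"] = list(self.universes)
        d["db_priority"] = list(self.db_priority)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run computed, serializable to JSON/TSV/markdown."""

    config: RunConfig
    partition_summary: dict[str, int]
    harmonization: HarmonizeReport
    compendium_counts: dict[str, int]
    overlaps: list[OverlapResult]
    scan: list[OverlapResult]
    scan_skipped: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tool": "csca",
            "version": __version__,
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "partition": self.partition_summary,
            "harmonization": self.harmonization.to_dict(),
            "compendium": self.compendium_counts,
            "overlaps": [r.to_dict() for r in self.overlaps],
            "scan": [r.to_dict() for r in self.scan],
            "scan_skipped": self.scan_skipped,
            "notes": self.notes,
        }


@contextlib.contextmanager
def _stage(name: str) -> Iterator[None]:
    """Tag any error escaping a stage with the stage name, so callers can
    mark the failed stage in a partial report."""
    try:
        yield
    except CscaError as exc:
        if not hasattr(exc, "stage"):
            exc.stage = name  # type: ignore[attr-defined]
        raise


def _load_compendium(config: RunConfig) -> list[CompendiumEntry]:
    path = Path(config.compendium_path)
    if path.suffix.lower() in (".tsv", ".txt"):
        return read_compendium_tsv(path)
    sets = read_gmt(path, default_category=config.default_category)
    return build_compendium(sets, config.weights)


def run_csca(config: RunConfig) -> RunReport:
    """Execute the full pipeline; stages run in fixed order.

    The query for every overlap test is the harmonized (human-namespace)
    set of all significant DEGs, up and down combined.  Each configured
    universe size yields its own overlap results, juxtaposed in the
    report as a sensitivity analysis.
    """
    notes: list[str] = []

    with _stage("partition"):
        records = read_cuffdiff_diff(config.deg_path)
        part = partition_degs(records, config.partition)
    psum = summarize_partition(part)
    logger.info("partition: %s", psum)

    with _stage("harmonize"):
        orthologs = read_ortholog_table(config.ortholog_path)
        hreport = harmonize(part.significant, orthologs, config.db_priority)
    query = hreport.targets
    logger.info("harmonized %d/%d significant genes", hreport.n_out,
                hreport.n_in)
    if hreport.conflicts:
        notes.append(
            f"{len(hreport.conflicts)} orthologue target conflict(s) resolved "
            f"by database priority {list(config.db_priority)}")
    if hreport.collapsed:
        notes.append(
            f"{len(hreport.collapsed)} many-to-one orthologue collapse(s); "
            "all kept (set semantics deduplicate)")

    with _stage("compendium"):
        entries = _load_compendium(config)
        wr_set = filter_by_wr(entries, config.min_wr)
        expr_set = filter_expression_evidence(entries, config.min_wr)
    ccounts = {
        "n_genes": len(entries),
        "n_wr_pass": len(wr_set),
        "n_expression_evidence": len(expr_set),
    }
    logger.info("compendium: %s", ccounts)

    overlaps: list[OverlapResult] = []
    targets = [(f"wr>={config.min_wr:g}", wr_set),
               (f"wr>={config.min_wr:g}_expression", expr_set)]
    with _stage("overlap"):
        for universe_n in config.universes:
            for label, target in targets:
                if not target:
                    notes.append(
                        f"target {label!r} empty; overlap test skipped")
                    continue
                r = overlap_test(query, target, universe_n,
                                 name=f"{label}@N={universe_n}")
                t = r.test
                logger.info("overlap %s: N=%d K=%d n=%d k=%d p=%.3g", r.name,
                            t.universe_n, t.marked_k, t.draw_n, t.overlap_k,
                            r.p_upper)
                overlaps.append(r)

    scan_results: list[OverlapResult] = []
    scan_skipped = True
    with _stage("scan"):
        if config.scan_targets_path:
            scan_sets = read_gmt(config.scan_targets_path,
                                 default_category="human_evolution")
            if scan_sets:
                scan_skipped = False
                for universe_n in config.universes:
                    for r in multi_list_scan(query, scan_sets, universe_n,
                                             config.correction, config.alpha):
                        t = r.test
                        logger.info(
                            "scan %s@N=%d: K=%d n=%d k=%d p=%.3g adj=%.3g",
                            r.name, t.universe_n, t.marked_k, t.draw_n,
                            t.overlap_k, r.p_upper, r.p_adjusted)
                        scan_results.append(dataclasses.replace(
                            r, name=f"{r.name}@N={universe_n}"))
            else:
                notes.append("scan-target GMT empty; scan stage skipped")
        else:
            notes.append("no scan-target GMT configured; scan stage skipped")

    return RunReport(
        config=config, partition_summary=psum, harmonization=hreport,
        compendium_counts=ccounts, overlaps=overlaps, scan=scan_results,
        scan_skipped=scan_skipped, notes=notes,
    )


_TSV_HEADER = ("name", "universe_n", "marked_k", "draw_n", "overlap_k",
               "expected", "fold_enrichment", "p_upper", "p_adjusted",
               "method")


def _result_rows(report: RunReport) -> list[dict]:
    return [r.to_dict() for r in report.overlaps + report.scan]


def render_report(report: RunReport, fmt: str, outdir: str | Path) -> Path:
    """Write the report as ``json``, ``tsv`` or ``markdown``.

    Machine formats keep full float precision; the markdown table rounds
    p-values to 3 significant digits for reading.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = outdir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True)
                        + "\n", encoding="utf-8")
    elif fmt == "tsv":
        path = outdir / "results.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for row in _result_rows(report):
                fh.write("\t".join(
                    "" if row[c] is None else
                    (f"{row[c]:.12g}" if isinstance(row[c], float) else
                     str(row[c]))
                    for c in _TSV_HEADER) + "\n")
    elif fmt == "markdown":
        path = outdir / "report.md"
        lines = ["# CSCA run report", "",
                 f"- tool: csca {__version__}",
                 f"- config hash: {report.config.config_hash()}",
                 f"- partition: {report.partition_summary}",
                 f"- harmonized: {report.harmonization.n_out} of "
                 f"{report.harmonization.n_in}",
                 f"- compendium: {report.compendium_counts}", "",
                 "| test | N | K | n | k | expected | fold | p | p_adj |",
                 "|---|---|---|---|---|---|---|---|---|"]
        for row in _result_rows(report):
            padj = "" if row["p_adjusted"] is None else f"{row['p_adjusted']:.3g}"
            lines.append(
                f"| {row['name']} | {row['universe_n']} | {row['marked_k']} "
                f"| {row['draw_n']} | {row['overlap_k']} "
                f"| {row['expected']:.3g} | {row['fold_enrichment']:.3g} "
                f"| {row['p_upper']:.3g} | {padj} |")
        for note in report.notes:
            lines += ["", f"note: {note}"]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ConfigError(f"unknown report format {fmt!r}")
    return path
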