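"""Partition a differential-expression table into up/down/excluded gene sets.

A gene is *up-regulated* when it passes the significance rule and its
log2 fold change is at least ``+lfc_min``, and *down-regulated* when it
passes significance with log2fc at most ``-lfc_min``.  The magnitude
threshold is applied sign-symmetrically: a published rule of the form
"log2FC <= 0.1" for down-regulation is read as log2fc <= -0.1, since
otherwise the down set would contain every up-regulated gene.

Significance defaults to requiring both the Cuffdiff ``significant`` flag
and q <= q_max; either requirement can be disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError
from .io_formats import DEGRecord

__all__ = ["PartitionConfig", "Partition", "partition_degs", "summarize_partition"]


@dataclass(frozen=True)
class PartitionConfig:
    """Thresholds for the up/down split.

    ``lfc_min`` bounds |log2fc| (inclusive); ``q_max`` bounds the BH
    q-value (inclusive).  Comparisons are inclusive as printed in the
    source convention (log2FC >= 0.1).
    """

    q_max: float = 0.05
    lfc_min: float = 0.1
    use_significant_flag: bool = True
    use_q_threshold: bool = True

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ConfigError(f"lfc_min must be >= 0, got {self.lfc_min}")
        if not (0.0 < self.q_max <= 1.0):
            raise ConfigError(f"q_max must be in (0, 1], got {self.q_max}")


@dataclass(frozen=True)
class Partition:
    """Disjoint up/down/excluded symbol sets covering the input genes."""

    up: frozenset[str]
    down: frozenset[str]
    excluded: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down or self.up & self.excluded or self.down & self.excluded:
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.up), len(self.down), len(self.excluded))

    @property
    def significant(self) -> frozenset[str]:
        """All genes assigned a direction (up or down)."""
        return self.up | self.down


def _dedupe(records: list[DEGRecord]) -> list[DEGRecord]:
    """Collapse duplicate gene symbols: smallest q wins, then largest
    |log2fc|, then first occurrence."""
    best: dict[str, tuple[float, float, int]] = {}
    chosen: dict[str, DEGRecord] = {}
    for idx, rec in enumerate(records):
        # -|lfc| so that a smaller key means a larger magnitude
        lfc_mag = abs(rec.log2fc)
        key = (rec.q_value, -lfc_mag if not math.isnan(lfc_mag) else math.inf, idx)
        prev = best.get(rec.gene_symbol)
        if prev is None or key < prev:
            best[rec.gene_symbol] = key
            chosen[rec.gene_symbol] = rec
    # preserve first-occurrence order of symbols
    seen: set[str] = set()
    out: list[DEGRecord] = []
    for rec in records:
        if rec.gene_symbol not in seen:
            seen.add(rec.gene_symbol)
            out.append(chosen[rec.gene_symbol])
    return out


def partition_degs(
    records: list[DEGRecord],
    config: PartitionConfig | None = None,
) -> Partition:
    """Split DEG records into up / down / excluded symbol sets.

    Duplicate symbols are collapsed first (smallest q, then largest
    |log2fc|, then first occurrence).  Infinite log2fc counts toward the
    matching side.  An empty input yields an empty partition.
    """
    config = config or PartitionConfig()
    up: set[str] = set()
    down: set[str] = set()
    excluded: set[str] = set()
    for rec in _dedupe(records):
        passes = True
        if config.use_significant_flag and not rec.significant:
            passes = False
        if config.use_q_threshold and rec.q_value > config.q_max:
            passes = False
        if passes and rec.log2fc >= config.lfc_min:
            up.add(rec.gene_symbol)
        elif passes and rec.log2fc <= -config.lfc_min:
            down.add(rec.gene_symbol)
        else:
            excluded.add(rec.gene_symbol)
    return Partition(up=frozenset(up), down=frozenset(down),
                     excluded=frozenset(excluded))


def summarize_partition(p: Partition) -> dict[str, int]:
    """Totals record: n_up, n_down, n_excluded, n_total."""
    n_up, n_down, n_excluded = p.counts
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_excluded": n_excluded,
        "n_total": n_up + n_down + n_excluded,
    }
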