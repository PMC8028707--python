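"""Map species gene symbols to one-to-one human orthologues.

A gene survives harmonization only if at least one homology database
reports a one-to-one orthologue for it; the target symbol is taken from
the highest-priority such database.  Genes whose only mappings are
one-to-many or many-to-many are dropped as ambiguous, and genes with no
entry at all (or only ``none`` entries) are dropped as having no known
orthologue — mirroring the curation rule of removing genes without a
one-to-one human orthologue in any database before statistical testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError
from .io_formats import HomologyType, OrthologEntry

__all__ = ["HarmonizeReport", "harmonize", "DEFAULT_DB_PRIORITY"]

logger = logging.getLogger(__name__)

#: No precedence between databases is published; this order is this
#: package's choice (configurable) and is flagged in the report whenever
#: it actually breaks a tie.
DEFAULT_DB_PRIORITY: tuple[str, ...] = ("ensembl", "homologene", "panther")


@dataclass(frozen=True)
class HarmonizeReport:
    """Outcome of one harmonization pass.

    ``mapped`` is source → target for genes with a one-to-one orthologue;
    ``conflicts`` records genes for which databases disagreed on the
    one-to-one target (resolved by priority); ``collapsed`` records
    distinct sources that mapped onto an already-used target (both kept —
    downstream set semantics deduplicate).
    """

    mapped: Mapping[str, str]
    dropped_no_ortholog: frozenset[str]
    dropped_ambiguous: frozenset[str]
    conflicts: Mapping[str, Mapping[str, str]]
    collapsed: frozenset[str]

    @property
    def n_in(self) -> int:
        return self.n_out + len(self.dropped_no_ortholog) + len(self.dropped_ambiguous)

    @property
    def n_out(self) -> int:
        return len(self.mapped)

    @property
    def targets(self) -> frozenset[str]:
        """The harmonized (human-namespace) gene set."""
        return frozenset(self.mapped.values())

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_dropped_no_ortholog": len(self.dropped_no_ortholog),
            "n_dropped_ambiguous": len(self.dropped_ambiguous),
            "n_conflicts": len(self.conflicts),
            "n_many_to_one_collapsed": len(self.collapsed),
            "mapped": dict(sorted(self.mapped.items())),
            "dropped_no_ortholog": sorted(self.dropped_no_ortholog),
            "dropped_ambiguous": sorted(self.dropped_ambiguous),
            "conflicts": {g: dict(sorted(dbs.items()))
                          for g, dbs in sorted(self.conflicts.items())},
        }


def harmonize(
    genes: Iterable[str],
    orthologs: Iterable[OrthologEntry],
    db_priority: Sequence[str] = DEFAULT_DB_PRIORITY,
) -> HarmonizeReport:
    """Resolve each gene to its one-to-one human orthologue, if any.

    Parameters
    ----------
    genes
        Source-species symbols (normalized to uppercase here).
    orthologs
        Mapping rows across one or more databases.  Rows from databases
        absent from ``db_priority`` are ignored with a warning.
    db_priority
        Databases in decreasing order of trust; the one-to-one target is
        taken from the first database in this list that reports one.

    The result is independent of entry order within each database: if one
    database reports several conflicting one-to-one targets for the same
    gene, the lexicographically smallest target wins (deterministic
    tie-break), and the conflict is recorded.
    """
    priority = [db.strip().lower() for db in db_priority]
    if not priority:
        raise ConfigError("db_priority must name at least one database")
    rank = {db: i for i, db in enumerate(priority)}

    query = {g.strip().upper() for g in genes if g.strip()}
    # gene -> db -> sorted one2one targets; gene -> set of non-one2one types seen
    one2one: dict[str, dict[str, set[str]]] = {}
    other_types: dict[str, set[HomologyType]] = {}
    ignored_dbs: set[str] = set()
    for e in orthologs:
        if e.database not in rank:
            ignored_dbs.add(e.database)
            continue
        if e.source_symbol not in query:
            continue
        if e.homology_type is HomologyType.ONE2ONE:
            one2one.setdefault(e.source_symbol, {}).setdefault(
                e.database, set()).add(e.target_symbol)
        else:
            other_types.setdefault(e.source_symbol, set()).add(e.homology_type)
    for db in sorted(ignored_dbs):
        logger.warning("ignoring orthologue entries from unknown database %r "
                       "(not in priority list %s)", db, priority)

    mapped: dict[str, str] = {}
    conflicts: dict[str, dict[str, str]] = {}
    dropped_no: set[str] = set()
    dropped_amb: set[str] = set()
    used_targets: dict[str, str] = {}
    collapsed: set[str] = set()
    for gene in sorted(query):
        by_db = one2one.get(gene)
        if by_db:
            per_db = {db: min(targets) for db, targets in by_db.items()}
            best_db = min(per_db, key=lambda db: rank[db])
            target = per_db[best_db]
            if len(set(per_db.values())) > 1:
                conflicts[gene] = per_db
                logger.info("one-to-one target conflict for %s: %s -> using %s (%s)",
                            gene, per_db, target, best_db)
            if target in used_targets:
                collapsed.add(gene)
                logger.info("many-to-one collapse: %s and %s both map to %s",
                            used_targets[target], gene, target)
            else:
                used_targets[target] = gene
            mapped[gene] = target
        elif gene in other_types and other_types[gene] != {HomologyType.NONE}:
            dropped_amb.add(gene)
        else:
            dropped_no.add(gene)
    return HarmonizeReport(
        mapped=mapped,
        dropped_no_ortholog=frozenset(dropped_no),
        dropped_ambiguous=frozenset(dropped_amb),
        conflicts={g: dict(v) for g, v in conflicts.items()},
        collapsed=frozenset(collapsed),
    )
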