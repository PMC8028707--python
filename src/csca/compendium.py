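"""The cross-species aggression-evidence compendium and its filters.

Each gene accumulates *occurrences* — (category, set name) pairs, one per
evidence set it appears in — and a weighted ranking (WR): the sum of the
weights of its occurrences.  A set's own weight takes precedence; when
the set carries none, the per-category default applies.  The default
category weights (causal 1.0; GWAS, selection-signature and expression
0.5 each) reproduce the WR lattice {1, 1.5, 2, 2.5} observed in curated
aggression compendia, but the scheme is a package choice and is fully
overridable.

Two filters feed the statistical stage:

* ``filter_by_wr`` — genes with WR >= threshold (inclusive; the standard
  inclusion rule is WR >= 1);
* ``filter_expression_evidence`` — WR-passing genes additionally backed
  by brain/behavior expression evidence: in at least two expression
  studies, or in one expression study plus at least one study of any
  other category (GWAS, selective sweep, knock-out, OMIM, OMIA, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, FormatError
from .io_formats import EvidenceSet

__all__ = [
    "DEFAULT_CATEGORY_WEIGHTS",
    "WeightConfig",
    "CompendiumEntry",
    "build_compendium",
    "filter_by_wr",
    "filter_expression_evidence",
    "read_compendium_tsv",
    "write_compendium_tsv",
]

DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "causal": 1.0,
    "gwas": 0.5,
    "selection_signature": 0.5,
    "expression": 0.5,
}

#: The category whose occurrence counts drive the expression-evidence rule.
EXPRESSION_CATEGORY = "expression"


@dataclass(frozen=True)
class WeightConfig:
    """Per-category default weights and the aggregation rule (sum only)."""

    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.aggregation != "sum":
            raise ConfigError(
                f"unsupported aggregation {self.aggregation!r}; only 'sum'")
        for cat, w in self.category_weights.items():
            if w < 0:
                raise ConfigError(f"negative weight {w} for category {cat!r}")

    def weight_for(self, evidence_set: EvidenceSet) -> float:
        if evidence_set.weight is not None:
            return evidence_set.weight
        try:
            return self.category_weights[evidence_set.category]
        except KeyError:
            raise ConfigError(
                f"no weight configured for category {evidence_set.category!r} "
                f"(set {evidence_set.name!r}) and the set carries none"
            ) from None


@dataclass(frozen=True)
class CompendiumEntry:
    """A gene, its evidence occurrences, and its weighted ranking."""

    gene: str
    occurrences: tuple[tuple[str, str], ...]  # (category, set name)
    wr: float

    def n_in_category(self, category: str) -> int:
        """Distinct evidence sets of ``category`` this gene occurs in."""
        return len({name for cat, name in self.occurrences if cat == category})

    def n_not_in_category(self, category: str) -> int:
        return len({name for cat, name in self.occurrences if cat != category})


def build_compendium(
    evidence_sets: Sequence[EvidenceSet],
    weights: WeightConfig | None = None,
) -> list[CompendiumEntry]:
    """Aggregate evidence sets into per-gene entries, sorted by WR
    descending then symbol.

    WR is additive over occurrences; "occurs in a set" counts each set at
    most once per gene (set membership, not symbol multiplicity).
    """
    weights = weights or WeightConfig()
    names = [s.name for s in evidence_sets]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate evidence set name(s): {dupes}")
    occ: dict[str, list[tuple[str, str]]] = {}
    wr: dict[str, float] = {}
    # sort sets by name so entry occurrence order is input-order independent
    for s in sorted(evidence_sets, key=lambda s: s.name):
        w = weights.weight_for(s)
        for gene in s.genes:
            occ.setdefault(gene, []).append((s.category, s.name))
            wr[gene] = wr.get(gene, 0.0) + w
    entries = [
        CompendiumEntry(gene=g, occurrences=tuple(occ[g]), wr=wr[g])
        for g in occ
    ]
    entries.sort(key=lambda e: (-e.wr, e.gene))
    return entries


def filter_by_wr(
    entries: Iterable[CompendiumEntry], min_wr: float
) -> frozenset[str]:
    """Genes with WR >= min_wr (inclusive)."""
    if min_wr < 0:
        raise ConfigError(f"min_wr must be >= 0, got {min_wr}")
    return frozenset(e.gene for e in entries if e.wr >= min_wr)


def filter_expression_evidence(
    entries: Iterable[CompendiumEntry], min_wr: float
) -> frozenset[str]:
    """WR-passing genes backed by expression evidence.

    Keep a gene iff WR >= min_wr and it occurs in at least two distinct
    expression-category sets, or in at least one expression set plus at
    least one set of any other category.
    """
    if min_wr < 0:
        raise ConfigError(f"min_wr must be >= 0, got {min_wr}")
    kept: set[str] = set()
    for e in entries:
        if e.wr < min_wr:
            continue
        n_expr = e.n_in_category(EXPRESSION_CATEGORY)
        n_other = e.n_not_in_category(EXPRESSION_CATEGORY)
        if n_expr >= 2 or (n_expr >= 1 and n_other >= 1):
            kept.add(e.gene)
    return frozenset(kept)


# ---------------------------------------------------------------------------
# Compendium TSV (gene, comma-separated "category:set_name", wr)
# ---------------------------------------------------------------------------

_COMPENDIUM_COLUMNS = ("gene", "categories", "wr")


def write_compendium_tsv(
    entries: Sequence[CompendiumEntry], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_COMPENDIUM_COLUMNS) + "\n")
        for e in entries:
            cats = ",".join(f"{cat}:{name}" for cat, name in sorted(e.occurrences))
            fh.write(f"{e.gene}\t{cats}\t{e.wr:g}\n")


def read_compendium_tsv(path: str | Path) -> list[CompendiumEntry]:
    """Read a compendium with precomputed WR values.

    Allows analyses on a supplied compendium table without knowing the
    weight scheme that produced it.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError("empty file", path=str(path), line=1)
        header = tuple(header_line.rstrip("\n").rstrip("\r").split("\t"))
        if header != _COMPENDIUM_COLUMNS:
            raise FormatError(
                f"expected header {list(_COMPENDIUM_COLUMNS)}, found {list(header)}",
                path=str(path), line=1,
            )
        entries: list[CompendiumEntry] = []
        for line_no, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n").rstrip("\r")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 columns, found {len(fields)}",
                    path=str(path), line=line_no,
                )
            gene = fields[0].strip().upper()
            occurrences: list[tuple[str, str]] = []
            if fields[1].strip():
                for tok in fields[1].split(","):
                    cat, _, name = tok.strip().partition(":")
                    occurrences.append((cat.strip().lower(), name.strip()))
            try:
                wr = float(fields[2])
            except ValueError:
                raise FormatError(
                    f"unparsable wr {fields[2]!r}", path=str(path), line=line_no,
                ) from None
            if wr < 0:
                raise FormatError(
                    f"negative wr {wr}", path=str(path), line=line_no)
            entries.append(CompendiumEntry(
                gene=gene, occurrences=tuple(occurrences), wr=wr))
    return entries
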