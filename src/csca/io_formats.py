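"""Readers and writers for the external tables the pipeline consumes.

Three dialects are pinned here:

* the 14-column Cuffdiff ``gene_exp.diff`` table (Cufflinks v2 header),
* GMT gene-set files, with ``category=...;weight=...`` metadata carried in
  the description field,
* a 4-column orthologue mapping TSV.

Parsing is strict: unknown headers and malformed rows raise
:class:`~csca.errors.FormatError` naming the file and line rather than
guessing, because silent column drift corrupts every downstream set
operation.  Gene symbols are normalized to uppercase at parse time; all
later set algebra assumes normalized symbols.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError

__all__ = [
    "Status",
    "HomologyType",
    "DEGRecord",
    "EvidenceSet",
    "OrthologEntry",
    "CUFFDIFF_COLUMNS",
    "read_cuffdiff_diff",
    "write_cuffdiff_diff",
    "read_gmt",
    "write_gmt",
    "read_ortholog_table",
    "write_ortholog_table",
]


class Status(str, enum.Enum):
    """Cuffdiff per-gene test status."""

    OK = "OK"
    NOTEST = "NOTEST"
    LOWDATA = "LOWDATA"
    HIDATA = "HIDATA"
    FAIL = "FAIL"


class HomologyType(str, enum.Enum):
    """Orthology relationship class as reported by a homology database."""

    ONE2ONE = "one2one"
    ONE2MANY = "one2many"
    MANY2MANY = "many2many"
    NONE = "none"


#: Exact Cuffdiff gene_exp.diff header (Cufflinks v2).  Other dialects are
#: rejected rather than guessed.
CUFFDIFF_COLUMNS: tuple[str, ...] = (
    "test_id", "gene_id", "gene", "locus", "sample_1", "sample_2",
    "status", "value_1", "value_2", "log2(fold_change)", "test_stat",
    "p_value", "q_value", "significant",
)


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result from a Cuffdiff run.

    ``log2fc`` is log2(value_2 / value_1); Cuffdiff prints ``inf`` /
    ``-inf`` when one group has zero expression, and those parse to signed
    infinities.  ``gene_symbol`` falls back to ``gene_id`` when the gene
    column is ``-``.
    """

    test_id: str
    gene_id: str
    gene_symbol: str
    locus: str
    sample_1: str
    sample_2: str
    status: Status
    value_1: float
    value_2: float
    log2fc: float
    test_stat: float
    p_value: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")
        if self.value_1 < 0 or self.value_2 < 0:
            raise ValueError("FPKM values must be non-negative")
        if self.significant and self.status is not Status.OK:
            raise ValueError("significant record must have status OK")
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass
class EvidenceSet:
    """A named gene set with an evidence category and optional weight.

    One compendium source study or one human-evolution gene list.  When
    ``weight`` is None the per-category default from the weight
    configuration applies.  Categories are free-form lowercase tokens; the
    canonical four are ``gwas``, ``selection_signature``, ``expression``
    and ``causal``.
    """

    name: str
    category: str
    genes: frozenset[str]
    weight: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("evidence set needs a non-empty name")
        if not self.genes:
            raise ValueError(f"evidence set {self.name!r} has no genes")
        if self.weight is not None and self.weight < 0:
            raise ValueError(f"evidence set {self.name!r} has negative weight")
        self.category = self.category.strip().lower()
        self.genes = frozenset(g.strip().upper() for g in self.genes)


@dataclass(frozen=True)
class OrthologEntry:
    """One (source symbol, target symbol, homology type, database) row."""

    source_symbol: str
    target_symbol: str
    homology_type: HomologyType
    database: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_symbol", self.source_symbol.strip().upper())
        object.__setattr__(self, "target_symbol", self.target_symbol.strip().upper())
        object.__setattr__(self, "database", self.database.strip().lower())
        if not self.source_symbol:
            raise ValueError("source_symbol must be non-empty")
        if self.homology_type is HomologyType.NONE:
            if self.target_symbol:
                raise ValueError("homology_type=none implies empty target_symbol")
        elif not self.target_symbol:
            raise ValueError(
                f"{self.homology_type.value} entry for {self.source_symbol} "
                "needs a target symbol"
            )


# ---------------------------------------------------------------------------
# Cuffdiff gene_exp.diff
# ---------------------------------------------------------------------------

def _parse_float(token: str, column: str, path: str, line_no: int) -> float:
    tok = token.strip()
    if tok in ("inf", "Inf", "+inf"):
        return math.inf
    if tok == "-inf":
        return -math.inf
    try:
        return float(tok)
    except ValueError:
        raise FormatError(
            f"unparsable numeric {token!r} in column {column!r}",
            path=path, line=line_no,
        ) from None


def read_cuffdiff_diff(path: str | Path) -> list[DEGRecord]:
    """Parse a Cuffdiff ``gene_exp.diff`` table into records, in file order.

    The header must match the 14-column Cufflinks v2 layout exactly.
    ``significant`` parses ``yes``/``no``; a ``-`` gene symbol falls back
    to the gene_id.  Raises :class:`FormatError` with the line number on
    any malformed row.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError("empty file", path=str(path), line=1)
        header = tuple(header_line.rstrip("\n").rstrip("\r").split("\t"))
        if header != CUFFDIFF_COLUMNS:
            missing = [c for c in CUFFDIFF_COLUMNS if c not in header]
            extra = [c for c in header if c not in CUFFDIFF_COLUMNS]
            detail = []
            if missing:
                detail.append(f"missing column(s) {missing}")
            if extra:
                detail.append(f"unexpected column(s) {extra}")
            if not detail:
                detail.append("columns out of order")
            raise FormatError(
                "not a Cuffdiff gene_exp.diff header: " + "; ".join(detail),
                path=str(path), line=1,
            )
        records: list[DEGRecord] = []
        for line_no, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n").rstrip("\r")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(CUFFDIFF_COLUMNS):
                raise FormatError(
                    f"expected {len(CUFFDIFF_COLUMNS)} columns, found {len(fields)}",
                    path=str(path), line=line_no,
                )
            row = dict(zip(CUFFDIFF_COLUMNS, fields))
            try:
                status = Status(row["status"])
            except ValueError:
                raise FormatError(
                    f"unknown status token {row['status']!r}",
                    path=str(path), line=line_no,
                ) from None
            sig_tok = row["significant"].strip().lower()
            if sig_tok not in ("yes", "no"):
                raise FormatError(
                    f"significant must be yes/no, found {row['significant']!r}",
                    path=str(path), line=line_no,
                )
            symbol = row["gene"].strip()
            if symbol in ("", "-"):
                symbol = row["gene_id"].strip()
            try:
                rec = DEGRecord(
                    test_id=row["test_id"],
                    gene_id=row["gene_id"],
                    gene_symbol=symbol.upper(),
                    locus=row["locus"],
                    sample_1=row["sample_1"],
                    sample_2=row["sample_2"],
                    status=status,
                    value_1=_parse_float(row["value_1"], "value_1", str(path), line_no),
                    value_2=_parse_float(row["value_2"], "value_2", str(path), line_no),
                    log2fc=_parse_float(row["log2(fold_change)"],
                                        "log2(fold_change)", str(path), line_no),
                    test_stat=_parse_float(row["test_stat"], "test_stat",
                                           str(path), line_no),
                    p_value=_parse_float(row["p_value"], "p_value", str(path), line_no),
                    q_value=_parse_float(row["q_value"], "q_value", str(path), line_no),
                    significant=sig_tok == "yes",
                )
            except ValueError as exc:
                raise FormatError(str(exc), path=str(path), line=line_no) from None
            records.append(rec)
    return records


def _fmt_float(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.6g}"


def write_cuffdiff_diff(records: Iterable[DEGRecord], path: str | Path) -> None:
    """Write records back to the Cuffdiff dialect (6 significant digits)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CUFFDIFF_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.test_id, r.gene_id, r.gene_symbol, r.locus,
                r.sample_1, r.sample_2, r.status.value,
                _fmt_float(r.value_1), _fmt_float(r.value_2),
                _fmt_float(r.log2fc), _fmt_float(r.test_stat),
                _fmt_float(r.p_value), _fmt_float(r.q_value),
                "yes" if r.significant else "no",
            ]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def _parse_gmt_description(desc: str) -> tuple[str | None, float | None]:
    """Extract ``category=...;weight=...`` metadata from a GMT description."""
    category: str | None = None
    weight: float | None = None
    for part in desc.split(";"):
        part = part.strip()
        if part.startswith("category="):
            category = part[len("category="):].strip().lower()
        elif part.startswith("weight="):
            weight = float(part[len("weight="):])
    return category, weight


def read_gmt(
    path: str | Path,
    *,
    default_category: str | None = None,
    category_by_name: dict[str, str] | None = None,
) -> list[EvidenceSet]:
    """Read a GMT file into evidence sets.

    GMT has no native metadata slot, so the description field may carry
    ``category=...;weight=...``.  When absent, the category comes from
    ``category_by_name`` (exact set-name lookup) or ``default_category``.
    Duplicate genes within a line are deduplicated and symbols uppercased.
    """
    path = Path(path)
    sets: list[EvidenceSet] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n").rstrip("\r")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line needs name, description and >=1 gene "
                    f"(found {len(fields)} field(s))",
                    path=str(path), line=line_no,
                )
            name, desc = fields[0].strip(), fields[1]
            if name in seen:
                raise FormatError(
                    f"duplicate set name {name!r}", path=str(path), line=line_no,
                )
            seen.add(name)
            category, weight = _parse_gmt_description(desc)
            if category is None and category_by_name:
                category = category_by_name.get(name)
            if category is None:
                category = default_category
            if category is None:
                raise FormatError(
                    f"set {name!r} has no category in its description and no "
                    "config default was supplied",
                    path=str(path), line=line_no,
                )
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(
                    f"set {name!r} has no genes", path=str(path), line=line_no,
                )
            sets.append(EvidenceSet(name=name, category=category, genes=genes,
                                    weight=weight, description=desc))
    return sets


def write_gmt(sets: Sequence[EvidenceSet], path: str | Path) -> None:
    """Write evidence sets as GMT, embedding category/weight metadata."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sets:
            desc = f"category={s.category}"
            if s.weight is not None:
                desc += f";weight={s.weight:g}"
            fh.write("\t".join([s.name, desc, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Orthologue table
# ---------------------------------------------------------------------------

_ORTHOLOG_COLUMNS = ("source_symbol", "target_symbol", "homology_type", "database")


def read_ortholog_table(path: str | Path) -> list[OrthologEntry]:
    """Read the 4-column orthologue mapping TSV (header exact)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError("empty file", path=str(path), line=1)
        header = tuple(header_line.rstrip("\n").rstrip("\r").split("\t"))
        if header != _ORTHOLOG_COLUMNS:
            raise FormatError(
                f"expected header {list(_ORTHOLOG_COLUMNS)}, found {list(header)}",
                path=str(path), line=1,
            )
        entries: list[OrthologEntry] = []
        for line_no, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n").rstrip("\r")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"expected 4 columns, found {len(fields)}",
                    path=str(path), line=line_no,
                )
            try:
                htype = HomologyType(fields[2].strip().lower())
            except ValueError:
                raise FormatError(
                    f"unknown homology_type token {fields[2]!r}",
                    path=str(path), line=line_no,
                ) from None
            try:
                entries.append(OrthologEntry(
                    source_symbol=fields[0], target_symbol=fields[1],
                    homology_type=htype, database=fields[3],
                ))
            except ValueError as exc:
                raise FormatError(str(exc), path=str(path), line=line_no) from None
    return entries


def write_ortholog_table(entries: Iterable[OrthologEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_ORTHOLOG_COLUMNS) + "\n")
        for e in entries:
            fh.write("\t".join([e.source_symbol, e.target_symbol,
                                e.homology_type.value, e.database]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One uppercase symbol per line; blank lines ignored."""
    path = Path(path)
    out: set[str] = set()
    for raw in path.read_text(encoding="utf-8").splitlines():
        tok = raw.strip()
        if tok:
            out.add(tok.upper())
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8"
    )
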