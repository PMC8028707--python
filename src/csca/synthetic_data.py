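"""Seeded generators emulating every input the pipeline consumes.

The generators plant known structure — how many genes are significant,
how many fall on each side of the fold-change threshold, how many
intersect a designated target set, which genes have one-to-one
orthologues — so that every stage and every statistical property of the
pipeline can be exercised offline with exact expectations.

Defaults mirror the bovine prefrontal-cortex aggression study scenario:
a 22,000-gene universe, 16,384 tested genes of which 1196 are
significant (918 up, 278 down at |log2FC| >= 0.1), 1157 with one-to-one
human orthologues, a 1701-gene evidence compendium with 654 genes at
WR >= 1 (96 of them expression-backed), 50 DEGs intersecting the WR >= 1
set (13 of those expression-backed), and thirteen human-evolution scan
lists of which one — 1003 genes with high-frequency archaic regulatory
mutations — shares 88 genes with the harmonized DEGs.

Synthetic symbols carry the reserved prefix ``SYNG`` so they can never
collide with real gene symbols in mixed tests.  Expression values are
cosmetic fields that satisfy format invariants only; no read-count or
FPKM biology is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import SpecError
from .io_formats import (
    DEGRecord,
    EvidenceSet,
    HomologyType,
    OrthologEntry,
    Status,
    write_cuffdiff_diff,
    write_gene_list,
    write_gmt,
    write_ortholog_table,
)

__all__ = [
    "SimSpec",
    "SetDesign",
    "make_universe",
    "make_deg_table",
    "make_evidence_sets",
    "sets_from_profiles",
    "make_ortholog_table",
    "PaperScenario",
    "paper_scenario",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study.

    ``planted_overlap`` as an int plants exactly that many significant
    genes inside the designated target set (deterministic scenarios); as
    a float it is the enrichment fraction rho in [0, 1], with rho = 0
    meaning significant genes are drawn uniformly from the universe so
    that the overlap with any fixed target set follows the
    hypergeometric null.
    """

    universe_n: int = 22000
    n_tested: int = 16384
    n_deg_sig: int = 1196
    n_up: int = 918
    n_down: int = 278
    target_set_size: int = 654
    planted_overlap: int | float = 50
    lfc_loc: float = 0.0
    lfc_scale: float = 0.5
    q_sig_max: float = 0.05
    ortholog_one2one_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_deg_sig:
            raise SpecError(
                f"violated n_up + n_down <= n_deg_sig "
                f"({self.n_up} + {self.n_down} > {self.n_deg_sig})")
        if self.n_deg_sig > self.n_tested:
            raise SpecError(
                f"violated n_deg_sig <= n_tested "
                f"({self.n_deg_sig} > {self.n_tested})")
        if self.n_tested > self.universe_n:
            raise SpecError(
                f"violated n_tested <= universe_n "
                f"({self.n_tested} > {self.universe_n})")
        if isinstance(self.planted_overlap, int):
            if self.planted_overlap > min(self.n_deg_sig, self.target_set_size):
                raise SpecError(
                    f"violated planted_overlap <= min(n_deg_sig, "
                    f"target_set_size) ({self.planted_overlap} > "
                    f"min({self.n_deg_sig}, {self.target_set_size}))")
            if self.n_deg_sig - self.planted_overlap > \
                    self.universe_n - self.target_set_size:
                raise SpecError(
                    "violated n_deg_sig - planted_overlap <= universe_n - "
                    "target_set_size (not enough off-target genes)")
        else:
            if not (0.0 <= self.planted_overlap <= 1.0):
                raise SpecError(
                    f"violated 0 <= rho <= 1 ({self.planted_overlap})")
        if not (0.0 <= self.ortholog_one2one_fraction <= 1.0):
            raise SpecError("violated 0 <= ortholog_one2one_fraction <= 1")


def make_universe(universe_n: int, seed: int) -> list[str]:
    """A deterministic shuffled list of unique uppercase symbols."""
    if universe_n < 1:
        raise SpecError(f"universe_n must be >= 1, got {universe_n}")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(universe_n - 1)))
    symbols = [f"SYNG{i:0{width}d}" for i in range(universe_n)]
    order = rng.permutation(universe_n)
    return [symbols[i] for i in order]


def _f6(x) -> float:
    # 6-significant-digit text precision: generated values survive a
    # write/read round trip bit-faithfully
    return float(f"{float(x):.6g}")


def _lfc_draws(rng: np.random.Generator, n: int, loc: float, scale: float
               ) -> np.ndarray:
    # symmetric heavy-tailed magnitudes; Laplace per the study's long-tailed
    # fold-change distribution
    return np.abs(rng.laplace(loc, scale, size=n))


def make_deg_table(
    spec: SimSpec,
    universe: Sequence[str],
    target_genes: Sequence[str] | None = None,
) -> list[DEGRecord]:
    """Generate a Cuffdiff-dialect DEG table with planted structure.

    Exactly ``n_up`` records get significant=yes, q <= q_sig_max and
    log2fc >= 0.1; exactly ``n_down`` the mirror image (log2fc is built
    as +-(0.1 + |draw|) so threshold satisfaction is unambiguous); any
    further significant genes get |log2fc| < 0.1; all remaining tested
    rows fail both the flag and the q threshold.  With an integer
    ``planted_overlap``, exactly that many significant genes come from
    ``target_genes`` (default: the first ``target_set_size`` genes of
    ``universe``).
    """
    if len(universe) != spec.universe_n:
        raise SpecError(
            f"universe has {len(universe)} genes but spec.universe_n = "
            f"{spec.universe_n}")
    rng = np.random.default_rng(spec.seed)
    if target_genes is None:
        target_genes = universe[: spec.target_set_size]
    target = set(target_genes)
    off_target = [g for g in universe if g not in target]

    if isinstance(spec.planted_overlap, int):
        n_in = spec.planted_overlap
        in_idx = rng.choice(len(target_genes), size=n_in, replace=False)
        out_idx = rng.choice(len(off_target), size=spec.n_deg_sig - n_in,
                             replace=False)
        sig_genes = [target_genes[i] for i in sorted(in_idx)] + \
                    [off_target[i] for i in sorted(out_idx)]
        sig_genes = list(rng.permutation(sig_genes))
    else:
        rho = float(spec.planted_overlap)
        if rho == 0.0:
            idx = rng.choice(spec.universe_n, size=spec.n_deg_sig, replace=False)
            sig_genes = [universe[i] for i in sorted(idx)]
            sig_genes = list(rng.permutation(sig_genes))
        else:
            # each significant slot comes from the target with prob rho
            forced = rng.random(spec.n_deg_sig) < rho
            n_in = int(min(forced.sum(), len(target_genes)))
            in_idx = rng.choice(len(target_genes), size=n_in, replace=False)
            out_idx = rng.choice(len(off_target),
                                 size=spec.n_deg_sig - n_in, replace=False)
            sig_genes = [target_genes[i] for i in sorted(in_idx)] + \
                        [off_target[i] for i in sorted(out_idx)]
            sig_genes = list(rng.permutation(sig_genes))

    sig_set = set(sig_genes)
    n_extra = spec.n_deg_sig - spec.n_up - spec.n_down
    up_genes = sig_genes[: spec.n_up]
    down_genes = sig_genes[spec.n_up: spec.n_up + spec.n_down]
    extra_genes = sig_genes[spec.n_up + spec.n_down:]

    nonsig_pool = [g for g in universe if g not in sig_set]
    nonsig_genes = nonsig_pool[: spec.n_tested - spec.n_deg_sig]

    records: list[DEGRecord] = []

    def _emit(genes: Sequence[str], lfc: np.ndarray, q: np.ndarray,
              significant: bool) -> None:
        p = q * rng.uniform(0.05, 1.0, size=len(genes))
        v1 = rng.uniform(1.0, 100.0, size=len(genes))
        for i, g in enumerate(genes):
            v2 = v1[i] * float(2.0 ** np.clip(lfc[i], -30, 30))
            records.append(DEGRecord(
                test_id=g, gene_id=g, gene_symbol=g,
                locus=f"chr{1 + i % 29}:{1000 * i + 1}-{1000 * i + 999}",
                sample_1="q1", sample_2="q2", status=Status.OK,
                value_1=_f6(v1[i]), value_2=_f6(v2),
                log2fc=_f6(lfc[i]), test_stat=_f6(lfc[i] * 2.0),
                p_value=_f6(p[i]), q_value=_f6(q[i]),
                significant=significant,
            ))

    q_sig = rng.uniform(0.0, spec.q_sig_max, size=spec.n_deg_sig)
    # +-(0.1 + |draw|): threshold satisfied with margin, never on the boundary
    lfc_up = 0.1 + _lfc_draws(rng, spec.n_up, spec.lfc_loc, spec.lfc_scale) + 1e-6
    lfc_down = -(0.1 + _lfc_draws(rng, spec.n_down, spec.lfc_loc,
                                  spec.lfc_scale) + 1e-6)
    lfc_extra = rng.uniform(-0.0999, 0.0999, size=n_extra)
    _emit(up_genes, lfc_up, q_sig[: spec.n_up], True)
    _emit(down_genes, lfc_down, q_sig[spec.n_up: spec.n_up + spec.n_down], True)
    if n_extra:
        _emit(extra_genes, lfc_extra, q_sig[spec.n_up + spec.n_down:], True)

    n_nonsig = len(nonsig_genes)
    if n_nonsig:
        q_ns = rng.uniform(spec.q_sig_max + 0.001, 1.0, size=n_nonsig)
        lfc_ns = rng.laplace(spec.lfc_loc, spec.lfc_scale, size=n_nonsig)
        _emit(nonsig_genes, lfc_ns, q_ns, False)

    order = rng.permutation(len(records))
    return [records[i] for i in order]


@dataclass(frozen=True)
class SetDesign:
    """Requested name/category/size (and optional weight) of one set."""

    name: str
    category: str
    size: int
    weight: float | None = None


def make_evidence_sets(
    designs: Sequence[SetDesign],
    universe: Sequence[str],
    seed: int,
    overlaps: Mapping[tuple[str, str], int] | None = None,
) -> list[EvidenceSet]:
    """Build sets of exact sizes with exact pairwise intersections.

    Sets are assembled from disjoint gene blocks plus one shared block
    per requested pair, so the stated pairwise intersections are honored
    exactly and unrequested pairs are disjoint.  Triple-wise overlaps are
    zero by construction; a design that cannot be realized this way (a
    set smaller than the sum of its requested overlaps, or more genes
    than the universe holds) raises :class:`SpecError`.
    """
    overlaps = dict(overlaps or {})
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise SpecError("set names must be unique")
    shared_need: dict[str, int] = {n: 0 for n in names}
    for (a, b), c in overlaps.items():
        if a not in shared_need or b not in shared_need or a == b:
            raise SpecError(f"overlap names a distinct pair of sets: {(a, b)}")
        if c < 0:
            raise SpecError(f"negative overlap for {(a, b)}")
        shared_need[a] += c
        shared_need[b] += c
    for d in designs:
        if shared_need[d.name] > d.size:
            raise SpecError(
                f"set {d.name!r} of size {d.size} cannot hold "
                f"{shared_need[d.name]} shared genes")
    total = sum(d.size for d in designs) - sum(overlaps.values())
    if total > len(universe):
        raise SpecError(
            f"design needs {total} distinct genes, universe has {len(universe)}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(universe))
    pool = iter(order)

    def take(n: int) -> list[str]:
        return [universe[next(pool)] for _ in range(n)]

    members: dict[str, list[str]] = {n: [] for n in names}
    for (a, b), c in sorted(overlaps.items()):
        block = take(c)
        members[a].extend(block)
        members[b].extend(block)
    out: list[EvidenceSet] = []
    for d in designs:
        members[d.name].extend(take(d.size - len(members[d.name])))
        out.append(EvidenceSet(name=d.name, category=d.category,
                               genes=frozenset(members[d.name]),
                               weight=d.weight))
    return out


def sets_from_profiles(
    profiles: Mapping[str, Sequence[tuple[str, str]]],
    set_categories: Mapping[str, str],
    set_weights: Mapping[str, float] | None = None,
) -> list[EvidenceSet]:
    """Materialize evidence sets from per-gene occurrence profiles.

    ``profiles`` maps gene -> [(category, set name), ...]; the inverse
    image of each set name becomes one EvidenceSet.  Used to plant exact
    WR and evidence-rule outcomes gene by gene.
    """
    set_weights = set_weights or {}
    genes_by_set: dict[str, set[str]] = {}
    for gene, occ in profiles.items():
        for cat, name in occ:
            if set_categories.get(name, cat) != cat:
                raise SpecError(
                    f"set {name!r} used with conflicting categories")
            genes_by_set.setdefault(name, set()).add(gene)
    return [
        EvidenceSet(name=name, category=set_categories[name],
                    genes=frozenset(genes), weight=set_weights.get(name))
        for name, genes in sorted(genes_by_set.items())
    ]


def make_ortholog_table(
    genes: Sequence[str],
    one2one_fraction: float,
    seed: int,
    *,
    n_one2one: int | None = None,
    required_one2one: Sequence[str] = (),
    database: str = "ensembl",
) -> list[OrthologEntry]:
    """Orthologue entries for ``genes`` with a controlled composition.

    The chosen fraction (or exact count ``n_one2one``) of genes get an
    identity one-to-one mapping; ``required_one2one`` genes are always
    among them.  Half of the remainder get two one-to-many rows each and
    the other half no entry at all, so both drop reasons are exercised.
    """
    if not (0.0 <= one2one_fraction <= 1.0):
        raise SpecError(f"one2one_fraction must be in [0, 1], got "
                        f"{one2one_fraction}")
    genes = [g.upper() for g in genes]
    required = {g.upper() for g in required_one2one}
    unknown = required - set(genes)
    if unknown:
        raise SpecError(f"required_one2one genes not in list: {sorted(unknown)}")
    if n_one2one is None:
        n_one2one = round(one2one_fraction * len(genes))
    if not (len(required) <= n_one2one <= len(genes)):
        raise SpecError(
            f"violated |required| <= n_one2one <= |genes| "
            f"({len(required)} <= {n_one2one} <= {len(genes)})")
    rng = np.random.default_rng(seed)
    optional = [g for g in genes if g not in required]
    idx = rng.choice(len(optional), size=n_one2one - len(required),
                     replace=False)
    mapped = required | {optional[i] for i in idx}
    entries: list[OrthologEntry] = []
    rest = [g for g in genes if g not in mapped]
    for g in genes:
        if g in mapped:
            entries.append(OrthologEntry(g, g, HomologyType.ONE2ONE, database))
    for j, g in enumerate(rest):
        if j % 2 == 0:
            entries.append(OrthologEntry(g, g + "A", HomologyType.ONE2MANY,
                                         database))
            entries.append(OrthologEntry(g, g + "B", HomologyType.ONE2MANY,
                                         database))
        # odd-indexed rest genes get no entry at all
    return entries


# ---------------------------------------------------------------------------
# The full paper-scenario bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaperScenario:
    """All four pipeline inputs with mutually consistent planted counts."""

    spec: SimSpec
    universe: list[str]
    deg_records: list[DEGRecord]
    compendium_sets: list[EvidenceSet]
    scan_sets: list[EvidenceSet]
    ortholog_entries: list[OrthologEntry]
    wr1_genes: frozenset[str]          # planted WR >= 1 target (654)
    expression_genes: frozenset[str]   # planted expression-evidence subset (96)
    planted: dict[str, int]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit gene_exp.diff, compendium.gmt, scan_lists.gmt,
        orthologs.tsv and universe.txt; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "deg": outdir / "gene_exp.diff",
            "compendium": outdir / "compendium.gmt",
            "scan": outdir / "scan_lists.gmt",
            "orthologs": outdir / "orthologs.tsv",
            "universe": outdir / "universe.txt",
        }
        write_cuffdiff_diff(self.deg_records, paths["deg"])
        write_gmt(self.compendium_sets, paths["compendium"])
        write_gmt(self.scan_sets, paths["scan"])
        write_ortholog_table(self.ortholog_entries, paths["orthologs"])
        write_gene_list(self.universe, paths["universe"])
        return paths


def paper_scenario(seed: int = 0) -> PaperScenario:
    """The deterministic study-scale scenario.

    Plants, in one mutually consistent bundle: 16,384 tested genes, 1196
    significant (918 up / 278 down), 1157 with one-to-one orthologues, a
    1701-gene compendium with 654 genes at WR >= 1 of which 96 carry
    expression evidence, 50 harmonized DEGs inside the WR >= 1 set (13
    inside the 96), and thirteen scan lists of which the first — 1003
    genes — shares exactly 88 genes with the harmonized DEGs.
    """
    spec = SimSpec(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2025]))
    universe = make_universe(spec.universe_n, seed)

    # index layout on the shuffled universe
    overlap50 = universe[0:50]             # DEG ∩ WR>=1
    expr_in_deg = overlap50[0:13]          # also in the 96-gene subset
    rest_wr1 = universe[50:654]
    wr1 = overlap50 + rest_wr1             # 654 genes at WR >= 1
    expr96 = expr_in_deg + rest_wr1[0:83]  # 96 expression-backed genes
    low_wr = universe[654:1701]            # 1047 compendium genes below 1
    deg_rest = universe[1701:1701 + 1146]  # remaining significant DEGs
    sig_genes = overlap50 + deg_rest       # 1196 significant genes

    # up/down: 24/26 among the 50 compendium matches, remainder split so
    # totals are 918 and 278
    up_genes = overlap50[0:24] + deg_rest[0:894]
    down_genes = overlap50[24:50] + deg_rest[894:1146]
    unmapped = deg_rest[1107:1146]         # 39 DEGs without one-to-one

    # --- compendium profiles -------------------------------------------------
    set_categories = {
        "EXPR_MOUSE": "expression", "EXPR_FOX": "expression",
        "EXPR_RAT": "expression",
        "KO_MOUSE": "causal", "GWAS_HUMAN": "gwas", "GWAS_DOG": "gwas",
        "SWEEP_CATTLE": "selection_signature",
    }
    profiles: dict[str, list[tuple[str, str]]] = {}
    for g in expr96:  # two expression studies -> WR 1.0, rule satisfied
        profiles[g] = [("expression", "EXPR_MOUSE"), ("expression", "EXPR_FOX")]
    wr1_only = [g for g in wr1 if g not in set(expr96)]  # 558 genes
    for g in wr1_only[0:300]:  # knock-out evidence -> WR 1.0, no expression
        profiles[g] = [("causal", "KO_MOUSE")]
    for g in wr1_only[300:]:  # GWAS + sweep -> WR 1.0, no expression
        profiles[g] = [("gwas", "GWAS_HUMAN"),
                       ("selection_signature", "SWEEP_CATTLE")]
    for g in low_wr[0:524]:  # single GWAS hit -> WR 0.5
        profiles[g] = [("gwas", "GWAS_DOG")]
    for g in low_wr[524:]:  # single expression hit -> WR 0.5
        profiles[g] = [("expression", "EXPR_RAT")]
    compendium_sets = sets_from_profiles(profiles, set_categories)

    # --- scan lists (13) -----------------------------------------------------
    mapped_deg_rest = deg_rest[0:1107]
    scan_hit = mapped_deg_rest[0:88]
    far_pool = universe[2847:]
    scan_sets = [EvidenceSet(
        name="archaic_hf_regulatory", category="human_evolution",
        genes=frozenset(scan_hit) | frozenset(far_pool[0:915]), weight=0.0)]
    off = 915
    for i in range(12):
        scan_sets.append(EvidenceSet(
            name=f"human_evolution_{i + 2:02d}", category="human_evolution",
            genes=frozenset(far_pool[off:off + 500]), weight=0.0))
        off += 500

    # --- DEG table -----------------------------------------------------------
    records: list[DEGRecord] = []

    def _emit(genes: Sequence[str], sign: int, sig: bool) -> None:
        n = len(genes)
        if sig:
            q = rng.uniform(0.0, spec.q_sig_max, size=n)
            lfc = sign * (0.1 + 1e-6 +
                          np.abs(rng.laplace(spec.lfc_loc, spec.lfc_scale, n)))
        else:
            q = rng.uniform(spec.q_sig_max + 0.001, 1.0, size=n)
            lfc = rng.laplace(spec.lfc_loc, spec.lfc_scale, size=n)
        p = q * rng.uniform(0.05, 1.0, size=n)
        v1 = rng.uniform(1.0, 100.0, size=n)
        for i, g in enumerate(genes):
            v2 = v1[i] * float(2.0 ** np.clip(lfc[i], -30, 30))
            records.append(DEGRecord(
                test_id=g, gene_id=g, gene_symbol=g,
                locus=f"chr{1 + i % 29}:{1000 * i + 1}-{1000 * i + 999}",
                sample_1="nonaggressive", sample_2="aggressive",
                status=Status.OK,
                value_1=_f6(v1[i]), value_2=_f6(v2),
                log2fc=_f6(lfc[i]), test_stat=_f6(lfc[i] * 2.0),
                p_value=_f6(p[i]), q_value=_f6(q[i]),
                significant=sig,
            ))

    _emit(up_genes, +1, True)
    _emit(down_genes, -1, True)
    sig_set = set(sig_genes)
    nonsig = [g for g in universe if g not in sig_set][
        : spec.n_tested - spec.n_deg_sig]
    _emit(nonsig, +1, False)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    # --- orthologue table ----------------------------------------------------
    tested = sig_genes + nonsig
    mapped = [g for g in sig_genes if g not in set(unmapped)] + nonsig
    entries = make_ortholog_table(
        tested, 1.0, seed, n_one2one=len(mapped), required_one2one=mapped)

    return PaperScenario(
        spec=spec, universe=universe, deg_records=records,
        compendium_sets=compendium_sets, scan_sets=scan_sets,
        ortholog_entries=entries,
        wr1_genes=frozenset(wr1), expression_genes=frozenset(expr96),
        planted={
            "n_tested": spec.n_tested, "n_sig": 1196, "n_up": 918,
            "n_down": 278, "n_one2one": 1157, "n_compendium": 1701,
            "n_wr1": 654, "n_expression_rule": 96, "overlap_wr1": 50,
            "overlap_expression": 13, "overlap_scan_hit": 88,
            "n_scan_lists": 13, "scan_hit_size": 1003,
        },
    )
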