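# Methods

## The statistical model

All inference in this package reduces to one sampling model. Fix a gene
universe of N genes — the number of genes assumed *eligible* to appear in
both lists, not the measured union of the inputs. A target set marks K of
them. If a query list of n genes were drawn uniformly without replacement
from the universe, the overlap count X with the target would follow the
hypergeometric distribution, and the evidence that the observed overlap k
is excessive is the inclusive upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

computed exactly (scipy's survival function, log-space internally; no
normal approximation at any N). The tail is inclusive because the
scientific question is "k **or more** matches"; an exclusive variant is
deliberately not offered. Alongside p the package reports the expected
overlap nK/N and the fold enrichment (k/n)/(K/N), the conventional effect
size of over-representation tables.

Assumptions worth stating explicitly:

* **Exchangeability under the null** — every universe gene is equally
  likely to enter the query. Ascertainment that favors, say, highly
  expressed genes in both the query and the target violates this and
  inflates significance. The universe size is therefore an explicit
  sensitivity parameter: analyses should be run at more than one N
  (`universes` accepts a list, e.g. a genome-wide estimate of 22,000 and a
  brain-expressed estimate of 18,700) and conclusions that flip between
  plausible universes reported as fragile. Note p is increasing in N here:
  a larger assumed universe makes a fixed overlap look more surprising.
* **Full containment** — both lists are assumed to lie inside the
  universe; K and n are used as given. When an explicit universe gene set
  is supplied (`restrict_to_universe`), the lists are intersected with it
  first and the counted size overrides the nominal N (with a warning if
  they disagree).

For a family of target lists, `multi_list_scan` applies Bonferroni
(p·m capped at 1; family-wise error control, the appropriate choice for a
small fixed family of curated lists) or Benjamini–Hochberg (FDR control)
across the m lists. Generic over-representation analysis (`ora`) uses the
one-sided Fisher exact test — mathematically identical to the
hypergeometric tail for the same 2×2 table, an identity asserted at run
time on every row — with BH-FDR across annotation sets.

## Pipeline stages and their parameters

| parameter | default | meaning |
|---|---|---|
| `q_max` | 0.05 | max BH q-value (inclusive) for significance |
| `lfc_min` | 0.1 | min \|log₂FC\| (inclusive) for a direction call |
| `use_significant_flag` | true | additionally require Cuffdiff's own call |
| `db_priority` | ensembl > homologene > panther | orthologue tie-break order |
| category weights | causal 1.0; gwas, selection_signature, expression 0.5 | WR contribution per evidence set |
| `min_wr` | 1.0 | WR inclusion threshold (inclusive) |
| `universes` | (22000, 18700) | universe sizes N for the sensitivity pair |
| `correction` | bonferroni | multi-list scan correction |
| `alpha` | 0.05 | significance level for flagging |

**Partition.** The down-regulation rule is the sign-symmetric mirror of
the up rule: log₂FC ≤ −`lfc_min`. (Published threshold statements of the
form "log₂FC ≤ 0.1" for down-regulated genes are read this way; taken
literally they would make the down set a superset of the up set.)
Duplicate symbols collapse to the record with the smallest q, then the
largest |log₂FC|, then first occurrence. Infinite fold changes (one group
at zero expression) count toward their side. Whether the headline DEG
counts of a given study were computed over all tested genes or only the
significant ones is often unstated; both paths are exposed
(`use_significant_flag`, `use_q_threshold`) and the default requires both
the flag and the q cut.

**Harmonization.** A gene survives iff at least one database reports a
one-to-one orthologue; the target comes from the highest-priority such
database. Genes with only one-to-many/many-to-many mappings are dropped as
ambiguous, distinct from genes with no orthologue at all; both tallies
appear in the report. Databases do not publish a canonical precedence, so
the default priority order is this package's own choice — conflicts it
resolves are listed in the report rather than silently absorbed. Two
sources mapping to one human target are both kept (downstream set algebra
deduplicates); the collapse is logged.

**Weighted ranking.** WR is an additive score over the evidence sets
containing a gene, each set contributing its own weight or its category's
default. The default weights (causal evidence 1.0 — knock-out, OMIM, OMIA;
association-level evidence 0.5 — expression, GWAS, selection signatures)
reproduce the WR value lattice {1, 1.5, 2, 2.5} seen in curated aggression
compendia, but they are a package convention, not a community standard:
override them (`WeightConfig`, or per-set `weight=` in the GMT description
field) whenever the source compendium documents its own scheme. A
compendium with precomputed WR values can be read directly from TSV,
bypassing the weight scheme entirely. The expression-evidence filter keeps
a WR-passing gene iff it occurs in ≥ 2 distinct expression sets, or in ≥ 1
expression set plus ≥ 1 set of any other category; occurrences count
distinct sets, never duplicated symbols within one set.

## The synthetic-data generator

The generator emulates the four input artifacts — DEG table in the
Cuffdiff dialect, evidence GMT, orthologue TSV, universe list — with
*planted* structure: exact significant/up/down counts, an exact overlap
with a designated target set, an exact one-to-one orthologue count, and
per-gene evidence profiles that realize chosen WR and filter outcomes
exactly. Symbols use a reserved `SYNG` prefix so synthetic and real
symbols cannot collide.

The default `SimSpec`, and the `paper_scenario` bundle built from it, pin
the study-scale conditions this package was written around: 16,384 tested
genes in a 22,000-gene universe, 1196 significant (918 up / 278 down),
1157 with one-to-one orthologues, a 1701-gene compendium with 654 genes at
WR ≥ 1 of which 96 carry expression backing, 50 DEGs inside the WR ≥ 1 set
(13 inside the 96), and thirteen scan lists whose first — 1003 genes —
shares exactly 88 genes with the harmonized DEGs. Log₂ fold changes are
drawn as ±(0.1 + |Laplace(0, 0.5)|), guaranteeing threshold satisfaction
without boundary ambiguity; q-values are uniform below 0.05 for
significant rows and above it otherwise.

What the generator does **not** emulate: read counts, FPKM biology,
library-size or length effects, correlated expression, p/q consistency
with any actual test statistic, or realistic orthologue synteny.
Expression columns are cosmetic fields satisfying format invariants. A
green pipeline on synthetic data therefore demonstrates the correctness of
the set algebra, the counting, and the exact statistics — not the
biological validity of any upstream differential-expression call.

`planted_overlap` accepts an exact count (deterministic scenarios, used
for all reproduction checks) or a fraction rho; rho = 0 draws significant
genes uniformly from the universe, so the overlap with any fixed target
follows the hypergeometric null — the basis of the calibration test.

## Numerical and testing choices

* **Independent oracles.** The exact tail is checked against full
  enumeration of all C(N, n) draws for every N ≤ 12, and against a
  Monte-Carlo null at study scale (10⁵ replicates, agreement within 3
  binomial standard errors). The MC sampler is an explicit
  without-replacement simulation — each universe gene gets an i.i.d.
  uniform key and the n smallest are the draw — sharing no code with the
  tail computation and not sampling any library's hypergeometric
  distribution.
* **Null calibration.** The raw upper tail of a discrete statistic is
  *superuniform* under the null, not uniform: between attainable values
  its CDF sits above the diagonal by up to the local pmf, so a KS test of
  raw p-values against U(0, 1) fails for structural reasons unrelated to
  correctness. The calibration test therefore uses the randomized tail
  P(X > k) + U·P(X = k) (U ~ Uniform(0, 1)), which is exactly uniform
  under the null, over 500 rho = 0 pipeline replicates (KS at α = 0.01),
  plus a direct comparison of the empirical overlap-count tail with the
  exact hypergeometric tail. Inference always uses the raw, conservative
  tail; the randomized tail exists only for calibration
  (`randomized_upper_tail`).
* **Problem sizes in the suite.** Round-trip and partition tests run at a
  reduced scale (universes of a few thousand genes); the scenario tests
  run at full study scale (22,000-gene universe, 16,384-row table), where
  the whole pipeline completes in about two seconds. The calibration test
  uses N = 5000, K = 600, n = 300 — wide enough support (σ ≈ 5.5) for a
  meaningful distributional check at 500 replicates.
* **Ties and degenerate inputs.** Empty DEG input yields an empty
  partition (not an error); an empty scan GMT skips the stage with a note;
  sets are compared case-insensitively via uppercase normalization at
  parse time; k = 0 yields p = 1 and fold enrichment 0; P(X ≥ 0) is
  exactly 1. Conflicting one-to-one targets within a single database break
  ties lexicographically so results never depend on file row order.
* **Precision.** Machine outputs (JSON/TSV) keep full float precision;
  human-readable reports round p to 3 significant digits; text round-trips
  of generated tables are exact at 6 significant digits.

## Known limitations

* Overlap tests treat gene lists as unstructured sets; gene length, GC,
  expression-level or family structure biases shared by query and target
  are not modeled and will inflate significance in real data.
* The universe size is an assumption, not an estimate; the package only
  makes the assumption explicit and easy to vary.
* The default WR weights are a convention (see above); WR comparisons
  across compendia built with different schemes are meaningless.
* Harmonization trusts the supplied orthologue table; it performs no live
  database queries and no synteny or sequence-level validation.
* The ORA stage is generic over supplied annotation sets; it does not ship
  or reconstruct any annotation database, so its fold enrichments are only
  comparable within one annotation source.
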