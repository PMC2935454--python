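# Methods

This note records the models behind each module, the tunable parameters
that matter, what the synthetic world does and does not emulate, and the
design choices made where the procedure was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## SNV classification

A pileup column holds the multiset of read observations (base or gap, Phred
quality, platform tag, read id) over one consensus position. Classification
is per-column and two-tiered:

| parameter | strong | weak |
|---|---|---|
| min reads per allele | 3 | 2 |
| top-k quality sum | top-3 ≥ 60 | top-2 ≥ 45 |
| depth cap | ≤ 30 | none |
| homopolymer indel rule | ≥1 short-read obs per allele | same |

Choices the criteria themselves leave open, resolved as follows:

* **Depth** counts all non-N observations at the column, both platforms
  pooled — the criteria quote a single depth per site. Whether the cap
  should instead count only reads behind the two variant alleles is
  unresolvable from the stated rules; the all-reads reading is the stricter
  and simpler one.
* **Gap quality** is the minimum of the same read's flanking base
  qualities; at a read's terminal column only one flank exists and its
  quality is used as-is. A gap with no flanks at all is an unusable
  observation and raises.
* **Homopolymer predicate**: an indel base sitting in a mononucleotide run
  of length ≥ `homopolymer_min_run` (default 2 — the run length is not
  specified anywhere, and 2 is the weakest run that can mislead
  flow-based base calling; configurable).
* The weak tier is evaluated independently, but a strong column is never
  re-labelled weak, so reported totals are inclusive (strong ⊂ all).
* The 6–30 depth range often quoted for strong SNVs is an *outcome* (6 =
  3+3 minimum support, 30 = the cap), not an extra filter.
* N observations carry no allele information and are excluded from both
  evidence and depth. Ties between alleles break lexicographically.
* Coordinates are 0-based half-open everywhere except the VCF writer
  (1-based; deletions left-normalized to the start of their homopolymer
  run and anchored on the preceding base).

Watterson's estimator θ̂ = S/(a_n L) is used for nucleotide diversity; the
source SNP study behind the reported θ values does not print its estimator,
so Watterson is an explicit assumption of this package.

## Coverage

"Covered" means depth ≥ 1; no higher threshold is stated anywhere, and the
partition/exclusive-fraction results would otherwise depend on an invented
parameter. Intervals are canonical (sorted, disjoint, maximal) half-open
BED intervals. The uniform-coverage miss fraction is the Poisson zero class
e^(−c); note that a 25× short-read expectation of e^(−25) ≈ 10⁻⁹ % —
published figures around 6×10⁻⁴ % imply a much lower *effective* coverage,
so the fold-coverage is an explicit argument and the package takes no side.

## Anchoring

* **Combined map**: markers are ranked per chromosome by mean claimed
  position; cross-source chromosome conflicts resolve by precedence
  linkage > physical (chromosome assignment is a genetic-map product;
  the physical map contributes density), and every conflict is logged.
* **Segmentation** is greedy left-to-right maximal blocks, each
  single-chromosome and strictly monotone in map rank. Greedy maximal is
  provably minimal for this piece structure; the suite checks it against
  exhaustive cut-set enumeration up to 12 hits.
* **Orientation** is the sign of the Kendall rank correlation between
  scaffold position and map rank; single-marker or tied blocks report
  forward with an explicit unknown flag. No published orientation rule
  exists to follow.
* **Split breakpoints** go midway between the flanking conflicting hits —
  the true breakpoint is unobservable between markers, and the midpoint is
  the minimax choice.
* `min_markers` defaults to 1 (single-marker scaffolds are placeable);
  raise it for conservative placement. Order-index ties break by scaffold
  id for determinism.
* Chromosomes without usable maps (sex chromosomes in practice) can be
  populated from a reference liftover table (`place_by_liftover`), ordered
  and oriented by reference coordinates.

## Devog scan

Each gene has one avian-pair ω and several mammalian pairwise ω values, so
a two-sample test is impossible; the test is a one-sample two-sided t of
the mammalian log-ω sample against the avian log ω (df = #mammal pairs −
1). The six mammalian pairs are all unordered pairs of {human, mouse, dog,
opossum}. Genes with ω = 0 or dS = 0 cannot be log-transformed and are
excluded (no pseudocount) and logged. BH step-up controls FDR (q = 0.05
default); acceleration ⇔ adjusted p < q, two-sided, with the t sign giving
the direction and a paired t on per-mammal turkey-vs-chicken log ω
assigning the lineage for accelerated genes. Degenerate cases (zero
variance off the hypothesized mean) are flagged rather than silently given
infinite statistics downstream.

GO over-representation uses the standard one-sided hypergeometric upper
tail (the historical EASE score is an external tool's modification; the
clean hypergeometric is the documented substitute). GO-term dissimilarity
is d = 1 − |N(X)∩N(Y)|/min(|N(X)|,|N(Y)|) over Devog membership sets —
the exact published formula is unrecoverable, so this overlap form is a
package decision, injectable via `dissimilarity_matrix(metric=...)`.
Average-linkage clustering delegates to SciPy's UPGMA; Wilcoxon exact mode
is enumerated in-package (midranks; p = probability of a rank-sum at least
as far from its mean as observed) because library exact modes fall back on
ties; enumeration is used automatically for n ≤ 12.

## Gene families

The copy-number rate is R_ij = (n_ij − n_ih)/T_jh (reference species h,
divergence time T in My). The printed form of this equation is not
recoverable, so the unnormalized difference rate is the package's
definition, with the rate function pluggable (e.g. normalize by n_ih + 1).
Rate-pattern grouping defaults to the per-species sign vector
(expanded/contracted/equal) — the weaker, more robust reading of "sorting
species by R" — with a species-ranking mode available. Lineage-specific
calls use presence = copy number ≥ 1 and absence = 0, both configurable.

## Synthetic world

The generators state one fixed world: a heterozygous diploid genome;
long-read platform at 5× mean depth, 366 b reads, homopolymer deletion
errors (1% per base inside runs); short-read platform at 25×, 74 b reads,
substitution errors (0.3%); qualities uniform over Phred 20–40 (the
simplest model that exercises quality-sum thresholds); het SNP rate 10⁻³
and indel rate 3×10⁻⁴ (matching the observed roughly 3:1 SNV:indel
ratio at ~10⁻³ overall heterozygosity). Columns are truth-aligned —
read mapping and assembly are out of scope, and classification operates on
alignments, so per-position depths are Poisson and each read picks a
haplotype by fair coin. `balanced_het=True` replaces the coin by a
deterministic even split; the 100%-recall property is exercised in that
mode, since binomial sampling at depth 6 can legitimately starve an allele
below 3 reads — a sampling limitation, not a classifier error.

In the ω generator the avian pair reports the gene's baseline log ω
exactly while all other pairs scatter around it (σ = 0.25); this is what
makes the one-sample t exactly calibrated (null p-values uniform, FDR
controlled), and is the stated interpretation of "all pairs drawn from one
distribution" — all pairs share the gene's rate, the avian pair being the
focal measurement. Accelerated genes (5% default) shift the avian pair and
the affected lineage's bird–mammal pairs by log(effect), effect = 2 by
default (≈ the weakest shift a 6-pair t reliably detects at q = 0.05).

What a green test does **not** establish: the generators have no GC bias,
no mapping or assembly artifacts, no quality miscalibration, no linked
variants, and idealized marker maps with uniform spacing — recovery rates
on this world are upper bounds for real data.

## Numerical notes

* All generators derive their randomness from one integer seed
  (`numpy.random.default_rng`); identical seeds give byte-identical
  serialized outputs.
* Exact Wilcoxon comparisons use a 10⁻⁹ tolerance when comparing rank-sum
  deviations to avoid float midrank artifacts.
* Empty inputs return explicit undefined flags (`None` ts/tv ratio, `None`
  mean gap length) rather than NaN arithmetic.
* Genome-scale headline figures (hundreds of thousands of SNVs, tens of
  thousands of scaffolds, hundreds of accelerated genes) require the full
  read set and cross-species alignments and are out of desk-scale reach;
  the suite instead verifies in-report arithmetic exactly and the
  procedures against independent oracles.
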