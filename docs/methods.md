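# Methods

## Variant classification

Each coding variant receives one global MAF, taken from the ExAC-style
frequency column when present and otherwise from the dbSNP-style
column; values above 0.5 are folded to the minor allele (1 − value)
with a warning, and values outside [0, 1] are rejected. A variant
asserted pathogenic in either clinical source (ClinVar-style or
UniProt-style flag) is classed *disease-causing* regardless of
frequency, so the three classes are disjoint tallies and a pathogenic
variant with a recorded MAF is never double-counted. Otherwise
MAF < 0.01 is *rare* (including MAF exactly 0) and MAF ≥ 0.01 is
*common* — the boundary belongs to common. Variants with neither a
frequency nor an assertion are unclassifiable: dropped from counts,
tallied in the ingest report. Consequence terms are normalized
(lower-case; spaces, apostrophes and prime marks to underscores; 3′/5′
to `3_prime`/`5_prime`) and the non-exonic classes `downstream_gene`,
`3_prime_utr` and `5_prime_utr` are excluded before classification;
the exclusion set is a parameter. Conflicting pathogenicity assertions
resolve to pathogenic (the flags are OR-ed); a variant annotated to
several genes counts once per (variant, gene) pair, since the
gene-level test needs per-gene evidence; exact duplicates of a
(variant, gene) pair are removed.

## The enrichment test

For gene $g$ with $n_g$ classified variants, $k_{gc}$ of class $c$,
the universe is all classified variants across all genes: $N = \sum_g
n_g$, $K_c = \sum_g k_{gc}$. The p-value is the hypergeometric upper
tail $\Pr(X \ge k_{gc})$ with $X \sim \mathrm{Hypergeom}(N, K_c,
n_g)$, computed via the survival function (never exactly 0, monotone
non-increasing in $k$). Every gene with $n_g \ge 1$ is tested for every
class, so the Benjamini–Hochberg family size $m$ is identical within a
class run; adjustment uses the standard step-up with cumulative
minimum, which makes rank ties irrelevant. A gene is enriched when the
adjusted p ≤ α; α defaults to 0.05 and is exposed everywhere. The
three per-class enriched sets (EVsets) may in principle overlap; any
overlap is reported, never resolved — disjointness in real data is an
empirical observation, not a constraint.

Two consequences of this design are worth knowing. First, a single
gene holding the whole universe gets p = 1 by construction. Second,
the universe composition is itself the reference: if a large share of
the variant mass sits in strongly enriched genes, the complement is
mechanically depleted and ordinary genes drift toward weak apparent
enrichment in the depleted class. The recovery experiment (below)
therefore keeps the planted mass small.

## Gene-set characterization

A gene is *essential* when its mouse-ortholog knockout is lethal (MGI
flag) or it appears in the OGEE essentiality database; missing flags
count as non-essential. Percentages are rounded to the nearest integer
for essentiality summaries and to one decimal for disease-annotation
overlap, matching the two reporting styles. Constraint comparisons use
pLi and dN/dS with complete-case handling: missing scores are dropped
per set and the dropped counts reported; a set with fewer than two
scored genes makes the affected comparison unavailable rather than
fabricated. The omnibus test is Kruskal–Wallis; pairwise tests are
two-tailed Mann–Whitney with mid-ranks, exact enumeration when both
groups have ≤ 50 observations and no ties, otherwise the tie-corrected
normal approximation; pairwise p-values are BH-adjusted. Proportion
comparisons use Fisher's exact test (two-sided, conditional) because
it stays valid at the set sizes involved (n = 32); note that on the
disease-annotation table 20/32 vs 91/282 Fisher gives p ≈ 0.0014,
whereas an unconditional chi-square would fall just under 0.001 — the
package asserts only what its own test computes.

Network analysis treats the interactome as a simple undirected graph:
reversed, duplicated and self-loop records are removed at load (degree
counts distinct interactors). Genes absent from the network have
degree 0 and stay in medians and ranges. The *enriched adjacency
subnetwork* is the induced subgraph on the union of the three EVsets
with isolated nodes dropped — paths through non-enriched intermediates
are deliberately not included; per-set node counts partition the nodes
with priority disease > rare > common in the (empirically absent) case
of multi-set membership. First-degree neighbor extraction filters a
gene's direct interactors on the disease-annotation flag.

A variant is *population-specific* when its allele count is non-zero
in exactly one population — presence/absence, regardless of allele
number. A *rare-to-common switch* is a variant observed below frequency
0.01 in at least one population and at or above 0.01 in another.

## The synthetic-data generator

The generator emulates the study inputs at configurable scale; its
defaults reproduce the emulated catalogue's global shape: 589,983
variants in proportions 0.8157/0.1387/0.0456 (481,277 rare / 81,822
common / 26,884 disease-causing) across 17,975 genes, with planted set
sizes 800/32/282 mirroring the published EVset sizes, and a scale-free
interaction network whose mean degree (≈ 26) matches 279,904
interactions over ~21k genes.

Per-gene expected variant counts are a multinomial over log-normal
relative intensities (dispersion σ, default 1.0) — a proxy for coding
length that reproduces the long right tail of per-gene counts in real
exomes. Each variant's class is drawn from its gene's probability
triple: the configured global proportions for background genes, and
for a planted gene the planted class's odds multiplied by the
enrichment shift and renormalized. Because planted genes draw from
shifted triples, heavy planting (the 800/32/282 defaults at shift 8)
moves the *realized* global mixture a few percent away from the
configured proportions; the study-scale tally checks therefore run
with planting off. A shift of exactly 1 is the explicit null. MAFs are
uniform inside the class bin (rare strictly below 0.01, common in
[0.01, 0.5)); ~85% of frequencies live in the ExAC-style column and
the rest only in the dbSNP-style column, exercising source priority;
every disease variant carries at least one pathogenicity assertion and
half also carry a frequency.

Annotations are drawn per planted-set label: essentiality from
per-set Bernoulli rates (defaults 0.64/0.53/0.11/0.35 for
disease/rare/common/background, the published rates with a
genome-typical background), pLi from per-set Beta distributions
skewed toward 1 for the constrained sets and toward 0 for the common
set, dN/dS log-normal with medians ≈ 0.15 (constrained) and ≈ 0.45
(common); 5% of scores are set missing to exercise complete-case
paths. The network is Barabási–Albert (or Erdős–Rényi) over a
configurable fraction (default 80%) of genes; planted disease/rare
genes are always members and are mapped onto top-quartile-degree
nodes, emulating the hub position of disease genes in curated
interactomes, while common-planted genes are ordinary members. The
raw edge file plants reversed duplicates and self-loops so the
cleaning step is testable against the recorded clean edge count. The
population table covers a capped sample of non-disease variants over
7 gnomAD-style populations (allele number 10,000): 30% of sampled
rare variants are planted population-specific, 5% are planted
rare-to-common switches, all other variants are observed in ≥ 2
populations on one side of the 0.01 boundary — in particular common
variants are never population-specific, matching the observed
behaviour the generator emulates. All draws flow from one seed
through named sub-streams; identical seeds give byte-identical
output files.

What the generator does *not* emulate: nucleotide sequences, genomic
coordinates, linkage disequilibrium, realistic site-frequency spectra
(frequencies are uniform within the rare/common bins), gene-length–
mutability correlation beyond the intensity proxy, and annotation
errors. Passing recovery tests therefore demonstrate correctness of
the pipeline's logic under its stated model, not robustness to the
biases of real catalogues (e.g. study-bias in interaction databases).

## Operating-characteristic experiments

`evsets.experiments` fixes two seeded designs. *Recovery*: 1,000
genes, 150,000 variants, 5 planted genes per class at shift 8 with
doubled intensity (every planted gene > 200 variants; planted mass
≈ 3% of the universe, small enough that the universe remains a valid
reference for unplanted genes), α = 0.05, 20 replicates; reported are
pooled recall and pooled empirical FDR. *Null calibration*: 500
genes, 25,000 variants, nothing planted, shift 1, 20 replicates;
reported is the per-class declared fraction against α + 3 binomial
standard errors. These sizes keep each experiment under a minute on
one CPU while leaving detection power at the planted effect
essentially 1.

## Numerical and degenerate-input conventions

Hypergeometric parameters are validated (0 ≤ k ≤ min(n, K), n ≤ N,
K ≤ N); p-values outside (0, 1] are rejected by the BH step; a class
absent from the universe yields an empty, warned result rather than an
error; empty record tables aggregate to empty count tables; an empty
gene set is rejected where a summary would divide by zero; an edge
list that cleans to nothing is an error, while malformed rows are
skipped with warnings. Reports are JSON with sorted keys and no
timestamps so reruns are byte-comparable.
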