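# evsets

Gene-level enrichment of rare, common and disease-causing coding
variants, and characterization of the resulting gene sets.

Large variant catalogues (ExAC/gnomAD-style population surveys, dbSNP,
and clinical archives such as ClinVar and UniProt) let one ask which
protein-coding genes carry more of a particular kind of variant than
expected. `evsets` implements that analysis as a reusable pipeline for
human genetics researchers: it classifies coding variants as **rare**
(global minor allele frequency, MAF < 0.01), **common** (MAF ≥ 0.01) or
**disease-causing** (asserted pathogenic in a clinical database,
irrespective of frequency), tests each gene for over-representation of
each class, and then characterizes the resulting *enriched-variant gene
sets* (EVsets) by gene essentiality, constraint scores, protein-
interaction network position, disease-annotation overlap and
population-level allele-frequency behaviour.

Because the underlying database snapshots are not redistributable, the
package ships a synthetic-data generator that emulates all four inputs
(variant table, gene annotations, interaction edge list, per-population
allele counts) with *planted* enrichment structure, so every stage can
be tested against known ground truth.

## The statistic

For a gene containing $n$ classified variants of which $k$ belong to
class $c$, in a universe of $N$ variants of which $K$ are class $c$,
the enrichment p-value is the hypergeometric upper tail

$$P = \Pr(X \ge k), \qquad X \sim \mathrm{Hypergeom}(N, K, n),$$

i.e. the probability of drawing at least $k$ class-$c$ variants when
drawing the gene's $n$ variants without replacement from the universe.
P-values are adjusted per class with the Benjamini–Hochberg step-up
procedure; genes with adjusted $P \le \alpha$ (default 0.05) form that
class's EVset. Set comparisons use the Kruskal–Wallis rank-sum test
(omnibus), two-tailed Mann–Whitney tests (pairwise, BH-adjusted) and
Fisher's exact test for proportions.

## Worked example

Simulate a catalogue of 150,000 variants over 1,000 genes in which 5
genes each are planted with eight-fold enriched odds of rare, common
and disease-causing variants, then run the full pipeline:

```python
from evsets.experiments import recovery_config
from evsets.pipeline import run_pipeline

cfg = recovery_config(404)          # a SimulationConfig
block = {"n_genes": cfg.n_genes, "n_variants_total": cfg.n_variants_total,
         "planted_rare_genes": 5, "planted_common_genes": 5,
         "planted_disease_genes": 5, "enrichment_shift": 8.0,
         "planted_intensity_boost": 2.0, "gene_intensity_dispersion": 0.1,
         "class_proportions": list(cfg.class_proportions), "seed": 404}
report = run_pipeline({"simulate": block, "alpha": 0.05}, "demo_out")
```

The run report (also written to `demo_out/report.json`) contains:

```
inputs:       n_classified=150000  n_rare=121788  n_common=21242  n_disease=6970
evset sizes:  rare=5  common=5  disease=6
recovery:     rare recall=1.0  common recall=1.0  disease recall=1.0
```

All 15 planted genes are recovered; the one extra disease-set gene is a
false discovery within the 5% FDR budget. `n_rare/n_common/n_disease`
are the classified variant tallies (here ≈ 81/14/5%, the configured
global mixture), and `recovery` compares each EVset against the planted
truth. The report also carries essentiality percentages per set, pLi
and dN/dS rank-test comparisons, degree statistics and the
enriched-gene adjacency subnetwork, and population-level summaries
(fraction of variants not population-specific, number of rare-to-common
frequency switches across populations).

The same pipeline runs from files instead of a simulation: point the
config's `inputs:` block at `variants.tsv`, `genes.tsv`, `edges.tsv`
and `populations.tsv` (tab-separated; see `evsets.simulate` for column
layouts). A CLI mirrors every stage:

```sh
evsets simulate --seed 1 --out-dir data/
evsets run config.yaml --out-dir results/
```

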