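# genomeflux

Reconstruction of gene gain/loss dynamics of microbial defense systems
from groups of closely related prokaryotic genomes.

Bacterial and archaeal genomes are in constant flux: gene families are
gained (mostly by horizontal transfer), lost, and occasionally expanded
or contracted by duplication. Defense systems — restriction-modification
(RM), toxin-antitoxin (TA), abortive infection (Abi) and CRISPR-Cas —
are among the most mobile parts of the genome. `genomeflux` provides a
tested, reusable implementation of the analysis pipeline used to
quantify this: a phylogenetic birth-death-gain model with posterior
event decoding, defense-vs-all relative-rate statistics, PCA summaries,
and randomization tests for chromosomal clustering of defense genes
("defense islands"). A synthetic-data generator with logged ground truth
makes every stage testable without access to the original genome
database.

It is aimed at comparative genomicists working with phyletic patterns
(gene family × genome count matrices) over rooted species trees of
tight genome clusters (ATGCs: alignable tight genomic clusters).

## The model

A gene family of size *n* evolves along each branch of a rooted species
tree as a continuous-time Markov chain that

* decreases at rate *nμ* (per-copy loss),
* increases at rate *κ + nλ* (gain by immigration plus per-copy
  duplication).

The root state follows the chain's stationary distribution (negative
binomial with size *κ/λ* and success parameter *λ/μ*; Poisson with mean
*κ/μ* when *λ = 0*). Family likelihoods are computed by pruning over
size states {0..M}, conditioned on the family being observed, and
maximized over (κ, λ, μ) in staged rounds that add optional per-edge
rate multipliers and up to four equal-probability discrete-gamma rate
categories. An inside–outside pass then yields, for every family and
edge, the posterior probabilities of the four genome dynamics events
(GDE):

| event     | parent → child state pattern |
|-----------|------------------------------|
| gain      | 0 → ≥1                       |
| loss      | ≥1 → 0                       |
| expansion | child > parent ≥ 1           |
| reduction | parent > child ≥ 1           |

Summed posteriors are normalized to **events per COG per genome**, and
defense-vs-all relative rates are the ratios (DS/N_DS)/(ALL/N_ALL) per
event type. Chromosomal clustering of defense genes is tested by
comparing the median nearest-neighbor distance (in gene-index units,
circular) against uniform without-replacement resampling, at the gene or
directon (maximal co-directed gene run) level.

## Worked example

Simulate a 8-genome cluster with 1000 gene families (5% defense,
1.5-fold defense rate multiplier, clustered defense genes) and run the
full pipeline:

```bash
genomeflux simulate --out demo/data --seed 42 --n-leaves 8 --n-families 1000
genomeflux full --data demo/data --out demo/results --seed 42 --reps 2000
```

`demo/results/model.txt` holds the fitted rates — here
κ̂ = 0.370, λ̂ = 0.264, μ̂ = 1.042 against generating values
(0.4, 0.2, 1.0). `demo/results/flux/relative_rates.tsv` holds the
defense-vs-all ratios:

```
atgc   genus      gain_ratio  loss_ratio  expansion_ratio  reduction_ratio  all_gde_ratio
SYNTH  synthetic  1.42        1.27        0.88             0.53             1.07
```

Defense families, simulated with inflated rates, show elevated gain and
loss ratios. The reconstructed event density (`normalized_rates.tsv`,
`total` column: 0.19 events per COG per genome over 546 observed
families) is in the range reported for real tight clusters. The
co-localization test (`cluster_tests.tsv`) rejects random placement of
defense genes on every replicon (p ≈ 5e-4 at 2000 randomizations),
reflecting the island concentration used in the simulation.

The packaged 36-cluster defense-vs-all rate table can be summarized
directly:

```bash
genomeflux table1-stats --out demo/table1
```

which reports mean relative rates of 1.3 (gain), 1.5 (loss),
1.04 (expansion), 1.5 (reduction) and 1.4 overall; 30 of 36 clusters
with gain ratio above 1; a 9/18/9 high/average/low flux split with
*Helicobacter* (ATGC050, ratio 2.63) at the top; and a PCA of the four
ratio columns with PC1 = 54% and PC2 = 25% of the variance.

## Library layout

| module                      | contents                                            |
|-----------------------------|-----------------------------------------------------|
| `genomeflux.io_formats`     | Newick trees, count/annotation/rate tables, fixture |
| `genomeflux.bdg_model`      | transition matrices, likelihood, fitting, decoding  |
| `genomeflux.flux_stats`     | normalization, relative rates, flux classes, tests  |
| `genomeflux.pca_summary`    | PCA of relative rates                               |
| `genomeflux.chrom_clustering` | directons, co-localization randomization tests    |
| `genomeflux.synthetic_atgc` | ground-truth generator (trees, families, maps)      |
| `genomeflux.cli`            | `genomeflux` console script                         |
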