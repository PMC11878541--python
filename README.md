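# enamelphylo

Phylogenetic signal in tooth-enamel proteomes, end to end: predict
per-individual protein sequences from genomic variants, score per-site
conservation and evolutionary rates, simulate post-mortem peptide
fragmentation at calibrated stages, infer and compare phylogenies, and
measure evolutionary rate covariation between genes.

## Who this is for

Mature tooth enamel preserves a small set of proteins (AMELX, ENAM,
AMBN, AMTN, MMP20, and a handful of others, plus occasionally
co-extracted collagens) for millions of years — far beyond ancient DNA.
Paleoproteomics therefore reconstructs fragments of these proteins from
fossil teeth and places extinct taxa on phylogenies. The package is for
researchers who want to ask, *before* drilling a fossil: how much
phylogenetic information do enamel proteins carry, how fast does it
decay as peptides fragment with age, and which alignment sites carry
the signal? All analyses run on synthetic data with a known generating
process, so every claim is checkable against the truth.

## The models at the core

* **Sequence evolution.** Proteins evolve along a tree under a
  time-reversible 20-state chain (default: symmetric equal rates,
  uniform frequencies) with site rates $r_i \sim \Gamma(\alpha,\alpha)$
  (mean 1); a branch of length $t$ applies $P(t r_i) = e^{Q t r_i}$.
* **Site rates (empirical Bayes).** With a discrete-gamma prior
  ($k$ equal-weight categories with rates $r_c$), the score of site $i$
  is the posterior mean rate
  $\hat r_i = \sum_c r_c w_c L_i(r_c) \big/ \sum_c w_c L_i(r_c)$,
  where $L_i(r_c)$ comes from Felsenstein pruning on a fixed tree; the
  shape $\alpha$ is profiled on a grid by maximum likelihood. Shannon
  entropy $H_i = -\sum_a p_a \log_2 p_a$ is the model-free counterpart.
* **Fragmentation.** Peptides recovered from dated samples are mapped
  onto alignment columns; a stage mask retains the best-covered columns
  down to a target fraction of the supermatrix width (defaults 0.41 /
  0.12 / 0.06 / 0.01 for the stages "100 ka", "1 to 2 Ma", "5 Ma",
  "10 Ma", matching supermatrix reductions 9,557 → 3,884 / 1,139 /
  593 / 98 columns).
* **Inference and comparison.** Distance (p, Poisson or gamma
  corrected) + neighbor joining, pruning log-likelihood for fixed
  topologies, nonparametric column bootstrap, Robinson–Foulds distance
  and rank-level monophyly against a reference tree.
* **Evolutionary rate covariation (ERC).** Per-gene branch lengths are
  OLS-fitted on a shared topology; relative rates divide by the
  across-gene branch mean; per gene pair
  $z = \operatorname{atanh}(r)\sqrt{n-3}$ over the $n$ shared branches,
  with a mean-statistic permutation test against random gene sets.

## Worked example

`python examples/03_fragmentation_stages.py` simulates a 16-taxon
14-protein supermatrix, derives stage masks from simulated dated
peptides, and infers one tree per stage (3 seeds):

```
     stage  width  fraction  mean RF
      full   1482      1.00      0.7
    100 ka    608      0.41      2.0
 1 to 2 Ma    178      0.12      3.3
      5 Ma     89      0.06      5.3
     10 Ma     15      0.01     12.7
```

Reading: at "100 ka" fragmentation, 41% of the columns survive and the
inferred tree differs from the truth by ~2 RF units (one wrong split);
by "10 Ma" only ~1% of columns remain and most of the topology is lost.
The other examples cover proteome-prediction round trips (`01`),
conservation scoring against known site rates (`02`), case-study
placement of a single fragmented taxon (`04`), and ERC (`05`). A thin
CLI (`enamelphylo simulate|predict|concat|conserve|infer|compare|
run-experiment`) wraps the same library calls for shell use.

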