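# Methods

This note documents the models, defaults and design choices behind
`enamelphylo`, and what the synthetic experiments do and do not show.

## Sequence evolution and the synthetic generator

Species trees are pure-birth (Yule) trees: lineages split at rate
(number alive) × `birth_rate`, stopping one waiting time after the
n-th split, so tips are contemporaneous. Branch lengths are rescaled so
the root-to-tip depth equals `tree_height` (default 0.3 expected
substitutions per site — enamel proteins are slowly evolving, and this
puts typical pairwise distances in the 0.1–0.5 range where distance
corrections matter but are not saturated).

Alignments evolve under a reversible 20-state chain. The default is the
symmetric equal-rates model with uniform stationary frequencies — the
amino-acid analogue of Jukes–Cantor — because the per-protein model
choices a model-selection step would make are downstream conveniences,
not part of the machinery under study; any general time-reversible
exchangeability matrix can be supplied. The generator's rate matrix is
scaled to one expected substitution per site per unit branch length.

Site rates are i.i.d. Gamma(α, mean 1) draws (default α = 0.5, strong
heterogeneity) rescaled to unit *empirical* mean. The rescaling is a
deliberate choice: the latent truth exposed to tests is then exactly
mean-one, matching the convention of the estimators, at the cost of a
vanishing O(1/√n) distortion of the gamma law.

No indels are simulated: real alignments are built by an external
aligner, and simulated proteins are generated already aligned. The
per-protein default widths are the 14 study proteins at a 1:7
scale-down of their human lengths (total 1,482 columns), preserving the
relative contribution of collagens vs. enamel-matrix proteins while
keeping experiments fast; `n_taxa` defaults to 16.

Back-translation emits a single-contig toy genome (genes separated by
20-nt spacers, alternating strands), a GFF3 with one CDS per protein,
and per-individual VCFs of haploid homozygous SNVs. One codon is chosen
per (column, residue), so synonymous differences never arise and the
round trip through proteome prediction is exactly lossless — this is a
tested invariant, not an accident.

### Ancient peptide survival

No quantitative survival model for enamel peptide sites exists in the
literature; the one implemented here is a package choice. Site *i* of a
sample aged *a* Ma survives with probability
`expit(c_i − s·ln(a/a0))`, with site intercepts `c_i ~ N(−1.5, 1.5²)`,
slope `s = 1` and scale `a0 = 1` Ma; age 0 survives with probability 1.
This encodes the two assumptions the study system motivates: survival
is heterogeneous across sites, and decays monotonically with age.
Surviving runs are further split at in-vivo cleavage points (each
inter-residue boundary cut with probability 0.05), reflecting the
enzymatic processing of the enamel matrix during amelogenesis. The
intercept spread (not the mean) controls how sharply coverage
concentrates on "durable" sites and hence how nested stage masks are.

## Proteome prediction

Internal coordinates are 0-based half-open; GFF and VCF positions are
converted at the boundary. Missing or non-PASS genotypes become `N` at
the nucleotide level and any codon containing `N` translates to `X`.
Heterozygous calls resolve to the first allele by default (a `mask`
policy turns the codon into `X` instead) — the consensus-calling
convention upstream of such data rarely leaves heterozygotes, so the
default matters little and is configurable. Indels are skipped with a
warning rather than applied: frameshifted predictions would be removed
by curation anyway, and silently applying them would corrupt the
residue-to-column map. A trailing stop codon is stripped; internal
stops translate to `*` and set a QC flag.

Three missing-data symbols are kept distinct throughout: `-` alignment
gap, `X` masked residue, `?` simulated fragmentation loss. Completeness
counts (`-` + `X` + `?`) drive representative selection (most complete
individual per species, ties to the lexicographically smallest id).

## Conservation scoring

Shannon entropy treats `-`/`X`/`?` as ordinary symbols by default, so
heavily masked columns read as diverse — the same behaviour the
model-free measure has on real supermatrices, and the reason a
rate-based score is the better signal detector. The empirical-Bayes
rate uses k = 16 discrete-gamma categories (category means, equal
weights) and profiles α on a 60-point log-grid over [0.05, 10]. Missing
symbols contribute likelihood one in the pruning pass, so an
all-missing site falls back to the prior mean rate of exactly 1 and is
flagged. Smoothing uses a centered window (default 20) that shrinks at
the edges, preserving track length.

For variable/conserved partitioning, raw (unsmoothed) scores are
normalized to mean one within each protein and split at 1 (≥ 1 is
"variable"); per-protein normalization prevents slow proteins (the
collagens) from being globally classified as conserved. Both the raw
and z-scored rate tracks are emitted; partitioning uses the raw track.

## Phylogenetic engine

Distances count mismatches over columns where both rows have a genuine
residue; corrections are `p`, Poisson `−ln(1−p)` or gamma
`α((1−p)^(−1/α)−1)`. Observed p at or above 95% of the 19/20 ceiling is
capped and flagged as saturated. Neighbor joining is the standard
Q-criterion agglomeration, deterministic: exact Q ties break by the
lexicographically smallest cluster-name pair (clusters named by their
smallest leaf), and only the upper triangle of Q is inspected because
floating-point summation order makes Q asymmetric in the last bit.
Negative branch estimates clamp to zero. Pairs with zero comparable
sites abort tree building with a named-pair report — at the oldest
fragmentation stage this is a realistic outcome and the caller decides
(the pipeline marks the stage failed and continues).

Pruning likelihoods rescale partials at every node, collapse duplicate
site patterns, and batch gamma categories; the implementation is checked
against exhaustive ancestral-state summation to 1e-8 on small trees.
Bootstrap supports are fractions of *successful* replicates containing
each point-estimate split; replicates that lose all comparable sites
for some pair are skipped and counted.

Full ML topology search is deliberately out of scope: NJ provides the
search, pruning likelihood scores fixed or constrained topologies. RF
distances count non-trivial bipartitions only, topology-only, after
derooting; rank monophyly asks whether some edge induces exactly the
group's leaf set (singletons trivially monophyletic).

## Fragmentation stages

Coverage profiles count, per column, how many mapped peptides from
dated samples recover it. Peptides map by exact, unique substring match
on the anchor row's ungapped sequence (`X`/`?` in the anchor match
anything); ambiguous or unmatched peptides are discarded with a report.
Stage masks come in two modes: an age threshold (retain columns
recovered from samples at least that old) or a target retained fraction
(rank all columns by coverage, ties by protein order then lower index,
keep the top fraction of the concatenated width). Fraction-based masks
are nested by construction and the canonical four stages use fractions
0.41/0.12/0.06/0.01, calibrated to the published stage supermatrix
widths; age-based masks may legitimately violate nesting (a young stage
can include dentin collagens absent from older ones), so nesting is
only warned about there. The exact coverage-to-stage rule used on the
real data is not published; both modes are documented approximations.
TUFT1 — for which no ancient peptides are known — can be forced empty
at all partial stages; a fraction-1.0 stage represents the intact
alignment and keeps every column.

Case-study mode fragments only the target taxa (their lost columns
become `?`, width unchanged), mimicking the placement of a fragmentary
fossil among full-length references. Placement is scored as: does the
inferred tree contain the split joining the target to its true sister
clade from the generating tree.

## Evolutionary rate covariation

Branch lengths per gene are OLS solutions of the path-incidence system
(a pair's distance equals the sum of branch lengths separating it),
clamped at zero; the system must be full rank or the fit is refused.
Genes missing taxa are fitted on the pruned topology and only master
branches still uniquely identifiable get values; merged branches stay
missing. Relative rates divide by the across-gene branch mean —
deterministic and simple, but one of several definitions in the
literature and a known divergence risk. A consequence quantified in the
tests: deviations from a G-gene mean correlate at exactly −1/(G−1)
under independence, so the null mean pairwise z sits at
`atanh(−1/(G−1))·√(n−3)` rather than 0 (−0.37 at G=20, n=51) and only
vanishes as the pool grows. The permutation test is immune to this
shift — its null is built from the same pool — and its rejection rate
calibrates to α (measured 0.05 at α=0.05, 200 trials).

Fisher z uses √(n−3) with r capped at ±0.999999; pairs with fewer than
4 shared branches or zero variance are reported not-computable. The
permutation p is the add-one estimator, floor 1/(n_perm+1); the default
n_perm is 10,000 (reduced in calibration loops for speed).

## Experiment sizes and determinism

The pipeline's synthetic experiments default to 16 taxa and a
1,482-column supermatrix; sweeps use 20 seeds, ERC calibration 200
trials at n_perm=500, and bootstraps 50 replicates — sizes chosen so a
full run finishes in minutes on one core while leaving the Monte-Carlo
bands (e.g. rejection rate 0.03–0.07) comfortably resolvable. Every
stochastic routine takes an explicit seed, derived seeds go through
`SeedSequence`, and each experiment writes a manifest (config, seeds,
parameter hash) sufficient to reproduce its outputs bit-identically.

## What passing tests do and do not show

The generator realizes exactly the statistical structure the estimators
assume (tree-like evolution, gamma rates, independent sites, no
alignment error). Passing tests therefore demonstrate internal
correctness and statistical consistency — not robustness to model
violations real data carry: alignment and annotation errors,
deamidation and other diagenetic modifications, compositional
heterogeneity, incomplete lineage sorting, or reference bias in peptide
identification. Exact tree recovery additionally requires
identifiability: a random birth tree can contain internal branches of
~0.003 expected substitutions that no 2,000-site alignment resolves, so
exact-recovery checks use a balanced tree with 0.05-substitution
branches, while trend experiments keep random trees and report means.
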