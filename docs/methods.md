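# Methods

`orthomat` re-implements, as a tested reusable pipeline, an unbiased
phylogenomic gene-selection and tree-inference procedure for mixed
genome/transcriptome datasets: core ortholog construction from reference
proteomes, a phylogenetic orthology filter, top-hit profile search in
transcriptome unigene sets, coverage and composition-bias filters, a
trimmed supermatrix, maximum-likelihood phylogeny with bootstrap, and
likelihood-ratio congruence clustering of gene partitions.  Everything
is exercised on synthetic transcriptome data with known ground truth.

## The synthetic study

The generator (`synthetic_study`) emulates the statistical structure of
a 14-taxon charophyte study: six reference taxa with complete proteomes
(four land plants — *Arabidopsis*, *Populus*, *Oryza*, *Physcomitrella* —
and the chlorophyte outgroups *Ostreococcus*, *Chlamydomonas*) and eight
charophyte transcriptome taxa with incomplete unigene sets.  The default
species tree places the Zygnematales (*Penium*, *Spirogyra*) sister to
the land plants; terminal branches are 0.15–0.5 and internal branches
0.05–0.25 substitutions/site, deep-divergence values typical of
plant/green-algal protein trees, with the focal Zygnematales+LP branch at
0.06 so its recovery is informative but not trivial.

Per gene:

* the gene tree is the species tree (or, with probability
  `incongruent_fraction`, default 0.10, a conflicting topology with the
  Charales sister to land plants), decorated by a birth–death
  duplication/loss process along branches (`dup_rate`, `loss_rate`,
  default 0.02 events per branch-length unit; a duplication copies the
  whole subtree below its point, the minimal structure that stresses
  in-paralog clustering);
* each transcriptome taxon then drops the gene independently with one
  minus its occupancy probability; the default occupancy vector
  (1.0, 0.65625, 0.8875, 1.0, 0.1125, 1.0, 0.8875, 0.68125 for
  Chlorokybus, Chaetosphaeridium, Coleochaete, Klebsormidium,
  Mesostigma, Nitella, Penium, Spirogyra) reproduces the per-taxon gene
  representation observed in the study this emulates, including one
  taxon with only ~11% coverage;
* sequences evolve under LG with four discrete-gamma rate categories
  (`gamma_alpha` default 1.0); no indels are simulated, so the truth
  alignment is exact and alignment correctness is tested separately on
  gapped fixtures;
* a `biased_fraction` (default 0.15) of genes carries amino-acid
  compositional heterogeneity: one randomly chosen lineage drifts toward
  skewed equilibrium frequencies (one residue at 0.30, the rest uniform)
  with a 3x rate acceleration in that lineage (`bias_rate_scale`).  The
  shift must be lineage-restricted: a gene-wide frequency change leaves
  every row matching the gene's own pooled composition and is therefore
  invisible to any row-versus-pool composition test.  The acceleration
  reflects that compositional shifts in real lineages ride on rate
  shifts, and makes composition relax far enough at desk-scale branch
  lengths to be detectable (~75–90% of biased genes are flagged, ~2% of
  clean ones).

All randomness derives from one integer seed through fixed-offset
`SeedSequence` spawns, so studies are byte-reproducible.

What the generator does **not** emulate: assembly artifacts, chimeric or
fragmented unigenes, within-transcriptome redundancy, indels, codon
structure, or site-heterogeneous (CAT-like) processes.  Passing tests
therefore demonstrate the pipeline's logic and statistics, not
robustness to assembly noise.

## Ortholog inference

Similarity is Smith–Waterman local alignment (BLOSUM62, gap open 11,
extend 1, raw-score cutoff 40; `X` scores 0 everywhere).  Reciprocal
best hits between each proteome pair seed groups; an exact score tie for
a query's best hit voids its uniqueness and blocks the seed.  A
same-species sequence joins as an in-paralog when it scores at least as
high against its seed as the two seeds score against each other, with
confidence `(score - seed_score) / (self_score - seed_score)` clamped to
[0, 1] (cutoff 0.05).  Pairwise groups extend across all six reference
taxa by connected components over shared seed sequences; components
covering every reference taxon become core groups, the rest are counted
and discarded.

Each core group is then aligned (one representative per taxon, the
highest-confidence member), trimmed, and given an ML tree under WAG+G;
the group is kept only if every configured clade constraint (default:
monophyly of the land plants, monophyly of the chlorophyte outgroups) is
a bipartition of the unrooted tree.  The constraint set is a documented
default and fully configurable, since "well-known relationships" is a
judgment call.

## Profile search

Each kept group becomes a position-specific log2-odds profile: columns
with more than 50% gaps are dropped; the background is the alignment's
global residue frequencies with one Laplace pseudocount; column scores
use a pseudocount weight of 1 and a floor of -10 bits.  Unigenes are
scored by their best ungapped local diagonal run (exhaustive over all
offsets, vectorized Kadane scan), and only the single top-scoring
unigene per taxon is accepted — the "top hit only" decision surface that
lets a hit go straight into the phylogenetic matrix.  The acceptance
threshold is 30 bits: on default studies the best random match in a
transcriptome-sized search space reaches 15–23 bits while true orthologs
score above 150, so 30 bits separates the two with wide margins on both
sides.  A reciprocal re-check against the reference proteomes is
available behind a config flag but off by default, consistent with the
top-hit-only design.

## Matrix assembly

Groups must cover every major charophyte lineage (Chlorokybus;
Klebsormidium; Nitella; Coleochaete OR Chaetosphaeridium; Penium OR
Spirogyra); then the composition filter removes genes where any taxon's
residue composition deviates from the gene's pooled composition
(chi-square, df = number of pooled residues minus 1, alpha 0.05; gaps
and X excluded; the any-taxon aggregation is config-exposed).  On
tree-generated data the test is conservative (rows are phylogenetically
correlated), so clean genes are rarely lost; the 5% nominal rate applies
to independent rows, which is exactly how the calibration check draws
its null.  Surviving alignments are column-trimmed: per-column non-gap
fraction and mean pairwise similarity (positive BLOSUM62 scores
normalized by the geometric mean of the diagonal entries) are window
averaged over `[i-w, i+w]` and both must pass (defaults gt=0.4, st=0.01,
w=3).  This windowed rule is a defined approximation driven by the
printed parameters of the tool it mirrors, not a re-implementation of
that tool's exact algorithm.  Trimmed genes are concatenated in
lexicographic order with gap fill and a 1-based inclusive partition
table; the coverage report counts a gene present for a taxon when its
partition holds at least one residue.

## Maximum likelihood engine

Poisson, WAG and LG models (embedded as plain-text exchangeability and
frequency tables), optional +G (four equal-probability discrete-gamma
categories with category-mean rates; alpha Brent-optimized on
[0.02, 100]) and +F (empirical frequencies, +19 AIC parameters).  The
likelihood core compresses columns to site patterns, runs Felsenstein
pruning with per-node rescaling, and treats gaps/X as missing data.
Branch lengths are optimized by coordinate ascent: each sweep refreshes
the down partials, then walks the tree in preorder maintaining up
partials so that every branch gets a Brent line search whose evaluations
cost one small eigenbasis contraction; lengths are clamped to
[1e-8, 20] and a sweep never lowers the log-likelihood (a guard reverts
the rare stale-cache decrease).  Topology search is NNI hill climbing
from a neighbour-joining start tree (Poisson-corrected p-distances):
both rearrangements of every internal edge are scored with
re-optimization of the central branch only, the best improving move is
applied, all branches re-optimized, and the search stops when no move
improves lnL by more than 1e-4.  NNI-only search is adequate at the
package's <=20-taxon design scale; it is not an SPR regime and may be
trapped on larger problems.  Bootstrap resamples pattern weights by a
multinomial over columns, reruns the search from the ML tree with a
capped number of branch sweeps per replicate, and reports bipartition
percentages.  The pruning core is verified against an independent
matrix-exponential enumeration oracle to 1e-8.

## Congruence clustering

Two gene sets are congruent when a single shared topology explains
their joint data: Delta = 2[(lnL_A + lnL_B) - lnL_AB].  Significance
comes from a parametric bootstrap on the fitted shared tree —
assumption-free and exact-size for any replicate count, since
p = (1 + #exceedances)/(1 + n_null) is valid by exchangeability.
`lrt_pair` exposes the plain pairwise test (default n_null = 99) with
every term a fully optimized single-tree fit; its statistic is
continuous, which is what makes its nominal 5% size measurable.  Joint
fits are multi-start (NJ plus each constituent set's tree) because a
trapped joint search inflates Delta.

The clustering tests *topological* congruence only: a set's likelihood
under a topology T is the sum over genes of the gene's
branch-length-optimized likelihood on T pruned to the gene's taxa, and
lnL_AB maximizes that sum over candidate shared topologies (the
single-branch-length concatenation search plus each side's own
topology).  This matters: with a single joint branch-length set the
statistic also measures branch-length heterogeneity, and because
agglomeration assembles sets selected for internal coherence, the
between-set branch-length noise of two large same-topology sets lands
systematically in the null's tail and fragments every clustering.  The
topological statistic is exactly zero whenever the sets' own topologies
agree with the shared one, so only genuine topology conflict counts.
Null replicates re-simulate each gene on its fitted branch lengths
under the shared topology and recompute the statistic with the same
machinery.

Clustering is agglomerative from singletons, always testing the pair
with the smallest Delta and halting at the first rejection.  Because the
procedure performs one test per merge (~n tests for n genes) selected
among all remaining pairs, the per-step alpha is Dunn-Šidák corrected by
the number of candidate pairs at that step; without the correction the
family-wise false-stop probability on a 20-gene problem is over 50%.
The corrected test is run sequentially: null replicates are drawn until
the first exceedance (which already guarantees p >= alpha_step, so the
merge is accepted) or until ceil(1/alpha_step) exceedance-free draws
(rejection), capped at 600 draws — below the cap the decision is
identical to the fixed-size test, at the cap very small per-step alphas
become conservative toward merging.  A Delta of zero merges without
drawing nulls (p is 1 by construction).

## Problem sizes and numerical choices

Desk-scale defaults keep every documented check cheap: studies of 40–100
genes x 150 aa across 14 taxa, 20 bootstrap replicates for pipeline
support values, congruence problems of 4–6 taxa and 20 genes with
n_null = 24 for calibration checks (the parametric bootstrap's size does
not depend on n_null, so this scales cost, not meaning).  Branch-length
tolerance is 1e-6 relative lnL; Brent xatol 1e-6 on lengths; transition
matrices are built from the symmetrized eigendecomposition and clipped
at 0 before row renormalization; site likelihoods are floored at 1e-300
before logs.  Ties everywhere (RBH subjects, top hits, AIC, NNI moves,
merge pairs) break lexicographically so runs are deterministic.

## Known limitations

* The Inparanoid simplification keeps only the seed/in-paralog rule; the
  original's overlap resolution and bootstrap confidence are out of
  scope, and group membership is the only contract.
* The profile search is an ungapped log-odds scan, not a profile HMM;
  it shares the decision surface (single top hit per taxon) but not the
  sensitivity of HMM search on remote homologs.
* The composition filter's gene-level "any taxon fails" aggregation is
  aggressive for many-taxon genes with independent rows; on
  tree-correlated data this is offset by the test's conservatism.
* Bayesian inference and site-heterogeneous models are deliberately
  absent; the engine is ML-only.
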