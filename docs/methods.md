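# Methods

This note records the models, estimators, parameter choices and known
limitations behind `coexnet`, stage by stage.

## Mutual-information network inference

**Estimator.** MI between two expression vectors is the plug-in estimate on
the joint contingency table after equal-frequency (quantile) discretization of
each vector, with a Miller–Madow bias correction applied to each entropy —
equivalently, MÎ = MI_plug-in + (m_x + m_y − m_xy − 1)/(2n), where m are the
occupied cell counts — clamped at zero, in nats. The bin count defaults to
b = max(2, ⌊√n / 2⌋) per axis (b = 5 at n = 100, b = 50 at n = 10,000), a
standard compromise between resolution and per-cell occupancy (~4n/ b² ≥ 16
expected counts per cell at the default). Quantile binning makes the estimator
rank-based, hence invariant to monotone transforms of each gene, and exactly
deterministic. Value ties are resolved by stable original-index order; this is
documented because it affects MI at small n. A constant (zero-variance) gene
is degenerate: its MI with anything is defined as 0.

Calibration, measured over 100 replicates at n = 10,000 against the Gaussian
closed form −½ln(1−ρ²): bias ≤ 0.019 nats and SD ≤ 0.008 nats across
ρ ∈ {0, 0.3, 0.6, 0.9}. The frozen test tolerance, 0.06 nats, is the worst
|bias| + 5 SD, rounded up. The estimator interface is pluggable should a
kernel-density variant be wanted later.

**All-pairs computation.** Pairs are processed in row blocks; for each block
pair, the joint tables of all gene pairs are accumulated with one matrix
product per joint bin cell (b² products of block-sized indicator matrices).
Memory is bounded by O(block² · b²) and output order is canonical and
independent of the block size. The 1,999,000 pairs of the benchmark take a few
seconds per phenotype on one CPU.

**Pruning.** Edges are the k highest-MI pairs; ties at the k-th value are all
kept so the result does not depend on sort stability (the realized edge count
is reported alongside the nominal k). Network nodes are the genes incident to
at least one retained edge, so node counts vary by phenotype. At full
transcriptome scale the conventional cutoff is k = 100,000 (0.08% of all
pairs); the benchmark default is k = 1,200 = 0.06% of its 1,999,000 pairs,
inside the 0.01–0.1% retention band established for co-expression analyses of
this kind. Retention at the top of that band places the cutoff at the
signal/noise boundary of the sparsest phenotype and lets occasional
high-scoring null pairs attach stray genes to module communities; 0.06% keeps
the cutoff inside the co-expression signal for every phenotype. No
data-processing-inequality step is applied: the object of study is the
co-expression structure itself, not a regulatory-network approximation.

## Map-equation community detection

The two-level map equation scores a hard partition by the expected per-step
code length of an unrecorded random walk: L(M) = q H(Q) + Σᵢ pᵢ☉ H(Pᵢ), with
node visit rates pα = strength/2W (the stationary distribution of an
undirected weighted walk; no teleportation is needed), module exit rates
qᵢ from inter-module edge weight, and pᵢ☉ = qᵢ + Σ_{α∈i} pα. Bits throughout.

Minimization is Louvain-style on the map objective: passes of single-node
moves to the neighboring module (or a fresh singleton) with the largest
codelength decrease, then aggregation of modules into super-nodes carrying
their summed visit rates, iterated until a full pass improves by less than
1e-10 bits; the best of `n_trials` (default 10) seeded restarts is returned.
Accepted moves never increase the codelength, and results are reproducible
from the seed. Disconnected components can never share a module under this
objective, so the many independent components of a pruned network are handled
natively. Only the flat two-level codebook is implemented — communities are
treated as flat groups, not a hierarchy — and membership is hard; overlapping
communities are out of scope.

Community labels combine the phenotype with a rank number assigned by
decreasing size (ties: lexicographically smallest member gene). Numbers
emitted by other community-detection tools are assignment-order artifacts, so
labels are stable within this package but not comparable across tools.
Modularity Q = Σᵢ(eᵢᵢ − aᵢ²) on the weighted graph is reported per network; it
plays no role in detection. Communities below `min_size` (default 10 genes)
are excluded from all downstream analysis as unlikely to represent coherent
functions.

## Overrepresentation analysis

Each retained community is tested against every term of a GMT database with
the exact hypergeometric upper tail P(X ≥ k) for universe N, term size K,
community size n, overlap k. The testing universe is the network's genes
intersected with the annotation universe: community membership is conditional
on surviving top-k pruning, so the background must condition on the same
event. Terms with fewer than 3 universe genes or zero overlap are not tested.
Benjamini–Hochberg q-values are computed per community (the term family
actually tested for that gene list); a community is *enriched* if any term has
q < 0.05. A permutation mode (resampling same-size gene sets, add-one
smoothed) cross-validates the exact tail but is not the default. Communities
are *selected* when a significant term's description matches any of a keyword
list (case-insensitive substrings; defaults "immun", "inflamm", which cover
immune/immunity/immunological and inflammation/inflammatory) — a reproducible
stand-in for curation by inspection. Terms significant in exactly one network
are reported as that network's exclusive enrichment classes. No ontology-graph
propagation is performed; any flat GMT is accepted.

## Cross-network comparison and similarity clusters

Communities from different networks are compared at three levels, all with
the Jaccard index: gene composition, induced edge structure (edges identified
by endpoint gene-id pairs across networks — connection presence, not MI
weight), and significant-term profiles. Within-network pairs are excluded.
The meta-network has communities as nodes and gene-sharing pairs as edges
weighted by gene Jaccard; similarity clusters are its connected components
after deleting edges with weight < τ, singletons dropped, components ordered
by size. τ defaults to 0.2: low enough to keep designed overlaps down to
Jaccard ≈ 0.3, high enough that single-gene coincidences (Jaccard ≈ 0.02 for
30-gene communities) never link clusters. Cluster extraction by connected
components cannot assign one community to two clusters; overlapping
membership would require a different construction and is a documented
limitation. Both pairwise matrices (gene and edge Jaccard) are attached per
cluster, and a cluster-by-cluster gene-overlap matrix is exported for
heatmaps.

## Moderated differential expression

Per gene, a two-group pooled-variance fit of subtype against the reference
phenotype gives log₂FC, s² with df = n₁+n₂−2, and the ordinary t. The
variance prior (d₀, s₀²) is estimated by matching the mean and variance of
log s² to their digamma/trigamma expressions under the scaled
inverse-chi-square hierarchical model (trigamma inverted by Newton
iteration); identical variances give d₀ = ∞ (full shrinkage), d₀ = 0 disables
shrinkage. The posterior variance s̃² = (d₀s₀² + df·s²)/(d₀+df) yields the
moderated t with df_total = d₀+df. The B statistic (log posterior odds of
differential expression) is

B = log(p/(1−p)) − ½log r + ((1+df_total)/2)·log((t²+df_total)/(t²/r+df_total)),

r = (v_g+v₀)/v_g with v_g = 1/n₁+1/n₂. The fold-change prior v₀ is a
method-of-moments estimate from the top-p quantile of |moderated t|
(p = p_prior, default 0.01); this approximates, rather than reproduces, the
likelihood-based mixture estimate used by the reference R implementation, so
B values share that implementation's semantics and ranking (rank correlation
> 0.999 on a cross-check, with d₀, s₀², s̃² and moderated t agreeing to
numerical precision) but not its exact magnitudes. Calls use |log₂FC| ≥ 1 and
B ≥ 6, three ways (over / under / ns); no further multiple-testing correction
is applied to B. Per community and subtype, call counts are tabulated (genes
missing from a DE table count as ns with a warning).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
it defines the study conditions for every test. Per phenotype, module genes
follow x_g = a·z + ε with a module-shared standard-normal factor z per sample
and ε ~ N(0, σ²), giving within-module correlation a²/(a²+σ²) and pairwise
Gaussian MI −½ln(1−ρ²) as exact oracles; non-module genes are independent
noise; values are emitted directly on the log₂ scale. Cross-phenotype overlap
is realized by explicit index sets (a shared core of c genes plus private
tails, Jaccard exactly c/(2s−c)), never by resampling. Programmed shifts are
added to the named phenotype's samples. Everything is bit-reproducible from
the design seed.

The benchmark design: 5 phenotypes (reference "Normal" + four tumor
subtypes), 2,000 genes, 100 samples each, 8 planted modules of 20–40 genes,
loading a = 1, residual σ = 0.7 (ρ ≈ 0.67). Six modules form cross-phenotype
families with pairwise Jaccards 1.0, 0.8, 0.667, 0.6, 0.5, and 0.316; two are
phenotype-private. Shared modules carry immune-style descriptions (so keyword
selection exercises the real path); private ones do not. Default decoys: 50
random 20-gene terms. DE truth: one family shifted +1.5 log₂ in all tumor
subtypes, the Basal-private module +1.5 in Basal, and 30 background genes
−1.5 in LumB. A reduced 3-phenotype / 600-gene / 60-sample variant
(`small_design`) backs the fast end-to-end tests and the worked example.

**What the generator does not emulate:** count noise and mean–variance
coupling of RNA-seq, library-size and batch effects, heavy-tailed or
nonlinear dependence, correlated background structure, and cell-type
composition. Passing recovery tests therefore demonstrates correctness of the
algorithms under a clean dependence model, not performance on real tumor
data, where MI values, network composition and community counts will differ.

## Problem sizes and numerical choices

Tests and the acceptance script run the benchmark at 2,000 genes × 100
samples (≈2M pairs per phenotype), MI calibration at n = 10,000,
planted-partition recovery on 100-node graphs over 10 seeds, exact-tail
verification for every hypergeometric configuration with N ≤ 60, and
empirical-Bayes recovery at 10,000 genes — sizes chosen so the full suite
completes in well under a minute of estimator time per stage on one CPU while
keeping every statistical check adequately powered. Convergence tolerance of
the optimizer is 1e-10 bits; oracle equivalences are asserted at 1e-12;
probability arithmetic is done with scipy's log-gamma-based distributions.
Degenerate cases are defined explicitly: constant genes (MI 0), both-empty
edge sets (edge Jaccard 0 with a degeneracy convention), empty modules
(rejected), zero-variance genes in DE (flagged, shrunk toward the prior).

## Known limitations

- MI magnitudes depend on the binning rule; they are comparable within a run,
  not across estimators, and are not expected to match other tools digit for
  digit. Rank-based binning discards marginal shape information.
- The greedy map-equation optimizer finds local optima; seeded restarts
  mitigate but do not eliminate this, and partitions from other
  implementations may differ in detail while agreeing structurally.
- Whether FDR should be controlled per community or globally is a modeling
  choice; per-community is the default here and the alternative is a
  one-line change on the result table.
- Connected-component clusters cannot overlap; a community bridging two gene
  families merges them if its links both exceed τ.
- The B statistic's fold-change prior uses a moment approximation (see
  above); B-based decisions match at the published threshold in all tested
  regimes, but B magnitudes are estimator-specific.
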