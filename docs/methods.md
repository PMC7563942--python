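# Methods

This note documents the statistical and algorithmic choices behind
`fflhub`: what each stage computes, the knobs that matter, what the
synthetic benchmark does and does not establish, and the known
limitations.

## Differential expression

The screen contrasts two patient groups on a gene × sample matrix of
log2 intensities. The default per-gene test is **Welch's t** (unequal
variances, Satterthwaite degrees of freedom) with a two-sided p-value;
a gene is a DEG when *p* < α strictly, α = 0.05 by default. Up/down
classification uses the sign of log2 fold change defined as case mean −
control mean; a significant gene with log2FC exactly 0 is classified as
neither (direction `none`), so `n_up + n_down ≤ n_deg` with equality
whenever no fold change is exactly zero.

The alternative `geo2r-compat` mode reproduces the empirical-Bayes
moderated t-test used by the GEO2R/limma lineage of microarray tools:
per-gene pooled variances s²_g (df d = n₁+n₂−2) are modelled as scaled-F
fluctuations around a prior variance s₀² with prior df d₀. The
hyperparameters are fitted by method of moments on log s²_g — the
expectation and variance of log s² under the model involve digamma and
trigamma functions, and d₀ is obtained by Newton inversion of the
trigamma function. Each gene is then tested with the shrunken variance
(d₀s₀² + d s²_g)/(d₀+d) on d₀+d degrees of freedom. When the observed
log-variance spread is no larger than its sampling noise, d₀ → ∞ and all
genes share s₀². `prior_df=0` recovers the ordinary pooled-variance t.
A unit test cross-checks the statistics against Bioconductor limma's
`lmFit`/`eBayes` on a 150-gene fixture (max |Δt| < 0.05).

Degenerate inputs: two constant equal groups give (statistic 0, p 1);
constant but unequal groups raise an error rather than report an
infinite statistic.

Presentation-layer statistics follow the conventions of expression
heatmaps: per-row z-scoring (ddof = 1, constant rows become zeros with a
warning) and hierarchical clustering with Pearson distance 1 − r and
complete linkage. The agglomeration is the naive O(n³) algorithm with a
deterministic tie rule — among equidistant pairs, the smallest (i, j)
cluster-index pair merges first — because the intended inputs are tiny
(top-10/20 DEG panels) and determinism matters more than speed; heights
are validated against scipy's implementation on tie-free data. Group
comparisons of individual genes use the Wilcoxon rank-sum test: exact by
full enumeration of all C(n+m, n) group assignments (midranks under
ties) when n+m ≤ 12, otherwise the tie-corrected normal approximation
with continuity correction (within 0.02 of exact at 8 vs 8).

## PPI graph and centrality-based hub call

Interactions are kept when their combined confidence score is **strictly
greater than 0.9** (a score of exactly 0.9 is dropped). The graph is
simple and undirected: self-pairs are removed, duplicate pairs collapse
to the maximum score, and whitelisted genes without surviving
interactions remain as degree-0 nodes so that every DEG has a defined
rank. In the end-to-end pipeline the whitelist is the set of called DEGs
restricted to identifiers present in the interaction export (an export
only covers the proteins that were queried).

All six centralities are computed from first principles on the adjacency
structure (clique enumeration is delegated to networkx's maximal-clique
generator):

* **MCC** — Σ (|C|−1)! over maximal cliques containing the node, singleton
  cliques excluded, so isolated nodes score 0 and edgeless graphs never
  outrank connected structure.
* **EPC** — seeded Monte-Carlo percolation: per replicate draw a global
  threshold τ ~ U(0,1) and one uniform per edge, keep edges with u ≥ τ,
  and average the number of other nodes left in the node's component.
  1000 replicates by default; the acceptance suite validates the
  estimator against exact expectations obtained by edge-subset
  enumeration (the survival probability of a k-edge subset integrates to
  the Beta integral k!(m−k)!/(m+1)!).
* **Closeness** — harmonic form, robust to disconnected graphs.
* **Betweenness** — unnormalised, endpoints excluded (Brandes
  accumulation); normalisation is irrelevant for rank-based top-k lists.
* **Bottleneck** — per root, a BFS shortest-path tree with the
  deterministic parent rule "smallest node id among same-level
  candidates"; a node scores one point per root whose tree gives it a
  subtree strictly larger than a quarter of the tree's node count. The id
  tie-break trades label invariance for reproducibility: relabelling a
  graph can change parent choices, which is why the symmetry tests cover
  the other five measures only.
* **Radiality** — distances reweighted by the component diameter,
  averaged over the component; singleton components score 0.

Top-k lists (k = 10) sort by score descending, node id ascending, so
each list has exactly k members and Venn-region arithmetic over the six
lists stays defined. The hub call is the six-way intersection.

## Regulatory network and FFL mining

The miRNA→gene table passes two screening tiers: per-row binding
evidence (region `3UTR`, binding gap 1, score ≥ 0.95 — inclusive) and
then per-pair consensus across TargetScan, miRDB and miRTarBase, the
surviving pair consolidated into one edge. TF→gene edges require the
disease-curation flag (the flag models a manual literature call and is
carried per row). miRNA→TF edges carry no binding columns in the
emulated exports and are only deduplicated. The merged network is a
typed directed graph; TF→TF rows are dropped with a logged count, and
any identifier claimed by two roles is an error.

A feed-forward loop is a closed triad m→t, m→g, t→g. "Degree" for the
top-subnetwork ranking is the sum of the three members' total (in+out)
degrees in the merged network — the natural node-degree reading — with
lexicographic tie-breaking; the definition is echoed in the run report's
`degree_definition` field. In the pipeline, gene-directed regulatory
edges are first restricted to the hub genes the pipeline actually
called, mirroring the workflow in which regulatory databases are queried
for hub genes only (so an empty hub call yields an empty, but valid, FFL
stage).

## Seed matching

Sites are classified canonically: the UTR window complementary to miRNA
nt 2–7 (antiparallel, so the window read 5'→3' is the reverse complement
of the seed) is a 6mer; a match to nt 8 immediately 5' of the window
and/or an adenosine immediately 3' of it upgrade the site to 7mer-m8,
7mer-A1 or 8mer, each core reported once under its strongest type.
Coordinates are 0-based half-open internally and 1-based inclusive in
reports. G:U wobble pairing is off by default and never applies to the
position-1 A, which is an identity requirement on the UTR. No
thermodynamic, conservation or 3'-supplementary scoring is attempted.

## Synthetic data: what it emulates, and what it does not

The generator mimics the *shapes and filters* of the emulated study's
inputs, with planted structure for verification. All randomness derives
from one seed through independent per-table substreams, so adding or
resizing one table never perturbs another, and identical configurations
are byte-identical.

* **Expression** (defaults: 2000 genes, 13 cases vs 21 controls):
  baseline log2 intensities ~ Normal(8, 2); per-gene noise sd ~
  U(0.5·σ, 1.5·σ) with σ = 0.5; 10% of genes shifted ±1.5 log2 units in
  the case group (sign recorded). The sizes mirror the emulated cohort
  (34 samples, ≈200 expected true signals); the distributions themselves
  are stand-ins — the study's raw data distributions are not described —
  so calibration results (null false-positive rate ≈ α, power ≈ oracle)
  validate the *testing machinery*, not any particular microarray
  platform. No probe-level artifacts, normalisation or batch effects are
  simulated.
* **PPI** (defaults: 60 nodes, 5-clique): background topology is
  Barabási–Albert preferential attachment with 1 edge per incoming node
  (a high-confidence interaction export is sparse); the designated clique
  occupies the earliest (highest-degree, lowest-id) positions and its
  pairs are fully connected with scores U(0.92, 1.0); background edges
  score U(0.40, 0.95), so ≈9% of them survive the 0.9 cut and the clique
  must be recovered against clutter.
* **Regulatory tables**: each planted (miRNA, TF, gene) triple
  contributes its three edges, the miRNA→gene edge carrying full binding
  evidence under all three databases. Planted triples are sampled with a
  closure check so no *emergent* (unplanted) triad arises from their
  union — triad precision and recall of 1.0 are therefore by
  construction, and tests that assert them are testing the filters and
  the enumerator, not luck. Each decoy edge violates exactly one
  criterion (region, gap, score, consensus, or TF flag), cycling through
  the five kinds, so a filter bug is diagnosed by which decoy class
  leaks through.
* **Sequences**: a random 22-nt miRNA and a 500-nt UTR with one spliced-in
  8mer site at a recorded offset.

## Known limitations

* **Bottleneck vs planted cliques.** Inside a complete clique component
  every BFS subtree has size 1, which never exceeds a quarter of the
  tree: members of an isolated clique score 0 bottleneck regardless of
  how strong the clique is. Real hub proteins sit inside large sparse
  components where the measure behaves sensibly, but in the synthetic
  benchmark the planted clique reaches the bottleneck top-10 only
  through id tie-breaks or chance pendant edges. Consequently the
  six-way intersection recovers ≥4 of 5 planted nodes in roughly 70–85%
  of network seeds, not near-always; the five other measures recover
  the clique essentially always. The benchmark reports this rate
  honestly rather than redesigning the generator to hide the effect.
* The moderated-t hyperparameter fit assumes enough genes (≥10; in
  practice hundreds) for the log-variance moments to be stable.
* The exact Wilcoxon path enumerates C(n+m, n) assignments and is capped
  at n+m = 12; beyond that the normal approximation is used.
* EPC is a Monte-Carlo quantity; two runs agree only when given the same
  seed and replicate count (both are recorded in the run report).
* The pipeline consumes table exports; it neither queries web services
  nor re-implements their scoring, and the TF literature-curation step
  is modelled as an input flag, not text mining.
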