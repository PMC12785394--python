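# Methods

## Proteome representation

A protein is the vector p = (p_1 … p_n) of its k-mer type frequencies,
p_i = c_i / Σ_j c_j, where c_i counts overlapping windows of length k
(step 1) and n = |A|^k. The alphabet A is either the 20 canonical amino
acids in the fixed order `ACDEFGHIKLMNPQRSTVWY` or the 5-symbol
physicochemical reduction (aliphatic `AILMPV`, aromatic `FWY`, uncharged
`CGNQST`, positive `HKR`, negative `DE`, in that symbol order). The
k-mer index is lexicographic over the declared alphabet order, so vector
layouts are stable across runs.

A proteome vector pools raw counts over its m proteins before
normalizing: P_i = Σ_j c_ij / Σ_i Σ_j c_ij. This is length-weighted and
deliberately *not* the mean of per-protein vectors; the two differ
whenever protein lengths differ. Group-restricted vectors (membrane,
ribosomal, nucleotide-binding, or their complements) pool over the
selected subset only.

Windows containing any character without a position in the alphabet —
the rare residues U/O, ambiguity codes X/B/Z, gaps, stops — are skipped
entirely. The choice to extend the filter beyond U/O to every
non-canonical code is this package's own: real UniProt FASTA contains
them and a window with an untyped residue has no well-defined k-mer
type.

k is supported in 1–4 but capped with a warning at 4: a 20-letter
alphabet has 160,000 4-mer types, and a typical bacterial proteome of
~1.35 M residues averages only ≈ 8.4 occurrences per type, so 4-mer
frequency estimates are dominated by sampling noise (the package's
arithmetic check reproduces this).

## Distances

Four families, all operating on frequency vectors of the same space:

* generalized Minkowski d(p,q) = (Σ_i |p_i − q_i|^b)^(1/a); a=b=1 is L1
  (bounded by 2 on probability vectors), a=b=2 is L2. Other (a,b) are
  accepted but untested territory.
* correlation distance (1 − r)/2 with r the Pearson correlation of the
  two value sequences; range [0,1]; undefined (error) for a constant
  vector.
* intersection distance 1 − |P_a ∩ Q_a|/s over the top-s most frequent
  k-mer types of each vector, s = round(a·n) (half-up). Stored as a
  dissimilarity so it plugs into distance-based clustering; ties at the
  cutoff frequency break by ascending k-mer index, making top sets (and
  hence the distance) deterministic.

## Clustering and evaluation

Agglomerative clustering recomputes single/average/complete linkage
from the full distance matrix each round (no Lance–Williams updates);
ties break on the lexicographically smallest pair of cluster
representative labels (minimum member label), so the dendrogram is
invariant to input order. Heights are the linkage distance at each
merge. O(n^3) cost is irrelevant at ≤ a few hundred proteomes.

The dendrogram is converted to a flat clustering with a dynamic program
that maximizes the Rand index against the reference classification over
all tree-consistent partitions (every cluster is the full leaf set of
one node). Writing gain(v) = (same-class pairs) − (different-class
pairs) within v's leaves, the recursion is score(leaf) = 0,
score(v) = max(gain(v), score(left) + score(right)), collapsing v into
one cluster when gain(v) ties or beats its children (ties merge, so
same-class siblings always share a label). The optimal Rand then equals
(score(root) + D)/C(N,2), with D the number of different-class pairs —
an identity the tests verify on every instance, alongside exhaustive
enumeration of all tree-consistent partitions on trees of ≤ 12 leaves.

Because this conversion is Rand-optimal for *any* tree, even random
trees score high (every mismatched leaf can be split into its own
cluster, converting would-be false positives into true negatives).
Significance is therefore calibrated against a null of uniform random
binary trees, generated by joining two uniformly chosen live roots
until one remains — an exchangeable join process chosen because the
source of the trees states no particular distribution; the topology law
affects the null mean only weakly for small classes, and the seed is
exposed. Each tree is flattened optimally and scored; the samples are
fitted with a maximum-likelihood location-scale Student t and the 95%
right-tail critical value reported. At study scale (86 organisms, 18
clades of 3–6) the null mean is ≈ 0.954 with sd ≈ 0.0003, and a t null
with mean 0.9544, sd 0.0003 and df 8.14 puts the 5% critical value at
0.9549 (the sd is converted to the t scale parameter via
scale = sd·√((df−2)/df); using the sd as the scale directly would give
0.9550). On our samples the MLE df is large (the distribution is close
to a discretized normal), so the parametric and empirical tail p-values
are both reported.

## Composition analyses

`common_abundant_kmers` takes each vector's top round((I_t/100)·n)
types and keeps those present in at least ceil((I_c/100)·N) of the N
top sets; the count is monotone in both thresholds and reduces to a
plain set intersection at I_c = 100.

Within-group distance D_i is the mean over unordered distinct pairs,
2·Σ_{p<q} d(p,q)/(N_i(N_i−1)); between-group D_ij averages over all
N_i·N_j cross pairs. The separation margin (m2 − σ2) − (m1 + σ1)
(means/SDs taken over groups resp. group pairs) is positive when
between-group distances exceed within-group distances even after moving
one standard deviation toward each other. The same machinery serves
clade separability of proteome vectors and functional-group
separability of protein vectors.

## Synthetic panel generator

The generator emulates a multi-clade bacterial panel with known ground
truth. Per clade it draws a stationary amino-acid distribution and a
20×20 first-order transition matrix from Dirichlet priors centered on
uniform; the concentration is `clade_divergence`·20 (default divergence
10), so larger values shrink all clades toward a common composition.
Transition rows are centered on the clade stationary. First-order
Markov generation (not i.i.d. residues) is what gives 2-/3-mer
frequencies clade signal beyond single-residue composition. Functional
groups re-weight residues (membrane ×2 on `AILMPVFWY`, ribosomal ×2 on
`HKR`, nucleotide-binding ×1.5 on `GTK`) so group-level analyses have
signal; group labels occupy fixed fractions of each proteome (defaults
0.2/0.1/0.15).

One ancestral proteome is sampled per clade; each organism is a copy in
which every residue independently mutates with probability μ (default
0.05) to a draw from the clade stationary distribution. There are no
indels and no within-clade tree structure — organisms are exchangeable
mutated copies — which keeps ground truth exact and is sufficient for
k-mer composition tests. Defaults are 6 clades × 4 organisms, 300
proteins of 150–250 residues; `organisms_per_clade` accepts a range
(e.g. (3, 6)) to emulate unbalanced designs.

Two consequences worth knowing. First, because mutations resample from
the clade's own stationary distribution, clade identity survives even
μ = 1 (organisms become i.i.d. draws from the clade model); under the
default divergence the pipeline's Rand stays at 1.0 across
μ ∈ {0.02 … 0.6}, so the monotone-degradation property holds trivially
there — degradation below 1.0 requires weaker clade divergence.
Second, the generator omits real-proteome features — shared core genes,
homology across clades, length/composition heterogeneity, annotation
noise — so passing tests demonstrate correctness of the machinery and
recoverability of planted structure, not field performance on real
proteomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the null model at its full
10,000 trees (≈ 15 s), the flattening optimality check on 200 random
trees of 4–12 leaves against exhaustive enumeration, and the recovery
sweep over μ ∈ {0.02, 0.1, 0.3, 0.6} × 5 seeds at the default panel
size. Frequency vectors sum to 1 within 1e-9 (all-zero when a sequence
yields no valid window, e.g. only non-canonical residues). Empty group
selections, constant vectors under correlation, overlapping clusters,
and top sets that round to zero members raise errors rather than
returning degenerate values. All randomness flows through
`numpy.random.Generator` seeds recorded in every report.
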