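# Methods

This note documents the models, conventions and design choices behind
oudphylo, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signatures

**Definition.** For a transcriptome of total length *L* (sum of transcript
lengths, N bases included) and word size *k*, the signature component for
k-mer *z* is `OUD(z) = (N(z) − E1(z)) / E0(z)` with `E0(z) = (L − k)/4^k`
and `E1(z) = (L − k) · Π_j p(z_j)`, where `p` are mononucleotide frequencies
pooled over the whole transcriptome (N bases excluded).  Subtracting the
i.i.d. expectation removes the bulk composition (GC content) signal;
dividing by the uniform expectation makes the vector dimensionless and
roughly length-independent.

**Window convention.** `E0` and `E1` both use the literal `(L − k)` window
factor of the per-transcriptome definition, deliberately ignoring the
`k − 1` windows lost at each transcript boundary and windows skipped for
containing N.  The discrepancy is O(#transcripts · k / L); the true number
of counted windows is recorded on `KmerCounts.n_windows` for diagnostics.
Fidelity to the printed definition was preferred over internal elegance.

**Counting.** Windows never span transcript boundaries; any window
containing N is skipped.  Ingestion maps lowercase→uppercase, U→T and IUPAC
ambiguity codes→N; non-alphabetic residues are an error naming the record
and position.  k-mers are indexed lexicographically with A<C<G<T (index =
base-4 integer), fixed so bootstrap column resampling is reproducible.
Default strand policy is forward-only (stranded mRNA assemblies); a
canonical policy (count `min(w, revcomp(w))`) is available since k-mer
counters differ in this setting.

**Null models.** The default null is the i.i.d. mononucleotide model (E1).
A first-order Markov alternative is provided (`E(z) = (L − k) · p(z₁) ·
Π p(z_j | z_{j−1})`, transitions from pooled dinucleotide counts); it
removes dinucleotide as well as mononucleotide structure and is offered as
a variant, not the default.  If `E1(z) = 0` (absent base) and `N(z) = 0`
the component is 0; `E0 > 0` whenever `L > k`, so no division by zero is
possible.  Inputs with `L ≤ k` are rejected.

## ORF modes

Mode B reduces each component (Trinity's gene-level grouping; isoform
suffixes `_i<N>` and `_seq<N>` are stripped, any other id is its own
component) to its single longest ORF.  ORFs are stop-to-stop maximal codon
runs over all six frames, open ends allowed at sequence boundaries, with
the terminal stop codon included in the span; an ATG anchor is optional
(`require_start`).  The default minimum length is 300 nt (100 codons), the
conventional long-ORF threshold.  Codons containing N break a run (no codon
call is possible).  Length ties are broken deterministically: forward
strand before reverse, lower frame number, leftmost start, then source
transcript id.  Mode C further restricts mode-B CDS to gene ids present in
every strain's membership rows and fails loudly if the intersection is
empty.

## Distances, UPGMA and bootstrap

Signatures are compared by plain Euclidean distance.  UPGMA merges the pair
of clusters at minimal average-linkage distance, the merged node sitting at
half the merge distance, so trees are ultrametric by construction (checked
to 1e-9 in tests).  Among exactly equal minima the pair whose
(smaller, larger) representative labels — a cluster's representative is its
lexicographically smallest leaf — sort first is merged, making results
platform-independent.

Bootstrap replicates resample the `4^k` signature components with
replacement, applying the **same index multiset to every strain**, then
rebuild distances and the UPGMA tree.  Sharing the column multiset is the
only resampling under which replicate signatures remain comparable across
strains; it is an interpretation of "bootstrapping the deviations before
distance and tree calculation" and is stated here prominently because other
readings (per-strain independent resampling) would not yield comparable
columns.  Support of a reference bipartition is the percentage of
replicates containing it, computed on the non-trivial bipartitions of the
unrooted view (pendant and root-spanning splits excluded, canonical form =
smaller block, ties lexicographic).  Rooted trees can be re-rooted on an
outgroup's pendant edge; this leaves the bipartition set, and hence
supports, unchanged.

Newick output stores supports as internal node labels and branch lengths
with 17 significant digits.  Full float precision was chosen over a
6-digit convention so that read(write(tree)) preserves heights exactly and
two runs of the pipeline produce byte-identical files; determinism was
judged more valuable than compact output.

## Functional profiling

*Gene content*: a gene is "present in a group" iff at least one strain of
the group carries it (the presence rule is a package decision; a
stricter all-strains rule is easy to emulate by pre-filtering the table).
Exclusive genes occur in exactly one group, core genes in all groups.

*Enrichment*: hypergeometric upper tail `P(X ≥ x)` for overlap `x` between
a selected gene set (size `n`) and a pathway (size `K` after intersecting
its members with the declared universe, size `N_u`); `x = 0` gives exactly
`p = 1`.  The universe is the set of genes detected in at least one
compared strain (configurable).  Benjamini–Hochberg step-up adjustment is
applied across pathways.  Typical thresholds: 0.001 for gene-content
enrichment, 0.1 for expression-derived gene sets.  Note that BH adjustment
is monotone but **not** idempotent (re-adjusting adjusted values can change
them, e.g. (0.1, 0.3) → (0.2, 0.3) → (0.3, 0.3)); only single application
is meaningful.

*Module completeness*: a pathway module is `complete` if at most one
required enzyme is missing, `partial` if more than one is missing but the
designated core subset is intact, `missing` otherwise.  A structural
complex is `complete` if strictly more than half of its constituent modules
are complete, `missing` if none is, `partial` otherwise; the exact-half
case is assigned to `partial` because the defining green/blue colour rules
("majority" vs "less than half") leave it open, and the middle class is the
conservative choice.  Pathway and module definitions are user-supplied
TSVs; no database is queried.

## Synthetic data

The simulator generates the structure the method assumes about real data:

* a random coalescent-style ultrametric tree (exponential waiting times,
  rescaled so the root sits at `tree_depth`), or a user tree;
* root genes built as ATG + random sense codons + stop;
* Jukes–Cantor evolution along branches using the exact JC transition
  kernel `P(change) = 3/4 · (1 − exp(−4/3 · rate · t))` per branch, which
  composes to the true multiple-hit JC process (saturation identity 25%);
* Trinity-style components with 1..`max_isoforms` isoforms per gene
  (isoform 1 is the full gene, others are prefix/suffix truncations — never
  novel sequence, so longest-ORF selection can recover the gene);
* optional per-taxon gene loss, per-taxon GC shift (biased resampling of
  third codon positions, skipping changes that would create a stop) and
  planted group-exclusive genes for functional-profiling tests.

Defaults are the package's reference study conditions: 8 taxa, 200 genes of
900 nt, tree depth 1.0, rate 0.05 substitutions/site/unit height (root-to-
leaf expected difference ~5%, deepest leaf pairs ~9.5%), no loss, no GC
shift, up to 3 isoforms.  What the simulator does **not** emulate:
sequencing error, assembly fragmentation/chimerism, indels, expression
variation, selection.  Passing recovery tests therefore demonstrate correct
behaviour under clean tree-structured divergence, not robustness to
assembly artefacts.

## Resolution of the signature tree, and a known limitation

Between two leaves coalescing at height *h*, the expected squared signature
distance grows approximately linearly in *h*, and its relative fluctuation
is of order `sqrt(2/4^k)` — a property of the signature dimension, not of
the sequence length: both the tree signal and the fluctuations arise from
the same mutational randomness and scale identically with the amount of
sequence.  At k = 4 (256 components, ≈9% relative spread) internal branches
whose relative height gap is below roughly that spread are frequently
unresolvable no matter how much sequence is available; k = 6 (4,096
components) quarters the spread.  Consequently, on coalescent trees —
which routinely contain short internal branches — perfect topology recovery
at k = 4 fails in a substantial fraction of simulations even under the
reference conditions, while k = 6 recovers most of them.
`scripts/acceptance.py` computes both rates; the acceptance suite's k = 4
recovery test documents this limit by failing honestly rather than by
relaxing the conditions.

A second documented property (not a hard test): a strong GC shift applied
to a single taxon attracts it toward GC-similar clades — composition can
override phylogeny, which is exactly the failure mode expected of any
composition-based signature method and a reason to prefer mode B and to
inspect GC content alongside the tree.

## Problem sizes used in the checks

Oracle-agreement checks use 50 random transcript sets of total length
≤ 5,000 at k ∈ {2, 4, 6} against a naive substring-scan + direct-formula
oracle (agreement to 1e-12).  UPGMA is validated on cophenetic matrices of
100 random ultrametric trees with 4–16 leaves (exact topology, heights to
1e-9) and cross-checked against an independent average-linkage
implementation.  Topology recovery uses 20 simulated datasets under the
reference conditions.  Enrichment p-values are checked against exact tail
enumeration for universes up to 60 genes.
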