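# Methods

## Problem and approach

Regional trait data (one bounded value per province, e.g. the proportion of
cultivated land under rice) are tested for association with historical
relatedness, proxied by lexical distance between the language varieties
spoken in each province. The analysis is a chain of standard
cultural-phylogenetics steps: variety-level lexical distances → averaging
into a province-level matrix → a permutation Mantel test against the
province trait-difference matrix → a distance-based tree for inspection of
the historical structure. A significant Mantel correlation means the trait
carries phylogenetic/contact signal, i.e. province-level samples cannot be
treated as independent (Galton's problem).

## Lexical distances

**Levenshtein / LDN.** Words are compared as sequences of Unicode code
points after NFC normalization; no segmentation into multi-character sound
symbols is attempted, which keeps the comparison deterministic and
database-agnostic. `LDN(a,b) = lev(a,b)/max(|a|,|b|) ∈ [0,1]`. The distance
between two varieties is the mean per-concept LDN over shared concepts;
when a concept has synonyms, the per-concept value is the **minimum** LDN
over all cross-variety form pairs, so synonymy never inflates distance.

**LDND.** The variety-level LDN is divided by the mean LDN over all
cross-meaning form pairs of the *same* variety pair (every form for concept
i in one variety against every form for concept j ≠ i in the other, both
concepts shared). Two varieties with similar phoneme inventories have
cross-meaning LDN well below 1, and dividing by it removes that chance
component; values may exceed 1. The normalizer is per-pair, not global.
Degenerate cases raise: no shared concepts, fewer than two shared concepts
(no cross-meaning pairs), or a zero cross-meaning mean.

**Cognate-sharing distance.** With expert or automated cognate coding taken
as input, each shared concept counts as cognate when the two varieties'
cognate-class sets for it intersect; the distance is one minus the cognate
proportion, giving a dissimilarity in [0,1] comparable to the other
measures. Computing a *proportion* (rather than a raw shared-cognate count)
makes the measure independent of wordlist length.

Full matrices run through a numba-compiled kernel (the pure-Python
single-pair functions are the tested reference); at 139 varieties × 40
concepts the LDND matrix takes a few seconds.

## Aggregation

Province distance = arithmetic mean of variety distances over all
cross-province pairs; within-province pairs are excluded (they describe
internal diversity, not between-province separation). Trait difference =
|t_P − t_Q|, the absolute difference so the result is a valid
dissimilarity. Provinces lacking either lexical or trait data are dropped
before testing (complete-case analysis) and listed in the run report.

## Mantel test

Observed statistic: Pearson correlation of the n(n−1)/2 strictly-upper
triangle entries (Spearman available via `method="spearman"`). Null:
rows and columns of one matrix jointly permuted. The sampled test draws
permutations uniformly with replacement and applies the add-one correction
p = (1 + hits)/(1 + n_perm), which keeps the test exactly valid and p > 0.
Ties are counted as hits, with a 1e-12 slack against float noise. The
default tail is one-sided "greater" because the scientific hypothesis is a
positive association (similar traits ↔ similar vocabularies); the tail is
recorded in every report. `mantel_exact` enumerates all n! relabelings
(n ≤ 8, identity included, no correction) and serves as the small-n oracle.
Default permutation count is 10,000.

## Clustering

UPGMA: iteratively merge the two clusters with minimal average
inter-cluster distance (Lance–Williams update), merge height =
distance / 2, so an ultrametric input is reproduced exactly and the output
tree is ultrametric by construction. Ties are broken on the
lexicographically smallest pair of cluster representative labels, and a
merged node's children are ordered by representative label — output is
identical across platforms. Single and complete linkage sit behind a flag;
average linkage is the default because the input distances are themselves
averages and the analysis calls for a rooted tree. Top-k branches = leaf
sets after undoing the k−1 highest merges. Newick serialization writes
branch length = parent height − child height and quotes labels that need
it; "branch lengths" of the default tree are merge-height differences, not
evolutionary time.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with each stage seeded and deterministic:

* **Tree** — pure-birth (Yule) topology: lineages split after
  Exp(1/k) waiting times, the tree is cut when n tips exist plus one more
  exponential interval, and heights are rescaled to root height 1. This is
  the simplest scaffold consistent with a tree of descent.
* **Lexicon** — one ancestral word per concept (length uniform on 3–7,
  symbols uniform over the first `alphabet_size` letters). Per branch of
  length t: each symbol substitutes with probability `mutation_rate·t`;
  each concept is replaced by a fresh word and a globally fresh cognate
  class with probability `replacement_rate·t`. Two leaf forms share a class
  iff they descend from the same replacement event.
* **Borrowing** — optional horizontal transfer on a ring over leaf order
  (a 1-D abstraction of geographic adjacency; leaf order is tree order, so
  neighbours tend to be relatives). Each (variety, concept) copies form and
  class from a ring neighbour with probability `borrowing_rate`; events are
  applied sequentially and logged, so the log replays exactly.
* **Trait** — Brownian motion on the same tree from root liability 0 with
  variance `trait_step_variance` per unit branch length; leaf values are
  logistic-squashed into [0,1]. Province trait = mean over member
  varieties.
* **Provinces** — the k clades under the k−1 deepest splits, i.e.
  phylogenetically contiguous groups, mirroring how real provinces contain
  related varieties.

Defaults: 40 varieties, 18 provinces, 100 concepts, alphabet 10, mutation
0.3, replacement 0.25, borrowing 0, trait variance 1.0, chosen so a full
dataset simulates in well under a second while giving distances in the
informative range (cognate distances roughly 0.1–0.4 between provinces).
The 139-variety configuration used for the larger study shape pairs with
40 concepts, the length of the short standardized wordlists typical of
large cross-linguistic databases.

What the generator does **not** model: realistic phonology or sound-change
typology, semantic shift, synonym birth (each simulated variety has one
form per concept; the analysis code handles synonyms, the generator does
not produce them), population contact beyond the ring, or any causal
trait–lexicon link. Passing tests on synthetic data therefore show the
pipeline's statistical behaviour under a clean vertical-descent model, not
that real lexical databases meet these assumptions.

## Numerical and design notes

* Matrix files are square labeled TSV; floats are written at full repr
  precision and parsed with round-trip precision, so write→read is exact.
  Read-side symmetry and zero-diagonal tolerance is 1e-9, after which the
  matrix is exactly symmetrized.
* Wordlist parsing sorts varieties and per-concept forms, making results
  invariant to input row order.
* The Mantel permutation loop precomputes the centred first vector and
  exploits that the condensed multiset of the permuted matrix is
  invariant, so only one dot product per permutation is needed.
* Group-level Mantel power against a Brownian trait is intrinsically
  modest: each province pair contributes a single half-normal draw
  |ΔBM|, so the trait-vs-tree correlation is noisy (median Mantel r ≈ 0.17
  at 18 provinces under the defaults) and the confound fires in roughly
  half of replicates rather than nearly always. The reshuffled-trait
  control stays at the nominal 5%.
* Monte Carlo test sizes (replicate counts, permutation counts, tree
  sizes) are chosen to keep the full suite in a few minutes on one core
  while leaving comfortable statistical margins.

## Limitations

Distances, not likelihoods: no model-based phylogenetic inference, no
branch support, no partial Mantel or phylogenetic regression controls —
the package quantifies and demonstrates non-independence; it does not
correct an observed trait–trait correlation for it. County-level analyses
and external database acquisition are out of scope.
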