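# galtonlex

Cultural traits measured across regions are rarely independent samples:
neighbouring populations inherit practices from common ancestors and borrow
them through contact, so trait–trait correlations can be inflated or entirely
spurious — the classic *Galton's problem* of cross-cultural statistics.
`galtonlex` tests a bounded regional trait (the motivating case is the
proportion of cultivated land under rice paddies across Chinese provinces)
for exactly this kind of historical signal, using language as the proxy for
shared history: varieties that split recently, or that are in close contact,
have more similar vocabularies.

The package is aimed at quantitative linguists and cultural-evolution
researchers. It provides:

* **Lexical distances** between language varieties from long-format
  wordlists:
  * *cognate-sharing distance* — `1 − |{shared concepts whose cognate-class
    sets intersect}| / |{shared concepts}|`;
  * *LDN* — Levenshtein distance normalized by the longer word,
    `LDN(a,b) = lev(a,b) / max(|a|,|b|) ∈ [0,1]`, averaged over shared
    concepts (minimum over synonym pairs per concept);
  * *LDND* — LDN divided, per variety pair, by the mean LDN over all
    cross-meaning word pairs, correcting for chance similarity between
    sound inventories.
* **Province aggregation** — the distance between two groups is the mean
  variety-level distance over all cross-group pairs; the trait enters as the
  matrix of absolute differences `|t_P − t_Q|`.
* **Mantel permutation tests** — Pearson correlation `r` of the two
  condensed matrices, with the null distribution from jointly permuting rows
  and columns of one matrix; sampled p uses the add-one correction
  `p = (1 + hits)/(1 + n_perm)`, and an exact `n!` enumeration is available
  for small matrices.
* **UPGMA trees** — average-linkage clustering of any distance matrix into a
  rooted ultrametric tree (merge height = distance/2), top-*k* branch
  extraction, Newick export.
* **A synthetic-data generator** — coupled lexicon + trait evolution on a
  shared pure-birth tree (symbol mutation, cognate replacement, optional
  ring-neighbour borrowing, Brownian trait with logistic squashing), so the
  whole pipeline — and the confound itself — can be demonstrated without any
  external database.

## Worked example

Simulate a study at the default scale (40 varieties, 18 provinces, 100
concepts) and analyse it with both lexical measures:

```sh
galtonlex simulate --seed 11 --outdir sim
galtonlex run --wordlists sim/wordlists.tsv --groups sim/groups.tsv \
  --traits sim/traits.csv --measure cognate --measure ldnd \
  --permutations 10000 --seed 42 --outdir out
```

which prints

```
cognate: r = 0.1700, p = 0.0426 (10000 permutations, tail=greater)
ldnd: r = 0.0589, p = 0.2227 (10000 permutations, tail=greater)
report: out/report.json
```

The simulated trait is causally unrelated to the lexicon — the two share
only the tree they evolved on — yet the cognate-based Mantel test comes out
significant at the 5% level: provinces with similar rice proportions have
measurably more similar vocabularies purely through common descent. That is
Galton's problem in action; across replicates roughly half of such runs
reject at α = 0.05 (the per-run outcome varies, as the weaker LDND line of
this same run shows), while reshuffling the trait across provinces restores
the nominal 5% rate. `out/report.json` records every parameter, seed,
dropped group and intermediate file; `out/cognate_tree.nwk` holds the UPGMA
tree of the 40 varieties with its top four branches labelled in
`out/cognate_clusters.tsv`.

A library session for the same analysis:

```python
import galtonlex as gx

out = gx.make_dataset(gx.SimulationConfig(seed=11))
report = gx.run_analysis(out.wordlists, out.group_map, out.trait_table,
                         measures=("cognate",), n_perm=10_000, seed=42)
print(report.results["cognate"].mantel)
```

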