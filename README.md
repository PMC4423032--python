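# herbnet

Coherent **herb–compound–target–disease** network analysis for multi-herb
prescription corpora.

Traditional-medicine practitioners prescribe individually tailored formulae
of 15–30 herbs, so a corpus of hundreds of prescriptions hides its
regularities: which herbs form recurring pairs and cores, whether those
cores act synergistically at the molecular level, and how they relate to
the biology of the treated disease and to conventional drugs. `herbnet`
implements that analysis as a tested, reusable pipeline for systems-biology
researchers working with prescription corpora, together with a
synthetic-data generator that emulates such a study end to end with planted
ground truth, so every stage is verifiable offline.

## The methods at the core

**Herb-pair mining (distance-weighted mutual information).** For herbs
*x, y* with prescription-level occurrence probabilities,

```
score(x, y) = MI(x, y) / d(x, y)
MI(x, y)    = P(x,y) · log2[ P(x,y) / (P(x) P(y)) ]   (clamped at 0)
d(x, y)     = mean |pos(x) − pos(y)| over co-occurring formulae
```

The positional distance uses the traditional ordering of a formula
(principal herbs first), so herbs written close together count as more
related. Two core networks are built from these scores: the
*high-frequency network* (top-frequency herbs, significant co-occurrence
edges) and the *intersection network* (node-and-edge intersection of each
top herb's seed subnetwork).

**Target-profile prediction (structure × interactome concordance).** A
compound's score for protein *p* is the Pearson correlation between its
Tanimoto structure-similarity vector over reference drugs and *p*'s
closeness vector to those drugs' targets on the PPI network
(`exp(−shortest path)` decay). The top *K* = 100 proteins form the
compound's target profile; proteins hit by more than five of a herb's
compound profiles are the herb's targets.

**Multicomponent synergy (network topology × agent score).** Node
importance is the min–max-normalized mean of betweenness, closeness and
PageRank on the disease background network; the topology score of two
target sets is the symmetrized importance-weighted mean of
`exp(−distance to the nearest member of the other set)`, and the total
synergy is topology × agent score (phenotype cosine similarity, 1 when no
phenotype data exist). Herb-pair synergy is the mean over cross-herb
compound pairs.

**Functional overlap and drug bridging.** Herb target sets and disease
genes are tested for term enrichment (upper-tail hypergeometric,
Benjamini–Hochberg) against flat gene-set annotations, and their enriched
terms intersected. Compounds and reference drugs are linked into a bridge
network whenever their targets overlap or are adjacent on the
disease-restricted interactome; cluster composition is tested for
herb-property ↔ drug-class association (one-sided Fisher, BH-corrected).

## Worked example

```python
from herbnet import (GeneratorConfig, generate_dataset, normalize_corpus,
                     frequency_table, top_k_herbs)
from herbnet.dmim import (CorpusIndex, high_frequency_network,
                          seed_subnetwork, intersect_subnetworks)

ds = generate_dataset(GeneratorConfig(seed=0))
corpus = normalize_corpus(ds.raw_corpus, ds.lexicon)
print(f"{len(corpus)} prescriptions over "
      f"{len({h for p in corpus for h in p.herbs})} herbs, "
      f"mean size {sum(len(p) for p in corpus)/len(corpus):.2f}")

ft = frequency_table(corpus)
top10 = top_k_herbs(ft, 10)
index = CorpusIndex(corpus)
hfn = high_frequency_network(index, top10)
core = intersect_subnetworks([seed_subnetwork(index, s) for s in top10])
print(f"high-frequency network: {hfn.number_of_nodes()} nodes, "
      f"{hfn.number_of_edges()} edges")
print(f"core intersection network: {core.number_of_nodes()} nodes")
```

prints

```
871 prescriptions over 343 herbs, mean size 17.94
high-frequency network: 10 nodes, 45 edges
core intersection network: 14 nodes
```

i.e. synonym normalization recovers the full 343-herb vocabulary from the
871 noisy prescriptions; the ten most frequent herbs are so strongly
co-prescribed that all 45 possible pairs are significant; and intersecting
the ten seed subnetworks isolates the planted 14-herb core (the ten top
herbs plus the four-herb sub-formula planted by the generator).

The same run is available from the shell:

```sh
herbnet generate --out data --seed 0     # dataset + ground truth files
herbnet run --out run --seed 0           # full pipeline + run_report.json
herbnet dmim --out run --data data       # or any single stage
```

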