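# Methods

This note documents the models implemented in `herbnet`, the parameters
that matter, what the synthetic data emulate (and do not), and the design
choices made where the published ingredients left the formula open.

## 1. Corpus model and frequencies

A prescription is an ordered list of distinct standardized herb names; the
order encodes the traditional principal-to-auxiliary hierarchy, with
position 0 the leading herb. Raw corpora carry synonym/polyseme/acronym
noise; `normalize_corpus` maps every mention through a lexicon whose
synonym sets must be disjoint, preserving order and merging duplicates
onto the earliest position. Unknown names raise by default (surfacing
lexicon gaps); a drop-with-warning policy is available.

Accumulated frequency (AF) counts *presence per prescription* — herbs do
not repeat within a formula, so AF is bounded by the corpus size, which
matches the reported per-herb frequencies being below the number of
formulae. Normalized frequency is NF = AF / ΣAF over all herbs; NF sums
to 1 by construction. Frequency ties are broken lexicographically so that
top-k selections are reproducible.

## 2. Pair scoring and core networks

The pair score is `score(x,y) = MI(x,y) / d(x,y)`.

* **MI** is joint-probability-weighted pointwise mutual information with
  prescription-level occurrence probabilities, in bits (log base 2 by
  default; the base is configurable because the upstream description does
  not fix it). Negative values — co-occurrence below independence — are
  clamped to 0 by default: the score measures a *pairing propensity*, and
  an avoided pair has none. A pair that never co-occurs scores 0 without
  evaluating the distance.
* **d** is the mean absolute positional gap over co-occurring formulae.
  Distinct list entries make d ≥ 1, so the quotient is always defined.
  An optional mode divides each gap by (formula length − 1) for
  length-relative distances; it is off by default.

Edges are kept by the rule *score > 0 AND co-occurrence support ≥ 5*
(`EdgeRule`; both knobs configurable). No numeric significance cutoff was
published, so the default expresses "above independence, with non-trivial
support". An optional score-quantile cutoff within a seed's candidate
edges can prune subnetworks further; it is off by default and the planted
structure below is defined against the default rule.

The high-frequency network takes the top-k herbs as nodes and rule-passing
pairs as edges. A seed subnetwork contains the seed, all herbs whose pair
with the seed passes the rule, and rule-passing edges among members. The
core network is the node-AND-edge intersection of the top herbs' seed
subnetworks — edge intersection is included because both node and edge
counts are reported for such cores.

## 3. Target-profile prediction

The predictor assumes the structure–target coupling of drug space: a
compound structurally similar to known drugs tends to act near those
drugs' targets in the interactome.

* Structure similarity: Tanimoto coefficient over binary fingerprints
  (default length 128). Fingerprints are abstract bit vectors — ingesting
  real chemical fingerprints is a file-format change, not an algorithm
  change. An all-zero/all-zero pair is defined as similarity 0.
* Protein closeness to drug j: mean over drug-j targets of
  `exp(−shortest-path length)` on the unweighted PPI; disconnected pairs
  contribute 0, a protein that is itself a target contributes 1.
* Concordance = Pearson correlation of the two vectors (the published
  predictor is described as a linear regression model, hence Pearson, not
  a rank correlation). Zero-variance vectors score 0, so degenerate
  compounds rank last rather than erroring.
* Profiles keep the top K = 100 proteins, ties broken by protein id. Herb
  target sets keep proteins present in strictly more than 5 of the herb's
  compound profiles ("more than five compounds" read as support ≥ 6).

## 4. Synergy scoring

The published synergy method names its ingredients — a topology score on
a disease background network, an agent score, and betweenness/closeness/
PageRank for node importance — but not the combining formula. The
reconstruction implemented here is fully specified so results are
reproducible, and should be read as this package's formalization:

* importance(v) = mean of min–max-normalized betweenness, closeness and
  PageRank (damping 0.85). If a metric is constant over nodes it carries
  no ranking information and everyone receives 1 for that metric (this
  keeps cycle-graph symmetry meaningful). Single-node networks get
  importance 1 by convention.
* TS(T1→T2) = Σ_{i∈T1} imp(i)·exp(−minspl(i,T2)) / Σ_{i∈T1} imp(i), with
  minspl the distance to the nearest member of the other set; disconnected
  members contribute 0; an all-zero-importance set falls back to uniform
  weights. TS = (TS(T1→T2) + TS(T2→T1)) / 2. Identical sets score exactly
  1, sets in different components exactly 0; an inverse-distance decay
  1/(1+d) is available as config.
* Agent score = (1 + cosine)/2 of phenotype vectors, 1 when either is
  absent or zero — no phenotype data ship with the package, so the total
  score reduces to the topology score by default, and that default is a
  declared stand-in rather than a claim about phenotype similarity.
* Total = TS × AS ∈ [0,1]. Herb-pair synergy is the arithmetic mean of
  total scores over cross-herb compound pairs (the herb-level summary is
  described as an average in the source analysis); self-pairs are reported
  in the matrix but excluded from herb summaries.
* The background network defaults to the disease-gene-induced PPI subgraph
  plus first neighbors; the full PPI is available as config.

## 5. Enrichment and overlap

Terms are flat gene sets (GMT); no ontology propagation is performed and
none is claimed. p_raw is the exact upper-tail hypergeometric probability
P(X ≥ k); correction is Benjamini–Hochberg by default (Bonferroni as
option) across all tested terms, with "enriched" meaning adjusted p
strictly below α = 0.05. The overlap report lists shared and
side-exclusive enriched terms for two queries run against the same
annotation collection. The universe defaults to all PPI proteins, since
herb targets are drawn from the PPI-scored proteome.

## 6. Bridge networks and property association

The background is restricted to disease genes plus first neighbors
(configurable to genes only). Two agents are linked iff their (restricted)
target sets intersect or share at least one background edge — the stated
one-hop rule, implemented exactly; a graded-distance variant was
considered and rejected because the stated rule is binary. Compound target
sets entering the bridge are each compound's top-K profile intersected
with the background. Clusters are connected components by default (greedy
modularity as option), and networks are built per drug class by default.

The Cold↔immunomodulatory / Hot↔hormone observation is formalized as a
one-sided Fisher test of herb-property counts inside vs outside each
drug-containing cluster (herbs deduplicated — a herb is "inside" if any of
its compounds is), BH-corrected across (cluster × property) tests. The
source analysis reports this association visually; the test makes it
assertable on planted data.

## 7. Synthetic data: what it emulates, and what it does not

`GeneratorConfig` defaults encode the study conditions: 871 prescriptions
over 343 herbs, formula sizes 15–29 with mean 18, synonym noise (2
synonyms per herb, 30% of mentions), a planted top-10 herb clique
co-occurring in 80% of formulae, a 14-herb core whose extra four herbs
emulate a known sub-formula, per-herb compound libraries (8 compounds for
each of the 50 chemistry herbs), a 16-drug reference panel (9
immunomodulatory + 7 hormone, names transcribed from the published lists),
a preferential-attachment PPI, 129 disease genes, and 150 annotation
terms of which 9 are planted.

Construction details that matter:

* **Formula sizes** are a discretized Beta(2, b) on [15, 29] with b solved
  so the mean is 18; a uniform draw on the printed range would overshoot
  the printed average.
* **Module plant.** 80% of formulae open with all 14 core herbs (the
  four-herb sub-formula kept contiguous); top herbs additionally appear
  alone in 10% of the remaining formulae so their frequencies strictly
  dominate the core extras. Background herbs split into a 36-herb
  *companion* pool — the only filler of module formulae, and heavily
  present in non-module formulae — and a rare pool confined to non-module
  formulae with Zipf weights. This makes every core pair exceed the
  default edge rule while background pairs stay below it: companions
  co-occur with top herbs *below* independence (their MI clamps to 0) and
  rare herbs fail the support minimum, with multi-sigma margins, which is
  what makes the 45-edge clique and the exactly-14-node intersection
  reproducible across seeds. Every herb is guaranteed at least one
  occurrence (coverage pre-assignment), so normalization recovers the full
  vocabulary.
* **Chemistry.** Each chemistry herb is assigned a primary parent drug via
  the property coupling (Cold → immunomodulatory, Hot → hormone, Warm →
  either, otherwise any); all its compounds are 5%-mutated copies of the
  parent fingerprint and inherit the parent's targets as ground truth.
  Sharing one parent per herb is what makes the ">5 compounds" herb-target
  rule meaningful at 8 compounds per herb.
* **Interactome.** Preferential attachment with m = 3 and 2000 nodes by
  default. The node count is a deliberate scale choice: profiles keep
  K = 100 proteins, and on a much smaller proteome the top-100 covers so
  large a fraction of the universe that both enrichment and
  recovery-vs-chance comparisons degenerate (with K = 100 of 500 proteins,
  no ranking can exceed 5× the random expectation, because the random
  expectation is already a fifth of a perfect score). All counts are
  configurable; the defaults remain well below the real databases they
  emulate, which is declared, not hidden.
* **Disease genes** are sampled preferentially (exponential distance
  decay) from the densest network region; immunomodulatory drug targets
  are anchored near one disease sub-region, hormone targets near a distant
  one.
* **Annotations.** Planted terms are network-localized modules: a
  shortest-path ball around an anchor in the drug-target pool plus ~10
  disease genes. Uniform random gene mixtures would not be jointly
  enriched in disease genes and predicted herb targets; localized modules
  are, and are also what real functional terms look like on an
  interactome. Non-planted terms are uniform draws and serve as nulls.

Dedicated small scenarios exist per stage (`generate_pair_recovery_corpus`,
`generate_target_recovery_instance`, `generate_synergy_scenario`,
`generate_bridge_scenario`). The synergy scenario plants a pair whose
target sets interlock inside the hub module (sharing two targets) against
herbs with disjoint peripheral target sets. The bridge scenario uses a
background of **two** preferential-attachment modules joined by a two-node
path, so the two drug classes' target regions can neither overlap nor be
adjacent; a single scale-free graph offers no such guarantee, and the
one-hop link rule would otherwise occasionally merge the clusters.

**What passing tests do not show about real data.** The generator encodes
the structure–target coupling the predictor assumes (compounds are
literal fingerprint mutations of their parent drug), chemistry-free
fingerprints, a single-snapshot noise-free PPI, and flat annotations.
Recovery rates measured here are therefore upper bounds on what identical
settings would achieve on real corpora, real chemistry, and real
interactomes; the printed pair scores and synergy values of the original
study additionally depend on proprietary inputs and are treated as scale
references only.

## 8. Numerical and degenerate-input conventions

* Scores/probabilities are clamped to their nominal ranges where floating
  point can overshoot by an epsilon (topology score, cosine).
* Empty frequency tables, empty corpora, empty queries/universes, empty
  target sets, and disconnected-from-everything inputs raise informative
  errors at the operation whose precondition they violate; downstream
  callers that can continue (compound with no in-network targets, cluster
  with no annotated herbs, empty subnetwork intersection) warn and
  continue with the degenerate case recorded.
* All randomness flows from one `SeedSequence` split per sub-generator, so
  stages regenerate independently and datasets are byte-identical given
  (config, seed).
* Problem sizes in the test suite: the recovery experiments run 100/20/50/50
  replicates at the scenario scales above; the statistical-sanity null uses
  100 replicates × 200 terms on a 500-gene universe. These sizes give the
  planted effects multi-sigma margins while keeping the whole suite fast.

## 9. Known limitations

* The NIMS-style combining formula and the closeness transform exp(−spl)
  are reconstructions of methods whose exact published forms are not
  public; both are flagged as such above and exposed as config.
* Agent scores default to 1 (no phenotype data); synergy rankings are
  purely topological under that default.
* Herb-level target aggregation implements only the stated support rule;
  union- or score-sum aggregation variants are not implemented.
* Flat gene sets ignore ontology structure; enrichment p-values are not
  comparable to propagation-aware tools.
* No dosage, preparation, or temporal information is modeled; the corpus
  model is presence-and-order only.
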