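# Methods

## Data model and extraction

The unit of observation is an indexed citation: an article identifier plus
(descriptor, qualifier-set) annotations, the abstraction MEDLINE's MeSH
indexing reduces to for this analysis. A descriptor counts as a **drug
mention** when it maps to a known ingredient and carries a drug-role
qualifier (default `AE`, *adverse effects*); as an **ADE mention** when it
is in the manifestation vocabulary and either carries a manifestation-role
qualifier (default `CI`, *chemically induced*) or belongs to a configurable
set of descriptors inherently indicative of an adverse event (e.g.
drug-induced liver injury). Both qualifier sets are configurable because
real indexing policies vary. Unknown descriptors are ignored, not errors:
most headings on a real article are irrelevant to safety.

Drug–event pairing within an article is the full cross product of its drug
and ADE mentions. The article-level 2×2 counts the method rests on are
insensitive to which within-article pairing convention is chosen, and
co-occurrence is the standard convention when the indexing does not link a
specific drug to a specific manifestation.

## Terminology normalization and aggregation

Drug terms resolve to base ingredients through a term→ingredient table and
a precise-ingredient (salt/ester) → ingredient map that is transitively
closed at load time; normalization is idempotent. Ingredients carry one or
more drug codes, each assigned to a fourth-level class; class membership is
the union over codes, **deduplicated by ingredient** — a drug cross-filed
under two codes of the same class is one member. Classes with fewer than
`min_members` (default 4) observed ingredients are excluded: below that,
"class behaviour" is not meaningfully distinguishable from individual-drug
behaviour.

Manifestation terms own dot-separated tree numbers and aggregate to the
term owning the first two components of each tree number (second-level
roll-up, e.g. `C05.651.807` → `C05.651`). A term with several tree numbers
contributes to all its second-level classes — multi-assignment preserves
signal rather than arbitrarily picking one hierarchy position. Terms at or
above the second level aggregate to themselves.

## Analysis universe and PRR

The denominator population (the **universe**) is the set of articles with
at least one drug mention *and* at least one ADE mention. This makes the
2×2 table a true partition (a+b+c+d = universe size) and excludes articles
that could not contribute coherently to any cell. It also means all
proportions are conditional on an article being a drug-safety co-mention
article; PRRs are therefore compressed relative to risks defined on an
unconditional population, which is immaterial for the within-class
comparisons the verdict rests on.

PRR = (a/(a+b)) / (c/(c+d)) is computed for every pair with a ≥ 1. When
b = 0 or c = 0, 0.5 is added to all four cells first (zero-cell
correction). A pair whose row or column margin covers the entire universe
(c+d = 0 or a+b = 0) has no comparator population and is an error rather
than a number. Never-co-occurring pairs are assigned the neutral PRR 1
only when dense matrices are materialized for display. All transforms use
the natural logarithm. Class-level rows count an article once however many
member drugs it mentions; an article mentioning both a member and a
non-member still counts in the class row ("any member present").

Only PRR is implemented; the scan machinery is indifferent to the score,
and the record structure would accommodate other disproportionality
statistics, but no second score is provided.

## Class-effect determination

For an eligible pair — an eligible class all of whose members have a ≥ 1
evidence for the event — the member log-PRRs are split into two groups and
the group means compared:

* **Clustering.** Exact 1-D two-means: values are sorted and every
  contiguous split with both sides ≥ `min_cluster_size` (default 2) is
  scored by total within-cluster sum of squares; the optimal 1-D two-means
  partition is always contiguous in sorted order, so this search is exact.
  The size constraint is deliberate: it keeps Welch's test well defined
  (variance needs ≥ 2 points per group), and on the six-member worked
  example it returns the published partition, which the *unconstrained*
  optimum (splitting off the single largest value) would not. A
  conventional seeded Lloyd k-means (`lloyd_split`) is included for
  comparison only. Fewer than two distinct values yield a single cluster
  ("homogeneous by design"); the near-equality tolerance is exact equality
  by default.
* **Testing.** Welch's two-sample t-test (unequal variances,
  Welch–Satterthwaite degrees of freedom, two-sided). If both group
  variances are zero the test degenerates to p = 1 (equal means) or p = 0.
* **Verdict.** Single cluster → class effect by design; two clusters with
  p > α (default 0.05) → class effect (homogeneous); otherwise
  heterogeneous. Cluster means are always reported because a significant
  split with *both* means high may still be a class effect — that judgment
  is left to the reviewer, not automated.

No multiple-testing correction is applied across the scan (the manifest
records this); α is a per-pair decision threshold, not a family-wise
error rate.

### Known statistical limitation

The two groups handed to Welch's test are *chosen to maximize separation*.
Under a null in which all member log-PRRs are exchangeable noise, the
procedure therefore rejects far more often than α: simulation with six
iid normal values shows a rejection rate near 0.5 at α = 0.05, and because
the t statistic is scale invariant no amount of data shrinks it — tighter
log-PRRs shrink the between-cluster gap and the within-cluster variances
at the same rate. Consequently (a) the heterogeneous-verdict rate on a
null corpus sits far above α, and (b) genuinely uniform planted effects
are called heterogeneous roughly half the time. The acceptance quantities
`null_heterogeneous_rate` and `uniform_effect_recovery_accuracy` expose
this honestly (≈ 0.5–0.6 and ≈ 0.5 respectively at the default study
conditions), and the corresponding acceptance tests report the property rather than masking it. Subset effects, by contrast, are
recovered essentially always: the planted separation dwarfs the selection
effect. A calibrated alternative (e.g. a selection-adjusted test or a gap
statistic against a permutation null) is out of scope here because the
point of the package is the published procedure.

## Heat maps

Signal matrices hold log-PRR with 0 for non-co-occurring pairs. Both axes
are ordered by agglomerative clustering (Euclidean distance, complete
linkage); leaf order is the left-first dendrogram traversal, which is
deterministic for distinct merge heights. Tie handling follows the linkage
implementation's index order; since published leaf-ordering heuristics are
version-dependent, figure reproduction is treated as qualitative and the
exported TSV of the permuted matrix is the tested artifact. Rendering maps
low → red, mid → yellow, high → white.

## Synthetic corpus generator

The generator emulates article-level co-mention data: per article, a drug
count is drawn (default {1: 0.70, 2: 0.25, 3: 0.05} — most safety articles
discuss one drug), drugs are sampled uniformly, and each manifestation
term is included independently with probability
`min(1, baseline × max RR over the article's drugs)`. The max-RR
combination keeps multi-drug probabilities well defined; risks are
one-sided (drugs elevate events) because that is the regime PRR screening
addresses, though RR < 1 configurations are accepted. Default study
conditions: 5 classes × 6 members, 5 ADE classes × 3 terms, 50,000
articles, baseline 0.02 per term per article (a given manifestation term
in a few percent of drug-safety articles — enough for expected
co-occurrence counts in the tens-to-hundreds so log-PRRs are
well-resolved), one no-qualifier distractor heading per article on
average. Vocabularies exercise the terminology edge cases by
construction: ~20% of ingredients get a salt-form alias through the
precise-ingredient map, and one drug is cross-filed in a single-member
alternate-route class (ineligible by the size filter, so it perturbs no
verdict).

What the generator does **not** emulate: literature reporting biases
(case-report skew, drug age, indication channeling), correlated
co-prescription, within-class correlation of risks, or route-of-
administration confusion. Passing tests therefore show the machinery and
the decision rule behave as specified under clean sampling — not that the
procedure is robust to real-literature confounding.

All randomness flows through one seeded generator; a fixed seed reproduces
the corpus byte for byte.

## Problem sizes and numerical choices

Tests and the acceptance script run at the default study conditions above
(50,000-article corpora; 20 replicates for recovery; 300 value-sets for
the split-optimality check; 20 corpora of 50 articles for the counting
oracle). Contingency counting is vectorized as boolean matrix products and
verified against a per-article brute-force counter; the split search
breaks ties toward the smaller left cluster; table cells are exact
integers until the correction introduces halves. Degenerate inputs are
errors, not silent values: empty universe, empty row margins, duplicate
matrix records, groups of fewer than two values in Welch's test.
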