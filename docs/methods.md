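# Methods

## The phenolog model

Two phenotypes in different species are *phenologs* — orthologous
phenotypes — when the sets of genes underlying them overlap more than
expected by chance once gene orthology is taken into account.  The model
behind the statistic is deep homology: an ancestral gene module is
conserved across species even when the overt phenotypes it produces look
unrelated, so a gene associated with one member of a phenolog pair is a
candidate for the other.  Overlap significance is the upper tail of the
hypergeometric distribution: with m elements carrying phenotype A, n
carrying phenotype B, and v shared out of a universe of N, the p-value is
P(X ≥ v) for X ~ Hypergeometric(N, m, n).

A single phenolog is a weak predictor; this package ranks candidate genes
by integrating the k nearest neighbor phenotypes of a target phenotype,
found across all species in the dataset and within the target species
itself (*paralogous phenotypes*, related through gene duplication rather
than speciation).

## Comparison spaces and the two frameworks

All annotations reduce to binary element × phenotype matrices.  Two
frameworks translate annotations between species:

* **gene-based** — annotations of the other species are rewritten onto
  every ortholog in the target species.  A paralog expansion turns one
  annotation into several, inflating overlaps asymmetrically: the overlap
  statistics of a phenotype pair then depend on which species the search
  runs from.
* **orthogroup-based** (default) — both species' annotations are projected
  onto the orthogroups of the species pair (a gene belongs to at most one
  orthogroup per pair).  Paralogs collapse to a single element, and the
  overlap statistics are symmetric in the two species.  Under strict 1:1
  orthology the two frameworks coincide exactly, which is tested.

The universe N of a comparison is the number of orthogroups of the species
pair (cross-species) or the number of target-species genes annotated to
any phenotype (within-species).  Within-species comparisons run directly
in the target species' gene space: it is the only universe the two
phenotypes naturally share, since no speciation event separates them.

## Measures, weighting and classifiers

All supported measures are closed-form functions of (v, m, n, N) on
indicator vectors: hypergeometric tail, Pearson correlation (identical to
the phi coefficient of the 2×2 table), cosine v/√(mn), Tanimoto
v/(m+n−v), Euclidean √(m+n−2v) and Manhattan m+n−2v.  Neighbor ordering
uses a uniform "smaller is nearer" key (ascending p-value/distance,
descending similarity), with ties broken by (species, phenotype id) so
results are reproducible.

Each of the k neighbors contributes two numbers to the genes in its
column: f = v/m, the fraction of the target phenotype's elements shared
with the neighbor (an empirical estimate of that single phenolog's
precision; the denominator can be switched to the neighbor's cardinality),
and a weight w ∈ [0,1] derived from the configured weight measure.  The
mapping from measure to weight is a design decision of this package, since
the similarity-to-probability calibration is not specified by the theory:
hypergeometric p → 1−p, Pearson r → max(r, 0), cosine/Tanimoto pass
through, unbounded distances d → 1/(1+d).

Two classifiers combine contributions per gene:

* **naive Bayes**: X_i = 1 − ∏_l (1 − f_l w_l), treating neighbors as
  independent noisy predictors; scores live in [0,1] and every additional
  covering neighbor strictly increases a gene's score.
* **additive**: X_i = Σ_l w_l Φ_il, the incidence matrix times the weight
  vector; scores decompose exactly into per-neighbor contributions, which
  is what the contribution tables export.

Cross-species neighbors score orthogroups; a target gene inherits the
contribution of each orthogroup it belongs to (at most one per species
pair) and the classifier combines them — summation for additive, the
product form for naive Bayes.  This gene-level aggregation rule is the
natural extension of the two formulas to multi-pair membership.

Defaults: k = 40, Pearson for the neighbor search, hypergeometric for
weighting, naive Bayes — the best-performing pairing in cross-validation;
every other pairing is available through flags.  Ranks use the mean-rank
rule for tied scores, so ranks always sum to P(P+1)/2 over P candidates.

## Cross-validation

Leave-one-out, orthogroup-aware: for each phenotype with at least two
known genes, one associated gene is hidden together with **every
orthogroup containing it** (and, in the within-species gene space, its
paralogs from those orthogroups) — otherwise a co-annotated paralog would
leak the answer through the shared orthogroup.  Neighbor search and
scoring are recomputed on the masked data and the hidden gene's recovered
rank recorded; three repeats with distinct hidden genes (where cardinality
permits) are summarised by the median rank.  The recovery curve counts
phenotypes whose median rank is ≤ r.  A hidden gene that receives no score
ranks inside the zero-score tie group at the bottom of the list; a gene
absent from the candidate pool is assigned the mean rank it would have if
appended with score zero — a conservative, finite worst case.

n-fold cross-validation splits each phenotype's genes across folds
(phenotypes with fewer than four genes are excluded), treats withheld
genes as positives and all other ranked genes as negatives, and reports
per-phenotype ROC and precision–recall areas (scikit-learn).

The randomized-matrix control redraws every phenotype column uniformly at
its exact cardinality, destroying orthology structure while preserving
sizes.  A rank-based AUROC summarises a leave-one-out report: with one
positive at mean rank r in a pool of P, the fold's ROC area is
(P−r)/(P−1); the control should sit near 0.5.

Genes never annotated to any phenotype but present in the element universe
stay in the ranking — the rank of a recovered gene is only meaningful
against the full candidate pool.

## The synthetic benchmark

The generator emulates the structure the method assumes rather than any
real database: ancestral orthogroups shared across species, per-species
retention (Bernoulli, default 0.8) and geometric paralog counts
(support ≥ 1, default mean 2 — heavy-tailed family expansions of the kind
that motivated the orthogroup framework), disjoint conserved modules of
orthogroups, and phenotypes drawn partly from one module (signal) and
partly uniformly (noise).  Defaults: 4 species, 500 orthogroups, 5 modules
of 20, 6 phenotypes per module per species, signal fraction 0.6, phenotype
sizes 5–15 genes, plus 10 background phenotypes per species — enough
planted phenolog structure to recover, with realistic noise around it.
These sizes keep a full five-seed benchmark (real + randomized control +
k ablation) under a minute on one core.

What the generator does **not** emulate: phenotype ontologies and their
term correlations, the heavily skewed gene-per-phenotype distributions of
curated databases, annotation bias toward well-studied genes, and
evidence-quality heterogeneity.  Passing the benchmark therefore shows the
machinery recovers planted cross-species module structure above a matched
null; it does not certify performance on any particular biological
database.

## Numerical and degenerate-input choices

* Hypergeometric tails go through the survival function in (m, n)-
  canonicalized argument order, so p-values are bit-identical under
  swapping the two phenotypes.
* Pearson is undefined when either indicator is constant (empty or full
  column); such candidates are skipped in the neighbor search and an
  explicit error is raised in direct calls.
* Cosine and Tanimoto of an empty set are defined as 0.
* Quantitative profiles break score ties by condition id; the top/bottom
  window rule yields min(#conditions, top_k + bottom_k) assignments.
* Phenotypes below the minimum gene count (default 3) are removed before
  any matrix is built; the filter is idempotent.
* Location/stage expansion uses strict inequalities (> 50 genes per
  location, > 3 per stage), reading the construction rule literally.

## Known limitations

* Orthology is pairwise only; multi-species clustered orthogroups are out
  of scope, and inparalog confidence scores are ignored (membership is
  binary).
* Overlap p-values are not corrected for multiple testing, matching the
  original usage; neighbor ranks, not absolute p-values, drive the method.
* The weight calibration (measure → [0,1]) is heuristic; naive Bayes
  scores are therefore not calibrated probabilities.
* Absolute recovery numbers on real databases depend on database snapshots
  and are outside what the synthetic benchmark can reproduce.
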