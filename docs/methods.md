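# Methods

## Problem setting

Given a proteome, a set of experimentally supported phosphorylation sites for
one kinase family, per-namespace protein annotations, and optional
per-residue structure annotations, the package (i) finds annotation terms
over- or under-represented among the family's substrates, (ii) scores every
protein for substrate-likeness from those terms, (iii) trains and evaluates
site-level classifiers over combinations of sequence, structure and
functional features, and (iv) scans high-scoring candidate proteins for new
sites. Positions are 1-based everywhere; phospho-acceptors are S/T (Y is
accepted in the data model but the background pool and scan consider S/T
windows).

## Statistical model and procedures

### Term enrichment

For a namespace with incidence matrix over the background proteome
(N proteins, the study set of n substrate proteins included), each term with
background count K > 0 is tested with a two-sided hypergeometric test. The
two-sided p-value follows the minimum-likelihood convention used by
two-sided Fisher exact tests: the sum of P(X = j) over all j in the support
with P(X = j) ≤ P(X = k)·(1 + 1e−7). The relative tolerance absorbs floating-
point ties; the point probabilities are computed in log space. The p-values
are Bonferroni-corrected with m equal to the number of testable terms in the
namespace (terms with K = 0 are excluded from testing and from m; an
all-absent term carries no information and has no defined alternative).
Correction is per namespace, not pooled across namespaces, because the
feature groups are assembled and evaluated per namespace; pooled correction
can be obtained by passing a combined matrix. Significance threshold:
corrected p < 1e−2 (configurable `alpha`).

A doubling-of-the-smaller-tail two-sided p is not offered; the
minimum-likelihood convention is the package's single definition, validated
exhaustively against direct enumeration for all populations with N ≤ 25.

### Redundancy-weighted log-odds score

Feature probabilities use additive smoothing with pseudocount 1:
f1 = (count among substrates + 1)/(n + 2), likewise g1 over the background.
Smoothing guarantees finite log-odds for features absent (or universal) in
either set. The weight of feature i is its self-inclusive similarity mass
over the selected set: w_i = 1 + Σ_{r≠i} (1 − J_ir) with J the Jaccard
distance between background incidence columns (two all-zero columns are
treated as identical, with a warning). The self term keeps w_i ≥ 1 and makes
the single-feature case well defined. Weights are measured on the full
background incidence (the largest available sample).

The designed effect of the weighting is that exact duplicates share one
contribution: a feature duplicated d times has weight d per copy, so the
copies jointly contribute the original log-odds once. This invariance is
exact when the duplicated feature is orthogonal (Jaccard similarity 0) to the
remaining features; when a third feature is partially similar to the
duplicated one, its own weight also grows and the total score shifts
slightly. The weighting is a redundancy heuristic, not a calibrated
correlation correction, and is tested as such (orthogonal-complement models,
where the invariance holds to machine precision).

Score distributions of substrates versus background are compared with the
asymptotic two-sample Kolmogorov–Smirnov test. Proteome-scan candidates are
background proteins whose score strictly exceeds the median substrate score
(even-sized medians are the mean of the central order statistics).

### Site encodings

- Window: 2h+1 residues centered on the site, h = 4 (a 9-mer), padded with
  `X` where the window overruns a terminus.
- Sequence: 20 bits per residue in the fixed order `ACDEFGHIKLMNPQRSTVWY`;
  `X` (padding or unknown residue) encodes as all zeros. Column order is a
  pure permutation choice and cannot affect any downstream statistic or
  kernel classifier, so the alphabetical convention is fixed once.
- Secondary structure: one coil flag per residue (C → 1, H/E → 0), following
  the observation that phosphosites concentrate in coil regions.
- Accessibility: 7-bit one-hot with the bit at index min(score, 6); scores
  are nominally 0–9 but values above 6 are rare for phospho-candidates and
  clamp to the top bin. Score 0 sets bit 0 (index = score throughout).
  Missing structure records and padded positions contribute zeros.
- Total sequence+structure width for h = 4: 180 + 9 + 63 = 252. Functional
  features append one indicator per selected term of the group's namespaces.

### Identity filtering and negative sampling

Window identity is the fraction of positions with equal residues, with `X`
matching nothing (including another `X`). Positive windows are reduced
greedily in input order: a window is kept iff its identity to every
previously kept window is ≤ 0.7 (strictly above 0.7 is discarded). The
greedy first-come-kept rule is the package's tie-break; gapped or
protein-level identity is intentionally out of scope for site-level sets.
Negatives are uniform draws without replacement from the background pool
(every S/T window of the proteome minus known sites of any family), with the
same rejection rule, until the positive sample size is reached; exhaustion
raises an error stating the shortfall.

### Cross-validation protocol

Per repetition: sample a fresh balanced negative set; assign folds by
shuffling and round-robin dealing (site mode: sites of each class dealt
separately, so per-fold class counts are exactly equal; protein mode: source
proteins dealt first and sites follow their protein, for both classes, so no
protein spans train and test — class counts are then only approximately
equal per fold). Within each training fold, significant terms are re-selected
per namespace from the training-fold substrate proteins only. Each feature
group trains an SVC with C = 1 and RBF kernel width gamma = 1/(number of
features) on identical partitions; binary inputs are not rescaled. Accuracy
is pooled over the folds of a repetition (percent correct over positive and
negative test samples) and averaged over repetitions; "minus" is the
all-group mean minus the sequence-group mean. The default repetition count is
1000 to match full-scale use; tests and the acceptance script use 5–10
repetitions, which already give sub-point standard errors at these sample
sizes. Per-repetition RNG streams are derived as seed + repetition index and
are consumed only by negative sampling and fold shuffles — never conditioned
on annotation content — so fold assignments are invariant to adding or
removing annotation terms (this is what makes the leakage-guard test
well-defined).

### Final training and scan

The deployed classifier is trained on all homology-filtered positives plus
an equal number of freshly sampled negatives, with features selected on the
full substrate set. The scan classifies every non-known S/T window of the
candidate proteins; the decision threshold is the SVM's zero margin (no
probability calibration). Known sites are excluded from the scan output by
default because they are training data. Summary counts (candidate sites,
predicted sites, proteins with ≥ 1 predicted site) are recomputable from the
predictions table.

## Synthetic data generator

The generator emulates exactly the statistical structure the method
exploits:

- Background proteins: i.i.d. uniform residues (length 60 by default),
  resampled until at least one S/T is present.
- Substrates: 2 true sites each by default (50 substrates → 100 positive
  sites, comparable to a typical family's sample size). Site centers are S
  or T with equal probability, placed at least h+1 residues from the termini
  with non-overlapping windows; flanking residues are drawn from the motif
  distribution with probability `motif_strength` (default 0.8), else
  uniformly. The default motif is the minimal proline-directed consensus
  (P at +1), representing families whose sequence signal alone is modest so
  the contribution of functional features is visible; richer motifs can be
  supplied per configuration.
- Annotations: each namespace draws Bernoulli terms at
  `background_term_prob` (default 0.1) for all proteins; planted enriched
  (depleted) terms tilt the substrate probability by an odds ratio,
  p' = OR·p/(1 − p + OR·p), keeping the background probability
  interpretable. Defaults: seven namespaces × 40 terms, 4 enriched at OR 8
  and 2 depleted at OR 1/8. Planted terms are identifiable from their ids
  (`<ns>:enrNN`, `<ns>:depNN`).
- Structure: uniform labels over {H, E, C} and accessibility bins {0..6}
  per residue (i.e. structure is uninformative noise in synthetic data; the
  encoders are exercised, not advantaged).
- Determinism: a master seed spawns one child stream per component
  (proteome, sites, annotations, structure) and one grandchild per
  namespace, so datasets are byte-reproducible and adding a namespace never
  perturbs sequences or sites.

What the generator does **not** emulate — realistic residue composition and
length distributions, ontology DAG structure, correlated annotation terms,
informative structure, interaction-network topology — bounds what passing
tests show: they validate the statistics and the machinery under the model's
own assumptions, not performance on real proteomes.

`withhold_substrates` supports scan evaluation: chosen substrates keep their
sequences and annotations but lose their site records, so a correct scan
should re-rank them among the candidates and recover their planted sites.
Scan evaluation uses a moderate planting (OR 4, 2 enriched + 1 depleted
terms per namespace): at the strong default planting the score separates
substrates from background almost perfectly, the candidate set collapses to
near-substrates only, and within-protein discrimination cannot be measured —
moderate overlap is also the regime real score distributions show.

## Numerical and design choices

- Natural logarithm for all log-odds; only relative order matters
  downstream.
- Hypergeometric point probabilities via scipy in log space, with the
  per-(K, n, N) support cached; the enumeration oracle in the tests is
  independent (exact integer binomials).
- Non-standard residues map to `X` (all-zero one-hot) instead of rejecting
  the protein, since background proteomes contain rare codes.
- The STRING-like 3-column dialect materializes binary `partner:<id>` terms
  symmetrically for pairs at score ≥ 400 (configurable).
- Substrate proteins lacking any annotation in a namespace load as all-zero
  rows (they simply lack the terms).
- Pipeline artifacts contain no timestamps, so identical config+seed reruns
  are byte-identical.

## Known limitations

- The redundancy weighting is heuristic (see above); strongly and partially
  correlated feature sets shift scores slightly relative to an ideal
  decorrelation.
- Site-level CV can still share a source protein between train and test in
  site-split mode; protein-split mode exists precisely to quantify that
  optimism and gives systematically smaller functional gains.
- The scan inherits the score threshold's sensitivity to the substrate
  median; with few substrates the candidate set is noisy.
- Asymptotic KS p-values are used; at very small sample sizes they are
  approximate.
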