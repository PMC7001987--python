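# Methods

This note documents the models, defaults and design choices behind
`covrec`, and what the synthetic test conditions do and do not
demonstrate.

## Coverage featurization

Coverage tracks are integrated over half-open BED intervals:
`count_i = Σ_{b ∈ [start_i, end_i)} value(b)`. Features on chromosomes
absent from a track contribute 0, and features overhanging chromosome
ends are clipped; strand is ignored (coverage tracks are unstranded).
TPM uses the standard length-normalized definition (rates `count/length`
rescaled to sum to 10^6), which makes profiles invariant to global
sequencing depth. Summing bases before the rate division is equivalent
to averaging them, since the length normalization cancels the
difference. A dataset whose features capture no signal at all yields an
all-zero profile; it is flagged degenerate, kept for bookkeeping, and
excluded from classifier training. bigWig reading goes through pyBigWig;
the bedGraph fallback is parsed directly (4-column text).

## Ontology comparison

Ontologies are DAGs of `is_a` edges (OBO input via obonet; cycles are
rejected at load). `ancestors` is the transitive closure excluding the
term itself; `key_parents` intersects `{term} ∪ ancestors` with the
curated key-class set. A term that *is* a key class counts as its own
key parent, so identical annotations always compare similar — the
reflexive convention is ours; nothing in the comparison rule would
otherwise guarantee it.

Fuzzy matching scores `100 · (1 − d/max(|a|,|b|))` where `d` is the
Levenshtein distance (edlib), case-insensitive, with exact name/synonym
hits short-circuiting at 100. The default threshold is 90; matching at
100 reduces to exact matching, and raising the threshold can only remove
matches. Ties among equal-scoring terms resolve to the smallest term id
for determinism. The scorer applies to both cell-type and target terms.

Target similarity: non-TF pairs (histone marks, other proteins) are
similar iff they share a key class in any target ontology. A target is a
transcription factor when it resolves under a configured TF key class of
the GO-like ontology; TF pairs must *also* have an interaction-table
edge with score ≥ 0.4 (the medium-confidence convention; configurable).
Interaction lookups use the matched term's canonical name. Unmatched
terms degrade to "not similar" with a warning rather than erroring, so a
single bad record cannot block a batch comparison. When exactly one of
two records carries a target, the pair is not similar (applicability
mismatch).

## Class prediction from coverage

Labels are each record's key-parent set, making prediction multi-label
(a histone mark can sit under two location classes). Records whose term
yields no key class are excluded from training with a warning.

The input transform is `log2(TPM + 1)` followed by per-feature
standardization using training-split statistics. Feature filtering fits
a 100-tree random forest (impurity importance, fixed seed) on the
indicator-matrix labels and keeps the top 1,000 features (or all, if
fewer exist). One practical caveat, visible in the test suite: when
classes are separable by a single split, impurity importance
concentrates on a few of the mutually redundant discriminative features
(each tree purifies after one split, so at 100 trees only ~45 of 50
planted features can surface). Feature-recovery checks therefore use a
moderate planted shift (2 within-class SDs) where trees must consume
many features.

Cohorts are split 80/10/10 (train/validation/test) with round-half-up
sizes — train = round(0.8 n), validation = round(0.1 n), test = the
remainder — which yields exactly 80/10/10 at n = 100. Splits stratify on
the primary (lexicographically smallest) label when every stratum has ≥3
members, else fall back to a plain seeded shuffle. Training is refused —
a returned signal, not an exception — below 100 labelled datasets.

The predictor is a one-hidden-layer MLP (128 ReLU units, Adam), trained
with an explicit epoch loop so that early stopping (patience 10, max 200
epochs) monitors binary cross-entropy on the *designated* validation
split rather than an internal random one; best-epoch weights are
restored. Test accuracy is exact label-set match at a 0.5 per-class
threshold — stricter than per-class accuracy, which is recorded
alongside. All randomness is seeded; predictions are deterministic for a
fixed model.

## Network and views

Pairwise comparison is scoped to (assembly, experiment type) groups;
primary and metadata verdicts set independent edge flags. Incremental
integration of a new dataset compares it only against its own group,
which provably agrees with a full recompute (and is tested against it).
The collapsed graph merges datasets by annotated (cell type, target);
an inter-group edge exists if *any* member pair is similar (quorum of
one — the simplest defensible choice), with flags OR-ed. Layout is
Fruchterman–Reingold (networkx `spring_layout`, 200 iterations, fixed
seed). The dendrogram uses distance 1 − Pearson on log2(TPM+1) (constant
profiles get maximal distance 1 against everything, 0 to themselves) and
average linkage; Newick export goes through scikit-bio. PCA is fit once
on a reference cohort in the same transformed space and never refit at
projection time. Where several feature-class profiles exist per dataset,
comparisons default to the transcript model for RNA-seq and the promoter
model otherwise; the model mapping is caller-supplied, so any policy is
possible.

## Recommendations

Recommendation reasons are: similar to an owned dataset, similar to a
favorite, owned by a followed user. Owned and favorited datasets are
excluded from the output (recommending them is vacuous), other users'
private datasets are always excluded, and followed users' private
datasets are not surfaced either — the access rule dominates the follow
rule. The primary/metadata filter applies only to similarity-derived
reasons; follow-derived items are not similarity edges and pass through.
Ordering is by reason count descending, then dataset id — the ranking is
a determinism device, not a relevance model. The social graph persists
as one JSON document.

## Synthetic data

`generate_cohort` draws per-feature baseline log2 levels once
(N(5, 1)), adds each class's `mean_shift` (in within-class SD units) at
its planted signal features plus N(0, noise_sd) noise, exponentiates,
and renormalizes rows to the TPM scale. Mislabeling replaces the
annotation of an exact count round(fraction · n) of records with the
next class's term, planting primary-only similarity edges. Default study
conditions used in tests and the acceptance script: two classes of 100
members, 2,000 features, 25 signal features per class, shift 3 SD —
large enough that a working pipeline should reach ≥0.9 held-out
exact-set accuracy, with label-shuffled controls at the 0.5 chance
level.

The timecourse vignette emulates a differentiation experiment: four
timepoint profiles (days 0, 2, 4, 30) interpolate linearly between the
stem-like and cardiac-like class centroids in log space (noise at half
the cohort SD), with all four annotated by the uploader as embryonic
stem cells. The reference cohort has 100 datasets per class so it clears
the training gate.

What passing these tests shows: the pipeline's arithmetic, gating,
privacy and symmetry contracts hold, and the classifier recovers planted
structure under log-normal noise. What they do not show: performance on
real coverage data, where class structure is weaker, label noise is not
exact, batch effects violate the i.i.d. noise assumption, and ontologies
are orders of magnitude larger. The toy anatomy/GO-like/histone
ontologies preserve the *shapes* that matter (multi-parent DAGs, key
classes at an intermediate level) but not real vocabulary scale, so
fuzzy-matching precision on real free text is untested here.

## Numerical notes and limitations

- TPM conservation is exact to 1e-6 relative; all-zero inputs are the
  single sanctioned exception.
- Split sizes use round-half-up, avoiding banker's-rounding asymmetries
  at odd multiples of 5.
- RF importance ties break toward the lower feature index (stable
  argsort), making selection deterministic.
- The interaction table stores the max score per unordered pair and is
  case-insensitive on protein names.
- No GPU, no hyperparameter search; the MLP defaults are deliberately
  small. With ~1,000 inputs and cohorts of a few hundred, training takes
  seconds.
- Model persistence writes JSON metadata plus an npz weights file at run
  time.
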