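# covrec

Coverage-profile similarity networks and social recommendations for
genomics datasets.

Public repositories hold tens of thousands of sequencing datasets
(RNA-seq, ChIP-seq, ATAC-seq, ...) with inconsistent, free-text
annotation. `covrec` implements the engine behind a data-discovery
service for this setting: it decides, for every pair of datasets from the
same assembly and experiment type, whether they are similar — judged
independently from **primary data** (read coverage) and from **annotated
metadata** — and turns the resulting network into exploratory views and
per-user dataset recommendations driven by social interactions
(ownership, favorites, follows).

## The method

**Featurization.** Each dataset's genome-wide read coverage (bigWig, or
bedGraph as a text fallback) is summed over fixed feature lists
(promoters, gene bodies, transcripts, enhancers) and converted to
transcripts-per-million: with per-feature coverage `c_i` over length
`L_i`,

```
TPM_i = 10^6 · (c_i / L_i) / Σ_j (c_j / L_j)
```

Only the TPM profile and metadata are retained.

**Metadata similarity.** Free-text cell-type and target terms are
fuzzy-matched (normalized Levenshtein ratio on [0, 100]) onto ontologies:
an anatomy ontology for cell/tissue types, a GO-like ontology for protein
targets, and a histone-modification ontology that groups marks by their
genomic location of enrichment (H3K4me3 sits under both *at active
promoters* and *at poised promoters*). Each ontology carries designated
**key parent classes** (e.g. *cardiovascular system*); two annotations
are similar when they share one. Transcription-factor target pairs must
additionally show an interaction edge (score ≥ 0.4) in a STRING-like
protein-interaction table.

**Primary-data similarity.** Key ontology classes are predicted from the
TPM profile itself: a random forest ranks features by importance and the
top 1,000 are fed to a multi-layer perceptron trained per (assembly,
experiment type, metadata field, feature class), with an 80/10/10
train/validation/test split and a minimum cohort of 100 labelled
datasets. Prediction is multi-label (sigmoid scores, 0.5 threshold); two
datasets are similar when their predicted class sets intersect.

**Network and recommendations.** Edges carry independent
`by_primary`/`by_metadata` flags. Datasets sharing an annotated (cell
type, target) pair collapse into one node, laid out force-directed;
profiles also feed an average-linkage dendrogram (1 − Pearson on
log2(TPM+1)) and a PCA projection frozen on a reference cohort. A user is
recommended datasets similar to what they own or favorite and datasets
owned by users they follow; private datasets drive the engine for their
owner but are never surfaced to others.

## Worked example

`python examples/06_timecourse.py` runs the differentiation vignette: a
synthetic reference cohort (100 stem-like + 100 cardiac-like RNA-seq
datasets) plus four timepoint datasets interpolating between the two
expression states, all annotated as embryonic stem cells by their
uploader. It prints:

```
reference model held-out accuracy: 1.00
tc_day00: predicted ['BT:stem'], PC1=-15.9
tc_day02: predicted ['BT:stem'], PC1=-14.4
tc_day04: predicted ['BT:stem'], PC1=-11.8
tc_day30: predicted ['BT:cardio'], PC1=+15.7
recommended to uploader: 200 datasets (100 stem-like, 100 cardiac-like)
```

The day-0 dataset classifies to the stem-cell class and day 30 to the
cardiovascular class; the late timepoint's PC1 coordinate has crossed to
the cardiac side of the projection. Because the day-30 annotation still
says "embryonic stem cell", its links to cardiac reference data are
primary-only edges — coverage-based similarity catches the cell-state
transition that the metadata misses — and the uploader is recommended
datasets from both ends of the trajectory.

The other scripts in `examples/` each demonstrate one capability
(featurization, metadata comparison, training, network views,
recommendations). A thin `covrec` CLI wraps the same functions for
shell use (`covrec --help`).

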