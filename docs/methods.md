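# Methods

This note documents the models, conventions and design choices behind each
stage, the synthetic-data generators used to validate them, and the known
limitations.

## Domain-hit assembly and architecture classification

Hits arrive either as HMMER3 per-domain tabular output (`--domtblout`) or as
a 6-column TSV (protein_id, hmm_name, env_start, env_end, evalue,
protein_length). Coordinates are 1-based inclusive envelope coordinates
throughout, and overlap between two envelopes is
`min(end1, end2) − max(start1, start2) + 1`; keeping the source format's
convention avoids off-by-one drift. For domtblout input the per-domain
independent E-value (i-Evalue, column 13) is used as the hit E-value, since
the cutoff is applied per hit; the default cutoff is 0.01.

Different HMMs for the same domain family (TIR and TIR-like models, several
NBARC or TPR models) frequently report the same region. Two same-class hits
are treated as redundant when their envelopes overlap by **strictly more
than 20 aa**. Redundancy is resolved per connected component of the
over-overlap graph — redundancy is transitive in practice, since chained
HMM hits tile the same domain — keeping a single representative: lowest
E-value, ties broken by longer envelope, then lexicographic HMM name. The
tie-break order is arbitrary but fixed, because a deterministic pipeline
matters more than any particular choice among statistically identical hits.
Dedup applies within every domain class, not only TIR: the same multi-model
redundancy arises for NBARC and TPR model sets. Hits of different classes
never suppress each other (a TIR and an NBARC can legitimately abut).

Minimum domain lengths are TIR ≥ 50 aa and NBARC ≥ 150 aa (inclusive);
classes without a configured minimum pass unfiltered. Merging precedes
length filtering, so a short redundant fragment can never mask a full-length
domain it overlaps.

Classification applies ordered rules: TNP (TIR+NBARC+TPR) before TNL
(TIR+NBARC+LRR) before TN (TIR+NBARC); then TIR-only (TIR present, protein
strictly shorter than 400 aa, no other predicted domain); any remaining TIR
protein is TIR-other; proteins without TIR are non-TIR. TNP precedence means
a TIR+NBARC+LRR+TPR protein is a TNP, consistent with counting TNPs in
their own column only. Two deliberately open choices: domain order (TIR
N-terminal of NBARC) is *not* required by default — the N-terminal position
is descriptive, not diagnostic — but can be enforced with a flag; and the
400-aa rule uses the full annotated protein length, as the mature-sequence
length is generally unavailable from proteome FASTA files.

## Alignment column filtering

A column is removed iff its gap fraction is **strictly greater** than the
threshold (default 0.40). Both `-` and `.` count as gaps; any letter,
including `X`, is a residue; residues are uppercased on read because aligner
dialects differ in case usage. All-gap columns (possible after subsetting an
alignment) are removed at any threshold below 1 and flagged. The kept-column
list maps new to original 1-based indices, so per-column statistics computed
after filtering can always be reported in original coordinates. Column
residue frequencies are taken over non-gap characters (gap fraction reported
separately), and a reference-sequence mapping converts alignment columns to
1-based ungapped positions of a chosen reference — the device used to
express motif columns (catalytic glutamate, interface residues, αD helix) in
the coordinates of a reference TIR domain. Motif window boundaries are
user-supplied configuration, not defaults, since they are defined against a
specific reference structure.

## Shared-clade detection

Internal node labels carry branch support in two dialects: `single` (one
ultrafast-bootstrap value) and `dual` (`SH-aLRT/UFboot`, as produced by ML
inference run with both tests). Unlabeled nodes carry no support and simply
fail the thresholds — tree inference tools leave some nodes unlabeled, and
erroring there would make real trees unusable. Threshold comparisons are
strict (UFboot > 90, SH-aLRT > 80). Trees read with a basal polytomy (the
unrooted convention) are midpoint-rooted when branch lengths allow;
midpoint rooting is deterministic and needs no outgroup.

A clade qualifies when it passes both support thresholds and its leaves span
at least `min_lineages` (default 2) lineages from a user-supplied taxonomy
table (leaf → species → lineage, e.g. Rosids/Asterids/monocots/magnoliids);
lineage assignment is never inferred. Maximal qualifying clades are
returned; nested qualifying clades are reachable via a flag. Group labels
are `group_1..k` by size — biological names are assigned by the analyst
afterwards. Note that the *count* of maximal groups is not monotone in the
support threshold (a lower threshold can qualify an ancestor that absorbs
several groups into one); the set of qualifying clades itself is monotone,
and that is the invariant the test suite checks.

Representative selection for reduced trees takes `min(per_group, size)`
leaves per group, stratified by lineage first (one random leaf per lineage)
and filled randomly, deterministic under a fixed seed. This is a principled
selection scheme, not a reconstruction of any particular published
representative set, whose selection criteria are not recoverable.

Caveat: supports are attached to nodes, so for clades lying on the path
between old and new root, re-rooting changes which bipartition a stored
support describes. Clades off the root path are unaffected, which is the
case exercised by the tests.

## Co-occurrence screening

Orthogroup tables (row = orthogroup, per-species comma-separated gene lists)
are binarized at the species level: present iff the gene list is non-empty
after stripping whitespace. Presence is never weighted by copy number. A
pattern query fixes required presence/absence per species; matching is
strict by default — the screen is meant to retain only high-confidence
candidates — with an explicit `max_mismatches` relaxation available
(default 0). Downstream refinement by reciprocal sequence searches in
discriminatory species is a manual external step: the module emits the
candidate list for that follow-up and accepts a keep-list file to apply its
outcome, rather than deciding borderline cases (e.g. fragmentary hits in a
required-absent species) itself. Profile agreement between two rows is
reported as Jaccard over present-species sets (defined as 1 when both are
empty) and as the fraction of species with equal values.

## Expression association

Expression is binarized at tpm **strictly greater** than the threshold
(default 0). Each gene yields a 2×2 table of expressed × triggered over
samples; the one-sided Fisher exact test (alternative: expression more
likely in triggered samples) is the upper hypergeometric tail, computed with
exact `Fraction` arithmetic — no floating-point summation — so agreement
with enumeration is exact to representation precision. Degenerate margins
(gene expressed everywhere or nowhere, by trigger margin) return p = 1
rather than NA, keeping the Bonferroni denominator stable. Bonferroni uses
m = number of genes tested per study by default (configurable);
stars are assigned on adjusted p-values with strict comparisons. Samples
pooled within a species/study are the test units; a two-sided alternative is
available by flag. z-scores standardize each sample (column) across genes
with the sample (n−1) standard deviation; constant columns become zeros
with a warning. Pooling across heterogeneous public RNA-seq studies is
accepted — that heterogeneity is precisely why only binarized expression
and per-sample z-scores are interpreted, never raw tpm magnitudes.

## Synthetic data

Generators are pure functions of (spec, seed) and emit exactly the formats
the analysis stages read.

*Proteomes.* Default: 10 species × 20 proteins, planted per species as
5 TNL, 3 TN, 2 TIR-only, 1 TNP, 9 non-TIR. Planted domains always survive
the filters (TIR ≥ 50 aa, NBARC ≥ 150 aa, E-values in 1e-30..1e-4;
TIR-only proteins < 400 aa). Injected noise exercises each filter and is
removable by construction: spurious hits carry E-values above 0.01 or TIR
lengths below 50 aa with E-values worse than any true hit and placements
clear of planted domains; redundant same-class hits overlap their true
domain by > 20 aa with strictly worse E-values. Sequences are random
residues — classification reads hit tables, not sequences — and FASTA is
emitted for interface completeness.

*Trees.* Random-join topologies (no substitution-model simulation; the
clade detector needs labelled topologies, not evolution). Default 200
leaves, four planted clades spanning 2–3 of four lineages with supports
95/90 (> 90/> 80), and twelve decoys alternating between multi-lineage
clades with UFboot in 20–85 and well-supported single-lineage clades; all
scaffold nodes get sub-threshold supports, so the planted clades are exactly
the maximal qualifying set.

*Orthogroups.* Default 1,000 orthogroups × 10 species with 7 planted rows
matching a 5-present/5-absent pattern; background rows are i.i.d. Bernoulli
(p = 0.3) per species with rejection of accidental pattern matches, making
the planted rows the unique matches.

*Expression.* Default 12 genes (6 responsive) × 5 triggered + 5 control
samples; responsive genes are expressed in triggered samples with
probability 1 and leak into controls with probability 0 by default;
non-responsive genes are expressed at 0.6 independently of status. Non-zero
tpm values are lognormal(μ = 2, σ = 1) — magnitudes are display-level
realism, as only exceedance of the 0 threshold enters the test. The null
calibration uses 2,000 genes with no responsive set at 6 vs 6 samples.

What passing on synthetic data does *not* show: robustness to
non-filterable annotation noise (borderline E-values, truncated gene
models), to phylogenetic error correlated with alignment quality, to
orthology-inference errors, or to RNA-seq batch structure. The generators
validate the logic of the pipeline, not the upstream tools.

## Problem sizes and numerics

The test suite runs the merge oracle on 200 random hit sets (≤ 50 hits),
clade detection on twenty 200-leaf trees plus brute-force per-node checks on
≤ 64-leaf trees, pattern matching on twenty 1,000 × 10 matrices, Fisher
enumeration checks for margins up to 30 at ≤ 1e-12 relative error, and a
2,000-gene null calibration; the whole suite completes in a few seconds.
The null check asserts the one-sided binomial envelope
0.05 + 3·√(0.05·0.95/2000) as an upper bound only: the exact test is
discrete and conservative at 6 vs 6 samples (observed null fraction ≈ 2%),
so no exact implementation can sit *at* the nominal level there.

## Pipeline

All thresholds live in one `ThresholdConfig` serialized with every run;
strictness conventions are centralized there so stages cannot disagree.
`run_pipeline` validates the configuration before any stage executes,
records SHA-256 hashes of every input, per-stage row counts and output
paths in `report.json`, and expands all randomness from a single top-level
seed, so a run is reproducible from its report alone.
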