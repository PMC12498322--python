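# Methods

## Module coverage as a completeness signal

Single-copy marker genes do not transfer to plastids: their genomes are
reduced, their gene content varies by lineage (organelle-to-nucleus
transfer), and large repeats confound assembly. Instead, completeness is
read off the *functional* content. A KEGG module is an ordered series of
steps, each a boolean expression over KO identifiers; its DEFINITION
grammar uses spaces between steps (top-level AND), commas for
alternative orthologs (OR), `+` for members of a complex (AND), `-` for
non-essential members, and parentheses for grouping (a space inside
parentheses is again AND). We define module completeness as the fraction
of steps whose expression is satisfied by the genome's KO set, with
optional (`-`) leaves treated as satisfied so that they can never lower
a score. Presence is binary — annotation counts beyond one do not change
module satisfaction — because step satisfaction is a set property;
counts matter only to the subsampler (below). A binary per-module mode
(1 only for fully complete modules) is available as a flag on
`coverage_vector` for users who prefer a presence/absence reading.

The per-module fractions, in a fixed catalog order, form the feature
vector. The parser enforces the grammar strictly (errors carry the
offending position) and round-trips through a canonical serialization.

## Simulating incompleteness

Training examples are made from reference annotation profiles by
sampling a uniformly random sub-multiset of *annotation tokens* without
replacement: a profile with `N` tokens at nominal completeness `f` keeps
`round(f·N)` tokens (rounding half away from zero — the convention is
arbitrary but fixed and documented). Sampling tokens rather than
distinct KOs mirrors losing genes from an incomplete assembly: a KO
annotated on three genes survives partial loss more often than a
single-copy one. The training grid is 0–100 % in 5 % increments (21
levels, one subsample per reference per level by default; replicates are
configurable); held-out evaluation uses the coarser 10–100 % in 10 %
increments grid. Every grid cell's seed is derived from the master seed
and the cell's (genome, fraction, replicate) identity via a blake2b
digest, so partial re-runs and parallel runs reproduce identical cells.

References smaller than 94 kb — the median plastid genome size of
protists — are excluded from training by `filter_training_references`,
so degenerate miniature genomes do not drag the model's notion of "100 %
complete" downward.

## The regressors

Three scikit-learn regressors are supported: AdaBoost, gradient boosting
and random forest, each with the library's documented default
hyperparameters (no tuning; the defaults are recorded in the model
artifact's provenance). The labeled grid is split 90:10 and
cross-validated 5-fold with shuffling, always at the level of *source
genomes*: all 21 simulated levels of one reference stay together, so no
fold or test set ever contains a subsample of a genome seen in training.
Predictions are clamped to [0, 100] post hoc. Evaluation reports
per-level medians and population standard deviations (SD 0 for a single
prediction), an ordinary least-squares fit of predicted ~ expected with
adjusted R², Pearson correlation, mean squared error on labels rescaled
to [0, 1], and the median of (expected − predicted) — positive means
underestimation. Selection takes the algorithm with the smallest
absolute median discrepancy, breaking ties by larger Pearson r and then
by fixed name order; on both our synthetic study and typical runs this
selects gradient boosting.

Degenerate cases are reported, not guessed at: a constant predictor
yields `pearson_r = None`, and a single distinct test label yields
`linear_fit = None`.

## The bin retention rule

A bin is a probable plastid bin when the fraction of its span (in
nucleotides, not contig counts — both are computed, span drives the
decision) on plastid-classified contigs **strictly exceeds**
`min_plastid_content` (default 0.90); a bin at exactly the threshold is
not retained. Mitochondrial and unknown contigs count toward the
denominator as non-plastid span. Bins below `min_bin_span_bp` (default
50 kb, matching the reduced bin size used at binning time) are reported
with a sub-span flag rather than dropped, since the binner has already
applied its own floor. Classifier labels are normalized
case-insensitively; "chloroplast" is a synonym for plastid, while a bare
"organelle" label is ambiguous and maps to unknown.

## Report assembly

One report row per probable plastid bin: span, contig counts, the
completeness prediction, a bin-level lineage, and marker-gene presence.
Contig-level CAT-style lineages become a bin call by span-weighted
majority: the deepest lineage prefix supported by more than half of the
bin's classified span; with no majority at any depth, the deepest common
ancestor of all classified contigs. Marker loci come from hmmer
domain-table hits (rbcL) and barrnap-style GFF3 rRNA predictions
(16S/23S/5S-like; plastid rRNAs carry bacterial-style names owing to
their endosymbiotic origin). Coordinates are GFF3 1-based inclusive;
minus-strand loci are reverse-complemented on FASTA extraction, and loci
exceeding their contig's length are skipped with a warning. Missing side
tables leave columns empty; they never fail the join.

## Synthetic data: what it emulates and what it does not

The bundled catalog is 36 hand-written KEGG-style definitions over real
plastid- and organelle-relevant K-numbers (photosystems, ATP synthase,
RuBisCO, plastid RNA polymerase and ribosomal proteins, respiratory
complexes), exercising every grammar feature. Synthetic *plastid-like*
references include each catalog KO with probability 0.95 at 1 + Poisson(1)
copies and draw spans uniformly from 100–250 kb; *mitochondria-like*
references draw a few dozen tokens from the numerically smallest 5 % of
catalog KOs (which cluster in the respiratory-complex modules) with
spans of 15–70 kb. Toy samples are uniform-random nucleotide sequences
with composition-controlled bins — classification is consumed from
tables, never computed from sequence, so realistic base composition
would add nothing.

These generators reproduce the *structure* of the real task — a feature
vector that rises monotonically with completeness, two organelle classes
with strongly separated module coverage — but not its hard parts:
annotation error from homology search, shared metabolic modules between
plastids and bacteria (the reason bacterial MAGs must be removed before
completeness scoring), lineage-specific module absence, or fragmented
gene models on contig edges. Passing tests therefore demonstrate that
the machinery recovers planted signal under the stated protocol, not
that the numeric accuracy transfers to any particular real dataset.

## Problem sizes and numerical choices

The synthetic study runs with 100 plastid-like references (≈2,100 grid
examples), 50 + 50 organelle-contrast profiles and 50 random bin
fixtures — large enough for stable medians and correlations at 36
features, and a comfortable desk-scale run. Fixed choices: rounding half
away from zero in the subsampler; strict `>` at the bin threshold;
genome-level splits and folds; clamping to [0, 100]; MSE on the [0, 1]
label scale; blake2b-derived sub-seeds (< 2³¹). Model artifacts embed
algorithm, feature order, seed and package version, and loading fails
loudly on a major-version or catalog mismatch rather than silently
reordering features.

## Known limitations

- Module coverage saturates: above ~90 % nominal completeness the
  feature vector barely changes, so predictions compress near the top of
  the scale (visible as a slope slightly below 1).
- The completeness model is only as good as its reference set; the
  bundled synthetic references are a test harness, and real use requires
  training on annotation profiles of real plastid genomes.
- Bacterial bins sharing metabolic modules with plastids can score as
  complete; the tool assumes high-quality bacterial MAGs were removed
  upstream.
- Contig classification and binning errors propagate directly into the
  span fractions; the retention rule has no mechanism to correct them.
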