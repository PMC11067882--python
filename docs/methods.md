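# Methods

This note documents the models, parameter choices, and numerical details
behind `itfscreen`, and what the synthetic generators do and do not
emulate.

## Junction tags

Each construct's ectopic transcript is identified by two junction tags:

* forward: `upstream[-v:] + cds[:k]`
* reverse: `revcomp(cds[-k:] + downstream[:v])`

with ORF core `k = 21` nt and vector contribution `v = 7` nt (28 nt
total). 28 nt is long enough to be effectively unique in a mammalian
transcriptome yet short enough to fit comfortably inside a 90-nt cDNA
read. Ambiguity codes are rejected at parse time because tags must be
exact-matchable; a CDS that does not start with ATG or end with a stop
codon warns rather than errors, to tolerate tagged fusion constructs.

**Uniqueness.** A tag is unusable if it occurs verbatim (either strand) in
the reference genome, or equals another construct's tag. Collisions are
resolved by growing the ORF-side core one nucleotide at a time (the vector
side is fixed by the construct), giving the shortest unique tag of the
required form, up to a 50-nt cap. Genome collision means exact full-length
substring match — no alignment scoring and no near-match detection; the
operating assumption is that tag matching downstream is also exact.
Constructs are processed in input order, each checked against the genome
and all previously finalized tags, so of two colliding constructs the
later one is extended. Whether an extension should add ORF-side or
vector-side bases is not externally constrained; ORF-side was chosen
because the vector context is shared by all constructs, so vector-side
extension can never separate two constructs with identical ORF prefixes.

## Read scanning and UMI aggregation

Default matching is exact substring search (`str.find`); an optional
Hamming tolerance (substitutions only, no indels) replaces the fuzziness a
local aligner would provide. Every tag is searched as given and as its
reverse complement, covering reads from either strand; hit positions are
reported in read coordinates. Reads lacking a cell barcode or UMI are
dropped before scanning and counted in the scan summary.

Hits are grouped per (cell barcode, UMI) — one captured molecule. The
molecule is assigned to the TF supported by the most distinct reads; a
read hitting several TFs' tags votes for each, and a tie for the top count
excludes the molecule (`tf_tie`). When reads carry an external aligner's
gene annotation, a molecule is excluded (`aligner_conflict`) when
*strictly more than half* of its reads are annotated to a gene that is
present, not "NA", and different from the tag-derived TF; molecules whose
reads are all unannotated are retained, since the tag match is positive
evidence the aligner simply lacked.

Read ingestion supports a tabular format (read_id, cell_barcode, umi,
sequence, aligner_gene) and 10x-style paired FASTQ with a configurable
mate-1 layout (default 16-nt barcode + 12-nt UMI).

## Threshold sweep and cell calls

At minimum-UMI threshold *t*, a cell is `single` if exactly one TF has
≥ *t* retained UMIs, `multi` if two or more do. Sweeping *t* over 1–5 and
taking the argmax of the single-TF count (ties toward the smaller
threshold) separates true induction from ambient contamination: ambient
molecules arrive at 1–2 UMIs, true inductions at ~8, so the single count
peaks in between (at 3 under the default simulation conditions).
`control` cells have **zero** iTF UMIs at any level; cells with
sub-threshold evidence are `unassigned` — neither perturbed nor clean
control — making the label partition total.

Cell QC uses strict inequalities: more than 1000 detected genes, less
than 10% of counts in mitochondrial genes, more than 10,000 molecules.
Mitochondrial genes default to the mouse "mt-" name prefix, overridable
with an explicit list. Single-TF proportions are reported over both the
all-cells and the QC-passing denominators.

## Differentiation index

* **Normalization.** Default log1p-CP10K: each cell scaled to 10,000
  total counts, then log(1+x). This is a deliberately simple,
  well-understood substitute for heavier variance-stabilizing models; the
  normalization argument accepts any callable with the same contract, so
  an externally variance-stabilized matrix can be dropped in. All-zero
  cells are left as zeros with a warning.
* **PCA.** The induced-TF genes are removed before fitting (the index
  must measure downstream transcriptome change, not the induction
  itself). 50 components by default — beyond that the per-PC explained
  variance of scRNA-seq data is typically negligible — capped at the
  feasible rank with a warning. PCA is fitted on all cells jointly so
  control and perturbed cells share one coordinate system. The exact
  solver is used for small problems and seeded randomized SVD for large
  ones; the random_state default (0) makes results reproducible.
* **Index.** `d_i = (‖s_i − c‖ − μ)/σ` with `c` the control-cell centroid
  in PC space and μ, σ the mean and *sample* (n−1) standard deviation of
  control distances. Euclidean distance is the natural metric for PCA
  coordinates. At least 3 control cells and σ > 0 are required;
  perfectly equidistant controls (σ = 0) raise `DegenerateControls`
  rather than producing infinities.
* **Potency test.** One-sided ("greater") Mann–Whitney U of a TF's
  single-TF cells against controls — high index means departure from the
  undifferentiated state, and the one-sided test matches that reading; a
  two-sided alternative is a flag away. Adjustment is Benjamini–Hochberg
  by default (Bonferroni available); potency is adjusted p < 0.01
  strictly. TFs with fewer than 3 cells are reported but flagged
  untested.
* **Gene-set variants.** Sets are intersected with the matrix, the
  induced-TF genes (and optionally ribosomal genes, default prefixes
  Rps/Rpl) removed, and sets below 15 genes dropped. For each retained
  set the pipeline (normalize → restrict → PCA → index) is re-run, PCs
  capped at the set size — re-fitting per set rather than sub-setting
  loadings, because a restricted gene space has its own covariance
  structure. Restricting to the full gene universe reproduces the global
  index exactly, which the tests assert.
* **Percentile ranks.** Index ranges differ between gene sets, so per-TF
  medians are compared as percentile ranks:
  `100·(#smaller + 0.5·#ties)/(n−1)` — max 100, min 0, all-tied 50.
* **Similarity.** TF × TF Pearson correlation of median-index vectors
  across gene sets (Spearman available); zero-variance rows are dropped
  with a warning. Hierarchical clustering uses average linkage on
  1 − correlation, clipped at 0 against floating-point overshoot.

## Pseudobulk and smoothing

Pseudobulk is the arithmetic mean of log-normalized values per group
(single-TF groups plus control); groups under 3 cells are flagged
`low_n` rather than dropped. Marker panels are reported as
ratio-of-de-logged-means against the control group (reference exactly 1)
or as log-space differences (reference 0). The moving-window average
(default window 100, step 1) emits one mean per full window; relating a
gene ordering to binding scores uses a seeded permutation of the scores
across genes as the null profile — permutation is the natural
randomization when only the pairing of score to rank position is in
question.

## Synthetic generators

Both generators are pure functions of (params, seed) via
`numpy.random.default_rng`, and return ground truth sufficient to
recompute every downstream expectation.

**Tag reads.** Per cell: one true TF (uniform over the pool), true UMIs
Poisson(mean 8) resampled to ≥ 1; with probability 0.5 one contaminating
TF (uniform over the others) at 1 or 2 UMIs (uniform) — ambient
contamination of a *different* construct, the mechanism that creates
spurious multi-TF cells. Each UMI emits 3 reads of 90 nt with the forward
or reverse tag (random orientation) at a random offset in random
background, with optional per-base substitution noise (default 0).
Default pool size is 80 constructs. Not emulated: transcript structure,
positional coverage bias, barcode/UMI sequencing errors, and full-cell
doublets — so passing tests show the threshold logic handles ambient
contamination, not barcode collision artifacts.

**Expression cohorts.** Baseline per-gene means lognormal(0, 1); counts
negative binomial with var = m + 0.3·m² (0.3 is a typical scRNA-seq
overdispersion). Potent populations add a log-scale mean shift to a
random gene panel drawn from the non-induced genes; null populations
equal baseline. One near-silent marker gene per population, named after
it and strongly expressed only there, emulates the induced transcript and
exercises the TF-gene exclusion. Not emulated: gene–gene correlation
structure, library-size variation between populations, batch effects —
so recovery results speak to the index's sensitivity under clean
overdispersed noise, not to robustness against confounding.

## Problem sizes used in tests and the acceptance script

Threshold selection runs 20 replicate screens of 1000 cells × 80
constructs (~26,000 reads each) through the full read-level pipeline.
Potency recovery runs 50 replicate cohorts of 2000 control cells plus 10
shifted and 10 null populations of 100 cells over 2000 genes — large
enough for stable Mann–Whitney behavior at adjusted p < 0.01 while
keeping a full run to a few minutes. Type-I behavior of the potency test
is checked on 200 pure-null replicates of 5 populations each. Oracle
equivalence for tag scanning uses 10,000 random 60-nt reads against an
exhaustive position × pattern Hamming scan.

## Known limitations

* Exact (or fixed-Hamming) tag matching cannot recover tags disrupted by
  indels; the production-scale alternative is a local aligner front-end,
  for which the scanner's tabular input is the integration point.
* The default normalization is not a variance-stabilizing model; for
  data with strong mean–variance coupling, supply an externally
  normalized matrix.
* No barcode whitelist correction, doublet detection beyond the
  multi-TF rule, or embedding/visualization — those belong to the
  surrounding single-cell toolchain.
* With very few control cells the z-normalization parameters are noisy;
  the hard floor is 3 controls, but stable references need far more.
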