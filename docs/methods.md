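# Methods

This note documents the models and procedures `cyclescan` implements, the
design choices made where the method descriptions left the design open,
and what the synthetic-data generator does and does not emulate.

## TIP regulatory scoring

The characteristic profile of a ChIP-seq dataset is the per-base mean
signal at strand-oriented offsets −h … +h from the TSS, averaged over a
gene set; windows truncated at chromosome edges are zero-padded and the
denominator stays `2h+1` so scores remain comparable across genes. The
profile normalised to unit sum gives positional weights; a gene's
regulatory score is the weighted sum of the signal in its own window — a
weighted average, hence bounded by the window's signal extremes. An
all-zero profile makes the weights undefined and raises an explicit
degenerate-profile error rather than returning NaNs.

Defaults: `h = 5000` (a 10 kb window) for regulatory scores and a 1 kb
half-width (2 kb window) for the unweighted average-signal comparator,
both configurable. An optional moving-average smoothing of the profile is
available (off by default) because raw per-base averages are noisy when
few TSSs are available.

Standardisation across genes uses the sample standard deviation
(`ddof = 1`), a one-sided upper-tail normal p-value and Benjamini–Hochberg
adjustment; genes with `q < 0.01` (configurable) are called targets of
the TF. The across-gene z-scores have mean 0 and unit sample sd by
construction. Class contrasts (cell-cycle versus non-cell-cycle score
distributions) use Welch's two-sample t-test by default; the
pooled-variance variant is available by flag because the method is often
described generically as "Student's t-test".

## Motif scanning

Scanning follows the MATCH matrix-similarity definition. Counts receive a
pseudocount of 1 before conversion to frequencies (the standard guard
against zero cells; the choice matters little for well-populated
matrices). The information weight of a position is
`I(i) = Σ_b f(i,b)·ln(4·f(i,b))` — zero for an uninformative position,
increasing with skew — and a window of bases `b_1…b_L` scores
`Σ_i I(i)·f(i,b_i)`, min–max normalised over the matrix's attainable
range so MSS ∈ [0,1] with the consensus at exactly 1 and the
anti-consensus at 0. CSS is the identical construction restricted to the
core window (annotated, or else the 5 consecutive positions maximising
`Σ I(i)`). Both strands are scanned; `N` bases score the position
minimum. A fully degenerate matrix (zero attainable range) scores every
window 1, the only consistent limit of "distance from worst toward
best". Hits are retained when both MSS and CSS reach their cutoffs.

Matrix-specific cutoffs are read from a sidecar table, with package
defaults MSS ≥ 0.85 and CSS ≥ 0.75 when a matrix carries none. The
per-gene, per-motif score `B[i,j]` sums the MSS of all retained hits
(growing with site count); max-aggregation is available by flag. `B` is
exactly 0 when a promoter has no retained site.

Promoters are the 1 kb upstream of the TSS: `[pos−1000, pos)` on the
'+' strand, the reverse complement of `(pos, pos+1000]` on '−',
truncated at contig ends.

## Random-Forest models

Feature tables put TF regulatory-score columns and motif-score columns
side by side (deterministic order: TF columns then motif columns,
lexicographic); a gene absent from a score set contributes 0. Forests use
500 trees, √P features per split and no depth limit; the tree count is
reduced in tests and the acceptance script (150–300) where the extra
variance is immaterial.

Cross-validation is 10-fold and deliberately *unstratified*: genes are
partitioned at random irrespective of label. Each gene is scored exactly
once out-of-fold by its positive-vote fraction; a fold whose training
partition collapses to a single class triggers a warning and inherits
that class's probability. The ROC curve is sampled at 100 trapezoidal
threshold partitions; thresholds are placed at score *quantiles* rather
than evenly in score value, because evenly spaced thresholds waste
partitions whenever scores cluster (the trapezoid–exact gap then exceeds
any stated tolerance on small or heavy-tailed score sets). The exact
Mann–Whitney rank AUC is computed alongside and the two agree within 0.01
on any input with ≥20 distinct scores.

Importance is reported both as mean decrease in Gini (from a full-table
forest, as `feature_importances_`) and as %IncMSE (out-of-fold
permutation: per CV fold, each held-out feature column is permuted 10
times and the relative increase in squared-error of the predicted
probability is averaged). Ablation repeatedly removes the currently
most important feature (ties broken lexicographically for determinism)
and re-estimates both importance and cross-validated AUC, stopping at one
feature. The reduced model keeps the top-10 TF and top-10 motif features
of the full model and reruns cross-validation.

Phase-specific models select positives by peak expression time on the
0–100 scale with the standard overlapping ranges — M/G1 95–100 ∪ 0–20,
G2/M 80–95, G2 70–90, S 47–70, G1/S 20–60, all half-open — against the
full negative set; one gene may enter several phase sets.

Expression-matched negative sets quantile-bin the positive expression
distribution (10 bins by default) and sample negatives per bin without
replacement, borrowing from the nearest neighbouring bins (with a
warning) when a bin runs dry. Matching controls for the expression
confounder: training labels derived from expression time courses
over-represent highly expressed genes, and TF binding itself tracks
expression, so an unmatched model partly learns expression level rather
than periodicity.

## Genome-wide scan and empirical FDR

Artificial control TSSs are drawn uniformly over total genome length
(per-chromosome counts proportional to length), strands uniform, category
`artificial`. Exclusion zones around real TSSs are supported but off by
default. At threshold t, `FDR = F_rand/F_real`; PPV = 1 − FDR where
FDR ≤ 1; `F_real = 0` raises an explicit no-positive-predictions error.
Curves are tabulated on a 0–1 grid at step 0.01, reporting both the raw
and the clipped ratio. The estimator is calibrated exactly when real
negatives are feature-exchangeable with random genomic positions; the
calibration test therefore builds its catalogue from planted positives
plus nulls at random positions, and the residual bias is the known factor
N/n_null from positives inflating F_real. Per-gene reports over
alternative promoters flag "split-promoter" genes whose TSS
probabilities spread by more than 0.4.

## Enrichment statistics

Peak times map to angles by θ = 3.6·peak_time (the 0–100 scale spans one
360° cycle; the mapping is the only linear surjection preserving 0).
Windows of 30° slide in 20° steps — adjacent windows share 10° — and
wrap circularly, so every gene falls in one or two windows (1.5 on
average). Each window's 2×2 table (in-window × target) is tested with a
one-sided Fisher's exact test in the enrichment direction (two-sided by
flag). Gene-set overlap tests require the universe size explicitly —
inferring it from the inputs silently changes the null. PPI partner
statistics are computed on an undirected simple graph; per-class means of
partners, cell-cycle partners and percent cell-cycle partners are
reported, and class pairs are compared by a chi-squared test (no
continuity correction) on aggregate (class × partner-is-cell-cycle)
counts.

## The synthetic-data generator

The generator plants every effect the pipeline is meant to detect and
writes the assignments to a truth table. Defaults describe the study
conditions; all are configurable.

* **Geometry.** 2 chromosomes × 2 Mb, 1,000 genes (850 protein-coding,
  100 lincRNA, 50 pseudogene), evenly spaced with jitter, random strands.
  Dense packing is rejected ("infeasible geometry") when spacing cannot
  hold a promoter window.
* **Labels.** A fraction (default 0.03, the rough genome-wide share of
  periodic genes) of each category is cell-cycle; positives draw a peak
  time uniform on [0,100). Classifier experiments override the fraction
  to ~0.5 to emulate the roughly balanced curated training sets used for
  model fitting.
* **Expression confounder.** Positives' expression is shifted up by 1 sd,
  and *every* TF's binding odds increase with expression (default 1
  log-odds unit per sd). This reproduces the key confounding structure:
  all TFs separate the classes marginally, but only planted-effect TFs
  survive expression matching.
* **TF binding.** 20 TFs, 8 informative. Binding is Bernoulli with
  `logit P = logit(0.15) + ln(4)·[informative ∧ positive] +
  ln(4)·[phase-preferred] + 1·expression`. Bound genes receive one
  Gaussian peak: height 20 × lognormal(0, 0.5) strength, sd 100 bp,
  centred at a N(0, 900 bp) offset from the TSS, on a lognormal(0, 0.5)
  background interpolated from 25 bp nodes; tracks are stored binned at
  25 bp (bedGraph-like). The wide offset spread is deliberate: real
  binding sites scatter across promoter-proximal and -distal zones, and
  that spread is precisely what makes learned positional weights superior
  to a fixed 2 kb window mean. With tight offsets (sd ≈ 300 bp) the plain
  window mean is already near-optimal and the weighted score has no room
  to win — measured directly during design.
* **Motifs.** 20 matrices (L = 10, consensus count 17/20 per position),
  5 informative, planted into positives at rate π+ = 0.4 and negatives at
  π− = 0.1 as instances sampled from the matrix's own frequencies at
  uniform offsets. Cutoffs are calibrated per matrix from its own
  instance-score distribution (MSS cutoff at the 25th percentile,
  floor 0.75; CSS at the 10th, floor 0.5) in the spirit of
  matrix-specific minimum-false-positive cutoff profiles: a deliberate
  sensitivity sacrifice that keeps random-sequence matches rare. Fewer
  informative motifs than TFs, plus this detection loss, make the motif
  channel genuinely weaker than the TF channel — the qualitative
  structure the classifier experiments expect.
* **Validation data.** Knockdown screens sample half their hits from true
  positives; the PPI graph boosts edge odds 3× per cell-cycle endpoint.

What the generator does **not** emulate: read-level sequencing noise,
mappability and GC artefacts, realistic promoter nucleotide composition,
correlated TF binding (each TF binds independently given label and
expression), motif co-occurrence grammar, and annotation errors. Passing
tests therefore demonstrate that the pipeline recovers planted structure
of realistic shape and size — not that it would meet the same numbers on
any particular real dataset.

## Problem sizes in tests and the acceptance script

End-to-end checks run on scaled-down geometries chosen so the full
pipeline stays comfortably interactive: 1 Mb chromosomes, 400 genes
(~5 kb spacing) and a 2 kb TIP half-width matched to that spacing —
with toy gene densities a 10 kb window overlaps neighbouring genes'
peaks and measures mostly contamination, an effect real ~90 kb gene
spacing does not produce. The planted effect sizes stay at their
defaults. The TIP-versus-average contrast experiment uses 500 genes per
replicate, where the per-replicate win probability of the weighted score
is stable; the FDR calibration uses a 6 Mb catalogue genome with 60
planted positives, 3,000 null TSSs and 6,000 controls.

## Known limitations

* Characteristic profiles are estimated from the same gene set they later
  score; with very few TSSs the weights overfit single peaks (smoothing
  mitigates this).
* The empirical FDR estimator inherits its assumption that negatives look
  like random genome; promoter-like negatives with residual binding make
  it anti-conservative at low thresholds and conservative at high ones.
* %IncMSE is computed on out-of-fold predictions with a modest number of
  permutations (10) and is noisier than MDG on small tables.
* Motif scanning is exhaustive per window and per matrix; for thousands
  of matrices over genome-scale promoter sets a dedicated scanner would
  be preferable.
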