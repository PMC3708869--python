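# cyclescan

Predict cell-cycle-regulated promoters from transcription-factor binding
and regulatory-motif content.

Microarray time courses miss many periodically expressed genes — lowly
expressed genes in particular — and say nothing about the thousands of
non-coding promoters in modern annotations. `cyclescan` implements a
promoter-feature route instead: it learns what the promoters of known
cell-cycle genes look like in *trans* (TF ChIP-seq binding) and in *cis*
(regulatory motif matches), and then scores any transcription start site
(TSS) — protein-coding, lincRNA, pseudogene — for the probability that it
drives periodic expression.

The package is aimed at regulatory genomicists who have per-base ChIP-seq
signal tracks, a TSS catalogue and a training list of periodic genes, and
want a calibrated, genome-wide classifier plus the validation statistics
that go with it.

## The model

**TIP regulatory scores.** For a ChIP-seq dataset with per-base signal
*s(x)*, the characteristic binding profile around the TSS is

    c_k = (1/N) Σ_g s_g(k),    k = −h … +h   (default h = 5000)

averaged over all genes *g*, strand-oriented and zero-padded at
chromosome ends. Normalised weights *w_k = c_k / Σ c* turn each gene's
own window into a single regulatory score

    r_g = Σ_k w_k · s_g(k),

a weighted average that concentrates on wherever the TF characteristically
binds. The baseline comparator is the plain mean signal in a 2 kb
TSS-centred window. Scores are standardised across genes (z, one-sided
normal p, Benjamini–Hochberg q) to call each TF's targets.

**Motif scores.** Promoters (1 kb upstream of the TSS) are scanned on
both strands with TRANSFAC-format position frequency matrices using the
MATCH information-weighted similarity score: with frequencies *f(i,b)* and
information weights *I(i) = Σ_b f(i,b) ln 4f(i,b)*, a window scores
*Σ_i I(i) f(i,b_i)*, min–max normalised so the consensus scores 1 (MSS;
CSS is the same score over the 5-position core). Retained hits are summed
per gene × motif into the binding-score matrix **B**, with B = 0 when a
promoter has no site.

**Classification.** Random Forests (500 trees, √P features per split)
with unstratified 10-fold cross-validation, out-of-fold probabilities,
ROC curves over 100 trapezoidal partitions, Gini (MDG) and permutation
(%IncMSE) importance, iterative most-important-feature ablation, reduced
top-10 TF + top-10 motif models, and phase-specific models over the
standard peak-time bins (M/G1 95–100∪0–20, G2/M 80–95, G2 70–90,
S 47–70, G1/S 20–60 on the 0–100 scale).

**Genome-wide application.** A trained model scores an arbitrary TSS
catalogue together with ~10,000 artificial TSSs placed uniformly at
random in the genome. At threshold *t* the empirical false discovery rate
is FDR(*t*) = F_rand/F_real (fractions of artificial and real TSSs called
positive), with precision PPV = 1 − FDR. Downstream validation includes
circular 30°-window/20°-step Fisher enrichment of TF targets over the
cell-cycle phase axis, Fisher overlap tests against external gene sets,
and chi-squared protein-interaction partner statistics.

**Synthetic data.** `cyclescan.simulate` generates complete toy studies —
genome, TSS catalogue, per-TF signal tracks with Gaussian peaks planted
preferentially at cell-cycle promoters, motif matrices with instances
planted at class-dependent rates, an expression confounder, phase
preferences, PPI graphs and knockdown screens — with every planted fact
recorded in a truth table, so the whole pipeline is testable end to end
without any external data.

## Worked example

```python
from cyclescan import SimConfig, simulate, cross_validate
from cyclescan.pipeline import features_from_bundle

cfg = SimConfig(
    seed=100,
    n_chroms=2, chrom_length=1_000_000,
    n_genes={"protein_coding": 300, "lincRNA": 60, "pseudogene": 40},
    frac_cell_cycle=0.5, tip_half_width=2000,
)
bundle = simulate(cfg)                       # 400 genes, 20 TFs, 20 motifs
table = features_from_bundle(bundle, "both", h=2000)
for subset in ("tf", "motif", "both"):
    names = [f for f, k in zip(table.feature_names, table.feature_kinds)
             if subset == "both" or k == subset]
    cv = cross_validate(table.subset_features(names), k=10, seed=100, n_trees=150)
    print(f"{subset:6s} AUC = {cv.auc:.3f}")
```

prints (3 models on the same 400 simulated genes):

```
tf     AUC = 0.865
motif  AUC = 0.607
both   AUC = 0.874
```

The combined model is the most accurate, the TF-binding model is close
behind, and the motif-only model trails — the planted structure makes
*trans* binding information stronger than *cis* motif content, and the
classifier recovers exactly that ordering. The truth table
(`bundle.truth`, `bundle.informative_tfs`) says which TFs and motifs were
actually planted, so importance rankings can be checked against ground
truth.

The same machinery is exposed on the command line:

```bash
cyclescan simulate --seed 0 --config sim.json --out simdata/
cyclescan tip --track simdata/track_TF01.bedgraph --tss simdata/tss.bed \
          --genome chrom_sizes.tsv --half-width 5000 --out scores.tsv
cyclescan run --seed 0 --out run_out/         # full pipeline + manifest
```

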