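# translatomics

Analysis pipeline for polysome-profiling translatome data: which mRNAs
change their translational state under stress, and which sequence features
explain it?

In a polysome-profiling experiment, cell extracts are fractionated on a
sucrose gradient and mRNA abundance is measured in the **total**,
**monosome** (single 80S ribosome) and **polysome** (multiple ribosomes)
fractions, under a control and a stress condition, with replicates. The
polysome:monosome ratio of a transcript proxies how actively it is being
translated. This package implements, end to end:

1. **Translation-state calling.** For gene *g* and condition *c*, the
   translation state is `ts_c(g) = log2(polysome_c / monosome_c)` (means of
   log2 intensities over replicates). The change in translation state is
   `Δ(g) = ts_stress − ts_control`, so |Δ| > 1 is a 2-fold change in
   absolute ratios. Significance comes from a per-gene two-factor
   (condition × fraction) linear model whose interaction contrast is
   exactly Δ, with optional empirical-Bayes variance moderation; genes are
   labelled **up** / **down** / **unchanged** by the joint rule
   |Δ| > τ (default 1.0) and BH-adjusted interaction *q* ≤ α (default 0.01).
2. **Sequence features.** Each transcript is split into 5′UTR / ORF /
   3′UTR and described by a fixed 77-column schema: region lengths and
   base composition, GC content around the start codon, a structural
   pseudo-energy per region, codon-usage indices (CAI, fop, tAI), a
   start-context score (AUG-CAI(r)), amino-acid composition, upstream-AUG
   / uORF / 5′UTR-stop features, transcript-level expression under both
   conditions, and a 28-entry RNA-binding-protein motif panel that
   includes the Puf3p element `CYUGUAAAUA` scanned in the 3′UTR.
3. **Random-forest classification.** One-vs-rest forests (up vs rest,
   down vs rest) with class-balanced weights, (ntree, mtry) tuned by
   out-of-bag error, an OOB confusion matrix, a pooled 10-fold
   cross-validated ROC/AUC, and feature importance by mean Gini decrease
   plus per-tree OOB permutation importance, each with a rank-biserial
   effect sign.
4. **Gene-set co-association.** Hypergeometric over/under-representation
   of RNA-binding-protein target sets and annotation terms in the
   translational classes, Benjamini–Hochberg corrected, with UPGMA
   clustering of the enrichment matrix and Euler-style overlap counts.
5. **Synthetic benchmark.** A generator that plants a ground-truth
   regulon: a condition × fraction interaction effect in expression, a
   Puf3-like 3′UTR element in regulon transcripts, codon-usage tiers, and
   target sets with controlled regulon overlap — so every stage is
   testable without external data.

## Worked example

Run the pipeline on a synthetic data set with a planted 80-gene
down-regulon (interaction effect −2 log2 units, noise σ = 0.25):

```python
from translatomics import PipelineConfig, run_pipeline
from translatomics.simulate import SimulationParams
from translatomics.forest import ForestConfig

config = PipelineConfig(
    simulate=SimulationParams(n_genes=600, regulon_size=80, up_regulon_size=60),
    forest=ForestConfig(ntree_grid=(250,), mtry_grid=(8,), n_folds=5),
    outdir="out", seed=42,
)
run_pipeline(config)
print(open("out/run_summary.txt").read())
```

```
translatomics run (seed=42)
genes in: 600; tested: 600; assembled: 600
class counts: up=59, down=80, unchanged=461

[up] TP=6 FP=6 TN=535 FN=53 AUC=0.721 (ntree=250, mtry=8)
    transcript_level_control     gini=0.0972 effect=+
    transcript_level_stress      gini=0.0754 effect=+
    aa_frac_I                    gini=0.0377 effect=+
[down] TP=37 FP=17 TN=503 FN=43 AUC=0.949 (ntree=250, mtry=8)
    Puf3_3utr                    gini=0.2749 effect=+
    transcript_level_stress      gini=0.0491 effect=+
    transcript_level_control     gini=0.0479 effect=+
top co-association: Puf3_like x down q=3.32e-39 (over)
```

Reading the block: the translation-state caller recovers the planted
classes (80/80 down, 59/60 up); the down-vs-rest forest separates them
with cross-validated AUC 0.949 and ranks the planted Puf3 3′UTR motif
first by Gini importance with a positive effect (more motif ⇒ more likely
down-regulated); the up class, which carries no sequence signal, is
predicted from transcript levels alone at AUC 0.72; and the planted
Puf3-like target set (70% regulon overlap) co-associates with the down
class at q ≈ 10⁻³⁹. TP/FP/TN/FN are out-of-bag confusion counts.

The same run is available from the shell:

```bash
translatomics run --config config.yaml --seed 42 --outdir out
translatomics simulate --outdir data --n-genes 3000 --regulon-size 400
translatomics features --fasta data/transcripts.fasta --regions data/regions.tsv \
    --expression data/expression.tsv --out features.tsv
translatomics classify --expression data/expression.tsv --out calls.tsv
translatomics enrich --sets-a data/rbp_targets.gmt --sets-b classes.gmt --out enrichment.tsv
```

## Data formats

FASTA transcript sequences (T/U normalised to RNA internally); TSV region
table (`transcript_id, utr5_len, orf_len, utr3_len`); long-format TSV
expression (`gene, condition, fraction, replicate, log2_intensity`); TSV
motif panel (IUPAC consensus or sidecar PWM); GMT gene sets. All outputs
are TSV plus a JSON run report; every output carries the run seed in its
header. See `docs/methods.md` for the model details and design choices.
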