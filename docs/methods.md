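# Methods

## Translation-state model

Input is a gene × (condition, fraction, replicate) matrix of log2
intensities with condition ∈ {control, stress} and fraction ∈ {total,
monosome, polysome}. The translation state of gene *g* under condition
*c* is

    ts_c(g) = mean_r log2 P_cr(g) − mean_r log2 M_cr(g),

the log2 polysome:monosome ratio of per-condition geometric means. The
change in translation state is Δ = ts_stress − ts_control — the log2 of
the ratio of the two ratios — so |Δ| > 1 corresponds to a 2-fold change in
absolute ratios. Replicates are aggregated as means of log2 intensities
(equivalently geometric means of intensities): symmetric, and invariant
under per-array rescaling, which also makes Δ invariant under adding any
constant to all intensities of one condition.

**Interaction test.** Per gene, the 2 (condition) × 2 (monosome,
polysome) cell design is fit as a two-factor linear model; the
interaction contrast (P_s − M_s) − (P_c − M_c) equals Δ and is tested
against the pooled within-cell residual variance s² (df = Σ n_cell − 4).
Requires ≥ 2 replicates per cell. With moderation enabled (the default)
the residual variance is shrunk toward the across-gene mean s̄²:

    s²_post = (d₀ s̄² + df s²) / (d₀ + df),   t ~ t(df + d₀),

a fixed-prior empirical-Bayes scheme (default d₀ = 4, configurable). Full
hyperparameter estimation of the prior is deliberately out of scope: the
fixed prior preserves the qualitative effect — stabilised small-n
variances — while keeping a closed form the test suite can verify against
the textbook ANOVA when moderation is off. Note the moderated test is
slightly conservative in the extreme tail relative to the unmoderated
exact test; calibration checks (type-I error within [0.04, 0.06] at
α = 0.05) are run with moderation off.

**Classification.** q-values are BH-adjusted across all tested genes
(the adjustment method for this step is a package choice; BH matches the
choice used for enrichment). Labels: up iff Δ > τ and q ≤ α; down iff
Δ < −τ and q ≤ α; otherwise unchanged (strict inequalities on τ;
defaults τ = 1.0, α = 0.01). "Unchanged" is the exact complement of
up ∪ down — no buffer zone around the threshold. Genes with an entirely
missing design cell are excluded, not imputed.

**Potentiation.** The transcriptional change (mean log2 total_stress −
mean log2 total_control) is correlated (Pearson) with Δ, and
stress-condition transcript levels of the up and down classes are
compared against the unchanged class with Wilcoxon rank-sum tests.

## Feature schema (default, 77 columns)

| block | count |
|---|---|
| region lengths (5′UTR, ORF, 3′UTR), nt | 3 |
| base fractions A/C/G/U per region | 12 |
| GC fraction before / after the start codon (30-nt windows) | 2 |
| folding pseudo-energy per region | 3 |
| CAI, fop, tAI, AUG-CAI(r) | 4 |
| amino-acid fractions of the encoded protein | 20 |
| upstream-AUG count, uORF presence, 5′UTR stop presence | 3 |
| transcript level (control), transcript level (stress) | 2 |
| motif panel (28 motif × region scores) | 28 |

The exact 77-way itemisation is a reconstruction: the historical feature
set is described only at block level in the sources it derives from, so
the split above is this package's own, chosen to cover every described
block and reproduce the stated total. The motif panel file is the single
source of truth for the motif block and is user-replaceable; the bundled
panel (also a labelled reconstruction of published yeast RBP consensus
elements) scans 14 motifs in both UTRs, including Puf3p's `CYUGUAAAUA` in
the 3′UTR. The Puf4 entry uses the longer 9-mer element `UGUAUAUUA`
because the 8-mer variant is a sub-pattern of the Puf3 site and would
duplicate its signal.

Details and conventions:

- **CAI** — geometric mean of relative adaptiveness w_c = usage_c / max
  synonymous usage, computed from a reference ORF set with a 0.5
  pseudocount; single-codon families (AUG, UGG) and stops excluded;
  N-containing codons skipped. The default reference set is the top
  decile of the input transcripts ranked by control-condition total
  level (self-contained; a fixed reference list can be supplied).
- **fop** — fraction of optimal codons (per-family maximum w) among
  codons with a synonymous choice.
- **tAI** — per-codon weights Σ (1 − s) · tGCN over recognising
  anticodons with the standard wobble penalties (s_G:U = 0.41,
  s_I:C = 0.28, s_I:A = 0.9999, s_U:G = 0.68), normalised by the maximum;
  zero weights imputed with the geometric mean of nonzero weights. The
  bundled S. cerevisiae tRNA gene-copy table is an approximate
  reconstruction of the genomic census (marked as such in the data file)
  and replaceable.
- **AUG-CAI(r)** — geometric mean over the −6..−1 start context of
  f(base)/f_max(position), positional frequencies learned from the same
  reference set as CAI (0.5 pseudocount).
- **uORF flag** — an upstream AUG with an in-frame stop wholly inside
  the 5′UTR; the stop-presence flag counts any-frame stop triplets.
- **Folding pseudo-energy** — a deterministic Nussinov-style maximum
  base-pairing dynamic program (Watson–Crick + G:U, minimum hairpin loop
  3) with +1 per pair and +1 per stacked pair, reported as minus the
  optimal score (arbitrary units, lower = more structured). Only the
  first 70 nt of a region are folded by default (the DP is cubic;
  local-window folding is standard practice for long regions). This
  proxy is bit-reproducible, which the test contract requires; a
  pluggable external hook accepts a thermodynamic folder (e.g. RNAfold)
  for applications needing physical energies. Regions < 8 nt score 0.
- **Motif scanning** — forward strand only (mRNA); `count` scoring
  counts all (overlapping) windows matching the IUPAC consensus, with a
  sequence N matching only fully degenerate motif positions;
  `max_log_odds` takes the max over windows of Σ log2(PWM/0.25), with a
  floor of −100 for regions shorter than the motif.
- **Missing values** (empty UTRs when permitted, absent expression) are
  imputed with the per-feature median; no missingness indicators are
  added, keeping the column count fixed at 77.

## Forest protocol

The learner is scikit-learn's RandomForestClassifier; this package owns
the protocol around it. One-vs-rest tasks (up vs rest, down vs rest) are
tuned over ntree ∈ {250, 500, 1000} × mtry ∈ {⌊√p/2⌋, ⌊√p⌋, ⌊2√p⌋} by
OOB misclassification error under a fixed seed, ties broken toward
smaller ntree then smaller mtry. "Class weighting to match class
proportions" is implemented as inverse-prevalence (balanced) weights —
the only reading that changes training. Reported per task: the OOB
confusion matrix of the tuned forest; a pooled stratified 10-fold
cross-validated ROC with trapezoid AUC (equal to the concordance
probability); and an importance table with mean Gini decrease, per-tree
OOB permutation importance (error increase after permuting one column
within each tree's OOB samples, averaged over trees), and an effect sign
from the rank-biserial (Mann–Whitney) correlation between the feature
and the positive class — robust for heavy-tailed count features where a
Pearson sign would be dominated by outliers. All randomness flows from
one seed.

## Enrichment

Overlap of sets A and B in a universe of size N (default: the transcripts
entering classification, a deliberately conservative universe) is scored
hypergeometrically: upper tail for k ≥ expectation (direction `over`),
lower tail otherwise (`under`) — under-representation gets its own tail
probability, not 1 − p. BH correction is applied matrix-wide for
all-pairs co-association and per-query for term enrichment. Enrichment
matrices are clustered with average-linkage (UPGMA) on Euclidean
distances of signed −log10(q) values (q floored at 1e-300), with
deterministic tie-breaking by input order. Overlap counts enumerate every
membership pattern for up to 6 sets. Set-difference controls ("class
minus binders") are supported by plain set algebra on the collections.

## Synthetic benchmark

The generator emulates the statistical structure of the stress
experiment; its defaults are the study conditions used by the test suite
and the acceptance script:

- 3000 genes; a 400-gene down-regulon with interaction effect Δ = −2
  planted only in the stress × polysome cell (exactly the contrast the
  ANOVA tests); a 200-gene up-regulon at Δ = +2 so both one-vs-rest tasks
  run; 3 replicates per cell; observation noise σ = 0.25.
- log2 I = baseline_g + fraction effect + condition effect + planted
  interaction + N(0, σ²), baseline_g ~ N(10, 1). The total fraction
  carries a +1 baseline shift for both regulated sets (regulated
  transcripts tend to be abundant, so the transcript-level features are
  informative) and an independent per-gene N(0, 0.5) transcriptional
  stress response, keeping transcriptional and translational changes
  uncorrelated overall.
- UTR lengths log-normal (5′ median ≈ 55 nt, 3′ median ≈ 110 nt,
  yeast-like); ORF lengths log-normal in codons (median ≈ 330). UTRs are
  i.i.d. uniform ACGU — a documented simplification; real UTRs have
  biased composition, so passing tests show signal recovery under clean
  backgrounds, not robustness to compositional confounding.
- ORF codons are drawn per gene from one of three bias tiers (probability
  0.25/0.55/0.85 of using the family's highest-tAI codon), spreading
  CAI/fop/tAI so the forest has non-motif signal to work with.
- A concrete Puf3 element instance (Y sampled) is planted at a uniform
  position in regulon 3′UTRs with probability 0.9, background 0.05;
  chance consensus matches in unplanted UTRs are recorded in the ground
  truth rather than scrubbed, so specificity checks stay honest.
- The Puf3-like target set draws ⌈ρ·size⌉ members from the regulon
  (default ρ = 0.7) and the remainder uniformly from the rest of the
  universe, so at ρ = 0 the set is a uniform draw and its regulon overlap
  follows the hypergeometric null. Decoy RBP sets are uniform draws; two
  annotation terms draw 70% of members from the regulon.

Every generator is a pure function of (params, seed); emitted files pass
the strict readers unchanged.

## Numerical and interface choices

- Sequences are held in RNA space (T→U on read) because the motif
  vocabulary is RNA. Region tables use transcript-local lengths, not
  genomic coordinates, removing strand ambiguity; one row per transcript
  (UTR-isoform choice is the caller's).
- The upper-tail hypergeometric survival function is computed by scipy in
  a numerically stable form; BH by statsmodels; exhaustive enumeration
  and hand-computed step-up values pin both in the tests.
- Problem sizes in the test suite: the full benchmark (3000 genes) runs
  once and is shared across the end-to-end checks; unit tests use
  600-gene simulations. These sizes give stable statistics (e.g. ±3 SE
  binomial bands) while keeping the suite quick to iterate on.
- The pipeline estimators follow scikit-learn conventions (get/set_params,
  fitted attributes with trailing underscores); `SequenceFeaturizer.fit`
  and `.transform` accept an optional `expression=` keyword beyond the
  sklearn signature, needed for the data-derived CAI reference and the
  transcript-level columns.

## Known limitations

- The folding proxy ranks structuredness; it is not a thermodynamic
  energy and ignores loop entropies and dangles.
- The bundled tGCN table and motif panel are reconstructions; analyses of
  real data should substitute curated tables.
- The fixed-prior variance moderation does not estimate d₀ from the data.
- The uniform-background generator does not model compositional biases,
  array-specific noise, or mRNA decay dynamics.
- The one-row-per-transcript region table cannot represent multiple UTR
  isoforms.
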