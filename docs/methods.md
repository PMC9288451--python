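# Methods

This note documents the models, parameters and design choices behind
`fibrocouple`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Study design and contrasts

The analysed design is two longitudinal mouse fibrosis models sampled at
days 3, 7, 14, 21 and 28 post-administration: Bleomycin instillation
(treated n = 8, NaCl controls n = 6 per day) and AAV-mediated TGFβ1
overexpression (treated n = 5, AAV-stuffer controls n = 5 per day) — 24
animals per day, 120 in total. Animals are sacrificed per day, so the sample
sheet lists controls per day explicitly and every contrast pairs a treated
group with its same-day, same-model control group. Whether control groups
were shared across readouts in comparable real studies is usually not
recorded; per-day controls are this package's stated convention.

## Differential expression

Counts are normalised to `log2(count / library_size * 1e6 + 0.5)`. The 0.5
prior count is the conventional stabiliser for zero counts; its influence
vanishes as counts grow. Lowly expressed features are removed before
testing: a feature must reach CPM ≥ 1 (inclusive) in at least as many
samples as the smallest (model, arm, day) group.

The DE engine is a Welch (unequal-variance) two-sided t-test on log-CPM per
contrast, with Benjamini–Hochberg adjustment across all features *within one
contrast* (one model × day), mirroring the per-contrast convention of
moderated linear-model pipelines. This is a deliberate simplification of a
moderated-variance fit: it forgoes precision weights and variance shrinkage,
costing some power at small n but keeping the contrast structure and
thresholds identical; a moderated option could be added behind the same
contract. Features that are constant in both groups get p = 1 (no
evidence), never NaN. The DE call is |log₂FC| ≥ 0.6 AND adjusted p ≤ 0.05.
(Some published variants of this analysis style use 0.5 as the fold-change
cutoff; 0.6 is the default here and both are configurable.) Under the global
null the engine is slightly conservative (empirical type-I rate ≈ 0.043 at
nominal 0.05 on simulated overdispersed counts), a known property of t-tests
on log-transformed counts.

## Lung-function coupling

The phenotype trajectory is the treated-arm group-mean lung compliance
(mL/cmH₂O) per day — five points per model. Correlation is computed between
a feature's five per-day log₂FC values and the five compliance values
(Pearson by default). With five points r is granular and no p-value is
attached; selection uses the threshold alone (|mean r| ≥ 0.85 across the two
models by default, with a strict per-model mode available). Gene selection
additionally requires day-21 adjusted p ≤ 0.05 in both models and a
consistent sign of the day-21 log₂FC, and ranks by mean day-21 log₂FC.
Per-animal correlation is not attempted: log₂FC is a group-level quantity.

The model-specificity partition at a given day uses magnitude-only cutoffs
(|log₂FC| ≥ 0.6 in one model exclusively, or in both → "common", signs
free); direction consistency is enforced later in gene selection rather than
in the partition.

## Seed conservation

Seeds are mature positions 2–7 (1-based, inclusive). Mouse–human pairs are
matched by name after stripping the species prefix, case-insensitively; the
-5p/-3p arm must match. Both seeds and full mature sequences are scored by
global Needleman–Wunsch alignment with match = 1, mismatch = 0 and a linear
gap penalty of −2 per gapped symbol. No standard gap value exists for this
scoring scheme; −2 is configurable, and for equal-length 6-nt seeds any
negative gap penalty makes gaps suboptimal, so the conservation rule —
*conserved* ⇔ seed score = 6 ⇔ seed identity — is gap-insensitive (asserted
as a property test). The mature-similarity flag defaults to score ≥ 20
(inclusive); a strict `> 20` switch exists because both conventions appear
in practice. Mouse miRNAs without a same-name human partner are categorised
`unpaired` and treated as non-conserved by the exclusion filter.

## miRNA–mRNA pairing and network

Spearman's ρ is computed for every (miRNA, mRNA) combination across all
samples of both models and all time points on filtered log-CPM, vectorised
as a product of standardised rank matrices (ties get average ranks).
High-confidence pairs satisfy ρ ≤ −0.6 AND sequence-based prediction by at
least 2 of the 5 tool columns in the prediction table; all comparisons are
inclusive. External prediction tables are the primary prediction source; the
built-in `seedmatch` predictor (reverse-complement seed occurrence in a
target sequence) exists so synthetic pipelines are self-contained.

The network's nodes are the selected miRNAs and their first-neighbour mRNAs;
mRNA–mRNA co-expression edges (Spearman by default, Pearson configurable —
the edge-correlation kind is a genuinely open choice) are added at r ≥ 0.75.
Nodes carry the day-21 log₂FC in the AAV model, the number of significant
contrasts, and the lung-function correlation. SIF uses relation tokens
`represses` and `coexpr`; GraphML carries all annotations as attributes.

## Staged miRNA selection

Stages, in order: (1) |mean r| ≥ 0.85, the sign of r defining direction
(anti-correlated with compliance ⇒ UP); (2) DE at ≥ 1 time point in each
model (configurable to either-model); (3) day-21 log₂FC signs must agree
between models and match the correlation-derived direction; (4) UP ∧
non-conserved candidates excluded; (5) high-confidence targets attached for
reporting. The stage-1/2 thresholds reuse the mRNA pipeline's values — the
only thresholds stated anywhere for this analysis style — and are fully
configurable. The audit table records every candidate's fate, so per-stage
in/out counts are always reconstructable; each stage's output is provably a
subset of its input.

## Synthetic study generator

The generator emulates the study conditions, not any particular dataset:

- **Compliance.** Baseline 0.06 mL/cmH₂O (typical for adult mice), a
  logistic deficit ramp reaching a 50 % drop: Bleomycin with midpoint day 6
  (declining from the first sampling day), AAV-TGFβ1 with the midpoint
  shifted by the onset delay (default 7 days, flat at day 3), both models
  near their minima at day 21. A smooth ramp rather than a hard step mirrors
  the gradual fibrotic stiffening of the real phenotype. Measured
  trajectories add 0.5 % log-normal noise.
- **Counts.** Negative binomial via a gamma–Poisson mixture, dispersion 0.05
  (typical for inbred-mouse bulk RNA-seq), gene-wise baselines drawn
  log-normally (σ = 1.5) and scaled to an expected library of 10⁶ with ±15 %
  log-normal library-size variation. Defaults: 2 000 genes, 300 miRNAs —
  desk-scale universes chosen so a 20-seed recovery run completes in well
  under a minute while leaving the multiple-testing burden meaningful.
- **Planted structure.** 20 UP and 10 DOWN tracking genes and 12 planted
  miRNAs (UP/DOWN × conserved/non-conserved: 4/2/4/2) whose log₂ signal is
  the model's compliance deficit normalised to day 21 and scaled to an
  effect size of 2.0 at day 21 (within the range of strongly induced
  fibrosis markers). Planted features are drawn from a well-expressed
  baseline stratum, as real fibrosis markers are. Each planted miRNA
  receives 3 targets whose means are multiplied by (1 − ρ·s) for induced
  miRNAs and (1 + ρ·s) for lost miRNAs, with repression strength ρ = 0.8 and
  s the normalised disease signal — so repression by induced miRNAs is
  strong (down to 0.2×) while de-repression saturates at 1.8×, making
  DOWN-miRNA pairs intentionally harder to recover. Human orthologs of
  conserved planted miRNAs share the seed exactly and keep ≥ 20 matching
  mature positions; non-conserved orthologs differ in ≥ 1 seed position.
  The prediction table supports every planted pair with 2–3 tools and adds
  decoys: single-tool random pairs, single-tool anticorrelated pairs, and
  two-tool uncorrelated pairs, so both filters of the intersection can fail.
- **Determinism.** One integer seed drives everything; identical configs
  produce byte-identical artifacts.

**What passing recovery tests show — and don't.** On 20 seeded default
studies the pipeline recovers planted tracking genes with sensitivity ≥ 0.9
and false-discovery proportion ≤ 0.1, planted hit miRNAs with sensitivity
≥ 0.9, and planted miRNA→target pairs through the high-confidence
intersection with sensitivity ≥ 0.8. The generator omits batch effects,
cell-type composition shifts, shared-pathway correlation between unplanted
genes, mapping artifacts and the partial day-28 resolution seen in real
Bleomycin studies; recovery on this simulator therefore demonstrates
internal correctness of the filter cascade under its own noise model, not
expected operating characteristics on real data. One intrinsic effect the
simulator *does* share with real data: because CPM is compositional, strong
planted mass changes shift unplanted features' apparent log₂FC slightly
negative; at the default universe size this bias is ≈ 0.03 log₂ units and
negligible, which is why Monte-Carlo calibration checks run at full default
size rather than on reduced fixtures.

## Numerical choices and degenerate inputs

Undefined correlations (zero variance, all ties, fewer than 3 points) raise
a typed error in the scalar primitives and become explicit NaN + flag in
tabular outputs — never silent zeros. BH adjustment delegates to the
standard step-up implementation and is verified against a from-definition
oracle. Ranking ties in `pattern_rank` are broken by stable sort; undefined
correlations rank last. The pipeline's TSV outputs carry the run's config
hash as a `#` comment header (readers skip comment lines); GraphML stores it
as a graph attribute; SIF has no reliable comment syntax, so the SIF file's
hash is recorded in the run log instead.

## Known limitations

Welch-t DE is underpowered relative to moderated-variance engines at n ≤ 5
per group; five-point correlations cannot distinguish r = −0.85 from −0.95
reliably; the seed-match predictor models only exact 6-mer complementarity
(no wobble pairing, context scores or free energy); and the staged-selection
thresholds, while faithful defaults, are conventions rather than optimised
values.
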