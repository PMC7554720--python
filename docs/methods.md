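# Methods

This note records the models, assumptions and numerical choices behind
`pamuslink`, in the order the pipeline runs them.

## Study design assumed throughout

A three-arm continuous-culture experiment: control (C), nitrogen-deprived
(N-) and phosphorus-deprived (P-) turbidostats, four vessels per arm. The
proteome is measured once (day 3) on a single TMT 10-plex — 4 C, 4 N- and
2 P- channels, because ten labels cannot cover twelve vessels — while the
transcriptome covers all twelve vessels on days 3 and 5. The replicate unit
is the vessel; protein and transcript samples from the same vessel are
matched by that unit. The pipeline therefore must tolerate unequal sample
sets between assays, and every analysis that pairs the two omics layers
forms pairs only for vessels present in both.

## Synthetic data generator

The generator (`pamuslink.simulate`) emulates the statistical structure the
analysis assumes; its defaults are the study conditions above.

Per gene g: a baseline log2 mRNA abundance `m_g ~ N(4, 1.5²)`; a treatment
effect `δ_g` per contrast, nonzero for a Bernoulli-chosen fraction of genes
(defaults 40% for N- with SD 0.8 log2 units; 3% for P- with SD 0.4 — a
dense strong contrast against a sparse weak one); day-5 effects are the
day-3 effects scaled by 1.6, same sign (monotone escalation). A coupling
coefficient `κ_g ∈ {+1, −1, 0}` with mixture (0.79, 0.21, 0.00) links the
layers: the protein log2 deviation is `κ_g · (δ + b)` where
`b ~ N(0, 0.15²)` is a per-vessel biological fluctuation shared between
assays. Compartment shifts add a constant to protein effects for annotated
compartments (default: plastid −0.4 log2 under N-, emulating plastid
proteome shrinkage). Protein baselines follow mRNA baselines with cross-gene
slope 0.5 plus N(0,1) scatter, so abundance–abundance correlation is
moderate, not perfect.

Reporter intensities per PSM are true per-channel linear abundance × a fixed
lognormal per-peptide response factor (σ = 0.5) × lognormal noise at CV 0.20,
mixed by a TMT isotope-impurity matrix (default: 3% leakage into each
adjacent channel). Response factors are fixed per peptide, which makes
reporter *shares*, not absolute intensities, the informative signal — raw
responses are only semi-quantitative across proteins. The number of distinct
observed peptides is Binomial(n_observable, target PAI), with the target PAI
rising in standardised log protein abundance (base 0.40, slope 0.15): this
is exactly the empirical PAI–log-abundance relationship that justifies emPAI
as an abundance estimate, and without it Mol% would carry no between-protein
signal. A configurable fraction (10%) of proteins yields a single unique
peptide, so the identification filter has real work; 3% decoy PSMs with low
posterior probabilities are appended. Transcript counts are
negative-binomial with per-sample expected counts proportional to
(2^log2-abundance × gene length), depth 3×10⁶ reads per sample, dispersion
0.05 (variance μ + αμ²; α = 0 degenerates to Poisson exactly).

Two planted GO terms (35 members each) are assembled by sampling genes whose
true N- protein effect exceeds ±0.3 log2 units — sampled across the whole
shifted tail rather than the extreme order statistics, so set membership
overlaps the background L2fc distribution the way real pathways do (taking
only the most extreme proteins produces quasi-separated logistic fits whose
Wald p-values collapse).

What the generator does **not** emulate: spectrum-level structure (m/z
peaks, fragmentation, chimeric spectra), peptide modifications and charge
states, read-level sequencing artefacts, batch effects, and — by default —
missing channels (a `missingness` knob exists but the default is complete
observation, since the real pattern of partial observation is not
characterised). Passing tests on this generator therefore demonstrate
correctness of the estimators under the assumed generative structure, not
robustness to acquisition artefacts.

All draws flow from one seed through per-stage child generators
(`default_rng([seed, stage])`), so each artefact — and the whole pipeline —
is bit-reproducible.

## Quantification

Digestion follows the tryptic rule (cleave after K/R unless followed by P);
missed cleavages concatenate up to m+1 adjacent fragments; duplicates count
once; modifications and charge states are ignored. The observable window is
monoisotopic 500–5000 Da (a typical Orbitrap precursor range), configurable;
the emPAI definition counts peptides within the instrument's scan range, and
0 missed cleavages is the default. Identification filtering thresholds
posterior probabilities so the estimated FDR (mean posterior error of the
retained prefix) stays at or below 3% at both peptide and protein level,
then requires ≥ 2 unique peptides per protein. Shared peptides are assigned
to the accession with the most unique peptides (ties: lexicographic) — a
parsimony rule in the spirit of cluster-style protein reporting. Isotope
correction solves the mixing system per PSM; negative solutions (noise) are
clamped to zero with a logged warning; a singular matrix is an error.
PSM-to-protein intensity aggregation is a sum (mean available via options).

Mol% conservation (each sample summing to 100) is exact by construction and
asserted to 1e-9. Because emPAI is a ratio of small integer counts, it is a
*discretised* abundance estimate: between-protein Mol% ordering matches true
abundance ordering only up to that discretisation (tests assert Spearman
ρ > 0.9 under zero noise), whereas the within-protein channel profile is
exactly proportional to true per-channel abundance under zero noise and
identity impurities.

## Differential expression

The permutation statistic is the absolute difference of group means of log2
abundance — two-sided by construction. With n_a + n_b samples the test
enumerates all C(n, n_a) label assignments exactly when there are ≤ 10,000,
otherwise it samples with a seeded generator; the add-one estimator
`p = (1 + #{perm ≥ obs}) / (1 + #perm)` keeps p strictly positive so BH is
well defined.

Exact enumeration on small designs makes p-values coarse: 4 vs 4 gives 70
assignments and a floor of 3/71 ≈ 0.042 (the observed assignment and its
mirror always count); 2 vs 4 gives 15 assignments and a floor of
2/16 = 0.125, so that contrast cannot reach p < 0.05 at all — the code
emits an under-powered-contrast warning. Two consequences are handled
explicitly:

- *Significance tiers.* A BH cut at 0.05 can only reject when the great
  majority of features sit at the p floor, so on a 40%-affected study the
  BH tier is empty by construction at this design size. `protein_de`
  defaults to the BH call, but the pipeline's run-report significance tier
  uses a per-contrast raw-p threshold (default 0.05) — the volcano-plot
  "central segment" convention — while always reporting `p_adj` and the BH
  boundary re-expressed on the raw-p scale (`corrected_raw_threshold`,
  which is consistent with `bh_adjust` by construction). Both thresholds
  are configurable per contrast.
- *Calibration designs.* Type-I-error checks use 6-vs-7-sample-per-group
  designs (924–3432 assignments), where the attainable level just below
  0.05 is 0.048–0.049; at 4 vs 4 the attainable level is 1/35 ≈ 0.029, a
  property of the discrete test, not an implementation artefact.

Transcript counts are normalised with median-of-ratios size factors
(geometric-mean reference over genes with no zero counts) — the same
normalisation family as the negative-binomial GLM tools this stand-in
replaces — then tested with the same permutation machinery on
log2(normalised + 1); the fold change itself is computed from normalised
means without pseudocount. The DE call is `p_adj < 0.05 AND |L2fc| > 1.0`
(absolute value: both tails). No shrinkage, independent filtering or
interaction models.

## Correlation framework

RPKM = count / (length_kb × mapped_reads_millions). Abundance models use
natural logs; all fold changes use log2. Zero Mol% or RPKM values are
excluded from log-scale fits (counted, not pseudocounted); pairs with
RPKM < 2.0 are excluded from the pooled model (configurable; raising the
threshold never adds pairs).

The pooled model is `log_rpkm ~ log_molpct` with random effects
`~1 + log_molpct | replicate`, fitted by REML via statsmodels MixedLM.
The fixed-slope confidence interval uses t quantiles with
`df = n_replicates − 2` rather than normal quantiles: with ~10 replicate
groups the Wald interval undercovers the generating slope (observed ~85–90%
for a nominal 95%), and the between-group-df correction restores coverage —
the same small-sample practice as Satterthwaite-style mixed-model inference.
Fewer than two replicates is an error (the model is degenerate; pooled OLS
is the advice in the message). The pooled Pearson R² is computed on the raw
filtered pairs, not on fitted values.

Per-gene fits regress ln RPKM (response) on ln Mol% (predictor), matching
the pooled model's orientation; R² is orientation-invariant and slope *sign*
is unaffected by the choice. Genes need ≥ 3 matched points; constant
predictors are excluded with reason codes. The slope-sign census drops
exactly-zero slopes and reports fractions over genes with a defined sign,
optionally restricted to significantly regulated proteins (the run report's
raw-p tier).

## Compartments

Location strings are split on commas/semicolons/periods and scanned left to
right; the first segment matching the shipped vocabulary decides
(first-listed precedence), so "Plastid, chloroplast thylakoid membrane" is
plastidial. Within a segment, longer vocabulary terms match first
("thylakoid membrane" before "membrane"); "chloroplast" synonymises to
plastid and membrane sub-locations roll up to "membrane". The mapping file
(`data/compartment_map.tsv`) is the extension point. An opt-in multi-assign
mode duplicates a protein into every listed compartment (counts then sum to
≥ n_proteins). Summaries report n, median L2fc and IQR per compartment;
groups below 5 proteins are flagged.

## Enrichment

The universe is the quantified features; set members without an L2fc are
removed before size filtering. The logistic model regresses membership
(0/1) on L2fc alone (no covariates); the slope is the log-odds ratio, p is
the slope's Wald test, and complete separation is caught and reported with
an infinite-LOR flag and a likelihood-ratio bound p-value instead of
crashing. Fisher tests are the classic hierarchy-free variant — one-sided
hypergeometric on the 2×2 (in-set × in-direction) table, run separately for
up and down lists, terms with < 5 annotated genes pruned. The set-level test
collapses GAGE's sample-resampling layer into a single member-vs-non-member
Welch t on precomputed L2fc (the inputs are already per-gene statistics);
only sets with *more than* 5 members are tested (strict inequality);
unidirectional mode reports a one-sided p per direction (BH within
direction), bidirectional mode tests |L2fc| two-sided. Default significance:
q < 0.01 (logistic), q < 0.05 (Fisher, set-level).

## Pipeline and reproducibility

One YAML config drives simulate → quantify → DE → correlate → compartments
→ enrich, with stage toggles. Every output TSV carries a versioned header
comment (`# pamuslink v… schema=… table=…`) and stable float formatting, so
a rerun with the same seed is byte-identical; wall-clock timings appear only
in log lines, never in files. The run report collects per-stage feature
counts (quantified proteins, significant calls per contrast, pairs,
compartments, enriched terms) plus a config echo and the seed.

## Problem sizes and test design

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own working sizes: studies of 150–1000 genes,
null calibrations with 2000–2500 features/terms, 20-replication coverage
checks, and 3-replicate averages for the discrete Fisher null (with an
exactly balanced up/ns split, whose attainable level just below 0.05 is
stable at ≈ 0.040). The 10-feature logistic worked example is checked
against a coarse grid-search maximum-likelihood oracle; digestion, masses,
BH, Fisher and 4v4 permutation p-values are checked against independent
brute-force computations.

## Known limitations

- The exact-permutation p floor makes BH-tier protein significance
  unattainable at the 10-channel design size, and the 2-channel P- contrast
  cannot reach raw p < 0.05; both facts are surfaced (warnings, reported
  thresholds) rather than worked around. Finer inference would need a
  different permutation scheme (e.g. spectrum-level) that the quantification
  source tools do not document.
- Transcript DE at 4 vs 4 with exact enumeration likewise rejects nothing at
  the joint BH + fold-change call at desk scale; the stand-in is calibrated
  and powered at larger replicate numbers (shown in tests) but is not a
  substitute for negative-binomial GLM inference on real data.
- emPAI discretisation bounds how finely Mol% can order proteins of similar
  abundance.
- The generator's coupling is linear on the log2 scale with fixed |κ| = 1;
  real translational regulation is heavier-tailed and time-dependent.
- GO terms are flat labels; no DAG propagation or hierarchy-aware testing.
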