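# Methods

## Scope and shape

`oncomito` is a library: the importable API plus `examples/` scripts are the
interface, and the pipeline stages are plain functions over a small set of
containers (`OmicsMatrix`, variant dataclasses, pandas frames). No console
entry point is shipped; `cohort.write_cohort` materializes a full synthetic
cohort directory where a shell-level "simulate" step would otherwise live.

## Differential testing

Per feature, an unpaired Welch t-test on log2 values, Benjamini–Hochberg
adjusted (via statsmodels), significant at q ≤ `fdr_level` (default 0.05);
the metabolome stage adds a nominal p ≤ 0.01 gate, and both gates are
configurable because the two criteria select almost but not exactly the
same set at these sample sizes. Samples are patient-matched, yet the
unpaired test is the default deliberately — it is the conventional choice
for this assay type at n = 6 — and a paired option is exposed. Welch
(unequal variances) rather than pooled: the robust default for small tissue
cohorts. Degenerate features (zero variance in both groups) get p = 1 when
the means agree and p = 0 otherwise; features with fewer than two valid
values in a group are skipped and logged.

## Left-censored imputation

Missing label-free intensities are assumed missing-not-at-random
(left-censored). Per sample column with observed mean m and SD s, missing
cells are drawn from N(m − 1.8·s, (0.3·s)²). The width 0.3 and downshift
1.8 are the conventional defaults of the mainstream label-free analysis
software; both are exposed in `ImputationParams`. Observed cells are never
altered; moment estimates need on the order of 30 observed values per
column to be stable.

## Compartment stratification

The regulation rule is mean ± 1 SD of log2 fold change *within* the
mitochondrial and non-mitochondrial compartments separately; the
mitochondrial annotation is a positive list (unannotated features count as
non-mitochondrial). With a degenerate zero-SD compartment no calls are
made. Mass ratios are per-patient ratios of summed raw-scale intensities
("total abundance"), not log-space means, with missing cells contributing
zero to the sums; the cohort mean ± SD of the per-patient ratios is
reported, which matches how such cohorts report a mean with a patient-level
SD.

## Enrichment

Weighted running-sum statistic with weight exponent default 1 (the classic
choice; weight 0 gives the plain KS form). Ranking ties are broken by
feature id for determinism. Significance uses gene-set permutation —
random member sets of equal size — because 6 + 6 phenotype labels admit far
too few distinct permutations. NES divides ES by the mean |null ES| of the
same sign; the nominal p is one-sided within the same-sign null, and the
FDR q compares the pooled null NES distribution with the observed NES
distribution, sign-stratified, as in the standard procedure. The floor of
the nominal p is 1/(1 + #same-sign permutations), so claims below 0.001
need several thousand permutations. Both published significance gates are
exposed (FDR ≤ 0.15 default, 0.25 optional).

## mtDNA

HF = alt/(alt+ref) with a Wilson score interval (statsmodels). Origin
calls: somatic if the variant is undetected in normal tissue or its normal
HF is below `detection_limit` (default 0.005); germline if present in both
tissues with |ΔHF| ≤ `hf_tolerance` (default 0.10); otherwise
unclassified. The tolerance is a design choice — concordance is required
but no numeric bound is standard — and both knobs live in
`MtdnaThresholds`.

Annotation translates the affected codon under the vertebrate mitochondrial
genetic code (Biopython table 2: AGA/AGG stops, ATA = Met), honoring strand
(the ND6-like gene is minus-strand). The packaged reference is a
**synthetic** 16,569 nt genome built deterministically in code
(`synthetic_genome`): the real gene order and coordinates are mimicked,
protein frames are stop-free by construction, and no real sequence is
shipped. Tests verify annotation against an independent full-CDS
translation oracle over every possible substitution in representative
genes.

Prioritization applies, in order: haplogroup-defining exclusion (the site
list is an input; haplogroup *prediction* is out of scope), then
variability < 0.0026 AND score > class threshold (0.43 / 0.35 / 0.60 for
non-synonymous, tRNA, rRNA). Stop-gain variants use the non-synonymous
threshold. Disease scores and variabilities are input annotations — the
package validates and applies thresholds, it does not compute them.

Copy ratio: per sample, dose = mean mtDNA coverage / mean nuclear coverage;
per pair, ratio = dose_tumor / dose_normal; cohort mean ± SD. The preset
truth is 1.79 (the figure-legend value; the same quantity is elsewhere
rounded to 1.6- or 1.8-fold).

## Nuclear statistics

The spectrum collapses all 12 substitution types onto the six
pyrimidine-reference classes (strand-symmetric by definition); indels are
skipped and counted. Ti/Tv = (C>T + T>C) / (four transversion classes).
Class enrichment is a two-sided exact binomial test against a baseline
spectrum, uniform by default — the published enrichment p-values were
produced by an unnamed test against an unstated baseline, so matching them
numerically is explicitly not attempted. The CNV dose test compares the
mean log2 fold change of loss-segment genes (gene midpoint inside a
half-open BED interval, copy state < 2) with means of equally sized random
gene draws; the one-sided p uses the add-one estimator (never exactly
zero). NaN fold changes count as unquantified and are excluded from both
the observed set and the null universe — leaving them in biases the null.

## Metabolome

Normalization divides each sample by its tissue amount and then its
internal-standard response. Fold changes are formed after flooring
sub-LOQ values to the metabolite's floor; flooring raises only the low
side, so an extreme fold like glutathione's (normals entirely below LOQ)
is a conservative lower bound. The default floor is the per-metabolite LOQ
supplied with the data; the fallback is the smallest positive observed
value of that metabolite. Fold changes are reported both as plain ratios
and in the signed convention (down-regulation as −1/ratio). One value per
metabolite per sample is modeled (single-transition peak areas).

## Synthetic cohorts

The generators define the study conditions; their defaults are the
`oncocytoma_v1` preset.

- **Proteome** (2000 proteins, 25% mitochondrial, 6 pairs): log2
  intensities N(base_i + effect, 0.5²), base_i ~ N(25, 2²). Per-patient
  mitochondrial mass factors are lognormal with mean 2.22; the natural-scale
  SD is 0.4, deliberately tighter than the 1.63 a real cohort shows, so
  twenty-cohort recovery has stable error bars while the mean structure is
  preserved. Non-mitochondrial factors: mean 0.97, SD 0.06. Forty CI
  subunits are instead set to factor 0.35 (depletion replaces the mass
  boost); five assembly factors per complex keep the boost, reproducing the
  "assembly factors up, CI subunits down" signature. MNAR missingness is a
  logistic function of the log2 value: P(missing) = 1/(1 + exp(k·(x − t)))
  with t at the 5% intensity quantile and steepness k = 2, giving ~6%
  overall missingness concentrated at low abundance. Note the preset truth
  for the *mitochondrial mass ratio* is the factor mean 2.22, while the
  recovered total-abundance ratio sits near 2.05–2.10 because depleted CI
  carries ~8% of mitochondrial intensity mass — a property of the preset,
  not an estimator bias.
- **Metabolome** (159 metabolites): 29 carry the reference signed folds
  (16 up, 13 down), the rest are null. Residual noise is lognormal with
  CV 0.20; an additional per-patient, per-metabolite lognormal effect
  (CV 0.20) is shared between the tumor and normal sample of a patient,
  because matched tissues correlate — the published table states no
  within-cohort dispersion, so both CVs are package choices, flagged in
  `MetabolomeSim`. Glutathione is emitted below its LOQ floor in every
  normal sample with tumor abundance at fold × floor. Raw values are
  multiplied by per-sample tissue masses and internal standards that the
  normalization stage divides back out.
- **mtDNA**: 54 germline events (59.3% haplogroup-flagged, concordant HF,
  mostly homoplasmic), 195 tumor-only events with HF ~ U(0.006, 0.069)
  except one homoplasmic non-synonymous variant; allele depths are binomial
  at depth 2000. The somatic class mix (35 synonymous / 63 non-synonymous /
  19 stop-gain / 78 non-coding) and the score pass rates (85.7% of somatic
  non-synonymous above threshold, 77.8% below the variability cutoff) follow
  the reference composition. Coverage summaries realize per-pair copy
  ratios lognormal around 1.79 (SD 0.64) with 10% coverage jitter.
- **Nuclear**: per-patient non-silent burdens lognormal with median 78
  (log-SD 0.5); effect classes proportional to 799:760:19:11:8; SNV classes
  multinomial on the six-class spectrum (400, 426, 1696, 259, 1228, 274)
  with random pyrimidine/purine strand representation; frameshifts as
  1-bp indels.
- **CNV**: two clonal loss segments of ~50 contiguous genes each (carrier
  fraction configurable); affected proteins get −0.5 log2 added to tumor
  columns.

What the generators do **not** emulate: correlated protein co-regulation
beyond the compartment/complex structure, batch effects, peptide-level
quantification noise, mtDNA strand bias or mutational signatures beyond the
six-class mix, subclonal CNV mosaics, or metabolite cross-talk. Passing
recovery tests therefore demonstrates estimator correctness under the
assumed generative structure, not robustness to every artifact of real
tissue data.

## Problem sizes and numerical choices

Recovery protocols use 20 cohorts × 6 pairs (2000 proteins / 159
metabolites), which puts Monte-Carlo error on cohort means near 2–4% —
comfortably inside the 10–15% recovery tolerances. Permutation tests use
300–5000 draws depending on the p-value resolution a claim needs.
Distinct RNG sub-seeds are derived for generation, segment placement,
imputation and permutation; sharing one stream across stages demonstrably
couples "random" gene draws to the data they are tested against.
Enrichment-score ties (|max deviation| equal on both sides) take the first
extreme; ES is clamped to [−1, 1] against ~1e-16 cumulative rounding.
Wilson bounds are clamped around the point estimate for the same reason.

## Known limitations

Published cohort-level results that depend on the real datasets (the 1823
quantified proteins, the 141 significant proteins, specific pathway NES
values, the p = 0.011 CNV test) are not reproducible from synthetic data
and are covered instead by calibration, oracle and recovery tests. The
GSEA implementation is calibration-tested, not bit-compatible with any
particular desktop GSEA release. Haplogroup prediction, variant calling,
spectral search and kinetic flux modeling are out of scope; their outputs
are this package's inputs.
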