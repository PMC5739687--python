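# oncomito

Multi-omics analysis of mitochondria-rich renal tumors (oncocytomas) against
patient-matched normal kidney tissue, for analysts working with label-free
proteomics, targeted metabolomics and exome-derived variant tables from small
matched cohorts.

Renal oncocytomas accumulate defective mitochondria: the mitochondrial
proteome shifts up roughly 2.2-fold while respiratory complex I (CI) is
selectively lost, mtDNA content rises in parallel, low-level heteroplasmic
mtDNA mutations accumulate, and the metabolome shows a massive glutathione
elevation against a below-detection normal background. Each of those
signals needs its own statistical treatment, which this package provides:

- **Compartment-stratified proteomics.** A global fold-change cutoff would
  call the entire mitochondrial proteome regulated, so log2 fold changes are
  split into mitochondrial / non-mitochondrial compartments and a protein is
  called regulated only beyond one SD from its compartment mean
  (`compartment_stats`). Mitochondrial mass is quantified as per-patient
  ratios of summed raw intensities (`mito_mass_ratio`); missing intensities
  are left-censored and imputed from a down-shifted Gaussian,
  N(m − 1.8·s, (0.3·s)²) per sample column (`impute_gaussian`).
- **Gene-set enrichment** with the weighted Kolmogorov–Smirnov-like running
  sum: hits add |r|^w / Σ|r|^w, misses subtract 1/(N − n_hits); ES is the
  signed extreme deviation, NES and FDR come from gene-set permutation
  (`gsea_run`, minimum set size 5).
- **mtDNA heteroplasmy.** HF = alt/(alt+ref) with Wilson 95% intervals;
  germline/somatic calls from tumor–normal HF concordance; in-frame
  annotation under the vertebrate mitochondrial code; prioritization of
  variants with nucleotide variability < 0.0026 and disease score above
  class thresholds (0.43 non-synonymous, 0.35 tRNA, 0.60 rRNA), after
  excluding haplogroup-defining sites (`prioritize`). mtDNA dose is
  estimated from coverage summaries as (mt/nuclear)-coverage ratios.
- **Nuclear mutation statistics.** Six-class pyrimidine-reference
  substitution spectrum, Ti/Tv, per-tumor non-silent burden, exact binomial
  class enrichment, and a permutation test for protein dose effects under
  CNV loss (`cnv_dose_test`).
- **Targeted metabolomics.** Tissue-mass / internal-standard normalization,
  LOQ-floored fold changes (sub-floor values are raised to the floor before
  ratio formation, making extreme folds conservative), Welch t-tests with
  Benjamini–Hochberg control at FDR 0.05 plus a p < 0.01 gate
  (`metabolome_differential`).
- **A synthetic matched-cohort generator** (`oncomito.cohort`) that emits
  all of the above inputs with known ground truth, so every stage is
  testable without any download.

## Worked example

```sh
python examples/metabolome_report.py
```

```
159 metabolites tested, 28 significant (15 up, 13 down in tumor)

top of the report (sorted by signed fold change):
  Reduced glutathione                 fold   5163.54  p=0.0000  q=0.0000  amino acids, peptides, and analogues
  Oxidized glutathione                fold    221.42  p=0.0000  q=0.0000  amino acids, peptides, and analogues
  N-Acetylneuraminic acid             fold     10.16  p=0.0000  q=0.0000  sugar acids and derivatives
  ...
glutathione fold is formed against the LOQ floor (censored=True): 5164-fold elevation
```

One seeded cohort of 6 tumor/normal pairs: the stage recovers the preset
effect table — 13 down-regulated metabolites exactly, 15 of the 16
up-regulated ones at this seed, and the glutathione fold (truth 5413) within
5% despite every normal-tissue value sitting below the LOQ floor. The other
examples cover the proteome mass shift and OXPHOS summaries
(`proteome_mass_shift.py`), mtDNA prioritization (`mtdna_prioritization.py`),
the mutation spectrum and CNV dose test (`nuclear_spectrum.py`), enrichment
(`gsea_demo.py`), and materializing a full cohort directory
(`simulate_cohort.py`).

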