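"""Mitochondrial mass shift and compartment-stratified regulation calls.

Generates one six-pair cohort, applies the stringent validity filter and
left-censored imputation, then computes per-patient total-abundance ratios
by compartment and the one-SD regulation thresholds.
"""

from oncomito import (
    compartment_stats,
    filter_min_valid,
    gen_proteome,
    impute_gaussian,
    log2_fold_changes,
    mito_mass_ratio,
    oncocytoma_v1,
    oxphos_complex_summary,
)

matrix, annotation, truth = gen_proteome(oncocytoma_v1(), seed=1)
print(f"generated {matrix.values.shape[0]} proteins x {matrix.values.shape[1]} samples,"
      f" {matrix.missing_mask().to_numpy().mean():.1%} missing (left-censored)")

filtered = filter_min_valid(matrix, "each_group_min3")
imputed = impute_gaussian(filtered, seed=2)
print(f"{len(filtered.features)} proteins pass the 3-of-6-per-group filter")

table, summary = mito_mass_ratio(imputed, annotation)
print(f"mitochondrial mass ratio: mean {summary['mito'][0]:.2f}"
      f" +- {summary['mito'][1]:.2f} SD (tumor accumulates mitochondria)")
print(f"non-mitochondrial ratio:  mean {summary['non_mito'][0]:.2f}"
      f" +- {summary['non_mito'][1]:.2f} SD (rest of the proteome unchanged)")

log2fc = log2_fold_changes(imputed)
thresholds, calls = compartment_stats(log2fc, annotation)
for label, th in thresholds.items():
    n_up = ((calls == "up") & (log2fc.index.isin(calls.index))).sum()
    print(f"{label}: up if log2fc > {th.up_cutoff:.3f}, down if < {th.down_cutoff:.3f}")
print(f"regulation calls: {(calls == 'up').sum()} up, {(calls == 'down').sum()} down"
      " (one SD beyond the compartment mean)")

summaries, verdict = oxphos_complex_summary(log2fc, annotation)
for s in summaries:
    print(f"  {s.complex}: subunit median log2fc {s.subunit_median:+.2f},"
          f" assembly factors {s.assembly_median:+.2f}")
print(f"OXPHOS verdict: {verdict} (complex I selectively depleted)")
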