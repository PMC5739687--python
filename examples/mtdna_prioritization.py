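"""mtDNA heteroplasmy calling, annotation and pathogenicity prioritization.

Generates paired tumor/normal mtDNA variant tables, classifies each variant
as germline or somatic from its heteroplasmic fractions, and applies the
prioritization gates (haplogroup exclusion, nucleotide-variability cutoff
0.0026, class-specific disease-score thresholds 0.43 / 0.35 / 0.60).
"""

from collections import Counter

from oncomito import (
    MtdnaThresholds,
    classify_cohort,
    gen_mt_variants,
    mtdna_copy_ratio,
    oncocytoma_v1,
    prioritize,
)

variants, coverage, truth = gen_mt_variants(oncocytoma_v1(), seed=3)
classify_cohort(variants)
origins = Counter(v.origin for v in variants)
print(f"{len(variants)} mtDNA variants: {origins['germline']} germline"
      f" (concordant HF in both tissues), {origins['somatic']} somatic (tumor-only)")

somatic = [v for v in variants if v.origin == "somatic"]
hfs = [v.tumor_hf for v in somatic if v.tumor_hf < 0.5]
print(f"somatic heteroplasmic fractions span {min(hfs):.3f}-{max(hfs):.3f}"
      " — low-level heteroplasmy, each below the homoplasmy threshold")

thresholds = MtdnaThresholds()
prioritized = [v for v in variants if prioritize(v, thresholds).prioritized]
by_class = Counter(v.functional_class for v in prioritized)
print(f"{len(prioritized)} variants prioritized as potentially pathogenic: "
      + ", ".join(f"{n} {c}" for c, n in by_class.items()))

example = next(v for v in prioritized if v.functional_class == "nonsynonymous")
result = prioritize(example, thresholds)
print(f"example m.{example.position}{example.ref}>{example.alt} ({example.gene}):")
for reason in result.reasons:
    print(f"  - {reason}")

groups = {s: ("tumor" if s.endswith("_T") else "normal") for s in coverage["sample"]}
pairs = {s: s[:-2] for s in coverage["sample"]}
table, mean, sd = mtdna_copy_ratio(coverage, groups, pairs)
print(f"mtDNA copy ratio from coverage summaries: mean {mean:.2f} +- {sd:.2f} SD"
      " (tumors carry more mtDNA per nuclear genome)")
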