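"""Materialize a complete synthetic cohort directory.

Writes every data product the pipeline consumes — proteome and metabolome
matrices (TSV), protein annotation, mtDNA variants (TSV + per-patient VCF),
coverage summaries, nuclear variants, CNV segments (BED) — plus the
generator ground truth as JSON, so external tools can be pointed at the
same files the analyses read.
"""

import sys
from pathlib import Path

from oncomito import oncocytoma_v1
from oncomito.cohort import write_cohort

outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/cohort_demo")
truth = write_cohort(oncocytoma_v1(), seed=42, outdir=outdir)
print(f"cohort written to {outdir}/:")
for path in sorted(outdir.iterdir()):
    print(f"  {path.name:28s} {path.stat().st_size:>9,} bytes")
print(f"\nground truth covers {len(truth['metabolome']['true_fold'])} metabolites,"
      f" {len(truth['cnv']['loss_genes'])} CNV-loss genes,"
      f" copy ratios for {len(truth['mtdna']['copy_ratio'])} pairs")
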