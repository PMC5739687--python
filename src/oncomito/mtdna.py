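"""Mitochondrial DNA variant analysis.

This module covers the mtDNA arm of the pipeline: heteroplasmic-fraction
(HF) estimation with Wilson confidence intervals, germline/somatic
classification from paired tumor/normal allele depths, functional annotation
of substitutions against a mitochondrial gene map (vertebrate mitochondrial
genetic code), pathogenicity prioritization with class-specific disease-score
thresholds and a nucleotide-variability cutoff, and mtDNA copy-ratio
estimation from exome coverage summaries.

The packaged reference genome is *synthetic*: :func:`synthetic_genome`
deterministically generates a 16,569 nt sequence laid out like the human
mitochondrial genome (D-loop wrapping the origin, two rRNAs, tRNA punctuation,
13 protein genes with one on the minus strand, stop-free reading frames).  It
carries the coordinate structure needed by the annotation logic without
shipping any real sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from statsmodels.stats.proportion import proportion_confint

MT_GENOME_LENGTH = 16569

#: Vertebrate mitochondrial genetic code (AGA/AGG stops, ATA = Met).
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_MITO_STOPS = set(_MITO_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

FUNCTIONAL_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "stop_gain",
    "tRNA",
    "rRNA",
    "dloop",
    "other_noncoding",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class MtVariant:
    """A single mtDNA substitution with paired tumor/normal allele depths.

    ``tumor_ad`` / ``normal_ad`` are ``(ref_count, alt_count)`` tuples;
    ``normal_ad=None`` means the variant was not detected in the normal
    tissue at all (distinct from an observed alt count of zero).
    """

    position: int
    ref: str
    alt: str
    patient: str | None = None
    tumor_ad: tuple[int, int] | None = None
    normal_ad: tuple[int, int] | None = None
    gene: str | None = None
    functional_class: str | None = None
    nucleotide_variability: float | None = None
    disease_score: float | None = None
    rna_prediction_score: float | None = None
    haplogroup_defining: bool = False
    origin: str = "unclassified"

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise ValueError(
                f"mtDNA position {self.position} outside rCRS range 1..{MT_GENOME_LENGTH}"
            )
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def tumor_hf(self) -> float | None:
        if self.tumor_ad is None:
            return None
        return heteroplasmic_fraction(self.tumor_ad[1], self.tumor_ad[0])[0]

    @property
    def normal_hf(self) -> float | None:
        if self.normal_ad is None:
            return None
        return heteroplasmic_fraction(self.normal_ad[1], self.normal_ad[0])[0]


@dataclass(frozen=True)
class GeneInterval:
    """One feature of the mitochondrial gene map, 1-based inclusive."""

    start: int
    end: int
    gene: str
    product: str  # protein | tRNA | rRNA | dloop
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_GENOME_LENGTH):
            raise ValueError(f"interval {self.gene} outside 1..{MT_GENOME_LENGTH}")
        if self.product == "protein" and (self.end - self.start + 1) % 3:
            raise ValueError(f"protein gene {self.gene} length not a codon multiple")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class MtGeneMap:
    sequence: str
    intervals: tuple[GeneInterval, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_GENOME_LENGTH:
            raise ValueError("sequence must be the full 16,569 nt circle")

    def locate(self, position: int) -> GeneInterval | None:
        for iv in self.intervals:
            if position in iv:
                return iv
        return None


@dataclass
class PrioritizationResult:
    prioritized: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# synthetic reference
# ---------------------------------------------------------------------------
# Simplified, overlap-free layout following the human mtDNA gene order.
# The D-loop wraps the coordinate origin (16024..16569 plus 1..576; the
# hypervariable stretches HV1 16024-16383 and HV2 57-372 fall inside it).
_LAYOUT: tuple[tuple[int, int, str, str, str], ...] = (
    (1, 576, "MT-DLOOP", "dloop", "+"),
    (577, 647, "MT-TF", "tRNA", "+"),
    (648, 1601, "MT-RNR1", "rRNA", "+"),
    (1602, 1670, "MT-TV", "tRNA", "+"),
    (1671, 3229, "MT-RNR2", "rRNA", "+"),
    (3230, 3304, "MT-TL1", "tRNA", "+"),
    (3307, 4260, "MT-ND1", "protein", "+"),
    (4263, 4331, "MT-TI", "tRNA", "+"),
    (4402, 4469, "MT-TM", "tRNA", "+"),
    (4470, 5510, "MT-ND2", "protein", "+"),
    (5512, 5579, "MT-TW", "tRNA", "+"),
    (5587, 5655, "MT-TA", "tRNA", "+"),
    (5904, 7445, "MT-CO1", "protein", "+"),
    (7446, 7514, "MT-TS1", "tRNA", "+"),
    (7518, 7585, "MT-TD", "tRNA", "+"),
    (7586, 8269, "MT-CO2", "protein", "+"),
    (8295, 8364, "MT-TK", "tRNA", "+"),
    (8366, 8524, "MT-ATP8", "protein", "+"),
    (8527, 9207, "MT-ATP6", "protein", "+"),
    (9208, 9990, "MT-CO3", "protein", "+"),
    (9991, 10058, "MT-TG", "tRNA", "+"),
    (10059, 10403, "MT-ND3", "protein", "+"),
    (10405, 10469, "MT-TR", "tRNA", "+"),
    (10470, 10763, "MT-ND4L", "protein", "+"),
    (10767, 12137, "MT-ND4", "protein", "+"),
    (12138, 12206, "MT-TH", "tRNA", "+"),
    (12207, 12265, "MT-TS2", "tRNA", "+"),
    (12266, 12336, "MT-TL2", "tRNA", "+"),
    (12337, 14148, "MT-ND5", "protein", "+"),
    (14149, 14673, "MT-ND6", "protein", "-"),
    (14674, 14742, "MT-TE", "tRNA", "+"),
    (14747, 15886, "MT-CYB", "protein", "+"),
    (15888, 15953, "MT-TT", "tRNA", "+"),
    (15956, 16023, "MT-TP", "tRNA", "+"),
    (16024, 16569, "MT-DLOOP", "dloop", "+"),
)

_SENSE_CODONS = sorted(_MITO_TABLE.forward_table)  # all 60 non-stop codons


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def synthetic_genome(seed: int = 16569) -> MtGeneMap:
    """Deterministically build the synthetic mitochondrial reference.

    Intergenic and non-coding stretches are uniform random bases; protein
    genes are filled with a start codon followed by random sense codons so
    the reference frame contains no stop, which keeps stop-gain annotation
    unambiguous.  The minus-strand gene (MT-ND6) is written as the reverse
    complement of its coding sequence.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=MT_GENOME_LENGTH)
    intervals = tuple(GeneInterval(*row) for row in _LAYOUT)
    for iv in intervals:
        if iv.product != "protein":
            continue
        n_codons = (iv.end - iv.start + 1) // 3
        codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=n_codons - 1))
        cds = "".join(codons)
        if iv.strand == "-":
            cds = _revcomp(cds)
        seq[iv.start - 1 : iv.end] = list(cds)
    return MtGeneMap(sequence="".join(seq), intervals=intervals)


def write_gene_map(gene_map: MtGeneMap, path) -> None:
    """Write the gene map as a GFF-like TSV (1-based inclusive coordinates)."""
    rows = [
        {"start": iv.start, "end": iv.end, "gene": iv.gene, "product": iv.product,
         "strand": iv.strand}
        for iv in gene_map.intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# heteroplasmy
# ---------------------------------------------------------------------------
def heteroplasmic_fraction(
    alt_count: int, ref_count: int, *, conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """HF = alt / (alt + ref) with a Wilson score confidence interval."""
    if alt_count < 0 or ref_count < 0:
        raise ValueError("allele depths must be non-negative")
    depth = alt_count + ref_count
    if depth < 1:
        raise ValueError("zero total depth: HF undefined")
    hf = alt_count / depth
    lo, hi = proportion_confint(alt_count, depth, alpha=1 - conf_level, method="wilson")
    # guard against ~1e-18 rounding placing the bound on the wrong side of HF
    lo = min(max(float(lo), 0.0), hf)
    hi = max(min(float(hi), 1.0), hf)
    return hf, (lo, hi)


def classify_origin(
    tumor: MtVariant,
    normal: MtVariant | None = None,
    *,
    hf_tolerance: float = 0.10,
    detection_limit: float = 0.005,
) -> str:
    """Call a paired variant germline, somatic or unclassified.

    Somatic: undetected in the normal tissue, or normal HF below the
    detection limit.  Germline: detected in both tissues with concordant HF
    (|HF_t - HF_n| within ``hf_tolerance``).  Anything else is unclassified.
    """
    if normal is not None and (
        normal.position != tumor.position
        or normal.ref != tumor.ref
        or normal.alt != tumor.alt
    ):
        raise ValueError("tumor and normal records describe different loci")
    hf_t = tumor.tumor_hf
    if hf_t is None:
        raise ValueError("tumor allele depths required for origin classification")
    normal_ad = normal.normal_ad if normal is not None else tumor.normal_ad
    if normal_ad is None:
        return "somatic"
    hf_n = heteroplasmic_fraction(normal_ad[1], normal_ad[0])[0]
    if hf_n < detection_limit:
        return "somatic"
    if abs(hf_t - hf_n) <= hf_tolerance:
        return "germline"
    return "unclassified"


# ---------------------------------------------------------------------------
# functional annotation
# ---------------------------------------------------------------------------
def _translate(codon: str) -> str:
    if codon in _MITO_STOPS:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def annotate_mt(variant: MtVariant, gene_map: MtGeneMap) -> MtVariant:
    """Assign gene symbol and functional class in place (and return it).

    Protein-gene substitutions are translated in-frame with the vertebrate
    mitochondrial code; tRNA/rRNA/D-loop positions are labelled by locus
    type; positions outside every mapped feature become ``other_noncoding``.
    """
    iv = gene_map.locate(variant.position)
    if iv is None:
        variant.gene = None
        variant.functional_class = "other_noncoding"
        return variant
    variant.gene = iv.gene
    if iv.product != "protein":
        variant.functional_class = iv.product if iv.product != "dloop" else "dloop"
        return variant

    ref_base = gene_map.sequence[variant.position - 1]
    if ref_base != variant.ref:
        raise ValueError(
            f"ref allele {variant.ref} at {variant.position} does not match "
            f"reference base {ref_base}"
        )
    if iv.strand == "+":
        offset = variant.position - iv.start
        cds_alt = variant.alt
        cds = gene_map.sequence[iv.start - 1 : iv.end]
    else:
        offset = iv.end - variant.position
        cds_alt = variant.alt.translate(_COMPLEMENT)
        cds = _revcomp(gene_map.sequence[iv.start - 1 : iv.end])
    codon_idx, within = divmod(offset, 3)
    ref_codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        variant.functional_class = "stop_gain"
    elif alt_aa == ref_aa:
        variant.functional_class = "synonymous"
    else:
        variant.functional_class = "nonsynonymous"
    return variant


# ---------------------------------------------------------------------------
# prioritization
# ---------------------------------------------------------------------------
def prioritize(variant: MtVariant, thresholds) -> PrioritizationResult:
    """Apply the pathogenicity prioritization gates to one variant.

    Haplogroup-defining variants are excluded outright.  For the scored
    classes, a variant is prioritized iff its nucleotide variability lies
    below the conservation cutoff AND its pathogenicity score exceeds the
    class threshold (non-synonymous / tRNA / rRNA each have their own).
    Classes without a score model (synonymous, D-loop, other non-coding)
    are never prioritized.

    ``thresholds`` is a :class:`~oncomito.config.MtdnaThresholds`.
    """
    reasons: list[str] = []
    if variant.haplogroup_defining:
        return PrioritizationResult(False, ["excluded: haplogroup-defining site"])

    cls = variant.functional_class
    threshold_by_class = {
        "nonsynonymous": thresholds.ds_nonsyn,
        "stop_gain": thresholds.ds_nonsyn,
        "tRNA": thresholds.ds_trna,
        "rRNA": thresholds.ds_rrna,
    }
    if cls not in threshold_by_class:
        return PrioritizationResult(
            False, [f"class {cls!r} not subject to score-based prioritization"]
        )

    if cls in ("tRNA", "rRNA") and variant.rna_prediction_score is not None:
        score, score_name = variant.rna_prediction_score, "rna_prediction_score"
    else:
        score, score_name = variant.disease_score, "disease_score"
    if score is None:
        raise ValueError(f"{score_name} missing for {cls} variant at {variant.position}")
    if variant.nucleotide_variability is None:
        raise ValueError(
            f"nucleotide_variability missing for variant at {variant.position}"
        )

    var_ok = variant.nucleotide_variability < thresholds.variability_cutoff
    reasons.append(
        f"variability {variant.nucleotide_variability:g} "
        f"{'<' if var_ok else '>='} cutoff {thresholds.variability_cutoff:g}"
    )
    cutoff = threshold_by_class[cls]
    score_ok = score > cutoff
    reasons.append(
        f"{score_name} {score:g} {'>' if score_ok else '<='} {cls} threshold {cutoff:g}"
    )
    return PrioritizationResult(var_ok and score_ok, reasons)


def score_gate_passes(variant: MtVariant, thresholds) -> bool:
    """Whether the pathogenicity-score gate alone passes (ignoring variability)."""
    threshold_by_class = {
        "nonsynonymous": thresholds.ds_nonsyn,
        "stop_gain": thresholds.ds_nonsyn,
        "tRNA": thresholds.ds_trna,
        "rRNA": thresholds.ds_rrna,
    }
    if variant.functional_class not in threshold_by_class:
        return False
    if variant.functional_class in ("tRNA", "rRNA") and variant.rna_prediction_score is not None:
        score = variant.rna_prediction_score
    else:
        score = variant.disease_score
    if score is None:
        raise ValueError("pathogenicity score missing")
    return score > threshold_by_class[variant.functional_class]


# ---------------------------------------------------------------------------
# copy ratio from coverage summaries
# ---------------------------------------------------------------------------
def mtdna_copy_ratio(
    coverage: pd.DataFrame,
    groups: Mapping[str, str],
    pairs: Mapping[str, str],
) -> tuple[pd.DataFrame, float, float]:
    """Per-pair tumor/normal mtDNA dose ratios from mean coverages.

    ``coverage`` must have columns ``sample``, ``mt_coverage``,
    ``nuclear_coverage``.  The per-sample mitochondrial dose is
    ``mt_coverage / nuclear_coverage``; each pair's ratio is
    ``dose_tumor / dose_normal``.  Returns the per-pair table plus the
    cohort mean and SD of the ratios.
    """
    cov = coverage.set_index("sample")
    if (cov["nuclear_coverage"] <= 0).any():
        bad = cov.index[cov["nuclear_coverage"] <= 0].tolist()
        raise ValueError(f"non-positive nuclear coverage for samples {bad}")
    dose = cov["mt_coverage"] / cov["nuclear_coverage"]
    by_patient: dict[str, dict[str, float]] = {}
    for sample, d in dose.items():
        by_patient.setdefault(pairs[sample], {})[groups[sample]] = d
    rows = []
    for patient, doses in sorted(by_patient.items()):
        if set(doses) != {"tumor", "normal"}:
            raise ValueError(f"patient {patient} lacks a complete tumor/normal pair")
        rows.append(
            {"patient": patient, "copy_ratio": doses["tumor"] / doses["normal"]}
        )
    table = pd.DataFrame(rows)
    ratios = table["copy_ratio"].to_numpy()
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else float("nan")
    return table, float(np.mean(ratios)), sd


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------
def classify_cohort(
    variants: Iterable[MtVariant],
    *,
    hf_tolerance: float = 0.10,
    detection_limit: float = 0.005,
) -> list[MtVariant]:
    """Set ``origin`` on every paired variant record and return the list."""
    out = list(variants)
    for v in out:
        v.origin = classify_origin(
            v, hf_tolerance=hf_tolerance, detection_limit=detection_limit
        )
    return out
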