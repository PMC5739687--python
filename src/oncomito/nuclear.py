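"""Nuclear somatic variant statistics and the CNV gene-dose test.

Covers the exome arm of the analysis: the six-class pyrimidine-reference
substitution spectrum (purine-reference changes are folded onto their
reverse complement), the transition/transversion ratio, per-tumor non-silent
mutation burden, exact-binomial class enrichment against a baseline
spectrum, and a permutation test asking whether proteins encoded in
copy-number-loss segments are expressed below random expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats import permutation_pvalue

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITION_CLASSES = ("C>T", "T>C")

EFFECT_CLASSES = ("silent", "missense", "nonsense", "frameshift_del", "frameshift_ins")
NON_SILENT = ("missense", "nonsense", "frameshift_del", "frameshift_ins")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class NuclearVariant:
    """A somatic nuclear SNV or small indel with its coding effect class."""

    patient: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class CnvSegment:
    """A copy-state interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    copy_state: int
    patient: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment coordinates {self.start}..{self.end}")

    def contains(self, chrom: str, position: float) -> bool:
        return chrom == self.chrom and self.start <= position < self.end


@dataclass
class SpectrumCounts:
    counts: dict[str, int]
    n_skipped_indels: int = 0

    def __post_init__(self) -> None:
        for cls in SPECTRUM_CLASSES:
            self.counts.setdefault(cls, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative spectrum count")

    @property
    def total(self) -> int:
        return sum(self.counts[c] for c in SPECTRUM_CLASSES)


def collapse_substitution(ref: str, alt: str) -> str:
    """Map any of the 12 substitution types onto its pyrimidine-reference class."""
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    key = f"{ref}>{alt}"
    if key not in SPECTRUM_CLASSES:
        raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
    return key


def spectrum_6class(variants: Iterable[NuclearVariant]) -> SpectrumCounts:
    """Tally SNVs into the six strand-symmetric substitution classes.

    Indels are skipped and counted in ``n_skipped_indels``.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        counts[collapse_substitution(v.ref, v.alt)] += 1
    return SpectrumCounts(counts, skipped)


def titv(counts: SpectrumCounts) -> float:
    """Transition/transversion ratio, (C>T + T>C) / (the four transversions)."""
    ti = sum(counts.counts[c] for c in TRANSITION_CLASSES)
    tv = counts.total - ti
    if tv == 0:
        raise ValueError("no transversions: Ti/Tv undefined")
    return ti / tv


def burden_stats(
    variants: Iterable[NuclearVariant],
) -> tuple[pd.Series, float, dict[str, int]]:
    """Per-patient non-silent mutation burden, cohort median, class totals.

    Silent variants contribute to the class totals but never to burden.
    """
    class_totals = {c: 0 for c in EFFECT_CLASSES}
    per_patient: dict[str, int] = {}
    for v in variants:
        if v.effect_class not in class_totals:
            raise ValueError(f"unknown effect class {v.effect_class!r}")
        class_totals[v.effect_class] += 1
        per_patient.setdefault(v.patient, 0)
        if v.effect_class != "silent":
            per_patient[v.patient] += 1
    burden = pd.Series(per_patient, dtype=int).sort_index()
    median = float(burden.median()) if len(burden) else float("nan")
    return burden, median, class_totals


def class_enrichment_test(
    counts: SpectrumCounts,
    baseline_probs: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Two-sided exact binomial test of each class against a baseline spectrum.

    The default baseline is uniform (1/6 per class).
    """
    total = counts.total
    if total == 0:
        raise ValueError("empty spectrum")
    if baseline_probs is None:
        baseline_probs = {c: 1 / 6 for c in SPECTRUM_CLASSES}
    norm = sum(baseline_probs[c] for c in SPECTRUM_CLASSES)
    if not np.isclose(norm, 1.0):
        baseline_probs = {c: baseline_probs[c] / norm for c in SPECTRUM_CLASSES}
    return {
        c: float(
            stats.binomtest(
                counts.counts[c], total, baseline_probs[c], alternative="two-sided"
            ).pvalue
        )
        for c in SPECTRUM_CLASSES
    }


# ---------------------------------------------------------------------------
# CNV gene dose
# ---------------------------------------------------------------------------
@dataclass
class CnvDoseResult:
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    n_loss_genes: int


def genes_in_loss_segments(
    segments: Sequence[CnvSegment],
    gene_locations: pd.DataFrame,
) -> list[str]:
    """Genes whose midpoint falls inside any loss segment (copy_state < 2).

    ``gene_locations`` is indexed by gene id with columns ``chrom``,
    ``start``, ``end`` (BED convention).
    """
    losses = [s for s in segments if s.copy_state < 2]
    hits: list[str] = []
    mid = (gene_locations["start"] + gene_locations["end"]) / 2.0
    for gene, row in gene_locations.iterrows():
        m = mid.loc[gene]
        if any(s.contains(str(row["chrom"]), m) for s in losses):
            hits.append(gene)
    return hits


def cnv_dose_test(
    log2fc: pd.Series,
    loss_genes: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> CnvDoseResult:
    """Is mean log2 fold change over CNV-loss genes lower than random gene sets?

    The null distribution is built from ``n_perm`` random draws (without
    replacement within a draw) of equally many quantified genes; the
    one-sided p-value uses the add-one permutation estimator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    log2fc = log2fc.dropna()  # a NaN fold change means the gene is unquantified
    quantified = [g for g in loss_genes if g in log2fc.index]
    if not quantified:
        raise ValueError("no CNV-loss gene is quantified in the fold-change table")
    observed = float(log2fc.loc[quantified].mean())
    rng = np.random.default_rng(seed)
    values = log2fc.to_numpy()
    k = len(quantified)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(values), size=k, replace=False)
        null[i] = values[idx].mean()
    p = permutation_pvalue(observed, null, direction="lower")
    return CnvDoseResult(observed, null, p, k)
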