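"""Proteome analysis: validity filtering, mitochondrial mass ratio,
compartment-stratified regulation thresholds, OXPHOS complex summaries.

The central idea is compartment stratification: mitochondria-rich tumors
shift the whole mitochondrial proteome upward, so a single global fold-change
cutoff would call essentially every mitochondrial protein regulated.  The
log2 fold-change distribution is therefore split into mitochondrial and
non-mitochondrial compartments and a protein is called regulated only when
it exceeds one standard deviation from its own compartment's mean.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .io import OmicsMatrix

OXPHOS_COMPLEXES = ("CI", "CII", "CIII", "CIV", "CV")


@dataclass
class CompartmentThresholds:
    compartment: str  # mito | non_mito
    mean_log2fc: float
    sd_log2fc: float

    @property
    def up_cutoff(self) -> float:
        return self.mean_log2fc + self.sd_log2fc

    @property
    def down_cutoff(self) -> float:
        return self.mean_log2fc - self.sd_log2fc


@dataclass
class ComplexSummary:
    complex: str
    subunit_log2fc: pd.Series
    assembly_log2fc: pd.Series

    @property
    def subunit_median(self) -> float:
        return float(self.subunit_log2fc.median()) if len(self.subunit_log2fc) else float("nan")

    @property
    def assembly_median(self) -> float:
        return float(self.assembly_log2fc.median()) if len(self.assembly_log2fc) else float("nan")


def filter_min_valid(matrix: OmicsMatrix, mode: str) -> OmicsMatrix:
    """Apply one of the two validity filters.

    ``each_group_min3``: keep features with at least 3 valid values in each
    group (the stringent filter; no imputation needed afterwards).
    ``one_group_full6``: keep features fully observed in at least one group;
    the other group's missing cells are meant to be imputed downstream —
    this is the permissive filter used to form ratios for proteins below
    the detection limit in one tissue.
    """
    tumor = matrix.tumor_values()
    normal = matrix.normal_values()
    n_t = tumor.notna().sum(axis=1)
    n_n = normal.notna().sum(axis=1)
    if mode == "each_group_min3":
        keep = (n_t >= 3) & (n_n >= 3)
    elif mode == "one_group_full6":
        keep = (n_t == tumor.shape[1]) | (n_n == normal.shape[1])
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return matrix.subset(matrix.values.index[keep])


def _is_mito(annotation: pd.DataFrame, features: pd.Index) -> pd.Series:
    # the annotation is a positive list: unannotated features are non-mito
    mito = annotation["is_mito"].reindex(features)
    return mito.fillna(False).astype(bool)


def mito_mass_ratio(
    matrix: OmicsMatrix,
    annotation: pd.DataFrame,
    *,
    log2_scale: bool = True,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-patient total-abundance tumor/normal ratios by compartment.

    For each patient and compartment, the ratio of summed raw intensities
    (tumor over normal); missing cells contribute 0 to the sums.  Returns
    the per-patient table and ``{'mito': (mean, sd), 'non_mito': (mean, sd)}``
    over the cohort.
    """
    values = matrix.values
    raw = np.power(2.0, values) if log2_scale else values
    raw = raw.fillna(0.0)
    mito = _is_mito(annotation, values.index)
    tumor_of = {matrix.pairs[s]: s for s in matrix.samples_of("tumor")}
    normal_of = {matrix.pairs[s]: s for s in matrix.samples_of("normal")}
    rows = []
    for patient in matrix.patients:
        t, n = raw[tumor_of[patient]], raw[normal_of[patient]]
        entry = {"patient": patient}
        for label, mask in (("mito", mito), ("non_mito", ~mito)):
            denom = n[mask].sum()
            if denom == 0:
                raise ValueError(
                    f"compartment {label} sums to zero in normal sample "
                    f"{normal_of[patient]!r}"
                )
            entry[f"{label}_ratio"] = t[mask].sum() / denom
        rows.append(entry)
    table = pd.DataFrame(rows)
    summary = {
        label: (
            float(table[f"{label}_ratio"].mean()),
            float(table[f"{label}_ratio"].std(ddof=1)),
        )
        for label in ("mito", "non_mito")
    }
    return table, summary


def compartment_stats(
    log2fc: pd.Series,
    annotation: pd.DataFrame,
    *,
    min_size: int = 10,
) -> tuple[dict[str, CompartmentThresholds], pd.Series]:
    """One-SD regulation thresholds per compartment plus per-feature calls.

    A feature is ``up`` if its log2 fold change strictly exceeds its
    compartment mean + SD, ``down`` below mean - SD, else ``none``.  With a
    degenerate (zero-SD) compartment no call is made.
    """
    mito = _is_mito(annotation, log2fc.index)
    thresholds: dict[str, CompartmentThresholds] = {}
    calls = pd.Series("none", index=log2fc.index, dtype=object)
    for label, mask in (("mito", mito), ("non_mito", ~mito)):
        vals = log2fc[mask].dropna()
        if len(vals) < min_size:
            raise ValueError(
                f"compartment {label} has {len(vals)} features (< {min_size})"
            )
        th = CompartmentThresholds(label, float(vals.mean()), float(vals.std(ddof=1)))
        thresholds[label] = th
        if th.sd_log2fc > 0:
            calls[mask & (log2fc > th.up_cutoff)] = "up"
            calls[mask & (log2fc < th.down_cutoff)] = "down"
    return thresholds, calls


def oxphos_complex_summary(
    log2fc: pd.Series,
    annotation: pd.DataFrame,
) -> tuple[list[ComplexSummary], str | None]:
    """Median subunit and assembly-factor log2 fold change per OXPHOS complex.

    Annotation columns used: ``complex`` (CI..CV or empty) and
    ``is_assembly`` (assembly factors are not part of the final complex and
    are summarized separately).  A complex with no quantified subunit is
    reported absent rather than erroring.  The qualitative verdict
    ``"CI_down_rest_up"`` is returned when the CI subunit median is negative
    while every other quantified complex has a positive subunit median.
    """
    ann = annotation.reindex(log2fc.index)
    comp = ann["complex"].fillna("")
    assembly = ann.get("is_assembly", pd.Series(False, index=log2fc.index))
    assembly = assembly.fillna(False).astype(bool)
    summaries = []
    for cx in OXPHOS_COMPLEXES:
        members = comp == cx
        if not members.any():
            continue
        summaries.append(
            ComplexSummary(
                complex=cx,
                subunit_log2fc=log2fc[members & ~assembly].dropna(),
                assembly_log2fc=log2fc[members & assembly].dropna(),
            )
        )
    verdict = None
    medians = {s.complex: s.subunit_median for s in summaries if len(s.subunit_log2fc)}
    if "CI" in medians and len(medians) > 1:
        others = [v for k, v in medians.items() if k != "CI"]
        if medians["CI"] < 0 < min(others):
            verdict = "CI_down_rest_up"
    return summaries, verdict


def log2_fold_changes(matrix: OmicsMatrix) -> pd.Series:
    """Per-feature log2fc = mean(log2 tumor) - mean(log2 normal) over valid cells."""
    return (
        matrix.tumor_values().mean(axis=1, skipna=True)
        - matrix.normal_values().mean(axis=1, skipna=True)
    )
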