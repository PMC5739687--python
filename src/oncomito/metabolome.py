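"""Targeted-metabolomics analysis: normalization, LOQ-floored fold changes,
differential testing and the significant-metabolite report.

Abundances are relative MRM peak areas (one value per metabolite per
sample).  Values are normalized by tissue amount and internal standard, and
fold changes are formed after flooring sub-LOQ values — the device that
turns "undetectable in normal tissue" into a finite, conservative ratio
(the headline case being reduced glutathione, quantifiable in tumors but
below background in several normal kidneys).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import OmicsMatrix
from .stats import differential_test


@dataclass
class FoldChangeRow:
    metabolite: str
    fold: float          # tumor mean / normal mean, floored, natural scale
    signed_fold: float   # Table-style signed representation: -1/fold when fold < 1
    censored: bool


def normalize_metabolome(
    raw: OmicsMatrix,
    tissue_mass: Mapping[str, float],
    internal_standard: Mapping[str, float],
) -> OmicsMatrix:
    """Divide each sample column by its tissue amount, then by its
    internal-standard response ratio."""
    values = raw.values.copy()
    for sample in values.columns:
        mass = tissue_mass[sample]
        standard = internal_standard[sample]
        if mass <= 0 or standard <= 0:
            raise ValueError(f"non-positive mass or standard for sample {sample!r}")
        values[sample] = values[sample] / mass / standard
    return raw.with_values(values)


def fold_change_with_floor(
    matrix: OmicsMatrix,
    floors: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-metabolite tumor/normal fold change with sub-LOQ flooring.

    Group means are computed after replacing values below the metabolite's
    floor by the floor itself.  When ``floors`` is None (or lacks a
    metabolite), the fallback floor is the smallest positive observed value
    of that metabolite across the cohort.  If both group means sit at the
    floor the fold is 1 and the row is flagged censored; a row is also
    flagged when flooring actually modified any of its cells.
    """
    tumor = matrix.tumor_values()
    normal = matrix.normal_values()
    rows = []
    for metabolite in matrix.values.index:
        t = tumor.loc[metabolite].dropna().to_numpy(dtype=float)
        n = normal.loc[metabolite].dropna().to_numpy(dtype=float)
        floor = None
        if floors is not None:
            floor = dict(floors).get(metabolite) if not isinstance(floors, pd.Series) \
                else (floors.get(metabolite) if metabolite in floors.index else None)
        if floor is None:
            positive = np.concatenate([t[t > 0], n[n > 0]])
            if positive.size == 0:
                raise ValueError(f"no positive value or floor for {metabolite!r}")
            floor = float(positive.min())
        if floor <= 0:
            raise ValueError(f"floor for {metabolite!r} must be positive")
        touched = bool((t < floor).any() or (n < floor).any())
        t_floored = np.maximum(t, floor)
        n_floored = np.maximum(n, floor)
        mt, mn = t_floored.mean(), n_floored.mean()
        if np.isclose(mt, floor) and np.isclose(mn, floor):
            fold, censored = 1.0, True
        else:
            fold, censored = mt / mn, touched
        signed = fold if fold >= 1 else -1.0 / fold
        rows.append({"metabolite": metabolite, "fold": float(fold),
                     "signed_fold": float(signed), "censored": censored})
    return pd.DataFrame(rows).set_index("metabolite")


def metabolome_differential(
    matrix: OmicsMatrix,
    floors: Mapping[str, float] | pd.Series | None = None,
    *,
    fdr_level: float = 0.05,
    p_cutoff: float | None = 0.01,
) -> pd.DataFrame:
    """Run the metabolome differential stage: floor, log2, Welch t-test.

    Significance applies both gates by default: BH q <= ``fdr_level`` and
    nominal p <= ``p_cutoff`` (pass ``p_cutoff=None`` for the q-only gate).
    """
    folds = fold_change_with_floor(matrix, floors)
    floored = matrix.values.copy()
    for metabolite in floored.index:
        row = floored.loc[metabolite]
        positive = row[row > 0]
        floor = None
        if floors is not None:
            mapping = floors if not isinstance(floors, pd.Series) else floors.to_dict()
            floor = dict(mapping).get(metabolite)
        if floor is None:
            floor = float(positive.min()) if len(positive) else np.nan
        floored.loc[metabolite] = row.clip(lower=floor)
    log2m = matrix.with_values(np.log2(floored))
    result = differential_test(log2m, fdr_level=fdr_level, p_cutoff=p_cutoff)
    result = result.set_index("feature")
    result["fold"] = folds["fold"]
    result["signed_fold"] = folds["signed_fold"]
    result["censored"] = folds["censored"]
    return result.reset_index(names="metabolite")


def volcano_table(
    differential: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, int, int]:
    """Significant metabolites sorted by fold change descending.

    ``groups`` optionally maps metabolite name to a chemical-class label.
    Returns the report plus the up/down counts (by sign of log2fc).
    """
    sig = differential[differential["significant"]].copy()
    if groups is not None:
        lookup = dict(groups) if not isinstance(groups, pd.Series) else groups.to_dict()
        sig["group"] = [lookup.get(m, "") for m in sig["metabolite"]]
    sig = sig.sort_values("signed_fold", ascending=False).reset_index(drop=True)
    n_up = int((sig["log2fc"] > 0).sum())
    n_down = int((sig["log2fc"] < 0).sum())
    return sig, n_up, n_down
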