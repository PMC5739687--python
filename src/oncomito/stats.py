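"""Shared statistical primitives.

Feature-wise two-sample testing with Benjamini-Hochberg correction,
left-shifted Gaussian imputation of missing-not-at-random intensities, and
add-one permutation p-values.  All operate on the log2 scale unless stated
otherwise.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DIFFERENTIAL_COLUMNS = (
    "feature",
    "mean_tumor",
    "mean_normal",
    "log2fc",
    "t_statistic",
    "p_value",
    "q_value",
    "significant",
    "regulation",
)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving under the original indexing and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_row(t_vals: np.ndarray, n_vals: np.ndarray) -> tuple[float, float]:
    """Welch t and two-sided p for one feature, handling degenerate variance."""
    if np.var(t_vals, ddof=1) == 0 and np.var(n_vals, ddof=1) == 0:
        # no within-group spread: identical means carry no evidence, any
        # difference is infinitely strong
        if np.isclose(t_vals.mean(), n_vals.mean()):
            return 0.0, 1.0
        return float(np.inf) if t_vals.mean() > n_vals.mean() else float(-np.inf), 0.0
    with warnings.catch_warnings():
        # one group may legitimately be constant (e.g. LOQ-floored cells)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(t_vals, n_vals, equal_var=False)
    return float(t), float(p)


def differential_test(
    matrix,
    *,
    fdr_level: float = 0.05,
    p_cutoff: float | None = None,
    paired: bool = False,
    min_valid: int = 2,
) -> pd.DataFrame:
    """Per-feature Welch two-sample t-test on a log2 tumor/normal matrix.

    Parameters
    ----------
    matrix
        An :class:`~oncomito.io.OmicsMatrix` holding log2 values.
    fdr_level
        BH significance level; a feature is significant when ``q <= fdr_level``
        and, if ``p_cutoff`` is given, additionally ``p <= p_cutoff``.
    paired
        Use a paired t-test ordered by patient instead of the unpaired Welch
        test.  Off by default: the unpaired test is the pipeline's standard
        even though samples are patient-matched.
    min_valid
        Features with fewer valid values in either group are skipped (logged).

    Returns a DataFrame with the :data:`DIFFERENTIAL_COLUMNS` layout;
    ``log2fc = mean_tumor - mean_normal``.
    """
    tumor = matrix.tumor_values()
    normal = matrix.normal_values()
    if paired:
        patients = [matrix.pairs[s] for s in tumor.columns]
        order = {matrix.pairs[s]: s for s in normal.columns}
        normal = normal[[order[p] for p in patients]]

    rows = []
    n_skipped = 0
    for feature in matrix.values.index:
        t_vals = tumor.loc[feature].dropna().to_numpy(dtype=float)
        n_vals = normal.loc[feature].dropna().to_numpy(dtype=float)
        if len(t_vals) < min_valid or len(n_vals) < min_valid:
            n_skipped += 1
            continue
        if paired:
            mask = ~(
                tumor.loc[feature].isna().to_numpy()
                | normal.loc[feature].isna().to_numpy()
            )
            tv = tumor.loc[feature].to_numpy(dtype=float)[mask]
            nv = normal.loc[feature].to_numpy(dtype=float)[mask]
            if len(tv) < min_valid:
                n_skipped += 1
                continue
            if np.allclose(tv, nv):
                t, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t, p = stats.ttest_rel(tv, nv)
            mt, mn = float(tv.mean()), float(nv.mean())
        else:
            t, p = _welch_row(t_vals, n_vals)
            mt, mn = float(t_vals.mean()), float(n_vals.mean())
        rows.append(
            {
                "feature": feature,
                "mean_tumor": mt,
                "mean_normal": mn,
                "log2fc": mt - mn,
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    if n_skipped:
        logger.info("differential_test: skipped %d features with <%d valid values",
                    n_skipped, min_valid)
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=list(DIFFERENTIAL_COLUMNS))
    result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    sig = result["q_value"] <= fdr_level
    if p_cutoff is not None:
        sig &= result["p_value"] <= p_cutoff
    result["significant"] = sig
    result["regulation"] = np.where(
        ~sig, "none", np.where(result["log2fc"] > 0, "up", "down")
    )
    return result[list(DIFFERENTIAL_COLUMNS)]


def impute_gaussian(
    matrix,
    width_factor: float = 0.3,
    downshift_factor: float = 1.8,
    seed: int = 0,
):
    """Replace missing log2 intensities by draws from a down-shifted Gaussian.

    Per sample column with observed mean m and SD s, missing cells are drawn
    from Normal(m - downshift * s, (width * s)^2) — the conventional
    left-censored imputation for label-free proteomics, emulating abundances
    below the detection limit.  Observed cells are never altered.  Moment
    estimates are per column; they are unstable below roughly 30 observed
    values per column.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for col in values.columns:
        column = values[col]
        observed = column.dropna()
        if observed.empty:
            raise ValueError(f"sample column {col!r} is entirely missing")
        n_missing = int(column.isna().sum())
        if n_missing == 0:
            continue
        m, s = observed.mean(), observed.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            s = 0.0
        draws = rng.normal(m - downshift_factor * s, width_factor * s, size=n_missing)
        values.loc[column.isna(), col] = draws
    return matrix.with_values(values)


def permutation_pvalue(
    observed: float,
    null_draws: Sequence[float],
    direction: str = "lower",
) -> float:
    """Add-one permutation p-value, p = (1 + #extreme) / (1 + n).

    ``direction='lower'`` counts null draws <= observed (test of
    "lower than random"); ``'greater'`` counts >=; ``'two-sided'`` doubles
    the smaller one-sided p (capped at 1).  The add-one estimator never
    returns exactly zero.
    """
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n = null.size
    p_lower = (1 + np.sum(null <= observed)) / (1 + n)
    p_greater = (1 + np.sum(null >= observed)) / (1 + n)
    if direction == "lower":
        return float(p_lower)
    if direction == "greater":
        return float(p_greater)
    if direction == "two-sided":
        return float(min(1.0, 2 * min(p_lower, p_greater)))
    raise ValueError(f"unknown direction {direction!r}")
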