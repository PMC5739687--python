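"""Weighted running-sum gene-set enrichment with permutation NES and FDR.

The enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov-like running sum over the ranked feature list: hits
increment by |score|^weight (normalized), misses decrement by 1/(N - n_hits).
Significance uses gene-set permutation — random member sets of equal size —
because a 6-vs-6 cohort offers too few phenotype permutations.  NES divides
ES by the mean |null ES| of the same sign; the nominal p is one-sided within
the same-sign null, and the FDR q compares the same-sign NES distributions
of null and observed sets, as in the classic procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import GeneSetCollection


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr_q: float
    significant: bool


def _ranked(scores: pd.Series) -> pd.Series:
    """Rank scores descending; ties broken lexicographically by feature id."""
    frame = scores.rename("score").rename_axis("feature").reset_index()
    frame = frame.sort_values(["score", "feature"], ascending=[False, True])
    return pd.Series(frame["score"].to_numpy(), index=frame["feature"].to_numpy())


def enrichment_score(
    scores: pd.Series,
    members: Iterable[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    ``scores`` maps feature id to ranking score (any order; ranked
    internally).  Raises if the set shares no feature with the ranking.
    """
    ranking = _ranked(scores)
    member_set = set(members)
    hit = np.fromiter((f in member_set for f in ranking.index), dtype=bool)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranking")
    return _es_from_hits(ranking.to_numpy(), hit, weight)


def _es_from_hits(
    scores: np.ndarray, hit: np.ndarray, weight: float
) -> tuple[float, np.ndarray]:
    n = scores.size
    n_hits = int(hit.sum())
    w = np.abs(scores[hit]) ** weight
    total = w.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted steps
        w = np.ones(n_hits)
        total = float(n_hits)
    increments = np.zeros(n)
    increments[hit] = w / total
    if n_hits < n:
        increments[~hit] = -1.0 / (n - n_hits)
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    # cumulative rounding can push the sum past +-1 by ~1e-16
    return float(np.clip(es, -1.0, 1.0)), running


def gsea_run(
    scores: pd.Series,
    sets: GeneSetCollection,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    weight: float = 1.0,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.15,
) -> pd.DataFrame:
    """Run the enrichment analysis over a collection of gene sets.

    Sets with fewer than ``min_size`` quantified members are excluded.
    Returns a DataFrame with columns name/size/ES/NES/p_value/fdr_q/
    significant, sorted by NES descending.  Significance requires both
    ``p <= p_threshold`` and ``q <= fdr_threshold``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranking = _ranked(scores)
    universe = ranking.index.to_numpy()
    score_arr = ranking.to_numpy()
    n = universe.size
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray, int]] = []
    for gs in sets:
        member_set = set(gs.members)
        hit = np.fromiter((f in member_set for f in universe), dtype=bool)
        size = int(hit.sum())
        if size < min_size:
            continue
        kept.append((gs.name, hit, size))
    if not kept:
        return pd.DataFrame(
            columns=["name", "size", "es", "nes", "p_value", "fdr_q", "significant"]
        )

    # one shared null per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for _, _, size in kept:
        if size in null_by_size:
            continue
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            hit = np.zeros(n, dtype=bool)
            hit[idx] = True
            null[i] = _es_from_hits(score_arr, hit, weight)[0]
        null_by_size[size] = null

    def normalize(es: float, null: np.ndarray) -> float:
        same = null[null > 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        return es / denom if denom > 0 else 0.0

    results = []
    null_nes_all: list[float] = []
    for name, hit, size in kept:
        es = _es_from_hits(score_arr, hit, weight)[0]
        null = null_by_size[size]
        same = null[null >= 0] if es >= 0 else null[null <= 0]
        if same.size:
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
        else:
            p = 1.0 / (1 + n_perm)
        results.append({"name": name, "size": size, "es": es,
                        "nes": normalize(es, null), "p_value": float(p)})
        null_nes_all.extend(normalize(e, null) for e in null)

    frame = pd.DataFrame(results)
    null_nes = np.asarray(null_nes_all)
    obs_nes = frame["nes"].to_numpy()
    qs = []
    for nes in obs_nes:
        if nes >= 0:
            null_frac = np.mean(null_nes[null_nes >= 0] >= nes) if (null_nes >= 0).any() else 0.0
            obs_frac = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            null_frac = np.mean(null_nes[null_nes <= 0] <= nes) if (null_nes <= 0).any() else 0.0
            obs_frac = np.mean(obs_nes[obs_nes <= 0] <= nes)
        qs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0)
    frame["fdr_q"] = qs
    frame["significant"] = (frame["p_value"] <= p_threshold) & (frame["fdr_q"] <= fdr_threshold)
    return frame.sort_values("nes", ascending=False).reset_index(drop=True)
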