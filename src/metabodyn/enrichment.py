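"""Metabolite set enrichment from PLS-loading feature importances.

Feature importances (sums of absolute PLS loadings) are propagated to every
annotation candidate of each feature — exact-mass annotation is ambiguous, so
one FIA feature may feed several metabolites — and a weighted
Kolmogorov-Smirnov running-sum enrichment (GSEA-style) scores pathway
definitions against the resulting metabolite ranking, with a member-label
permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathwayDefinition",
    "EnrichmentResult",
    "expand_to_metabolites",
    "enrichment_score",
    "gsea",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named metabolite set (e.g. a KEGG-style pathway)."""

    pathway_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("pathway must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"pathway {self.pathway_id} has duplicate members")


@dataclass
class EnrichmentResult:
    """Enrichment of one pathway against the metabolite ranking."""

    pathway_id: str
    name: str
    es: float
    nes: float
    p: float
    size: int
    leading_edge: tuple[str, ...]


def expand_to_metabolites(ranking: pd.DataFrame, annotations) -> pd.Series:
    """Propagate feature importances to annotated metabolites.

    Every (feature, candidate compound) pair contributes the feature's
    importance to that compound; a compound hit by several features keeps the
    maximum importance (avoiding double counting while retaining the
    strongest evidence). Unannotated features are dropped.

    Parameters
    ----------
    ranking : DataFrame
        Feature importances as returned by
        :func:`~metabodyn.timecourse.rank_features_by_loading`
        (index feature_id, column ``importance``).
    annotations : list of Annotation
        Exact-mass annotations from :func:`~metabodyn.fia.annotate_features`.

    Returns
    -------
    Series
        Compound id -> importance, sorted descending.
    """
    imp = ranking["importance"]
    scores: dict[str, float] = {}
    for ann in annotations:
        if ann.feature_id not in imp.index:
            continue
        v = float(imp[ann.feature_id])
        for compound_id, _adduct, _err in ann.candidates:
            if compound_id not in scores or v > scores[compound_id]:
                scores[compound_id] = v
    s = pd.Series(scores, dtype=float, name="importance")
    return s.sort_values(ascending=False)


def enrichment_score(
    ranked_ids: np.ndarray, importances: np.ndarray, member_mask: np.ndarray,
    weight_p: float = 1.0,
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score for one member set.

    Hits advance the running sum by |importance|^weight_p (normalized over
    hits), misses retreat it by 1/(N - n_hits); the ES is the extremum of the
    running sum (signed, in [-1, 1]). Returns (ES, index of the extremum).
    """
    n = len(ranked_ids)
    nh = int(member_mask.sum())
    if nh == 0 or nh == n:
        return 0.0, 0
    w = np.abs(importances) ** weight_p
    hit = np.where(member_mask, w, 0.0)
    hit_total = hit.sum()
    if hit_total == 0:  # all member importances zero: fall back to equal steps
        hit = member_mask.astype(float)
        hit_total = hit.sum()
    miss = np.where(member_mask, 0.0, 1.0 / (n - nh))
    running = np.cumsum(hit / hit_total - miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea(
    metabolite_ranking: pd.Series,
    pathways: list[PathwayDefinition],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 3,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Set enrichment of pathways against a metabolite importance ranking.

    The ranking must contain non-negative importances (absolute PLS loadings).
    Pathways with fewer than ``min_size`` members present in the ranking are
    dropped. The null distribution for each pathway comes from ``n_perm``
    member-label permutations (random same-size sets) with a fixed seed;
    p = (b + 1) / (n_perm + 1) where b counts null ES of the same sign at
    least as extreme, so p is never 0; NES = ES / mean(|null ES| of the same
    sign). Results are sorted by NES, descending.
    """
    if metabolite_ranking.empty:
        raise ValueError("metabolite ranking is empty")
    if (metabolite_ranking < 0).any():
        raise ValueError("importances must be non-negative (use absolute loadings)")
    # deterministic order: importance descending, id ascending on ties
    rk = metabolite_ranking.sort_index().sort_values(ascending=False, kind="stable")
    ids = rk.index.to_numpy(dtype=object)
    imp = rk.to_numpy(dtype=float)
    pos = {m: i for i, m in enumerate(ids)}
    n = len(ids)

    kept = []
    for pw in pathways:
        present = [m for m in pw.members if m in pos]
        if len(present) >= min_size:
            kept.append((pw, present))
    if not kept:
        warnings.warn("no pathway has enough ranked members; empty enrichment result")
        return []

    rng = np.random.default_rng(seed)
    results = []
    for pw, present in kept:
        mask = np.zeros(n, dtype=bool)
        mask[[pos[m] for m in present]] = True
        es, peak = enrichment_score(ids, imp, mask, weight_p)
        null = np.empty(n_perm)
        k = len(present)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = enrichment_score(ids, imp, pmask, weight_p)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        b_extreme = int((np.abs(same_sign) >= abs(es)).sum())
        p = (b_extreme + 1) / (n_perm + 1)
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            leading = tuple(m for m in ids[: peak + 1] if mask[pos[m]])
        else:
            leading = tuple(m for m in ids[peak:] if mask[pos[m]])
        results.append(
            EnrichmentResult(pw.pathway_id, pw.name, es, float(nes), float(p),
                             len(present), leading)
        )
    results.sort(key=lambda r: (-r.nes, r.pathway_id))
    return results
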