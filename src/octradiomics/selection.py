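"""Consensus feature selection.

Three rankers -- Welch t-test, Wilcoxon rank-sum and mRmR (minimum
redundancy, maximum relevance) -- each produce a top-15 list; the two
features with the lowest mean rank inside the three-way intersection are
selected.  If the intersection holds fewer than two features the fallback
is the lowest mean rank over the union of the top-15 sets (flagged).

Determinism: all orderings break ties lexicographically by feature name.
mRmR uses the MID (difference) form on tertile-discretized standardized
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

logger = logging.getLogger(__name__)

TOP_K = 15
N_SELECTED = 2


@dataclass
class RankedList:
    method: str
    features: list[str]
    scores: list[float]

    def rank_of(self, name: str) -> int:
        """1-based rank; features outside the list rank len+1."""
        try:
            return self.features.index(name) + 1
        except ValueError:
            return len(self.features) + 1

    def top(self, k: int) -> list[str]:
        return self.features[:k]


@dataclass
class ConsensusSelection:
    top_k: int
    rankings: dict[str, RankedList]
    intersection: list[str]
    selected: list[str]
    used_fallback: bool = False
    iteration: int | None = None
    fold: int | None = None


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.tolist()}")
    return labels == classes[0], labels == classes[1]


def _order(names: pd.Index, pvalues: np.ndarray) -> tuple[list[str], list[float]]:
    # NaN p-values (constant columns) sink to the bottom; ties break by name
    key = np.where(np.isfinite(pvalues), pvalues, np.inf)
    idx = sorted(range(len(names)), key=lambda i: (key[i], names[i]))
    return [names[i] for i in idx], [float(pvalues[i]) for i in idx]


def rank_ttest(table: pd.DataFrame, labels: pd.Series | np.ndarray) -> RankedList:
    """Features by ascending two-sample Welch t-test p-value."""
    y = np.asarray(labels)
    a, b = _check_two_classes(y)
    if a.sum() < 2 or b.sum() < 2:
        raise ValidationError("both classes need >= 2 rows for a t-test")
    X = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(X[a], X[b], axis=0, equal_var=False)
    feats, scores = _order(table.columns, np.asarray(res.pvalue))
    return RankedList(method="ttest", features=feats, scores=scores)


def rank_wilcoxon(table: pd.DataFrame, labels: pd.Series | np.ndarray) -> RankedList:
    """Features by ascending Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact p-values for small samples (n <= 12 total, where the normal
    approximation is poorest), tie-corrected normal approximation
    otherwise.
    """
    y = np.asarray(labels)
    a, b = _check_two_classes(y)
    if a.sum() < 1 or b.sum() < 1:
        raise ValidationError("both classes must be present")
    X = table.to_numpy(dtype=float)
    method = "auto" if y.size <= 12 else "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            X[a], X[b], axis=0, alternative="two-sided", method=method
        )
    feats, scores = _order(table.columns, np.asarray(res.pvalue))
    return RankedList(method="wilcoxon", features=feats, scores=scores)


def _discretize_tertiles(X: np.ndarray) -> np.ndarray:
    """Per-column tertile codes {0,1,2} (ties collapse bins harmlessly)."""
    q = np.quantile(X, [1 / 3, 2 / 3], axis=0)
    return (X > q[0]).astype(np.int64) + (X > q[1]).astype(np.int64)


def _mutual_information(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """MI in bits between two discrete code vectors."""
    n = codes_a.size
    mi = 0.0
    for va in np.unique(codes_a):
        pa = np.mean(codes_a == va)
        for vb in np.unique(codes_b):
            pj = np.mean((codes_a == va) & (codes_b == vb))
            if pj > 0:
                pb = np.mean(codes_b == vb)
                mi += pj * np.log2(pj / (pa * pb))
    return mi


def _mi_against_all(codes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Vectorized MI (bits) between each column of ``codes`` and ``target``."""
    n, p = codes.shape
    mi = np.zeros(p)
    t_vals = np.unique(target)
    for va in range(3):
        mask_a = codes == va  # n x p
        pa = mask_a.mean(axis=0)
        for vb in t_vals:
            sel = target == vb
            pb = sel.mean()
            pj = mask_a[sel].sum(axis=0) / n
            valid = pj > 0
            mi[valid] += pj[valid] * np.log2(pj[valid] / (pa[valid] * pb))
    return mi


def rank_mrmr(table: pd.DataFrame, labels: pd.Series | np.ndarray, k: int = TOP_K) -> RankedList:
    """Greedy mRmR (MID form): maximize I(f; label) minus mean I(f; selected)."""
    if k > table.shape[1]:
        raise ValidationError(f"k={k} exceeds feature count {table.shape[1]}")
    y = np.asarray(labels)
    _check_two_classes(y)
    X = table.to_numpy(dtype=float)
    X = np.where(np.isfinite(X), X, 0.0)
    codes = _discretize_tertiles(X)
    y_codes = (y == np.unique(y)[0]).astype(np.int64)

    names = list(table.columns)
    relevance = _mi_against_all(codes, y_codes)

    selected_idx: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(len(names))
    remaining = set(range(len(names)))
    name_rank = {n: i for i, n in enumerate(sorted(names))}
    while len(selected_idx) < k and remaining:
        if selected_idx:
            crit = relevance - redundancy_sum / len(selected_idx)
        else:
            crit = relevance.copy()
        best = min(remaining, key=lambda i: (-crit[i], name_rank[names[i]]))
        selected_idx.append(best)
        scores.append(float(crit[best]))
        remaining.discard(best)
        # update redundancy with the newly selected feature (MI in bits)
        red = np.zeros(len(names))
        sel_codes = codes[:, best]
        n = sel_codes.size
        for vb in np.unique(sel_codes):
            selmask = sel_codes == vb
            pb = selmask.mean()
            for va in range(3):
                col_is_va = codes == va  # n x p
                pa = col_is_va.mean(axis=0)
                pj = col_is_va[selmask].sum(axis=0) / n
                valid = pj > 0
                red[valid] += pj[valid] * np.log2(pj[valid] / (pa[valid] * pb))
        redundancy_sum += red
    return RankedList(
        method="mrmr", features=[names[i] for i in selected_idx], scores=scores
    )


def consensus_top2(
    rankings: list[RankedList] | dict[str, RankedList],
    k: int = TOP_K,
    iteration: int | None = None,
    fold: int | None = None,
) -> ConsensusSelection:
    """Intersection of the three top-k sets; the two lowest-mean-rank members.

    An intersection with fewer than two members falls back to mean rank
    over the union of the top-k sets (logged and flagged).
    """
    if isinstance(rankings, dict):
        ranked = rankings
    else:
        ranked = {r.method: r for r in rankings}
    tops = {m: set(r.top(k)) for m, r in ranked.items()}
    inter = set.intersection(*tops.values()) if tops else set()

    def mean_rank(name: str) -> float:
        return float(np.mean([r.rank_of(name) for r in ranked.values()]))

    used_fallback = False
    pool = inter
    if len(inter) < N_SELECTED:
        pool = set.union(*tops.values())
        used_fallback = True
        logger.info(
            "consensus intersection has %d members; falling back to top-%d union",
            len(inter), k,
        )
    ordered = sorted(pool, key=lambda n: (mean_rank(n), n))
    selected = ordered[:N_SELECTED]
    return ConsensusSelection(
        top_k=k,
        rankings=ranked,
        intersection=sorted(inter),
        selected=selected,
        used_fallback=used_fallback,
        iteration=iteration,
        fold=fold,
    )


def select_features(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = TOP_K,
    iteration: int | None = None,
    fold: int | None = None,
) -> ConsensusSelection:
    """Run all three rankers and take the consensus pair."""
    rankings = [
        rank_ttest(table, labels),
        rank_wilcoxon(table, labels),
        rank_mrmr(table, labels, k=min(k, table.shape[1])),
    ]
    return consensus_top2(rankings, k=k, iteration=iteration, fold=fold)
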