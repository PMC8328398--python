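"""Threshold gating of classifier prediction scores.

For a grid of thresholds on the rebounder prediction score (score >=
threshold -> predicted rebounder), the gate tabulates the percentage of
each outcome group classified correctly -- the trade-off a clinician
would use to pick an operating point that identifies one group (e.g.
>90% of non-rebounders) with high confidence.  As the threshold rises
the correctly-identified rebounder percentage is non-increasing and the
non-rebounder percentage non-decreasing, by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import NONREBOUNDER, REBOUNDER, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ThresholdCurve:
    table: pd.DataFrame  # columns: threshold, pct_rebounders_correct, pct_nonrebounders_correct


def default_grid(scores) -> np.ndarray:
    """Midpoints of sorted unique scores plus a fixed 0.30-0.70 step-0.02 grid."""
    s = np.unique(np.asarray(scores, dtype=float))
    mids = (s[:-1] + s[1:]) / 2 if s.size > 1 else np.array([])
    fixed = np.round(np.arange(0.30, 0.7001, 0.02), 2)
    return np.unique(np.concatenate([mids, fixed]))


def _as_positive(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return y == REBOUNDER
    return y.astype(bool)


def threshold_table(scores, labels, thresholds=None) -> ThresholdCurve:
    """Per-threshold percentage of each group classified correctly.

    Percentages are rounded to 2 decimals.  ``thresholds`` must be sorted;
    by default the score midpoints plus the fixed clinical-style grid.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_positive(labels)
    if pos.all() or not pos.any():
        raise ValidationError("threshold_table needs both classes present")
    if thresholds is None:
        thresholds = default_grid(scores)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValidationError("thresholds must be non-empty")
    if np.any(np.diff(thresholds) < 0):
        raise ValidationError("thresholds must be sorted ascending")

    rows = []
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    for t in thresholds:
        pred_pos = scores >= t
        rows.append(
            {
                "threshold": float(t),
                "pct_rebounders_correct": round(100.0 * (pred_pos & pos).sum() / n_pos, 2),
                "pct_nonrebounders_correct": round(100.0 * (~pred_pos & ~pos).sum() / n_neg, 2),
            }
        )
    return ThresholdCurve(table=pd.DataFrame(rows))


@dataclass
class GateResult:
    threshold: float | None
    target_group: str
    target_pct: float
    achieved_target_pct: float | None
    other_group_pct: float | None
    reachable: bool


def find_threshold(scores, labels, target_group: str, target_pct: float) -> GateResult:
    """Operating point achieving ``target_pct`` correct for ``target_group``.

    The search runs over midpoints of sorted unique scores.  Among the
    qualifying thresholds the one maximizing the other group's percentage
    is returned (for a non-rebounder target that is the smallest
    qualifying threshold; for a rebounder target the largest).  Returns
    an explicit unreachable result when no threshold qualifies.
    """
    if not 0 < target_pct <= 100:
        raise ValidationError("target_pct must be in (0, 100]")
    if target_group not in (REBOUNDER, NONREBOUNDER):
        raise ValidationError(f"target_group must be {REBOUNDER!r} or {NONREBOUNDER!r}")
    scores = np.asarray(scores, dtype=float)
    s = np.unique(scores)
    grid = (s[:-1] + s[1:]) / 2  # midpoints of sorted unique scores
    if grid.size == 0:
        return GateResult(None, target_group, target_pct, None, None, reachable=False)
    curve = threshold_table(scores, labels, thresholds=grid).table

    col = (
        "pct_rebounders_correct"
        if target_group == REBOUNDER
        else "pct_nonrebounders_correct"
    )
    other = (
        "pct_nonrebounders_correct"
        if target_group == REBOUNDER
        else "pct_rebounders_correct"
    )
    ok = curve[curve[col] >= target_pct]
    if ok.empty:
        logger.info("gate target %s >= %.1f%% unreachable", target_group, target_pct)
        return GateResult(None, target_group, target_pct, None, None, reachable=False)
    row = ok.loc[ok[other].idxmax()]
    return GateResult(
        threshold=float(row["threshold"]),
        target_group=target_group,
        target_pct=target_pct,
        achieved_target_pct=float(row[col]),
        other_group_pct=float(row[other]),
        reachable=True,
    )
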