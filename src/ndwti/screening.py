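"""Stage-wise feature screening by Spearman rank correlation.

Candidate features (vegetation indices or NDWTIs) are ranked by the absolute
Spearman correlation of each column with AGB on the training partition; the
top k (default 5, mirroring the per-stage model inputs) are selected.
Shapiro-Wilk normality statistics are reported alongside — they motivate the
rank-based correlation but gate nothing.  No multiple-testing correction is
applied to the screening correlations; the selection is a ranking, not an
inference, and downstream models are judged on a held-out partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .texture_index import canonical_pair_name

__all__ = [
    "CorrelationReport",
    "SelectionResult",
    "spearman",
    "shapiro_wilk",
    "rank_features",
    "select_top_k",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman correlation of one feature with AGB at one stage."""

    feature: str
    rho: float
    n: int
    stage: str = ""

    @property
    def abs_rho(self) -> float:
        return abs(self.rho)


@dataclass(frozen=True)
class SelectionResult:
    """The ordered top-k features of one family at one stage."""

    stage: str
    family: str  # "VI" or "NDWTI"
    selected: Tuple[CorrelationReport, ...]

    def names(self) -> List[str]:
        return [r.feature for r in self.selected]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on midranks, ties averaged).

    Returns NaN when either vector is constant (undefined sentinel).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def shapiro_wilk(x: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk normality test: returns (W, p)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def rank_features(
    feature_matrix: pd.DataFrame,
    agb: Sequence[float],
    stage: str = "",
) -> List[CorrelationReport]:
    """One correlation report per feature column, sorted by descending |rho|.

    Features with undefined correlation (constant columns) are dropped with a
    logged warning.  Ties in |rho| are broken by feature name so the ordering
    is deterministic.
    """
    agb = np.asarray(agb, dtype=float)
    if len(feature_matrix) != agb.size:
        raise ValueError(
            f"feature rows ({len(feature_matrix)}) and agb length ({agb.size}) differ"
        )
    reports: List[CorrelationReport] = []
    dropped: List[str] = []
    for name in feature_matrix.columns:
        col = feature_matrix[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            dropped.append(name)
            continue
        rho = spearman(col, agb)
        if np.isnan(rho):
            dropped.append(name)
            continue
        reports.append(CorrelationReport(feature=name, rho=rho, n=agb.size, stage=stage))
    if dropped:
        logger.warning(
            "dropped %d feature(s) with undefined correlation (first: %s)",
            len(dropped),
            dropped[:3],
        )
    reports.sort(key=lambda r: (-r.abs_rho, r.feature))
    return reports


def _is_pair_name(name: str) -> bool:
    return name.startswith("NDWTI(")


def select_top_k(
    reports: Sequence[CorrelationReport],
    k: int = 5,
    dedup: bool = True,
    stage: str = "",
    family: str = "",
) -> SelectionResult:
    """Top k features by |rho| with deterministic tie-breaking.

    With ``dedup`` (the default for NDWTI candidates), a pair and its reversal
    — identical up to sign, hence equal |rho| — count as one candidate; the
    lexicographically smaller ordered name is kept.  If fewer than k valid
    candidates exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(reports, key=lambda r: (-r.abs_rho, r.feature))
    selected: List[CorrelationReport] = []
    seen: Dict[str, str] = {}
    for rep in ordered:
        if dedup and _is_pair_name(rep.feature):
            key = canonical_pair_name(rep.feature)
            if key in seen:
                continue
            seen[key] = rep.feature
        selected.append(rep)
        if len(selected) == k:
            break
    if len(selected) < k:
        logger.warning(
            "only %d valid feature(s) available for top-%d selection", len(selected), k
        )
    return SelectionResult(stage=stage, family=family, selected=tuple(selected))
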