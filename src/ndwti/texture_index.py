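"""Normalized-difference wavelet texture indices (NDWTI).

Low-frequency (LL) wavelet texture statistics are orders of magnitude larger
than the detail-subband statistics, so all 64 WT features are min-max scaled
(scaler fitted on the training partition only) before pairing.  An NDWTI is

    NDWTI(WT1, WT2) = (WT1 - WT2) / (WT1 + WT2)

over the scaled features, for every ordered pair WT1 != WT2 — 64*63 = 4032
pairs, split 2256 high-high / 240 low-low / 1536 mixed by subband class.
Reversed pairs are redundant up to sign; they are kept here (the index table
carries all 4032 columns) and deduplicated only at selection time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "ScalerParams",
    "NDWTIPair",
    "fit_minmax",
    "apply_minmax",
    "enumerate_pairs",
    "compute_ndwti",
    "ndwti_table",
    "pair_name",
    "split_pair_name",
    "canonical_pair_name",
    "EPS_SUM",
]

#: |WT1 + WT2| below this returns the symmetric limit 0
EPS_SUM = 1e-12

_LOW_PREFIX = "LL"
#: split "A-B" only at the hyphen that precedes a subband prefix, so band
#: labels containing hyphens ("Red-edge") survive round-trips
_PAIR_SPLIT = re.compile(r"-(?=(?:LL|LH|HL|HH)_)")
_PAIR_NAME = re.compile(r"^NDWTI\((?P<body>.+)\)$")


def _subband_class(feature_name: str) -> str:
    return "low" if feature_name.startswith(_LOW_PREFIX) else "high"


@dataclass(frozen=True)
class NDWTIPair:
    """An ordered pair of WT feature names and its frequency class."""

    wt1: str
    wt2: str

    def __post_init__(self) -> None:
        if self.wt1 == self.wt2:
            raise ValueError("NDWTI pair members must differ")

    @property
    def pair_class(self) -> str:
        a, b = _subband_class(self.wt1), _subband_class(self.wt2)
        if a == b == "high":
            return "high_high"
        if a == b == "low":
            return "low_low"
        return "low_high"

    @property
    def name(self) -> str:
        return pair_name(self.wt1, self.wt2)


def pair_name(wt1: str, wt2: str) -> str:
    """Column name of a pair, mirroring ``NDWTI(LL_NIR_Var-LL_Red_Mea)``."""
    return f"NDWTI({wt1}-{wt2})"


def split_pair_name(name: str) -> Tuple[str, str]:
    """Invert `pair_name`, tolerating hyphenated band labels."""
    m = _PAIR_NAME.match(name)
    if not m:
        raise ValueError(f"not an NDWTI column name: {name!r}")
    parts = _PAIR_SPLIT.split(m.group("body"))
    if len(parts) != 2:
        raise ValueError(f"cannot split pair name {name!r}")
    return parts[0], parts[1]


def canonical_pair_name(name: str) -> str:
    """Orientation-free key: a pair and its reversal share one canonical name."""
    wt1, wt2 = split_pair_name(name)
    lo, hi = sorted((wt1, wt2))
    return pair_name(lo, hi)


@dataclass
class ScalerParams:
    """Per-feature (min, max) learned from a training partition.

    Thin wrapper around scikit-learn's ``MinMaxScaler`` keeping feature names
    attached; constant training columns scale to zero, and values outside the
    training range map linearly outside [0, 1] (no clipping).
    """

    feature_names: List[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaler parameters")


def fit_minmax(training_features: pd.DataFrame) -> ScalerParams:
    """Learn per-feature min/max from the training partition only."""
    if len(training_features) < 2:
        raise ValueError("need at least 2 training samples to fit the scaler")
    scaler = MinMaxScaler().fit(training_features.to_numpy(dtype=float))
    return ScalerParams(
        feature_names=list(training_features.columns),
        mins=scaler.data_min_,
        maxs=scaler.data_max_,
    )


def apply_minmax(params: ScalerParams, features: pd.DataFrame) -> pd.DataFrame:
    """Scale features with fitted parameters: ``(x - min) / (max - min)``.

    Constant training columns (zero range) map to 0.  Test values outside the
    training range fall outside [0, 1]; they are not clipped.
    """
    unknown = [c for c in features.columns if c not in params.feature_names]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    x = features.loc[:, params.feature_names].to_numpy(dtype=float)
    span = params.maxs - params.mins
    safe_span = np.where(span > 0, span, 1.0)
    scaled = (x - params.mins) / safe_span
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=features.index, columns=params.feature_names)


def enumerate_pairs(
    feature_names: Sequence[str], class_filter: Optional[str] = None
) -> List[NDWTIPair]:
    """All ordered pairs (wt1, wt2), wt1 != wt2, optionally filtered by class.

    ``class_filter`` is one of ``high_high``, ``low_low``, ``low_high``.
    """
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("feature names must be unique")
    pairs = [
        NDWTIPair(a, b) for a in feature_names for b in feature_names if a != b
    ]
    if class_filter is not None:
        if class_filter not in ("high_high", "low_low", "low_high"):
            raise ValueError(f"unknown class filter {class_filter!r}")
        pairs = [p for p in pairs if p.pair_class == class_filter]
    return pairs


def compute_ndwti(wt1_scaled, wt2_scaled):
    """Elementwise ``(WT1 - WT2) / (WT1 + WT2)`` with a zero-sum guard.

    When ``|WT1 + WT2| < EPS_SUM`` (both features at their training minimum)
    the symmetric limit 0 is returned.  Works on scalars and arrays.
    """
    wt1 = np.asarray(wt1_scaled, dtype=float)
    wt2 = np.asarray(wt2_scaled, dtype=float)
    s = wt1 + wt2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(s) < EPS_SUM, 0.0, (wt1 - wt2) / np.where(s == 0, 1.0, s))
    if out.ndim == 0:
        return float(out)
    return out


def ndwti_table(
    scaled_features: pd.DataFrame, pairs: Iterable[NDWTIPair]
) -> pd.DataFrame:
    """Index values for every pair, one column per pair, rows = samples."""
    values = scaled_features.to_numpy(dtype=float)
    col_index = {name: i for i, name in enumerate(scaled_features.columns)}
    data: Dict[str, np.ndarray] = {}
    for p in pairs:
        data[p.name] = compute_ndwti(values[:, col_index[p.wt1]], values[:, col_index[p.wt2]])
    return pd.DataFrame(data, index=scaled_features.index)
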