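"""Single-level 2-D orthonormal Haar decomposition and subband texture statistics.

A canopy reflectance patch is decomposed into one approximation subband (LL)
and three detail subbands (LH: horizontal detail, HL: vertical detail,
HH: diagonal detail) with the orthonormal Haar filter bank
(lowpass ``[1/sqrt2, 1/sqrt2]``, highpass ``[1/sqrt2, -1/sqrt2]``).  For Haar
the single-level separable transform reduces to a non-overlapping 2x2 block
transform, which is how it is implemented here; orthonormality gives an exact
energy-conservation (Parseval) invariant that the test suite asserts.

Four statistics are computed per subband — mean (Mea), population variance
(Var), energy (Ene, mean of squared coefficients) and entropy (Ent) — and
assembled over the four sensor bands into a 64-element wavelet texture (WT)
feature vector with canonical names such as ``LL_Red_Mea``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "BANDS",
    "SUBBANDS",
    "STATS",
    "SubbandSet",
    "haar_dwt2",
    "subband_stats",
    "compute_wt_features",
    "wt_feature_names",
]

#: canonical band keys (internal) -> display names used in feature labels
BAND_LABELS: Dict[str, str] = {
    "green": "Green",
    "red": "Red",
    "red_edge": "Red-edge",
    "nir": "NIR",
}
BANDS: Tuple[str, ...] = tuple(BAND_LABELS)
SUBBANDS: Tuple[str, ...] = ("LL", "LH", "HL", "HH")
STATS: Tuple[str, ...] = ("Mea", "Var", "Ene", "Ent")


@dataclass(frozen=True)
class SubbandSet:
    """The four coefficient arrays of a single-level 2-D decomposition."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {"LL": self.ll, "LH": self.lh, "HL": self.hl, "HH": self.hh}

    @property
    def energy(self) -> float:
        """Total squared coefficient mass over all four subbands."""
        return float(sum(np.sum(a * a) for a in self.as_dict().values()))


def _pad_to_even(patch: np.ndarray) -> np.ndarray:
    """Symmetric (edge-replicate) padding of odd dimensions to even size."""
    pr = patch.shape[0] % 2
    pc = patch.shape[1] % 2
    if pr or pc:
        patch = np.pad(patch, ((0, pr), (0, pc)), mode="symmetric")
    return patch


def haar_dwt2(patch: np.ndarray) -> SubbandSet:
    """Single-level orthonormal Haar decomposition of a 2-D patch.

    Parameters
    ----------
    patch
        2-D array, at least 2x2.  Odd dimensions are symmetrically padded to
        even size before decomposition.

    Returns
    -------
    SubbandSet
        LL/LH/HL/HH coefficient arrays of shape ``(ceil(M/2), ceil(N/2))``.
        Energy is conserved exactly (orthonormal filters): the sum of squared
        input pixels equals the sum of squared coefficients (for even-sized
        inputs; padding adds replicated pixels to the accounting).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] < 2 or patch.shape[1] < 2:
        raise ValueError(
            f"patch must be a 2-D array of at least 2x2, got shape {patch.shape!r}"
        )
    patch = _pad_to_even(patch)
    a = patch[0::2, 0::2]
    b = patch[0::2, 1::2]
    c = patch[1::2, 0::2]
    d = patch[1::2, 1::2]
    # 2x2 block transform of the separable orthonormal Haar filter bank
    ll = (a + b + c + d) / 2.0
    lh = (a + b - c - d) / 2.0  # row-lowpass / column-highpass
    hl = (a - b + c - d) / 2.0
    hh = (a - b - c + d) / 2.0
    return SubbandSet(ll=ll, lh=lh, hl=hl, hh=hh)


def subband_stats(subband: np.ndarray) -> Tuple[float, float, float, float]:
    """Mean, population variance, energy and entropy of one subband.

    ``Ent = -(1/MN) * sum q*log2(q)`` with ``q = |coefficient|`` and the
    continuous-limit convention ``q*log2(q) := 0`` at ``q = 0``.  The absolute
    value keeps the statistic defined on detail subbands, whose coefficients
    are signed and centred near zero.
    """
    sb = np.asarray(subband, dtype=float)
    if sb.size == 0:
        raise ValueError("subband is empty")
    mea = float(sb.mean())
    var = float(((sb - mea) ** 2).mean())
    ene = float((sb * sb).mean())
    q = np.abs(sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0.0, q * np.log2(np.where(q > 0.0, q, 1.0)), 0.0)
    ent = float(-terms.mean())
    return mea, var, ene, ent


def wt_feature_names() -> List[str]:
    """The 64 canonical WT feature names, in fixed subband/band/stat order."""
    return [
        f"{sb}_{BAND_LABELS[band]}_{stat}"
        for sb in SUBBANDS
        for band in BANDS
        for stat in STATS
    ]


def compute_wt_features(patches: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Compute the 64 wavelet texture features of one multiband ROI patch.

    Parameters
    ----------
    patches
        Mapping from the four band keys (``green``, ``red``, ``red_edge``,
        ``nir``) to equal-shaped 2-D reflectance patches.

    Returns
    -------
    dict
        64 named features ``{Subband}_{Band}_{Stat}``, e.g. ``LL_Red_Mea``.
    """
    missing = [b for b in BANDS if b not in patches]
    if missing:
        raise ValueError(f"missing band(s): {missing}")
    shapes = {np.asarray(patches[b]).shape for b in BANDS}
    if len(shapes) != 1:
        raise ValueError(f"band patches have mismatched shapes: {sorted(shapes)}")

    decomposed = {band: haar_dwt2(patches[band]).as_dict() for band in BANDS}
    features: Dict[str, float] = {}
    for sb in SUBBANDS:
        for band in BANDS:
            mea, var, ene, ent = subband_stats(decomposed[band][sb])
            label = BAND_LABELS[band]
            features[f"{sb}_{label}_Mea"] = mea
            features[f"{sb}_{label}_Var"] = var
            features[f"{sb}_{label}_Ene"] = ene
            features[f"{sb}_{label}_Ent"] = ent
    assert len(features) == 64
    return features
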