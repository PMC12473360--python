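"""Multiband raster I/O, plot-ROI resolution and per-ROI extraction.

Rasters are plain multiband TIFFs (band order green, red, red-edge, nir, one
page or plane per band); ROI layouts and AGB ground truth travel as CSV.
Pixel rectangles use 0-based, half-open ``[row0, row1) x [col0, col1)``
indexing, and an ROI must lie fully inside the raster — partial overlap is an
error, never a silent clip.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .wavelet import BANDS

__all__ = [
    "MultibandImage",
    "PlotROI",
    "SampleRecord",
    "read_raster",
    "write_raster",
    "read_roi_layout",
    "read_ground_truth",
    "extract_roi_patch",
    "roi_mean_reflectance",
    "agb_from_sample_weight",
    "load_samples",
]

#: required spectral bands, in on-disk order
BAND_ORDER = list(BANDS)  # green, red, red_edge, nir


class RasterFormatError(ValueError):
    """Raised when a raster lacks a required band or has malformed layout."""


@dataclass
class MultibandImage:
    """A four-band reflectance raster.

    ``bands`` maps the canonical band names to equal-shaped 2-D arrays;
    ``transform`` optionally carries a 6-tuple affine georeference (metadata
    only — pixel-space operations never consult it); ``nodata`` is an
    optional sentinel value marking invalid pixels.
    """

    bands: Dict[str, np.ndarray]
    transform: Optional[tuple] = None
    nodata: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [b for b in BAND_ORDER if b not in self.bands]
        if missing:
            raise RasterFormatError(f"missing band(s): {missing}")
        shapes = {np.asarray(a).shape for a in self.bands.values()}
        if len(shapes) != 1:
            raise RasterFormatError(f"bands have mismatched shapes: {sorted(shapes)}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.bands.values())).shape


@dataclass(frozen=True)
class PlotROI:
    """A rectangular plot region in pixel space (0-based, half-open)."""

    plot_id: str
    row0: int
    row1: int
    col0: int
    col1: int
    stage: str = "pre_heading"
    year: int = 0

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"ROI {self.plot_id!r} has empty bounds")


@dataclass
class SampleRecord:
    """One ROI joined with its ground-truth AGB and extracted reflectances."""

    plot_id: str
    stage: str
    agb: float
    reflectance_means: Dict[str, float]
    patches: Dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def write_raster(path: Path | str, image: MultibandImage) -> None:
    """Write a MultibandImage as a multiband TIFF (planes in band order)."""
    stack = np.stack([np.asarray(image.bands[b], dtype=np.float32) for b in BAND_ORDER])
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_raster(path: Path | str, nodata: Optional[float] = None) -> MultibandImage:
    """Read a multiband TIFF into a MultibandImage.

    The file must carry at least four bands, interpreted in the fixed order
    green, red, red-edge, nir; extra bands are ignored.  Reflectances are
    returned exactly as stored (no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise RasterFormatError(f"expected a band stack, got array of ndim {arr.ndim}")
    # accept (bands, H, W) or (H, W, bands); band counts are small (<= 8)
    if arr.shape[0] > 8 and arr.shape[-1] <= 8:
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] < len(BAND_ORDER):
        present = BAND_ORDER[: arr.shape[0]]
        missing = [b for b in BAND_ORDER if b not in present]
        raise RasterFormatError(
            f"raster has {arr.shape[0]} band(s); missing {missing}"
        )
    bands = {b: arr[i] for i, b in enumerate(BAND_ORDER)}
    return MultibandImage(bands=bands, nodata=nodata)


def read_roi_layout(path: Path | str) -> List[PlotROI]:
    """Read an ROI layout CSV (plot_id,row0,row1,col0,col1,stage,year)."""
    rois: List[PlotROI] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            rois.append(
                PlotROI(
                    plot_id=row["plot_id"],
                    row0=int(row["row0"]),
                    row1=int(row["row1"]),
                    col0=int(row["col0"]),
                    col1=int(row["col1"]),
                    stage=row.get("stage", "pre_heading"),
                    year=int(row.get("year", 0) or 0),
                )
            )
    return rois


def read_ground_truth(path: Path | str) -> pd.DataFrame:
    """Read the ground-truth table (plot_id, stage, agb_g_m2)."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    required = {"plot_id", "stage", "agb_g_m2"}
    missing = required - set(df.columns)
    if missing:
        raise RasterFormatError(f"ground truth missing column(s): {sorted(missing)}")
    if (df["agb_g_m2"] <= 0).any():
        raise ValueError("ground-truth AGB values must be positive")
    return df


def extract_roi_patch(
    image: MultibandImage, roi: PlotROI, on_nodata: str = "error"
) -> Dict[str, np.ndarray]:
    """Extract the per-band patches of one ROI.

    Raises a bounds error if the ROI is not fully inside the image extent.
    ``on_nodata`` controls behaviour when the image defines a nodata sentinel
    and the ROI contains such pixels: ``"error"`` (default) raises,
    ``"mask"`` returns masked arrays with the sentinel masked out.
    """
    h, w = image.shape
    if roi.row0 < 0 or roi.col0 < 0 or roi.row1 > h or roi.col1 > w:
        raise IndexError(
            f"ROI {roi.plot_id!r} [{roi.row0},{roi.row1})x[{roi.col0},{roi.col1}) "
            f"exceeds image extent {h}x{w}"
        )
    patches: Dict[str, np.ndarray] = {}
    for band in BAND_ORDER:
        patch = np.asarray(image.bands[band][roi.row0 : roi.row1, roi.col0 : roi.col1])
        if image.nodata is not None and np.any(patch == image.nodata):
            if on_nodata == "error":
                raise ValueError(
                    f"ROI {roi.plot_id!r} contains nodata pixels in band {band!r}"
                )
            patch = np.ma.masked_equal(patch, image.nodata)
        patches[band] = patch
    return patches


def roi_mean_reflectance(patch: np.ndarray) -> float:
    """Arithmetic mean reflectance over the unmasked pixels of a patch."""
    patch = np.ma.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.count() == 0:
        raise ValueError("all pixels masked")
    return float(patch.mean())


def agb_from_sample_weight(total_dry_weight: float, area: float = 0.25) -> float:
    """Convert a quadrat dry weight (g) to AGB per unit area (g/m2).

    The default quadrat is the 0.5 m x 0.5 m sampling frame (0.25 m2).
    """
    if area <= 0:
        raise ValueError("sampling area must be positive")
    if total_dry_weight < 0:
        raise ValueError("dry weight must be nonnegative")
    return total_dry_weight / area


def load_samples(
    image: MultibandImage,
    rois: Sequence[PlotROI],
    ground_truth: pd.DataFrame,
    on_nodata: str = "error",
) -> List[SampleRecord]:
    """Join ROIs with ground truth and extract patches and band means."""
    gt = ground_truth.set_index(["plot_id", "stage"])["agb_g_m2"]
    records: List[SampleRecord] = []
    for roi in rois:
        try:
            agb = float(gt.loc[(roi.plot_id, roi.stage)])
        except KeyError:
            raise KeyError(
                f"no ground truth for plot {roi.plot_id!r} stage {roi.stage!r}"
            ) from None
        patches = extract_roi_patch(image, roi, on_nodata=on_nodata)
        means = {b: roi_mean_reflectance(p) for b, p in patches.items()}
        records.append(
            SampleRecord(
                plot_id=roi.plot_id,
                stage=roi.stage,
                agb=agb,
                reflectance_means=means,
                patches=patches,
            )
        )
    return records
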