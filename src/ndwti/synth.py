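"""Synthetic four-band canopy scenes with paired biomass ground truth.

The generator emulates the statistical structure a UAV multispectral biomass
survey of a paddy crop presents to the feature-extraction pipeline:

* canopy cover is a saturating monotone function of above-ground biomass
  (AGB, g/m2): ``cover = 1 - exp(-coverage_gain * AGB)``;
* canopy pixels carry typical vegetation reflectance (high NIR, low red),
  soil pixels carry flat soil reflectance (NIR ~ red), so ROI-mean NDVI rises
  monotonically with AGB and saturates as the canopy closes;
* after heading, bright panicle-like speckle is overlaid with density
  proportional to ``speckle_density * AGB``, raising local contrast and hence
  high-frequency (HH) wavelet texture — the structural change that motivates
  texture features in the first place;
* additive Gaussian sensor noise, truncated at zero reflectance.

It deliberately does not attempt radiative-transfer realism; it provides the
monotone spectral link, the stage-dependent saturation and the post-heading
texture signal that the screening and modelling stages assume, so every
downstream stage is testable without field data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .wavelet import BANDS

__all__ = [
    "SceneConfig",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
    "write_dataset",
    "CANOPY_REFLECTANCE",
    "SOIL_REFLECTANCE",
    "PANICLE_REFLECTANCE",
]

#: typical vegetation spectrum: strong NIR plateau, chlorophyll red absorption
CANOPY_REFLECTANCE: Dict[str, float] = {
    "green": 0.12,
    "red": 0.05,
    "red_edge": 0.30,
    "nir": 0.45,
}
#: dry paddy soil: flat, slightly red-tilted spectrum (NIR ~ red)
SOIL_REFLECTANCE: Dict[str, float] = {
    "green": 0.15,
    "red": 0.18,
    "red_edge": 0.19,
    "nir": 0.20,
}
#: emerged panicles: bright in every band (senescing spikelets)
PANICLE_REFLECTANCE: Dict[str, float] = {
    "green": 0.30,
    "red": 0.28,
    "red_edge": 0.38,
    "nir": 0.50,
}

#: AGB ranges (g/m2) typical of the two phenological windows
PRE_HEADING_AGB_RANGE: Tuple[float, float] = (185.0, 1615.0)
POST_HEADING_AGB_RANGE: Tuple[float, float] = (633.0, 1947.0)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of the synthetic canopy scene generator.

    Parameters
    ----------
    plot_rows, plot_cols
        Layout of the plot grid; one sample (ROI) per plot per draw.
    patch_size
        Side length in pixels of each square ROI patch; even, >= 8.
    stage
        ``pre_heading`` or ``post_heading``; controls the default AGB range,
        the cover saturation rate and whether panicle speckle is rendered.
    agb_range
        Closed AGB interval (g/m2) the latent biomass is drawn from.
    coverage_gain
        Rate (m2/g) of the saturating cover link
        ``cover = 1 - exp(-coverage_gain * AGB)``.  The post-heading default
        is higher, so the red/NIR contrast saturates harder late season.
    speckle_density
        Expected panicle speckles per pixel per (g/m2) of AGB; only applied
        post-heading.
    noise_sd
        Standard deviation of the additive truncated-Gaussian sensor noise,
        in reflectance units.
    illumination_sd
        Log-scale standard deviation of a per-sample multiplicative
        brightness factor, emulating illumination and calibration drift
        between plots and flights.  Normalized-difference indices are
        invariant to it by construction; raw band means and LL statistics
        are not.
    cover_jitter_sd
        Log-scale standard deviation of a per-sample jitter on the
        AGB -> cover link, emulating variety and nitrogen-treatment
        differences in canopy architecture at equal biomass.
    seed
        Base seed for `generate_dataset`.
    """

    plot_rows: int = 3
    plot_cols: int = 6
    patch_size: int = 32
    stage: str = "pre_heading"
    agb_range: Optional[Tuple[float, float]] = None
    coverage_gain: float = 8e-4
    speckle_density: float = 3e-5
    noise_sd: float = 0.01
    illumination_sd: float = 0.08
    cover_jitter_sd: float = 0.25
    seed: int = 0
    canopy_reflectance: Dict[str, float] = field(
        default_factory=lambda: dict(CANOPY_REFLECTANCE)
    )
    soil_reflectance: Dict[str, float] = field(
        default_factory=lambda: dict(SOIL_REFLECTANCE)
    )
    panicle_reflectance: Dict[str, float] = field(
        default_factory=lambda: dict(PANICLE_REFLECTANCE)
    )

    def __post_init__(self) -> None:
        if self.stage not in ("pre_heading", "post_heading"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.patch_size < 8 or self.patch_size % 2:
            raise ValueError("patch_size must be even and >= 8")
        if self.plot_rows < 1 or self.plot_cols < 1:
            raise ValueError("plot layout must be at least 1x1")
        if self.agb_range is None:
            rng = (
                PRE_HEADING_AGB_RANGE
                if self.stage == "pre_heading"
                else POST_HEADING_AGB_RANGE
            )
            object.__setattr__(self, "agb_range", rng)
        lo, hi = self.agb_range
        if not (0 < lo < hi):
            raise ValueError("agb_range must be a positive increasing interval")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def effective_coverage_gain(self) -> float:
        # panicle emergence coincides with near-closed canopies: saturate harder
        if self.stage == "post_heading":
            return self.coverage_gain * 1.9
        return self.coverage_gain

    def cover_fraction(self, agb: float) -> float:
        """Saturating monotone AGB -> canopy cover link."""
        return 1.0 - float(np.exp(-self.effective_coverage_gain * agb))

    @property
    def n_plots(self) -> int:
        return self.plot_rows * self.plot_cols


@dataclass(frozen=True)
class SyntheticSample:
    """One synthetic ROI: four reflectance patches plus its latent AGB."""

    agb: float
    patches: Dict[str, np.ndarray]
    stage: str
    plot_id: str

    def __post_init__(self) -> None:
        missing = [b for b in BANDS if b not in self.patches]
        if missing:
            raise ValueError(f"missing band(s): {missing}")
        for band, patch in self.patches.items():
            if np.any(np.asarray(patch) < 0):
                raise ValueError(f"negative reflectance in band {band!r}")


def _canopy_mask(config: SceneConfig, cover: float, rng: np.random.Generator) -> np.ndarray:
    """Blobby canopy mask with an exact cover fraction.

    A white-noise field is smoothed to introduce spatial correlation (clumped
    tillers rather than salt-and-pepper) and thresholded at the quantile that
    realises the requested cover fraction exactly.
    """
    n = config.patch_size
    fld = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=1.5)
    k = int(round(cover * n * n))
    if k <= 0:
        return np.zeros((n, n), dtype=bool)
    if k >= n * n:
        return np.ones((n, n), dtype=bool)
    thresh = np.partition(fld.ravel(), n * n - k)[n * n - k]
    mask = fld >= thresh
    # quantile ties can overshoot by a pixel or two; trim deterministically
    extra = int(mask.sum()) - k
    if extra > 0:
        idx = np.flatnonzero(mask.ravel() & (fld.ravel() == thresh))[:extra]
        flat = mask.ravel()
        flat[idx] = False
        mask = flat.reshape(n, n)
    return mask


def generate_sample(
    config: SceneConfig,
    agb: float,
    rng: np.random.Generator,
    plot_id: str = "P01",
) -> SyntheticSample:
    """Render one four-band ROI patch for a given latent AGB value.

    Raises
    ------
    ValueError
        If ``agb`` lies outside ``config.agb_range``.
    """
    lo, hi = config.agb_range
    if not (lo <= agb <= hi):
        raise ValueError(f"agb {agb} outside configured range [{lo}, {hi}]")

    # per-sample canopy-architecture jitter: same biomass, varying cover
    if config.cover_jitter_sd > 0:
        eff_agb = agb * float(np.exp(rng.normal(0.0, config.cover_jitter_sd)))
    else:
        eff_agb = agb
    cover = 1.0 - float(np.exp(-config.effective_coverage_gain * eff_agb))
    mask = _canopy_mask(config, cover, rng)
    n = config.patch_size

    patches: Dict[str, np.ndarray] = {}
    for band in BANDS:
        patch = np.where(
            mask, config.canopy_reflectance[band], config.soil_reflectance[band]
        ).astype(float)
        patches[band] = patch

    if config.stage == "post_heading" and config.speckle_density > 0:
        lam = config.speckle_density * agb * n * n
        n_speckle = int(rng.poisson(lam))
        if n_speckle > 0:
            rows = rng.integers(0, n - 1, size=n_speckle)
            cols = rng.integers(0, n - 1, size=n_speckle)
            for band in BANDS:
                v = config.panicle_reflectance[band]
                for r, c in zip(rows, cols):
                    patches[band][r : r + 2, c : c + 2] = v  # 2x2 bright blob

    # per-sample multiplicative illumination/calibration factor (all bands)
    if config.illumination_sd > 0:
        gain = float(np.exp(rng.normal(0.0, config.illumination_sd)))
        for band in BANDS:
            patches[band] = patches[band] * gain

    if config.noise_sd > 0:
        for band in BANDS:
            noise = rng.normal(0.0, config.noise_sd, size=(n, n))
            patches[band] = np.maximum(patches[band] + noise, 0.0)

    return SyntheticSample(agb=float(agb), patches=patches, stage=config.stage, plot_id=plot_id)


def generate_dataset(
    config: SceneConfig, n_draws: int = 1
) -> List[SyntheticSample]:
    """Draw AGB values uniformly over the configured range and render samples.

    One sample per plot per draw; ``config.n_plots * n_draws`` samples in
    total, reproducible bit-exactly under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    samples: List[SyntheticSample] = []
    lo, hi = config.agb_range
    for draw in range(n_draws):
        for r in range(config.plot_rows):
            for c in range(config.plot_cols):
                agb = float(rng.uniform(lo, hi))
                plot_id = f"{config.stage[:4]}-d{draw:02d}-r{r}c{c}"
                samples.append(generate_sample(config, agb, rng, plot_id=plot_id))
    return samples


def write_dataset(
    samples: List[SyntheticSample],
    out_dir: Path | str,
    gap: int = 2,
) -> Tuple[Path, Path, Path]:
    """Assemble samples into one multiband scene raster plus layout tables.

    Patches are tiled row-major into a single mosaic separated by soil-filled
    gaps; the ROI layout CSV records each patch's half-open pixel rectangle
    and the ground-truth CSV records ``plot_id,stage,agb_g_m2``.

    Returns the paths ``(scene.tif, roi_layout.csv, ground_truth.csv)``.
    """
    from .io import MultibandImage, write_raster  # local import: avoid cycle

    if not samples:
        raise ValueError("no samples to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n = samples[0].patches["green"].shape[0]
    ncols = int(np.ceil(np.sqrt(len(samples))))
    nrows = int(np.ceil(len(samples) / ncols))
    height = nrows * n + (nrows + 1) * gap
    width = ncols * n + (ncols + 1) * gap

    bands = {
        b: np.full((height, width), SOIL_REFLECTANCE[b], dtype=float) for b in BANDS
    }
    layout_rows = []
    for i, s in enumerate(samples):
        gr, gc = divmod(i, ncols)
        r0 = gap + gr * (n + gap)
        c0 = gap + gc * (n + gap)
        for b in BANDS:
            bands[b][r0 : r0 + n, c0 : c0 + n] = s.patches[b]
        layout_rows.append(
            {
                "plot_id": s.plot_id,
                "row0": r0,
                "row1": r0 + n,
                "col0": c0,
                "col1": c0 + n,
                "stage": s.stage,
                "year": 2024,
            }
        )

    scene_path = out_dir / "scene.tif"
    write_raster(scene_path, MultibandImage(bands=bands))

    roi_path = out_dir / "roi_layout.csv"
    with roi_path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(layout_rows[0]))
        writer.writeheader()
        writer.writerows(layout_rows)

    gt_path = out_dir / "ground_truth.csv"
    with gt_path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["plot_id", "stage", "agb_g_m2"])
        writer.writeheader()
        for s in samples:
            writer.writerow(
                {"plot_id": s.plot_id, "stage": s.stage, "agb_g_m2": repr(s.agb)}
            )
    return scene_path, roi_path, gt_path


def paired_stage_dataset(
    n_pre: int,
    n_post: int,
    seed: int,
    patch_size: int = 32,
    noise_sd: float = 0.01,
) -> List[SyntheticSample]:
    """Convenience: a combined pre-/post-heading draw for end-to-end runs."""
    pre_cfg = SceneConfig(
        stage="pre_heading", patch_size=patch_size, noise_sd=noise_sd, seed=seed
    )
    post_cfg = SceneConfig(
        stage="post_heading",
        patch_size=patch_size,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    pre_draws = int(np.ceil(n_pre / pre_cfg.n_plots))
    post_draws = int(np.ceil(n_post / post_cfg.n_plots))
    pre = generate_dataset(pre_cfg, n_draws=pre_draws)[:n_pre]
    post = generate_dataset(post_cfg, n_draws=post_draws)[:n_post]
    return pre + post
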