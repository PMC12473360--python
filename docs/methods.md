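# Methods

## The estimation problem

Plot-scale above-ground biomass (AGB, g/m²) is regressed on features
extracted from four-band (green, red, red-edge, NIR) canopy reflectance
imagery. Two feature families are used: vegetation indices (VIs) computed
from ROI-mean reflectances, and normalized-difference wavelet texture
indices (NDWTIs) computed from subband statistics of the ROI pixel patches.
The central hypothesis the package operationalises is complementarity: VIs
carry most of the signal while the canopy is open, whereas texture keeps
responding after canopy closure and panicle emergence, so their fusion is
more accurate across the whole season than either family alone.

## Wavelet texture features

Each band patch undergoes one level of the orthonormal 2-D Haar transform
(lowpass `[1/√2, 1/√2]`, highpass `[1/√2, −1/√2]`), implemented as the
equivalent non-overlapping 2×2 block transform. Conventions:

* **LH** is row-lowpass/column-highpass (horizontal detail), **HL** its
  transpose, **HH** diagonal detail. The mapping agrees coefficient-for-
  coefficient with PyWavelets' `dwt2(…, 'haar')` (`LH↔cH`, `HL↔cV`,
  `HH↔cD`), which the test suite uses as an independent oracle.
* Orthonormal filters make energy conservation exact
  (`Σ input² = Σ subband coefficients²`), asserted to 1e−9 relative in the
  tests. An unnormalized Haar variant would only rescale features, which the
  min–max scaling later removes; the orthonormal form was chosen precisely
  because it yields this testable invariant.
* Odd-sized patches are edge-replicate padded to even size before
  decomposition, avoiding wrap-around artifacts at canopy borders.

Per subband the statistics are mean (`Mea`), population variance (`Var`,
divisor MN), energy (`Ene`, mean of squared coefficients — so
`Ene − Mea² = Var` identically) and entropy
`Ent = −(1/MN)·Σ q·log₂ q` with `q = |coefficient|` and `0·log₂ 0 := 0`.
The absolute value is a deliberate convention: detail-subband coefficients
are signed and centred on zero, where a raw `x·log₂ x` is undefined; taking
the magnitude preserves the functional form while keeping the statistic
defined everywhere. Whether a rescaled-coefficient convention would behave
differently only matters up to the subsequent min–max scaling.

## NDWTI construction

`NDWTI(WT1, WT2) = (WT1 − WT2)/(WT1 + WT2)` on min–max-scaled WT features.

* The scaler is fitted on the **training partition only** and applied,
  without clipping, to test data. Fitting on pooled data would leak test
  information into the feature construction.
* All ordered pairs are enumerated (4032 per stage; 2256 high–high, 240
  low–low, 1536 mixed). A pair and its reversal are identical up to sign —
  hence have equal |Spearman| with any response — and are deduplicated only
  at selection time (lexicographically smaller ordered name kept), so the
  enumeration stays the complete catalogue while the model inputs stay
  non-redundant.
* If both scaled features are at the training minimum the denominator
  vanishes; `|WT1+WT2| < 1e−12` returns 0, the symmetric limit.

## Vegetation-index registry

The registry is a YAML file of `name → formula` entries over the four band
means, evaluated by a guarded arithmetic interpreter (only `+ − * / **`,
`sqrt`, band names and constants; denominators below 1e−9 in magnitude yield
a NaN sentinel rather than ±inf, keeping downstream correlations defined).
The packaged default carries 21 standard four-band indices from the
remote-sensing literature — the normalized-difference family (NDVI, GNDVI,
NDRE, RENDVI), ratio and chlorophyll indices (RVI, GRVI, RERVI, CIgreen,
CIrededge, MSR, MTCI), soil-adjusted forms (SAVI, OSAVI with soil term 0.16,
GOSAVI, EVI2), and difference/nonlinear forms (DVI, RDVI, WDRVI, NLI, MCARI,
TVI). Users can substitute their own registry file.

## Screening and modelling

* **Split**: 75/25 random within each stage; train size is round-half-up of
  `0.75·n` (468 → 351/117, 234 → 176/58); the all-stage partitions are
  unions of the stage-wise ones, so no sample changes sides between stage
  and all-stage analyses.
* **Screening**: features ranked by |Spearman ρ| with AGB on the training
  partition, ties broken lexicographically; top 5 per family per stage
  (configurable). Shapiro–Wilk statistics are reported but gate nothing —
  they document why a rank correlation is appropriate. No multiple-testing
  correction is applied to the 4032 screening correlations: selection is a
  ranking, not an inference, and models are judged on held-out data; treat
  individual screening ρ values accordingly.
* **Simple regression**: univariate ordinary least squares on the single
  best-screened feature (optional quadratic flag). The simplest defensible
  form; the flag covers visibly curved relationships.
* **MLR**: ordinary least squares; rank-deficient designs fall back to the
  minimum-norm solution with a warning (near-collinear NDWTI selections do
  occur).
* **Tuned forest**: inputs z-scored with training-partition statistics; the
  objective is mean 10-fold cross-validated R²; the search is a
  tree-structured Parzen estimator (`ndwti.tuning`) — 10 random startup
  trials, good/bad split at the 25% quantile, per-dimension Parzen mixtures
  (truncated normals with Silverman-style bandwidth floored at 5% of span;
  add-one-smoothed categoricals), 24 candidates per step scored by the
  density ratio. Default space: n_estimators 50–500, max_depth 3–30,
  min_samples_split 2–10, min_samples_leaf 1–10, max_features
  {sqrt, log2, fraction ∈ [0.3, 1.0]}; 100 trials by default. The whole
  search is deterministic under its seed.
* **Metrics**: `R² = 1 − SSres/SStot` (may be negative out of sample;
  NaN sentinel for constant truth) and RMSE in g/m².

## Shapley interpretation

Attributions are interventional Shapley values against a background sample
(default: a 16-row training subsample). For ≤ 16 features the coalition
lattice is enumerated exactly, so local accuracy
(`base + Σφᵢ = prediction`) holds to float precision — the pipeline's fused
models have 10 features. Beyond 16 features a seeded antithetic
permutation-sampling estimator is used; its telescoping sum preserves local
accuracy exactly as well, only the per-feature split becomes Monte Carlo.
Z-scoring uses population σ (no Bessel correction); constant columns map to
zero with a warning. Both raw and Z-scored attributions are exported, since
either may be wanted on a summary plot's axis.

## Synthetic scene generator

`ndwti.synth` emulates what a two-stage UAV campaign presents to the
pipeline; one sample is a four-band reflectance patch plus its latent AGB.

* **Cover link**: `cover = 1 − exp(−g·AGB)` — monotone, saturating,
  two-parameter. Pre-heading `g = 8e−4` m²/g puts the AGB range
  (185–1615 g/m²) on the rising-to-saturating part of the curve;
  post-heading the effective gain is 1.9× higher (range 633–1947 g/m²), so
  the red/NIR contrast saturates harder late season.
* **Spectra**: canopy NIR 0.45 / red 0.05, soil NIR 0.20 / red 0.18 (flat),
  typical vegetation/soil values, fixed in the config so tests can derive
  exact expectations (e.g. ROI-mean NDVI < 0.2 at the range minimum).
* **Canopy geometry**: a Gaussian-smoothed random field thresholded at the
  exact cover quantile — clumped tillers rather than salt-and-pepper.
* **Panicle speckle** (post-heading only): 2×2 bright blobs in all bands,
  Poisson count with mean `speckle_density·AGB·area`, raising HH texture
  with biomass.
* **Nuisance structure**: a per-sample lognormal illumination factor
  (σ = 0.08) emulating calibration/illumination drift between plots and
  flights, a lognormal jitter on the cover link (σ = 0.25) emulating
  variety and nitrogen-treatment differences in architecture at equal
  biomass, and additive Gaussian sensor noise (σ = 0.01 reflectance)
  truncated at zero. Without the two per-sample terms the synthetic task is
  near-deterministic and uninformative; with them, held-out R² of the tuned
  models sits in the 0.65–0.8 band and brightness-normalized features enjoy
  exactly the advantage they are designed for.

What the generator does **not** emulate: radiative transfer (no PROSAIL-type
physics), 3-D canopy geometry, view/sun-angle effects, band misregistration,
or inter-plot spatial correlation. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes — monotone spectral links,
saturating cover, texture–biomass coupling after heading — not that any
particular accuracy will be achieved on field data.

## Problem sizes and numerical choices

The packaged end-to-end study (`run_synthetic_study`) uses about 500
quadrats (300 pre-, 200 post-heading), 32×32-pixel patches, a 20-trial
forest search over 50–300 trees with 10-fold CV, and 30 explained test
samples against a 16-row background; this keeps a complete three-stage run
to a few minutes on one core while leaving every qualitative contrast
(fusion gain, post-heading texture dominance) intact. Degenerate inputs are
handled by explicit sentinels rather than exceptions wherever a value can
flow into a ranking: undefined correlations and indices become NaN and are
dropped with a logged warning; constant scaler columns map to zero; ties
break lexicographically so every ordering is reproducible.

## Known limitations

* The NDWTI catalogue is quadratic in the feature count; at 64 WTs this is
  cheap, but the screening applies no multiplicity control (see above).
* Spearman screening is marginal: pairwise-redundant or jointly informative
  feature sets are neither penalised nor discovered.
* The synthetic benchmark shares its generative assumptions with the
  features being evaluated (monotone cover link, speckle-texture coupling),
  which is what makes qualitative reproduction possible — and why its R²
  values must not be read as field-accuracy claims.
* Interventional Shapley values against a small background are themselves a
  modelling choice; attributions answer "relative to this background", not
  "causally".
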