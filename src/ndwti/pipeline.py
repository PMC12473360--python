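"""End-to-end orchestration: features -> screening -> models -> attributions.

The analysis follows the standard multi-stage design: samples are split 75/25
within each growth stage, the all-stage partitions are unions of the
stage-wise ones, and for every stage three feature sets (top-5 VIs, top-5
NDWTIs, their fusion) are screened on the training partition and fed to
simple/MLR/tuned-RF regressions.  The tuned forest of the fused set is
explained with Shapley attributions.

Everything here is pure computation over in-memory tables; file artifacts and
hashing live in the CLI layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .indices import VIRegistry, compute_all_vis, default_registry
from .interpret import (
    AttributionMatrix,
    shapley_attributions,
    standardize_attributions,
    summarize_importance,
)
from .io import SampleRecord
from .modeling import (
    FitResult,
    ModelSpec,
    StageDataset,
    fit_mlr,
    fit_rf_tuned,
    fit_simple_regression,
    split_stagewise,
)
from .screening import SelectionResult, rank_features, select_top_k
from .texture_index import apply_minmax, enumerate_pairs, fit_minmax, ndwti_table
from .wavelet import compute_wt_features, wt_feature_names

__all__ = [
    "build_feature_table",
    "StageResult",
    "AnalysisResult",
    "run_full_analysis",
    "META_COLUMNS",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ("plot_id", "stage", "agb")
FEATURE_SETS = ("VIs", "NDWTIs", "VIs+NDWTIs")


def build_feature_table(
    samples: Sequence[SampleRecord], registry: Optional[VIRegistry] = None
) -> pd.DataFrame:
    """One row per sample: metadata, 21 VI columns, 64 WT columns."""
    registry = registry or default_registry()
    rows: List[Dict[str, float]] = []
    for s in samples:
        row: Dict[str, float] = {"plot_id": s.plot_id, "stage": s.stage, "agb": s.agb}
        row.update(compute_all_vis(registry, s.reflectance_means))
        row.update(compute_wt_features(s.patches))
        rows.append(row)
    df = pd.DataFrame(rows)
    logger.info(
        "feature table: %d samples, %d VI + %d WT columns",
        len(df), len(registry), len(wt_feature_names()),
    )
    return df


@dataclass
class StageResult:
    """Everything computed for one growth stage."""

    stage: str
    dataset: StageDataset
    vi_selection: SelectionResult
    ndwti_selection: SelectionResult
    simple_fits: Dict[str, FitResult] = field(default_factory=dict)
    mlr_fits: Dict[str, FitResult] = field(default_factory=dict)
    rf_fits: Dict[str, FitResult] = field(default_factory=dict)
    fused_train: Optional[pd.DataFrame] = None
    fused_test: Optional[pd.DataFrame] = None
    attributions: Optional[AttributionMatrix] = None
    importance: Optional[pd.DataFrame] = None
    standardized_attributions: Optional[pd.DataFrame] = None
    explained_features: Optional[pd.DataFrame] = None


@dataclass
class AnalysisResult:
    stages: Dict[str, StageResult]
    metrics: pd.DataFrame  # long table: stage, feature_set, model, partition, r2, rmse


def _stage_family_tables(
    ds: StageDataset, vi_cols: List[str], wt_cols: List[str]
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """VI train/test frames plus full 4032-column NDWTI train/test frames.

    The min-max scaler for the WT features is fitted on the training
    partition only and applied to both partitions.
    """
    scaler = fit_minmax(ds.X_train[wt_cols])
    wt_train = apply_minmax(scaler, ds.X_train[wt_cols])
    wt_test = apply_minmax(scaler, ds.X_test[wt_cols])
    pairs = enumerate_pairs(wt_cols)
    nd_train = ndwti_table(wt_train, pairs)
    nd_test = ndwti_table(wt_test, pairs)
    logger.info("stage %s: %d NDWTI columns constructed", ds.stage, nd_train.shape[1])
    return ds.X_train[vi_cols], ds.X_test[vi_cols], nd_train, nd_test


def run_full_analysis(
    features: pd.DataFrame,
    seed: int = 0,
    k: int = 5,
    train_fraction: float = 0.75,
    model_spec: Optional[ModelSpec] = None,
    explain: bool = True,
    max_explain: int = 40,
    background_size: int = 16,
    registry: Optional[VIRegistry] = None,
    fit_models: bool = True,
) -> AnalysisResult:
    """Screen, fit and (optionally) explain models for all three stages.

    Parameters
    ----------
    features
        Output of `build_feature_table` (or a CSV round-trip of it).
    seed
        Drives the split, the forest search and attribution sampling.
    k
        Features selected per family per stage.
    model_spec
        Forest search configuration; defaults to `ModelSpec` with its seed
        replaced by ``seed``.
    explain, max_explain, background_size
        Whether to compute Shapley attributions for the fused forest, on at
        most ``max_explain`` test samples against a ``background_size``
        training background.
    """
    registry = registry or default_registry()
    vi_cols = [n for n in registry.names() if n in features.columns]
    wt_cols = [n for n in wt_feature_names() if n in features.columns]
    if not vi_cols or len(wt_cols) != 64:
        raise ValueError("feature table lacks the expected VI/WT columns")

    by_stage = {}
    for stage in ("pre_heading", "post_heading"):
        sub = features[features["stage"] == stage]
        by_stage[stage] = (sub[vi_cols + wt_cols], sub["agb"].to_numpy())
    datasets = split_stagewise(by_stage, train_fraction=train_fraction, seed=seed)

    spec = model_spec or ModelSpec(seed=seed)
    stages: Dict[str, StageResult] = {}
    metric_rows: List[Dict] = []

    for stage, ds in datasets.items():
        vi_train, vi_test, nd_train, nd_test = _stage_family_tables(ds, vi_cols, wt_cols)

        vi_sel = select_top_k(
            rank_features(vi_train, ds.y_train, stage=stage),
            k=k, dedup=False, stage=stage, family="VI",
        )
        nd_sel = select_top_k(
            rank_features(nd_train, ds.y_train, stage=stage),
            k=k, dedup=True, stage=stage, family="NDWTI",
        )
        res = StageResult(
            stage=stage, dataset=ds, vi_selection=vi_sel, ndwti_selection=nd_sel
        )
        if not fit_models:
            stages[stage] = res
            continue

        family_frames = {
            "VIs": (vi_train[vi_sel.names()], vi_test[vi_sel.names()]),
            "NDWTIs": (nd_train[nd_sel.names()], nd_test[nd_sel.names()]),
        }
        fused_train = pd.concat(
            [family_frames["VIs"][0], family_frames["NDWTIs"][0]], axis=1
        )
        fused_test = pd.concat(
            [family_frames["VIs"][1], family_frames["NDWTIs"][1]], axis=1
        )
        family_frames["VIs+NDWTIs"] = (fused_train, fused_test)
        res.fused_train, res.fused_test = fused_train, fused_test

        # simple regression on the single best feature of each family
        for fam in ("VIs", "NDWTIs"):
            tr, te = family_frames[fam]
            best = tr.columns[0]
            res.simple_fits[fam] = fit_simple_regression(
                tr[best], ds.y_train, te[best], ds.y_test
            )
            _collect(metric_rows, stage, fam, "simple", res.simple_fits[fam])

        for fam, (tr, te) in family_frames.items():
            res.mlr_fits[fam] = fit_mlr(tr, ds.y_train, te, ds.y_test)
            _collect(metric_rows, stage, fam, "mlr", res.mlr_fits[fam])
            stage_spec = ModelSpec(
                space=dict(spec.space), n_trials=spec.n_trials,
                cv_folds=spec.cv_folds, seed=spec.seed,
            )
            res.rf_fits[fam] = fit_rf_tuned(tr, ds.y_train, stage_spec, te, ds.y_test)
            _collect(metric_rows, stage, fam, "rf", res.rf_fits[fam])

        if explain:
            rng = np.random.default_rng(seed + 17)
            tr, te = family_frames["VIs+NDWTIs"]
            explain_idx = rng.choice(
                len(te), size=min(max_explain, len(te)), replace=False
            )
            bg_idx = rng.choice(
                len(tr), size=min(background_size, len(tr)), replace=False
            )
            fit = res.rf_fits["VIs+NDWTIs"]
            X_explain = te.iloc[np.sort(explain_idx)]
            att = shapley_attributions(
                fit, X_explain, background=tr.to_numpy(dtype=float)[np.sort(bg_idx)],
                seed=seed,
            )
            res.attributions = att
            res.importance = summarize_importance(att)
            res.standardized_attributions = standardize_attributions(att)
            res.explained_features = X_explain

        stages[stage] = res

    metrics = pd.DataFrame(metric_rows)
    return AnalysisResult(stages=stages, metrics=metrics)


def run_synthetic_study(
    seed: int = 0,
    n_pre: int = 300,
    n_post: int = 200,
    patch_size: int = 32,
    n_trials: int = 20,
    cv_folds: int = 10,
    k: int = 5,
    explain: bool = True,
) -> AnalysisResult:
    """Generate a two-stage synthetic campaign and run the full analysis.

    Defaults reflect a season-scale study (about 500 quadrats split 3:2
    between pre- and post-heading) with a reduced 20-trial forest search over
    50-300 trees; these sizes keep a complete run to a few minutes on one
    core while leaving every qualitative contrast intact.
    """
    from .synth import paired_stage_dataset
    from .tuning import IntUniform

    samples = paired_stage_dataset(n_pre, n_post, seed=seed, patch_size=patch_size)
    records = [
        SampleRecord(
            plot_id=s.plot_id,
            stage=s.stage,
            agb=s.agb,
            reflectance_means={b: float(p.mean()) for b, p in s.patches.items()},
            patches=s.patches,
        )
        for s in samples
    ]
    table = build_feature_table(records)
    from .modeling import DEFAULT_RF_SPACE

    space = dict(DEFAULT_RF_SPACE)
    space["n_estimators"] = IntUniform(50, 300)
    spec = ModelSpec(space=space, n_trials=n_trials, cv_folds=cv_folds, seed=seed)
    return run_full_analysis(
        table, seed=seed, k=k, model_spec=spec, explain=explain,
        max_explain=30, background_size=16,
    )


def _collect(
    rows: List[Dict], stage: str, feature_set: str, model: str, fit: FitResult
) -> None:
    for partition, (r2, rmse) in fit.metrics.items():
        rows.append(
            {
                "stage": stage,
                "feature_set": feature_set,
                "model": model,
                "partition": partition,
                "r2": r2,
                "rmse": rmse,
            }
        )
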