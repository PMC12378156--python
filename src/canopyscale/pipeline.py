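"""End-to-end orchestration of the two-stage canopy-closure analysis.

Stage 1 (footprint scale): screen the LiDAR segment features by
random-forest importance, tune KNN/RFR/GBRT by Bayesian optimization under a
LOOCV objective on the field plots, and predict FCC for every footprint.

Stage 2 (regional scale): derive the raster covariate stack, screen it
(Pearson, VIF, normality), fit a geographically weighted regression on the
footprint predictions with an AICc-selected bandwidth, and extrapolate to a
wall-to-wall FCC map with diagnostics, class proportions and plot-based
validation.

The same chain runs with the unoptimized (default-hyperparameter) footprint
labels so the before/after comparison arithmetic of the report is computed
from live model runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import footprint as fp_mod
from . import gwr as gwr_mod
from . import raster_io, selection
from .covariates import regional_covariates
from .footprint import (
    FittedFootprintModel,
    ModelSpec,
    default_params,
    desk_scale_space,
    paper_scale_space,
    predict_footprints,
    prediction_accuracy,
    ratio_r2,
    resid_r2,
    rmse,
    train_and_select,
)
from .scene import SceneConfig, generate_scene, make_footprint_features, sample_plots

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
    "report_improvements",
    "fcc_distribution",
    "validate_against_plots",
]

ERROR_METRICS = frozenset({"rmse", "mar", "aicc"})


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full synthetic-mode pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    models: tuple[str, ...] = ("knn", "rfr", "gbrt")
    bo_budget: int = 50
    bo_init: int = 10
    space_scale: str = "desk"  # or "paper"
    rf_threshold: float = 0.05
    pearson_r_min: float = 0.2
    pearson_alpha: float = 0.01
    max_vif: float = 10.0
    normality_transform: str = "auto"
    gwr_kernel: str = "bisquare"
    gwr_bandwidth_mode: str = "adaptive_neighbors"
    max_gwr_train: int = 2000
    fcc_bins: tuple[float, ...] = (0.0, 0.3, 0.6, 1.0)
    seed: int = 7

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "scene" in data and isinstance(data["scene"], dict):
            sc = dict(data["scene"])
            for key in ("plot_beta_params", "plot_bounds"):
                if key in sc and sc[key] is not None:
                    sc[key] = tuple(sc[key])
            data["scene"] = SceneConfig(**sc)
        for key in ("models", "fcc_bins"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(raster_io.load_yaml(path))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Serializable summary of one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    footprint_selection: dict
    footprint_comparison: list[dict]
    footprint_improvements: dict
    best_model: str
    regional_selection: dict
    gwr: dict
    gwr_unoptimized: dict
    gwr_improvements: dict
    fcc_class_proportions: dict
    fcc_map_mean: float
    map_truth: dict
    plot_validation: dict
    stage_seconds: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).parent.mkdir(parents=True, exist_ok=True)
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def report_improvements(
    before: dict, after: dict, convention: str = "delta_over_before"
) -> dict:
    """Relative before/after changes, in percent, with explicit conventions.

    ``before`` and ``after`` map metric names to scalars or to equal-length
    sequences (one entry per model; per-model changes are averaged).  For
    error metrics (RMSE, MAR, AICc) the sign is flipped so an improvement is
    always positive.  Conventions: ``delta_over_before`` divides by the
    before value, ``delta_over_after`` by the after value, and ``averaged``
    uses delta_over_after for gain metrics and delta_over_before for error
    metrics (the mixed arithmetic of multi-model comparison tables).  A zero
    baseline is flagged undefined rather than raising.
    """
    if convention not in ("delta_over_before", "delta_over_after", "averaged"):
        raise ValueError(f"unknown convention {convention!r}")
    if set(before) != set(after):
        raise ValueError("before/after metric sets differ")
    out = {}
    for metric in before:
        b = np.atleast_1d(np.asarray(before[metric], dtype=float))
        a = np.atleast_1d(np.asarray(after[metric], dtype=float))
        if b.shape != a.shape:
            raise ValueError(f"shape mismatch for metric {metric!r}")
        error = metric.lower() in ERROR_METRICS
        conv = convention
        if convention == "averaged":
            conv = "delta_over_before" if error else "delta_over_after"
        num = (b - a) if error else (a - b)
        den = b if conv == "delta_over_before" else a
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * num / np.abs(den)
        entry = {
            "convention": conv,
            "averaged_over": int(b.size),
            "undefined": bool(np.any(den == 0)),
        }
        entry["percent"] = (
            float("nan") if entry["undefined"] else float(np.mean(pct))
        )
        out[metric] = entry
    return out


def fcc_distribution(
    fcc_map: np.ndarray, bins: tuple[float, ...] = (0.0, 0.3, 0.6, 1.0)
) -> dict[str, float]:
    """Proportions of valid map cells per FCC class bin.

    Bins are half-open with the last bin closed (numpy histogram
    convention); NaN cells are excluded from the denominator.  Raises when
    no valid cell remains.
    """
    vals = np.asarray(fcc_map, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid cells in the FCC map")
    if vals.min() < bins[0] or vals.max() > bins[-1]:
        raise ValueError("FCC values outside the bin range")
    counts, edges = np.histogram(vals, bins=np.asarray(bins, dtype=float))
    props = counts / counts.sum()
    return {
        f"[{edges[i]:g},{edges[i + 1]:g}{']' if i == len(props) - 1 else ')'}": float(p)
        for i, p in enumerate(props)
    }


def validate_against_plots(
    fcc_map: np.ndarray,
    plots: pd.DataFrame,
    cell_size: float,
) -> dict:
    """Compare the predicted map against field-plot measurements.

    Predicted FCC is read at each plot's nearest cell (the plot radius is
    below the cell size); plots falling outside the raster or on nodata are
    excluded and counted.  Returns the printed-formula R^2 (observed-mean
    convention), the Pearson correlation with its two-sided p-value, and the
    pair count.
    """
    fcc_map = np.asarray(fcc_map, dtype=float)
    rows_n, cols_n = fcc_map.shape
    x = plots["x"].to_numpy(dtype=float)
    y = plots["y"].to_numpy(dtype=float)
    col = np.floor(x / cell_size).astype(int)
    row = np.floor(rows_n - y / cell_size).astype(int)
    inside = (col >= 0) & (col < cols_n) & (row >= 0) & (row < rows_n)
    pred = np.full(len(plots), np.nan)
    pred[inside] = fcc_map[row[inside], col[inside]]
    ok = np.isfinite(pred)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("fewer than 3 co-located plot/map pairs")
    measured = plots["fcc_measured"].to_numpy(dtype=float)[ok]
    predicted = pred[ok]
    r, p = stats.pearsonr(predicted, measured)
    return {
        "r2": ratio_r2(measured, predicted),
        "pearson_r": float(r),
        "p_value": float(p),
        "n": int(ok.sum()),
        "n_excluded": n_excluded,
    }


def _gwr_stage(
    X: pd.DataFrame,
    y: np.ndarray,
    coords: np.ndarray,
    cov_grids: dict,
    mask: np.ndarray,
    cell_size: float,
    cfg: PipelineConfig,
) -> tuple[dict, np.ndarray, gwr_mod.GWRModel]:
    """Bandwidth selection, fit, in-sample summary and map prediction."""
    base = gwr_mod.GWRConfig(
        kernel=cfg.gwr_kernel, bandwidth_mode=cfg.gwr_bandwidth_mode
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gcfg, profile = gwr_mod.select_bandwidth(X.to_numpy(float), y, coords, base)
        model = gwr_mod.fit_gwr(X.to_numpy(float), y, coords, gcfg)
        fcc_map = gwr_mod.predict_grid(
            model,
            cov_grids,
            list(X.columns),
            cell_size,
            mask=mask,
            clamp=(0.0, 1.0),
        )
    summary = {
        **model.summary(),
        "r2": ratio_r2(y, model.fitted),
        "r2_resid": resid_r2(y, model.fitted),
        "rmse": rmse(y, model.fitted),
        "p_accuracy": prediction_accuracy(y, model.fitted),
        "mar": fp_mod.mean_absolute_residual(y, model.fitted),
        "aicc_profile_n": len(profile),
        "features": list(X.columns),
    }
    return summary, fcc_map, model


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineReport:
    """Execute the full two-stage chain and return the report.

    With ``outdir`` set, artifacts are written: the FCC map and covariate
    stack as TIFF, footprint predictions and plot samples as CSV, selection
    reports as JSON, and the report itself.  The run is fully reproducible
    from the configuration (seeded end to end).
    """
    cfg = config
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str):
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    try:
        scene = generate_scene(cfg.scene)
        footprints = make_footprint_features(scene)
        plots = sample_plots(scene, footprints=footprints)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[simulate] {exc}") from exc
    tick("simulate")

    feature_cols = [
        c
        for c in footprints.columns
        if c not in ("id", "x", "y", "true_fcc", "predicted_fcc")
    ]
    train_X = footprints.loc[
        footprints["id"].isin(plots["footprint_id"]), feature_cols
    ].reset_index(drop=True)
    train_y = (
        plots.sort_values("footprint_id")["fcc_measured"].to_numpy(dtype=float)
    )

    try:
        imp = selection.rf_importance_select(
            train_X, train_y, threshold=cfg.rf_threshold, seed=cfg.seed
        )
        kept = imp.kept
        if not kept:
            raise PipelineError("[footprint-select] no feature reached the threshold")
        spaces = {
            k: (desk_scale_space(k) if cfg.space_scale == "desk" else paper_scale_space(k))
            for k in cfg.models
        }
        result = train_and_select(
            train_X[kept],
            train_y,
            spaces=spaces,
            budget=cfg.bo_budget,
            n_init=cfg.bo_init,
            seed=cfg.seed,
            kinds=cfg.models,
        )
        footprints_opt = predict_footprints(result.model, footprints)
        # unoptimized counterpart of the winning learner
        base_spec = ModelSpec.of(result.best_kind, default_params(result.best_kind))
        base_est = fp_mod.make_estimator(base_spec, seed=cfg.seed)
        base_est.fit(train_X[kept].to_numpy(float), train_y)
        base_model = FittedFootprintModel(base_spec, base_est, list(kept))
        footprints_base = predict_footprints(base_model, footprints)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[footprint-model] {exc}") from exc
    tick("footprint_model")

    try:
        cov = regional_covariates(scene)
        coords_all = footprints[["x", "y"]].to_numpy(dtype=float)
        cov_table = pd.DataFrame(
            {name: scene.sample(grid, coords_all[:, 0], coords_all[:, 1])
             for name, grid in cov.items()}
        )
        y_opt = footprints_opt["predicted_fcc"].to_numpy(dtype=float)
        y_base = footprints_base["predicted_fcc"].to_numpy(dtype=float)
        pear = selection.pearson_screen(
            cov_table, y_opt, r_min=cfg.pearson_r_min, alpha=cfg.pearson_alpha
        )
        if not pear.kept:
            raise PipelineError("[regional-select] Pearson screen kept nothing")
        vif = selection.vif_filter(cov_table[pear.kept], max_vif=cfg.max_vif)
        norm = selection.normality_assess(
            cov_table[vif.kept], transform=cfg.normality_transform
        )
        reg_X = selection.apply_transforms(norm, cov_table[vif.kept])
        reg_grids = selection.apply_transforms(
            norm, {k: cov[k] for k in vif.kept}
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[regional-select] {exc}") from exc
    tick("regional_select")

    try:
        rng = np.random.default_rng(cfg.seed)
        n_fp = len(footprints)
        if n_fp > cfg.max_gwr_train:
            sub = np.sort(rng.choice(n_fp, size=cfg.max_gwr_train, replace=False))
        else:
            sub = np.arange(n_fp)
        gwr_opt, map_opt, model_opt = _gwr_stage(
            reg_X.iloc[sub],
            y_opt[sub],
            coords_all[sub],
            reg_grids,
            scene.mask,
            scene.cell_size,
            cfg,
        )
        gwr_base, _, _ = _gwr_stage(
            reg_X.iloc[sub],
            y_base[sub],
            coords_all[sub],
            reg_grids,
            scene.mask,
            scene.cell_size,
            cfg,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[gwr] {exc}") from exc
    tick("gwr")

    try:
        dist = fcc_distribution(map_opt, cfg.fcc_bins)
        val = validate_against_plots(map_opt, plots, scene.cell_size)
        truth = scene.true_fcc[scene.mask]
        mapped = map_opt[scene.mask]
        okm = np.isfinite(mapped)
        map_truth = {
            "r2": ratio_r2(truth[okm], mapped[okm]),
            "r2_resid": resid_r2(truth[okm], mapped[okm]),
            "pearson_r": float(stats.pearsonr(mapped[okm], truth[okm])[0]),
            "rmse": rmse(truth[okm], mapped[okm]),
        }
        fp_before = {
            m: [result.baseline_reports[k].as_dict()[m] for k in cfg.models]
            for m in ("r2_resid", "rmse", "p_accuracy")
        }
        fp_after = {
            m: [result.reports[k].as_dict()[m] for k in cfg.models]
            for m in ("r2_resid", "rmse", "p_accuracy")
        }
        fp_improve = report_improvements(fp_before, fp_after, "averaged")
        gwr_improve = report_improvements(
            {m: gwr_base[m] for m in ("r2_resid", "rmse", "aicc")},
            {m: gwr_opt[m] for m in ("r2_resid", "rmse", "aicc")},
            "delta_over_before",
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[report] {exc}") from exc
    tick("report")

    report = PipelineReport(
        config=cfg.to_dict(),
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        footprint_selection={
            "kept": kept,
            "importance_shares": {
                r.name: r.importance_share for r in imp.records
            },
        },
        footprint_comparison=result.comparison.to_dict(orient="records"),
        footprint_improvements=fp_improve,
        best_model=result.best_kind,
        regional_selection={
            "pearson_kept": pear.kept,
            "vif_kept": vif.kept,
            "transforms": {
                r.name: r.transform for r in norm.records if r.transform != "none"
            },
        },
        gwr=gwr_opt,
        gwr_unoptimized=gwr_base,
        gwr_improvements=gwr_improve,
        fcc_class_proportions=dist,
        fcc_map_mean=float(np.nanmean(map_opt)),
        map_truth=map_truth,
        plot_validation=val,
        stage_seconds=timings,
    )

    if outdir is not None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raster_io.write_raster(
            outdir / "fcc_map.tif",
            map_opt,
            scene.cell_size,
            epsg=cfg.scene.epsg,
        )
        footprints_opt.to_csv(outdir / "footprint_predictions.csv", index=False)
        plots.to_csv(outdir / "plots.csv", index=False)
        result.comparison.to_csv(outdir / "model_comparison.csv", index=False)
        imp.to_json(outdir / "footprint_selection.json")
        pear.to_json(outdir / "regional_pearson.json")
        vif.to_json(outdir / "regional_vif.json")
        norm.to_json(outdir / "regional_normality.json")
        report.to_json(outdir / "report.json")
        raster_io.save_yaml(cfg.to_dict(), outdir / "config.yaml")
    return report
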