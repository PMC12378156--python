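"""Screening gates that precede the two modeling stages.

The footprint stage keeps features whose random-forest importance share
reaches 5% of the total.  The regional stage chains a Pearson correlation
screen (|r| >= 0.2, significant at the 0.01 level), an iterative
variance-inflation-factor filter (VIF > 10 removed worst-first), and a
normality assessment (D'Agostino omnibus test, optional one-parameter
power transform) that licenses the geographically weighted regression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "VariableRecord",
    "SelectionReport",
    "rf_importance_select",
    "pearson_screen",
    "vif_filter",
    "normality_assess",
    "apply_transforms",
    "export_histograms",
]


@dataclass
class VariableRecord:
    """Per-candidate outcome of a screening gate."""

    name: str
    decision: str  # "kept" | "dropped"
    reason: str = ""
    importance_share: float | None = None
    pearson_r: float | None = None
    p_value: float | None = None
    vif: float | None = None
    normality_stat: float | None = None
    normality_p: float | None = None
    normality_pass: bool | None = None
    transform: str = "none"
    transform_lmbda: float | None = None


@dataclass
class SelectionReport:
    """Outcome of one screening gate over a candidate table."""

    stage: str
    records: list[VariableRecord] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return [r.name for r in self.records if r.decision == "kept"]

    @property
    def dropped(self) -> list[str]:
        return [r.name for r in self.records if r.decision == "dropped"]

    def record(self, name: str) -> VariableRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_json(self, path=None, **kwargs) -> str:
        payload = json.dumps(
            {"stage": self.stage, "records": [asdict(r) for r in self.records]},
            indent=2,
            **kwargs,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _check_features(features: pd.DataFrame) -> pd.DataFrame:
    features = pd.DataFrame(features)
    for col in features.columns:
        if features[col].isna().all():
            raise ValueError(f"feature column {col!r} is all-NaN")
    return features


def rf_importance_select(
    features: pd.DataFrame,
    target: np.ndarray,
    threshold: float = 0.05,
    n_estimators: int = 500,
    seed: int = 0,
) -> SelectionReport:
    """Keep features whose random-forest importance share reaches ``threshold``.

    A seeded random-forest regressor (500 trees by default) is fit to the
    target; mean-decrease-in-impurity importances are normalized to sum to 1
    and candidates with a share >= ``threshold`` (boundary inclusive) are
    kept.
    """
    features = _check_features(features)
    y = np.asarray(target, dtype=float)
    if len(features) < 10:
        raise ValueError("need at least 10 samples for importance screening")
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    rf.fit(features.to_numpy(dtype=float), y)
    shares = rf.feature_importances_
    total = shares.sum()
    if total > 0:
        shares = shares / total
    report = SelectionReport(stage="rf_importance")
    for name, share in zip(features.columns, shares):
        kept = share >= threshold
        report.records.append(
            VariableRecord(
                name=str(name),
                decision="kept" if kept else "dropped",
                reason="" if kept else f"importance share {share:.4f} < {threshold}",
                importance_share=float(share),
            )
        )
    return report


def pearson_screen(
    features: pd.DataFrame,
    target: np.ndarray,
    r_min: float = 0.2,
    alpha: float = 0.01,
) -> SelectionReport:
    """Keep variables with |r| >= ``r_min`` and two-sided p < ``alpha``.

    The magnitude boundary is inclusive; zero-variance variables are dropped
    with a reason rather than raising.
    """
    features = _check_features(features)
    y = np.asarray(target, dtype=float)
    if len(features) < 5:
        raise ValueError("need at least 5 samples for a correlation screen")
    report = SelectionReport(stage="pearson")
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x[~np.isnan(x)]) == 0:
            report.records.append(
                VariableRecord(str(name), "dropped", reason="zero variance")
            )
            continue
        r, p = stats.pearsonr(x, y)
        kept = abs(r) >= r_min and p < alpha
        reason = "" if kept else f"|r|={abs(r):.3f}, p={p:.3g}"
        report.records.append(
            VariableRecord(
                str(name),
                "kept" if kept else "dropped",
                reason=reason,
                pearson_r=float(r),
                p_value=float(p),
            )
        )
    return report


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others."""
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(features: pd.DataFrame, max_vif: float = 10.0) -> SelectionReport:
    """Iteratively remove the highest-VIF variable until all VIF <= ``max_vif``.

    Perfect collinearity shows up as an infinite VIF and is handled by
    removal.  The surviving records carry their final VIF values, so the
    post-condition ``max(vif) <= max_vif`` is assertable.
    """
    features = _check_features(features)
    if features.shape[1] < 2:
        raise ValueError("need at least 2 variables for a VIF filter")
    if len(features) <= features.shape[1]:
        raise ValueError("need n > p observations for a VIF filter")
    cols = list(features.columns)
    removed: list[tuple[str, float]] = []
    while len(cols) >= 2:
        vifs = _vif_values(features[cols].to_numpy(dtype=float))
        worst = int(np.argmax(vifs))
        if not (vifs[worst] > max_vif):
            break
        removed.append((str(cols[worst]), float(vifs[worst])))
        cols.pop(worst)
    final = dict(
        zip(cols, _vif_values(features[cols].to_numpy(dtype=float)))
        if len(cols) >= 2
        else [(cols[0], 1.0)]
    )
    report = SelectionReport(stage="vif")
    for name in features.columns:
        name = str(name)
        if name in final:
            report.records.append(
                VariableRecord(name, "kept", vif=float(final[name]))
            )
        else:
            v = dict(removed)[name]
            report.records.append(
                VariableRecord(
                    name, "dropped", reason=f"VIF {v:.2f} > {max_vif}", vif=v
                )
            )
    return report


def normality_assess(
    variables: pd.DataFrame,
    alpha: float = 0.05,
    transform: str = "auto",
) -> SelectionReport:
    """Omnibus skew/kurtosis normality assessment per variable.

    Uses the D'Agostino-Pearson test.  With ``transform="auto"`` a variable
    failing at ``alpha`` is refit with a one-parameter Yeo-Johnson power
    transform and retested; the fitted exponent is recorded so the same
    transform can be replayed on raster grids (:func:`apply_transforms`).
    All variables are kept; the report carries pass flags and transforms.
    """
    if transform not in ("auto", "none"):
        raise ValueError("transform must be 'auto' or 'none'")
    variables = _check_features(variables)
    if len(variables) < 20:
        raise ValueError("need at least 20 samples per variable")
    report = SelectionReport(stage="normality")
    for name in variables.columns:
        x = variables[name].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if np.ptp(x) == 0:
            raise ValueError(f"variable {name!r} is constant; normality untestable")
        stat, p = stats.normaltest(x)
        rec = VariableRecord(
            str(name),
            "kept",
            normality_stat=float(stat),
            normality_p=float(p),
            normality_pass=bool(p >= alpha),
        )
        if transform == "auto" and p < alpha:
            # Box-Cox for strictly positive data, Yeo-Johnson otherwise
            if x.min() > 0:
                xt, lmbda = stats.boxcox(x)
                rec.transform = "power-boxcox"
            else:
                xt, lmbda = stats.yeojohnson(x)
                rec.transform = "power"
            stat_t, p_t = stats.normaltest(xt)
            rec.transform_lmbda = float(lmbda)
            rec.normality_stat = float(stat_t)
            rec.normality_p = float(p_t)
            rec.normality_pass = bool(p_t >= alpha)
        report.records.append(rec)
    return report


def apply_transforms(report: SelectionReport, data):
    """Replay the power transforms recorded by :func:`normality_assess`.

    ``data`` may be a DataFrame (columns transformed in place on a copy) or a
    mapping of name -> ndarray grids.
    """
    lmbdas = {
        r.name: (r.transform, r.transform_lmbda)
        for r in report.records
        if r.transform.startswith("power") and r.transform_lmbda is not None
    }

    def _tf(values, kind, lm):
        values = np.asarray(values, dtype=float)
        if kind == "power-boxcox":
            return stats.boxcox(values, lm)
        return stats.yeojohnson(values, lm)

    if isinstance(data, pd.DataFrame):
        out = data.copy()
        for name, (kind, lm) in lmbdas.items():
            if name in out:
                out[name] = _tf(out[name].to_numpy(), kind, lm)
        return out
    out = dict(data)
    for name, (kind, lm) in lmbdas.items():
        if name in out:
            out[name] = _tf(out[name], kind, lm)
    return out


def export_histograms(variables: pd.DataFrame, outdir, bins: int = 30) -> list[str]:
    """Write one frequency-distribution histogram PNG per variable."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in variables.columns:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(variables[name].dropna(), bins=bins, color="#4c7a4c")
        ax.set_title(str(name))
        ax.set_ylabel("frequency")
        path = outdir / f"hist_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(str(path))
    return paths
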