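"""Footprint-scale canopy-closure regression.

Three base learners (k-nearest neighbors, random-forest regression, gradient
boosting regression trees) are tuned by Bayesian optimization — a Gaussian
process surrogate with a Matern-5/2 kernel and the expected-improvement
acquisition — against a leave-one-out cross-validation (LOOCV) objective,
scored with the four study metrics:

    R^2  = sum(yhat_i - ybar)^2 / sum(y_i - ybar)^2
    RMSE = sqrt(mean((y_i - yhat_i)^2))
    P    = (1 - RMSE / ybar) * 100          (percent prediction accuracy)
    MAR  = mean(|y_i - yhat_i|)             (mean absolute residual)

with ybar the mean of the observed values.  Note the R^2 form is a ratio of
explained to total sums of squares around the observed mean (it equals 1 for
a perfect predictor and can exceed 1 for an over-dispersed one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.neighbors import KNeighborsRegressor

__all__ = [
    "ratio_r2",
    "resid_r2",
    "rmse",
    "prediction_accuracy",
    "mean_absolute_residual",
    "EvalReport",
    "ModelSpec",
    "make_estimator",
    "default_params",
    "loocv_evaluate",
    "IntRange",
    "Categorical",
    "SearchSpace",
    "paper_scale_space",
    "desk_scale_space",
    "BOTrialHistory",
    "bo_minimize",
    "TrainResult",
    "train_and_select",
    "FittedFootprintModel",
    "predict_footprints",
]

MODEL_KINDS = ("knn", "rfr", "gbrt")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def ratio_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Explained-to-total sum-of-squares ratio around the observed mean."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ybar = y.mean()
    denom = np.sum((y - ybar) ** 2)
    if denom == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    return float(np.sum((yhat - ybar) ** 2) / denom)


def resid_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Conventional coefficient of determination, 1 - RSS/TSS.

    For a least-squares fit this coincides with :func:`ratio_r2` (the
    classical ESS/TSS decomposition); for out-of-fold machine-learning
    predictions the two diverge, and only this residual form falls when
    pure prediction noise is added.  Model comparisons therefore rank by
    this form; :func:`ratio_r2` is kept as the printed-formula metric.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / tss)


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def prediction_accuracy(y: np.ndarray, yhat: np.ndarray) -> float:
    """P = (1 - RMSE / ybar) * 100, in percent; NaN when ybar = 0."""
    ybar = float(np.mean(y))
    if ybar == 0:
        return math.nan
    return (1.0 - rmse(y, yhat) / ybar) * 100.0


def mean_absolute_residual(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(y, float) - np.asarray(yhat, float))))


@dataclass
class EvalReport:
    """LOOCV metric bundle with the per-fold predictions."""

    r2: float
    rmse: float
    p_accuracy: float
    mar: float
    predictions: np.ndarray
    y_mean: float
    r2_resid: float = float("nan")
    p_undefined: bool = False

    @classmethod
    def from_predictions(cls, y: np.ndarray, yhat: np.ndarray) -> "EvalReport":
        y = np.asarray(y, dtype=float)
        yhat = np.asarray(yhat, dtype=float)
        ybar = float(y.mean())
        return cls(
            r2=ratio_r2(y, yhat),
            rmse=rmse(y, yhat),
            p_accuracy=prediction_accuracy(y, yhat),
            mar=mean_absolute_residual(y, yhat),
            predictions=yhat,
            y_mean=ybar,
            r2_resid=resid_r2(y, yhat),
            p_undefined=(ybar == 0),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "r2_resid": self.r2_resid,
            "rmse": self.rmse,
            "p_accuracy": self.p_accuracy,
            "mar": self.mar,
        }


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A supported learner plus its hyperparameters."""

    kind: str
    params: tuple[tuple[str, object], ...] = ()

    @classmethod
    def of(cls, kind: str, params: dict | None = None) -> "ModelSpec":
        if kind not in MODEL_KINDS:
            raise ValueError(f"unsupported learner {kind!r}; choose from {MODEL_KINDS}")
        return cls(kind=kind, params=tuple(sorted((params or {}).items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def default_params(kind: str) -> dict:
    """scikit-learn default hyperparameters of each base learner."""
    return {
        "knn": {"n_neighbors": 5, "weights": "uniform"},
        "rfr": {
            "n_estimators": 100,
            "max_depth": None,
            "min_samples_split": 2,
            "min_samples_leaf": 1,
        },
        "gbrt": {
            "n_estimators": 100,
            "max_depth": 3,
            "min_samples_split": 2,
            "min_samples_leaf": 1,
        },
    }[kind]


def make_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a spec.

    The GBRT learning rate is fixed at 0.1 (it is not part of the tuned
    parameter set); tree learners are seeded for reproducibility.
    """
    params = spec.param_dict
    if spec.kind == "knn":
        return KNeighborsRegressor(**params)
    if spec.kind == "rfr":
        return RandomForestRegressor(random_state=seed, **params)
    if spec.kind == "gbrt":
        return GradientBoostingRegressor(random_state=seed, learning_rate=0.1, **params)
    raise ValueError(f"unsupported learner {spec.kind!r}")


def loocv_evaluate(
    model_spec: ModelSpec,
    features,
    target,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-out cross-validation of a learner.

    For each row i the learner is fit on the other n-1 rows and predicts
    row i; the four metrics are computed from the n out-of-fold predictions.

    ``model_spec`` may also be a zero-argument callable returning a fresh
    scikit-learn estimator (useful for probing the fold structure).
    """
    X = np.asarray(
        features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else features,
        dtype=float,
    )
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    yhat = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        est = (
            make_estimator(model_spec, seed=seed)
            if isinstance(model_spec, ModelSpec)
            else model_spec()
        )
        est.fit(X[train], y[train])
        yhat[i] = est.predict(X[i : i + 1])[0]
    return EvalReport.from_predictions(y, yhat)


# ---------------------------------------------------------------------------
# search spaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntRange:
    lo: int
    hi: int

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"integer bounds must satisfy lo <= hi, got {self}")


@dataclass(frozen=True)
class Categorical:
    values: tuple

    def __post_init__(self):
        if not self.values:
            raise ValueError("categorical domain must be non-empty")


#: A search space maps parameter names to domains for one learner.
SearchSpace = dict


def paper_scale_space(kind: str) -> SearchSpace:
    """Search domains sized for the full-budget (1,000-evaluation) study setting."""
    if kind == "knn":
        return {
            "n_neighbors": IntRange(2, 20),
            "weights": Categorical(("uniform", "distance")),
        }
    if kind in ("rfr", "gbrt"):
        return {
            "n_estimators": IntRange(50, 1000),
            "max_depth": IntRange(2, 20),
            "min_samples_split": IntRange(2, 20),
            "min_samples_leaf": IntRange(1, 10),
        }
    raise ValueError(f"unsupported learner {kind!r}")


def desk_scale_space(kind: str) -> SearchSpace:
    """Desk-scale search domains for ~50-plot training sets.

    With only a few dozen training rows, ensembles beyond ~100 trees and
    depths beyond ~8 change nothing but the runtime, so the tree domains are
    narrowed accordingly.
    """
    if kind == "knn":
        return {
            "n_neighbors": IntRange(2, 20),
            "weights": Categorical(("uniform", "distance")),
        }
    if kind in ("rfr", "gbrt"):
        return {
            "n_estimators": IntRange(10, 80),
            "max_depth": IntRange(2, 8),
            "min_samples_split": IntRange(2, 10),
            "min_samples_leaf": IntRange(1, 5),
        }
    raise ValueError(f"unsupported learner {kind!r}")


# ---------------------------------------------------------------------------
# Bayesian optimization
# ---------------------------------------------------------------------------

def _encode_dims(space: SearchSpace) -> list[tuple[str, object, int]]:
    """(name, domain, n_unit_dims) per parameter; categoricals use indicators."""
    dims = []
    for name, dom in space.items():
        if isinstance(dom, IntRange):
            dims.append((name, dom, 1))
        elif isinstance(dom, Categorical):
            dims.append((name, dom, len(dom.values)))
        else:
            raise TypeError(f"unsupported domain type for {name!r}: {type(dom)}")
    return dims


def _decode(u: np.ndarray, dims) -> dict:
    """Unit-cube point -> parameter dict (integers rounded, argmax category)."""
    params = {}
    k = 0
    for name, dom, nd in dims:
        if isinstance(dom, IntRange):
            val = int(dom.lo + round(float(u[k]) * (dom.hi - dom.lo)))
            params[name] = int(np.clip(val, dom.lo, dom.hi))
        else:
            params[name] = dom.values[int(np.argmax(u[k : k + nd]))]
        k += nd
    return params


def _encode(params: dict, dims) -> np.ndarray:
    u = []
    for name, dom, nd in dims:
        val = params[name]
        if isinstance(dom, IntRange):
            u.append(0.5 if dom.hi == dom.lo else (val - dom.lo) / (dom.hi - dom.lo))
        else:
            onehot = [0.0] * nd
            onehot[dom.values.index(val)] = 1.0
            u.extend(onehot)
    return np.array(u)


def _param_key(params: dict) -> tuple:
    return tuple(sorted(params.items()))


@dataclass
class BOTrialHistory:
    """Evaluated hyperparameter points, objective values and the incumbent."""

    params: list[dict] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    seed: int = 0
    n_init: int = 0
    n_iter: int = 0
    surrogate_kernel: str = ""

    @property
    def incumbent(self) -> tuple[dict, float]:
        i = int(np.argmin(self.values))
        return self.params[i], float(self.values[i])

    def trace(self) -> np.ndarray:
        """Running best (non-increasing) objective value."""
        return np.minimum.accumulate(np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params)
        df["objective"] = self.values
        df["best_so_far"] = self.trace()
        return df


def _expected_improvement(mu, sigma, best, xi=1e-4):
    sigma = np.clip(sigma, 1e-12, None)
    z = (best - mu - xi) / sigma
    return (best - mu - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bo_minimize(
    objective,
    space: SearchSpace,
    n_iter: int = 30,
    n_init: int = 10,
    seed: int = 0,
    initial_points: list[dict] | None = None,
) -> BOTrialHistory:
    """Minimize a black-box objective over a hyperparameter space.

    ``n_init`` seeded quasi-random (Latin hypercube) evaluations are followed
    by ``n_iter`` rounds of: fit a Gaussian-process surrogate (Matern-5/2,
    integer parameters by continuous relaxation and rounding, categoricals by
    indicator coding), maximize expected improvement over a seeded candidate
    set, evaluate the chosen point, and append it to the history.  Duplicate
    proposals are perturbed to a nearby unevaluated point.  A non-finite
    objective value is recorded as a worst-so-far penalty.  The total budget
    is exactly ``n_init + n_iter`` evaluations.

    ``initial_points`` (e.g. a learner's default configuration) are evaluated
    first and count toward ``n_init``.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if n_iter < 0:
        raise ValueError("the budget cannot be below n_init")
    dims = _encode_dims(space)
    d = sum(nd for _, _, nd in dims)
    rng = np.random.default_rng(seed)
    history = BOTrialHistory(
        seed=seed, n_init=n_init, n_iter=n_iter, surrogate_kernel="matern52"
    )
    seen: set[tuple] = set()
    worst = -np.inf

    def evaluate(params: dict) -> None:
        nonlocal worst
        y = objective(params)
        y = float(y) if np.isfinite(y) else math.nan
        if math.isnan(y):
            y = worst + abs(worst) if np.isfinite(worst) else 1e12
        worst = max(worst, y)
        history.params.append(params)
        history.values.append(y)
        seen.add(_param_key(params))

    def fresh(params: dict) -> dict:
        """Perturb a duplicate proposal to the nearest unevaluated point."""
        if _param_key(params) not in seen:
            return params
        for _ in range(200):
            cand = dict(params)
            name, dom, _ = dims[rng.integers(len(dims))]
            if isinstance(dom, IntRange):
                cand[name] = int(
                    np.clip(params[name] + rng.choice([-1, 1]), dom.lo, dom.hi)
                )
            else:
                cand[name] = dom.values[rng.integers(len(dom.values))]
            if _param_key(cand) not in seen:
                return cand
            params = cand
        return params  # space exhausted; re-evaluation is tolerated

    # -- initial design ----------------------------------------------------
    pending = list(initial_points or [])[:n_init]
    n_lhs = n_init - len(pending)
    if n_lhs > 0:
        lhs = qmc.LatinHypercube(d, seed=int(rng.integers(2**31)))
        pending.extend(_decode(u, dims) for u in lhs.random(n_lhs))
    for params in pending:
        evaluate(fresh(params))

    # -- surrogate loop ----------------------------------------------------
    kernel = ConstantKernel(1.0) * Matern(
        length_scale=np.full(d, 0.3), nu=2.5
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-9, 1e-1))
    for _ in range(n_iter):
        U = np.array([_encode(p, dims) for p in history.params])
        yv = np.asarray(history.values, dtype=float)
        yz = (yv - yv.mean()) / (yv.std() + 1e-12)
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=False,
            alpha=1e-8,
            n_restarts_optimizer=0,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(U, yz)
        cand = rng.random((256, d))
        # local refinements around the incumbent
        inc = U[np.argmin(yv)]
        local = np.clip(inc + 0.1 * rng.standard_normal((64, d)), 0.0, 1.0)
        cand = np.vstack([cand, local])
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, yz.min())
        params = fresh(_decode(cand[int(np.argmax(ei))], dims))
        evaluate(params)
    return history


# ---------------------------------------------------------------------------
# training and selection
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    """Outcome of per-learner tuning and comparison."""

    best_kind: str
    best_spec: ModelSpec
    model: "FittedFootprintModel"
    reports: dict[str, EvalReport]
    baseline_reports: dict[str, EvalReport]
    histories: dict[str, BOTrialHistory]
    comparison: pd.DataFrame


@dataclass
class FittedFootprintModel:
    """A fitted learner bound to the feature columns it was trained on."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        pred = self.estimator.predict(table[self.feature_names].to_numpy(dtype=float))
        return np.clip(pred, 0.0, 1.0)


def train_and_select(
    features: pd.DataFrame,
    target,
    spaces: dict[str, SearchSpace] | None = None,
    budget: int = 50,
    n_init: int = 10,
    seed: int = 0,
    kinds: tuple[str, ...] = MODEL_KINDS,
) -> TrainResult:
    """Tune every enabled learner by Bayesian optimization and pick a winner.

    The BO objective is the LOOCV RMSE.  Each learner's default
    configuration seeds the initial design, and an untuned default baseline
    is evaluated alongside.  The winner is the tuned learner with the highest
    LOOCV R^2 (ties broken by lower RMSE, then lower MAR); it is refit on the
    full training table.  ``comparison`` tabulates un-optimized and optimized
    R^2 / RMSE / P / MAR per learner.
    """
    if not kinds:
        raise ValueError("at least one learner kind must be enabled")
    features = pd.DataFrame(features)
    y = np.asarray(target, dtype=float)
    spaces = spaces or {k: desk_scale_space(k) for k in kinds}
    n_init = min(n_init, budget)  # small budgets are spent on the design
    n_iter = budget - n_init

    reports: dict[str, EvalReport] = {}
    baselines: dict[str, EvalReport] = {}
    histories: dict[str, BOTrialHistory] = {}
    best_specs: dict[str, ModelSpec] = {}
    rows = []
    for kind in kinds:
        base_spec = ModelSpec.of(kind, default_params(kind))
        baselines[kind] = loocv_evaluate(base_spec, features, y, seed=seed)

        def objective(params, _kind=kind):
            rep = loocv_evaluate(ModelSpec.of(_kind, params), features, y, seed=seed)
            return rep.rmse

        init = [
            {k: v for k, v in default_params(kind).items() if k in spaces[kind]}
        ]
        # defaults outside the search domain are clipped into it
        for name, dom in spaces[kind].items():
            if isinstance(dom, IntRange):
                val = init[0].get(name, dom.lo)
                init[0][name] = int(np.clip(val if val is not None else dom.hi,
                                            dom.lo, dom.hi))
            elif init[0].get(name) not in dom.values:
                init[0][name] = dom.values[0]
        histories[kind] = bo_minimize(
            objective,
            spaces[kind],
            n_iter=n_iter,
            n_init=n_init,
            seed=seed,
            initial_points=init,
        )
        tuned_params, _ = histories[kind].incumbent
        best_specs[kind] = ModelSpec.of(kind, tuned_params)
        reports[kind] = loocv_evaluate(best_specs[kind], features, y, seed=seed)
        for label, rep in (("un-optimized", baselines[kind]), ("optimized", reports[kind])):
            rows.append(
                {
                    "stage": label,
                    "model": kind.upper() if label == "un-optimized" else f"BO-{kind.upper()}",
                    "r2": rep.r2,
                    "r2_resid": rep.r2_resid,
                    "rmse": rep.rmse,
                    "p_accuracy": rep.p_accuracy,
                    "mar": rep.mar,
                }
            )

    winner = max(
        kinds, key=lambda k: (reports[k].r2_resid, -reports[k].rmse, -reports[k].mar)
    )
    est = make_estimator(best_specs[winner], seed=seed)
    est.fit(features.to_numpy(dtype=float), y)
    model = FittedFootprintModel(
        spec=best_specs[winner],
        estimator=est,
        feature_names=[str(c) for c in features.columns],
    )
    return TrainResult(
        best_kind=winner,
        best_spec=best_specs[winner],
        model=model,
        reports=reports,
        baseline_reports=baselines,
        histories=histories,
        comparison=pd.DataFrame(rows),
    )


def predict_footprints(
    model: FittedFootprintModel, table: pd.DataFrame
) -> pd.DataFrame:
    """Predict FCC for every footprint; predictions are clamped to [0, 1].

    Returns a copy of the table with a ``predicted_fcc`` column.
    """
    out = table.copy()
    out["predicted_fcc"] = model.predict(table)
    return out
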