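"""Seeded synthetic scenes, LiDAR-style footprint tables and field-plot samples.

The generator emulates the data a footprint-to-region canopy-closure study
works with: a stack of co-registered raster grids (optical reflectance bands,
VV/VH radar backscatter in dB, a DEM), a spatially-varying-coefficient (SVC)
surface that defines the true forest canopy closure (FCC), strip-sampled
laser footprints carrying ATL08-style segment features, and a small set of
field plots whose measured-FCC marginal matches the survey statistics
(n = 54, range 0.20-0.83, mean 0.50, SD 0.176).

True FCC is a clamped linear SVC model of standardized latent covariate
fields, so a geographically weighted regression is the correct estimator and
parameter recovery against the stored coefficient surfaces is well defined::

    fcc(u, v) = clip01( a0(u,v) + sum_k a_k(u,v) * z_k(u,v) + eps )

All randomness flows from ``SceneConfig.seed`` through a fixed
``numpy.random.SeedSequence`` splitting scheme, so identical configurations
yield bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SceneConfig",
    "RegionalScene",
    "generate_scene",
    "make_footprint_features",
    "sample_plots",
    "beta_shapes_from_moments",
    "INFORMATIVE_FEATURES",
]

#: The six informative ATL08-style segment features, in importance order.
INFORMATIVE_FEATURES = (
    "landsat_perc",
    "toc_roughness",
    "h_min_canopy",
    "h_dif_canopy",
    "n_toc_photons",
    "asr",
)

# Child-stream indices of the SeedSequence splitting scheme.  New consumers
# must append, never renumber, so that existing outputs stay reproducible.
_STREAM_COEF = 0
_STREAM_FIELDS = 1
_STREAM_BANDS = 2
_STREAM_FCC = 3
_STREAM_FOOTPRINT = 4
_STREAM_PLOTS = 5


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of a synthetic study scene.

    Parameters
    ----------
    grid_rows, grid_cols:
        Raster lattice size; at least 32 x 32 so a 5 x 5 texture window fits
        comfortably.
    cell_size:
        Raster cell edge, meters.
    seed:
        Master seed; every random stream is derived from it.
    coef_smoothness:
        Spatial wavelength (meters) of the coefficient surfaces and latent
        covariate fields.
    fcc_noise_sd:
        SD of the additive noise on the true-FCC surface.
    plot_noise_sd:
        SD of the plot measurement noise applied before rank-matching.
    feature_noise_scale:
        Multiplier on the built-in noise of every footprint feature; 0 gives
        exact deterministic feature links.
    n_footprint_tracks:
        Number of parallel north-south sampling strips.
    along_track_spacing:
        Footprint spacing along a strip, meters (segment length of the
        along-track aggregation).
    n_distractors:
        Number of uninformative footprint features added to the table.
    plot_n:
        Number of field plots.
    plot_beta_params:
        Shape parameters of the Beta law used to rank-match the plot
        marginal.  The default (1.374, 1.561) is solved so that, after
        truncation to ``plot_bounds``, the marginal has mean 0.50 and
        SD 0.176.
    plot_bounds:
        Truncation interval of the plot marginal, within [0, 1].
    truncate_plots:
        Disable to rank-match against the untruncated Beta law.
    epsg:
        Nominal projected CRS code recorded in raster metadata (UTM zone
        47N by default); coordinates are plain projected meters.
    """

    grid_rows: int = 128
    grid_cols: int = 128
    cell_size: float = 30.0
    seed: int = 20210
    coef_smoothness: float = 4000.0
    fcc_noise_sd: float = 0.05
    plot_noise_sd: float = 0.05
    feature_noise_scale: float = 1.0
    n_footprint_tracks: int = 8
    along_track_spacing: float = 100.0
    n_distractors: int = 44
    plot_n: int = 54
    plot_beta_params: tuple[float, float] = (1.374, 1.561)
    plot_bounds: tuple[float, float] = (0.20, 0.83)
    truncate_plots: bool = True
    epsg: int = 32647

    def __post_init__(self) -> None:
        if self.grid_rows < 32 or self.grid_cols < 32:
            raise ValueError(
                "grid must be at least 32 x 32 to support 5 x 5 texture windows"
            )
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.coef_smoothness <= 0:
            raise ValueError("coef_smoothness must be positive")
        for name in ("fcc_noise_sd", "plot_noise_sd", "feature_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_footprint_tracks < 1:
            raise ValueError("n_footprint_tracks must be a positive integer")
        if self.along_track_spacing <= 0:
            raise ValueError("along_track_spacing must be positive")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be nonnegative")
        if self.plot_n < 1:
            raise ValueError("plot_n must be a positive integer")
        a, b = self.plot_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("plot_beta_params must be positive")
        lo, hi = self.plot_bounds
        if not (0 <= lo < hi <= 1):
            raise ValueError("plot_bounds must satisfy 0 <= lo < hi <= 1")

    def with_(self, **kwargs) -> "SceneConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def width(self) -> float:
        return self.grid_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.grid_rows * self.cell_size


@dataclass
class RegionalScene:
    """Co-registered raster grids of a synthetic scene (north-up lattice).

    ``coef`` holds the true spatially varying coefficient surfaces
    (``intercept`` plus one per latent covariate); ``covariates`` holds the
    standardized latent fields ``z_k`` that enter the SVC model.  Band and
    terrain grids are derived from those latents so that vegetation indices
    computed from the bands correlate positively with ``true_fcc``.
    """

    config: SceneConfig
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    b8a: np.ndarray
    vv: np.ndarray
    vh: np.ndarray
    dem: np.ndarray
    coef: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray]
    true_fcc: np.ndarray
    mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.true_fcc.shape

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    def grids(self) -> dict[str, np.ndarray]:
        """All named grids, bands first (for raster export)."""
        out = {
            "green": self.green,
            "red": self.red,
            "nir": self.nir,
            "b8a": self.b8a,
            "vv": self.vv,
            "vh": self.vh,
            "dem": self.dem,
            "true_fcc": self.true_fcc,
        }
        out.update({f"coef_{k}": v for k, v in self.coef.items()})
        out.update({f"z_{k}": v for k, v in self.covariates.items()})
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate grids, meters; row 0 is the north edge."""
        rows, cols = self.shape
        cs = self.cell_size
        x = (np.arange(cols) + 0.5) * cs
        y = (rows - np.arange(rows) - 0.5) * cs
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest (row, col) cell indices of projected coordinates."""
        rows, cols = self.shape
        cs = self.cell_size
        col = np.clip((np.asarray(x) / cs).astype(int), 0, cols - 1)
        row = np.clip((rows - np.asarray(y) / cs).astype(int), 0, rows - 1)
        return row, col

    def sample(self, grid: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values of ``grid`` at projected coordinates."""
        row, col = self.index_of(x, y)
        return grid[row, col]


def beta_shapes_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Beta shape parameters matching a given (untruncated) mean and variance.

    Solves the moment equations ``alpha = mean * nu``, ``beta = (1-mean) * nu``
    with ``nu = mean (1 - mean) / variance - 1``.  For the survey marginal
    (mean 0.50, variance 0.030976) this gives alpha = beta ~= 3.535.
    """
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    nu = mean * (1 - mean) / variance - 1
    if nu <= 0:
        raise ValueError("variance too large for a Beta law with this mean")
    return mean * nu, (1 - mean) * nu


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    wavelength: float,
    cell_size: float,
) -> np.ndarray:
    """Standardized smooth Gaussian random field (unit variance, zero mean)."""
    sigma = max(wavelength / cell_size / 4.0, 0.6)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _harmonic(u, v, wavelength, terms: Sequence[tuple[float, float, float, float]]):
    """Low-order deterministic harmonic surface sum(c * sin/cos mixtures)."""
    w = 2 * np.pi / wavelength
    out = np.zeros_like(u)
    for c, fu, fv, phase in terms:
        out = out + c * np.sin(w * (fu * u + fv * v) + phase)
    return out


def generate_scene(config: SceneConfig) -> RegionalScene:
    """Generate a seeded synthetic scene with an SVC canopy-closure surface.

    The true-FCC surface is ``clip01(a0 + sum_k a_k z_k + eps)`` with smooth
    coefficient surfaces ``a_k`` (deterministic low-order harmonics plus a
    small seeded smooth field) and standardized latent covariates ``z_k``
    (``veg``, ``radar``, ``bright``).  Bands are constructed so the
    NDVI/GNDVI implied by them is monotone in ``z_veg``, the VV-VH backscatter
    difference decreases in ``z_radar``, and the B8A reflectance follows
    ``z_bright``; vegetation indices therefore correlate positively with FCC.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(6)
    rng_coef = np.random.default_rng(children[_STREAM_COEF])
    rng_fields = np.random.default_rng(children[_STREAM_FIELDS])
    rng_bands = np.random.default_rng(children[_STREAM_BANDS])
    rng_fcc = np.random.default_rng(children[_STREAM_FCC])

    shape = (cfg.grid_rows, cfg.grid_cols)
    L = cfg.coef_smoothness
    cs = cfg.cell_size
    u, v = np.meshgrid(
        (np.arange(cfg.grid_cols) + 0.5) * cs,
        (cfg.grid_rows - np.arange(cfg.grid_rows) - 0.5) * cs,
    )

    # Latent standardized covariate fields.  They vary on a much finer scale
    # than the coefficient surfaces (wavelength L/8 plus a white component):
    # local design variation is what makes the spatially varying coefficients
    # identifiable by a kernel-local regression.
    def _covariate_field() -> np.ndarray:
        f = 0.85 * _smooth_field(rng_fields, shape, L / 8, cs)
        f += 0.5 * rng_fields.standard_normal(shape)
        return (f - f.mean()) / f.std()

    z = {
        "veg": _covariate_field(),
        "radar": _covariate_field(),
        "bright": _covariate_field(),
    }

    # True coefficient surfaces: harmonics plus a small seeded smooth field.
    coef = {
        "intercept": 0.50
        + _harmonic(u, v, L, [(0.05, 1, 0, 0.0), (0.04, 0, 1, 1.1)])
        + 0.01 * _smooth_field(rng_coef, shape, L, cs),
        "veg": 0.13
        + _harmonic(u, v, L, [(0.05, 0, 1, 0.4), (0.04, 0.5, 0.5, 2.0)])
        + 0.008 * _smooth_field(rng_coef, shape, L, cs),
        "radar": 0.08
        + _harmonic(u, v, L, [(0.045, 1, 0, 2.2), (0.035, 0.5, -0.5, 0.7)])
        + 0.006 * _smooth_field(rng_coef, shape, L, cs),
        "bright": 0.06
        + _harmonic(u, v, L, [(0.04, 0.5, 0.5, 1.6), (0.025, 1, 0, 0.9)])
        + 0.005 * _smooth_field(rng_coef, shape, L, cs),
    }

    eps = (
        rng_fcc.standard_normal(shape) * cfg.fcc_noise_sd
        if cfg.fcc_noise_sd > 0
        else 0.0
    )
    linear = coef["intercept"].copy()
    for k in ("veg", "radar", "bright"):
        linear += coef[k] * z[k]
    true_fcc = np.clip(linear + eps, 0.0, 1.0)

    # Bands realizing the latents.  NDVI/GNDVI targets are monotone in z_veg
    # with small independent detail so the two indices are not collinear.
    ndvi_t = np.clip(0.45 + 0.18 * z["veg"], -0.95, 0.95)
    gndvi_t = np.clip(
        0.40 + 0.16 * z["veg"] + 0.06 * _smooth_field(rng_bands, shape, L / 2, cs),
        -0.95,
        0.95,
    )
    tot = 0.55 + 0.02 * _smooth_field(rng_bands, shape, L / 2, cs)
    nir = np.clip(tot * (1 + ndvi_t) / 2, 1e-4, 1.0)
    red = np.clip(tot * (1 - ndvi_t) / 2, 1e-4, 1.0)
    green = np.clip(nir * (1 - gndvi_t) / (1 + gndvi_t), 1e-4, 1.0)
    b8a = np.clip(
        0.30 + 0.05 * z["bright"] + 0.01 * _smooth_field(rng_bands, shape, L / 4, cs),
        1e-4,
        1.0,
    )
    vv = -8.0 + 1.0 * _smooth_field(rng_bands, shape, L / 2, cs)
    vh = vv - (6.0 - 1.5 * z["radar"])  # VV-VH falls as z_radar (and FCC) rise
    dem = 3200.0 + 400.0 * _smooth_field(rng_bands, shape, 2 * L, cs)

    return RegionalScene(
        config=cfg,
        green=green,
        red=red,
        nir=nir,
        b8a=b8a,
        vv=vv,
        vh=vh,
        dem=dem,
        coef=coef,
        covariates=z,
        true_fcc=true_fcc,
        mask=np.ones(shape, dtype=bool),
    )


def _footprint_positions(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Footprint centers on parallel north-south strips."""
    track_x = (np.arange(cfg.n_footprint_tracks) + 0.5) * (
        cfg.width / cfg.n_footprint_tracks
    )
    n_along = int(cfg.height // cfg.along_track_spacing)
    if n_along < 1:
        raise ValueError("scene too small for the along-track spacing")
    along_y = (np.arange(n_along) + 0.5) * cfg.along_track_spacing
    xx, yy = np.meshgrid(track_x, along_y, indexing="ij")
    return xx.ravel(), yy.ravel()


def make_footprint_features(
    scene: RegionalScene, config: SceneConfig | None = None
) -> pd.DataFrame:
    """Build the footprint feature table for a scene.

    Footprints sit on ``n_footprint_tracks`` parallel strips sampled every
    ``along_track_spacing`` meters.  The six informative features are stated
    monotone transforms of the local true FCC plus seeded noise
    (``landsat_perc = 100 * FCC + noise`` exactly at zero noise); the
    ``n_distractors`` remaining columns are pure noise, every third one a
    spatially autocorrelated field so that chance spatial correlation with
    FCC is represented.

    Returns a DataFrame with columns
    ``id, x, y, <6 informative>, <distractors...>, true_fcc``.
    """
    cfg = config or scene.config
    if cfg.n_footprint_tracks < 1:
        raise ValueError("n_footprint_tracks must be a positive integer")
    x, y = _footprint_positions(cfg)
    fcc = scene.sample(scene.true_fcc, x, y)
    n = x.size
    s = cfg.feature_noise_scale
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(6)[_STREAM_FOOTPRINT]
    )

    def noise(sd: float) -> np.ndarray:
        return rng.standard_normal(n) * sd * s if s > 0 else np.zeros(n)

    feats = {
        # percent cover product, direct analogue of FCC
        "landsat_perc": np.clip(100.0 * fcc + noise(14.0), 0.0, 100.0),
        # canopy-top height spread grows with closure (meters)
        "toc_roughness": np.clip(0.8 + 4.0 * fcc + noise(1.1), 0.0, None),
        # weakly coupled: minimum relative canopy height (meters)
        "h_min_canopy": 2.0 + 2.5 * fcc + noise(1.2),
        # h_canopy - h_median_canopy (meters)
        "h_dif_canopy": np.clip(0.5 + 3.0 * fcc + noise(1.1), 0.0, None),
        # apparent surface reflectance, weakly coupled
        "asr": np.clip(0.18 + 0.22 * fcc + noise(0.07), 0.0, 1.0),
    }
    # overdispersed photon counts: Poisson alone would be unrealistically
    # informative at these rates
    rate = (15.0 + 120.0 * fcc) * np.exp(noise(0.35))
    feats["n_toc_photons"] = (
        rng.poisson(rate) if s > 0 else np.rint(rate).astype(np.int64)
    )
    feats["n_toc_photons"] = feats["n_toc_photons"].astype(np.int64)
    # keep canonical ordering
    feats = {k: feats[k] for k in INFORMATIVE_FEATURES}

    # Distractors: iid noise, every third one spatially autocorrelated.
    for j in range(cfg.n_distractors):
        name = f"noise_{j + 1:02d}"
        if j % 3 == 0:
            fld = _smooth_field(
                rng, scene.shape, cfg.coef_smoothness / 8.0, cfg.cell_size
            )
            feats[name] = scene.sample(fld, x, y) + 0.2 * rng.standard_normal(n)
        else:
            feats[name] = rng.standard_normal(n)

    table = pd.DataFrame({"id": np.arange(n), "x": x, "y": y, **feats})
    table["true_fcc"] = fcc
    return table


def sample_plots(
    scene: RegionalScene,
    config: SceneConfig | None = None,
    footprints: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw field plots co-located with footprints.

    ``plot_n`` footprint positions are drawn without replacement; measured
    FCC is the local true FCC plus Gaussian noise, then rank-matched to a
    (truncated) Beta marginal so the sample reproduces the survey statistics
    while preserving the spatial association with the scene.

    Returns a DataFrame ``id, x, y, fcc_measured`` plus the source
    ``footprint_id`` and synthetic ``fcc_true`` columns.
    """
    cfg = config or scene.config
    if footprints is None:
        footprints = make_footprint_features(scene, cfg)
    if cfg.plot_n > len(footprints):
        raise ValueError(
            f"plot_n={cfg.plot_n} exceeds the {len(footprints)} available footprints"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(6)[_STREAM_PLOTS]
    )
    idx = np.sort(rng.choice(len(footprints), size=cfg.plot_n, replace=False))
    sub = footprints.iloc[idx]
    raw = sub["true_fcc"].to_numpy() + (
        rng.standard_normal(cfg.plot_n) * cfg.plot_noise_sd
        if cfg.plot_noise_sd > 0
        else 0.0
    )

    # Rank-match to the target marginal: sorted values are replaced by the
    # (truncated) Beta quantiles at plotting positions.
    a, b = cfg.plot_beta_params
    law = stats.beta(a, b)
    ranks = stats.rankdata(raw, method="ordinal") - 1
    pp = (ranks + 0.5) / cfg.plot_n
    if cfg.truncate_plots:
        lo, hi = cfg.plot_bounds
        flo, fhi = law.cdf(lo), law.cdf(hi)
        measured = law.ppf(flo + (fhi - flo) * pp)
    else:
        measured = law.ppf(pp)

    return pd.DataFrame(
        {
            "id": np.arange(cfg.plot_n),
            "x": sub["x"].to_numpy(),
            "y": sub["y"].to_numpy(),
            "fcc_measured": measured,
            "footprint_id": sub["id"].to_numpy(),
            "fcc_true": sub["true_fcc"].to_numpy(),
        }
    )
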