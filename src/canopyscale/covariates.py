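"""Regional predictor derivation: vegetation indices, SAR transforms,
windowed GLCM textures, and terrain derivatives.

Covariate grids follow the ``<SOURCE>_<FEATURE>`` naming convention used for
Sentinel-2 texture features (e.g. ``B3_HO``, ``B8_SM``, ``B8A_CR``), with the
band aliases B3 = green, B4 = red, B8 = NIR, B8A = narrow NIR.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MissingBandError",
    "compute_indices",
    "sar_transforms",
    "glcm_features",
    "cooccurrence_matrix",
    "haralick_from_matrix",
    "terrain_derivatives",
    "regional_covariates",
    "TEXTURE_NAMES",
    "GLCM_OFFSETS",
]

#: Haralick feature short names, in the conventional order.
TEXTURE_NAMES = ("ME", "VA", "HO", "CO", "DI", "EN", "SM", "CR")

#: The four standard co-occurrence directions (0, 45, 90, 135 degrees) as
#: unit (drow, dcol) steps on a north-up raster.
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_BAND_ALIAS = {"green": "B3", "red": "B4", "nir": "B8", "b8a": "B8A"}


class MissingBandError(KeyError):
    """A required spectral band is absent from the input mapping."""


def _band(bands: Mapping[str, np.ndarray], name: str) -> np.ndarray:
    if name not in bands:
        raise MissingBandError(name)
    return np.asarray(bands[name], dtype=float)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise ratio with NaN (nodata) where the denominator vanishes."""
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


# Standard index definitions.  EVI needs a blue band; EVI2 is its blue-free
# two-band variant.  IDVI has no standard definition in the literature and is
# implemented as the 1 + NDVI placeholder (see docs/methods.md); MASVI is an
# alias of MSAVI.
def compute_indices(
    bands: Mapping[str, np.ndarray], which: Iterable[str] | None = None
) -> dict[str, np.ndarray]:
    """Vegetation indices from reflectance grids.

    ``bands`` maps names (``green``, ``red``, ``nir``, optionally ``blue``)
    to reflectance grids in [0, 1].  ``which`` restricts the output; by
    default every index computable from the provided bands is returned.
    Zero denominators produce NaN, never exceptions; a missing band needed
    by an explicitly requested index raises :class:`MissingBandError`.
    """
    defs = {
        "NDVI": (("nir", "red"), lambda n, r: _safe_ratio(n - r, n + r)),
        "GNDVI": (("nir", "green"), lambda n, g: _safe_ratio(n - g, n + g)),
        "DVI": (("nir", "red"), lambda n, r: n - r),
        "SAVI": (("nir", "red"), lambda n, r: 1.5 * _safe_ratio(n - r, n + r + 0.5)),
        "OSAVI": (("nir", "red"), lambda n, r: _safe_ratio(n - r, n + r + 0.16)),
        "EVI": (
            ("nir", "red", "blue"),
            lambda n, r, b: 2.5 * _safe_ratio(n - r, n + 6 * r - 7.5 * b + 1),
        ),
        "EVI2": (
            ("nir", "red"),
            lambda n, r: 2.5 * _safe_ratio(n - r, n + 2.4 * r + 1),
        ),
        "RVI": (("nir", "red"), lambda n, r: _safe_ratio(n, r)),
        "MSAVI": (
            ("nir", "red"),
            lambda n, r: (2 * n + 1 - np.sqrt((2 * n + 1) ** 2 - 8 * (n - r))) / 2,
        ),
        "GRVI": (("green", "red"), lambda g, r: _safe_ratio(g - r, g + r)),
        "RDVI": (
            ("nir", "red"),
            lambda n, r: _safe_ratio(n - r, np.sqrt(np.clip(n + r, 0, None))),
        ),
        "IDVI": (("nir", "red"), lambda n, r: 1 + _safe_ratio(n - r, n + r)),
    }
    defs["MASVI"] = defs["MSAVI"]
    names = list(which) if which is not None else None
    out: dict[str, np.ndarray] = {}
    for name, (req, fn) in defs.items():
        if names is not None and name not in names:
            continue
        if names is None and any(b not in bands for b in req):
            continue
        out[name] = fn(*(_band(bands, b) for b in req))
    if names is not None:
        unknown = set(names) - set(defs)
        if unknown:
            raise KeyError(f"unknown indices: {sorted(unknown)}")
    return out


def sar_transforms(vv_db: np.ndarray, vh_db: np.ndarray) -> dict[str, np.ndarray]:
    """Backscatter difference (dB) and linear power ratio of VV and VH.

    ``VV_minus_VH = vv - vh`` in dB; ``VV_over_VH = 10**((vv - vh)/10)`` is
    the equivalent ratio of linear powers.
    """
    vv = np.asarray(vv_db, dtype=float)
    vh = np.asarray(vh_db, dtype=float)
    if vv.shape != vh.shape:
        raise ValueError(f"shape mismatch: {vv.shape} vs {vh.shape}")
    diff = vv - vh
    return {"VV_minus_VH": diff, "VV_over_VH": 10.0 ** (diff / 10.0)}


def _quantize_minmax(win: np.ndarray, levels: int) -> np.ndarray:
    """Per-window min-max quantization to ``levels`` integer bins."""
    mn = win.min(axis=(-2, -1), keepdims=True)
    mx = win.max(axis=(-2, -1), keepdims=True)
    span = mx - mn
    span[span == 0] = 1.0  # constant windows map to level 0
    q = np.floor((win - mn) / span * levels)
    return np.clip(q, 0, levels - 1).astype(np.int16)


def cooccurrence_matrix(
    patch: np.ndarray,
    levels: int = 64,
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS,
    step: int = 1,
    quantize: bool = True,
) -> np.ndarray:
    """Symmetric normalized gray-level co-occurrence matrix of one window.

    The patch is min-max quantized to ``levels`` bins (unless ``quantize`` is
    False and it already holds integer levels), pairs are accumulated over
    the given offsets at distance ``step`` in both directions, and the matrix
    is normalized to sum to 1.
    """
    patch = np.asarray(patch, dtype=float)
    q = (
        _quantize_minmax(patch[None, None], levels)[0, 0]
        if quantize
        else patch.astype(np.int64)
    )
    P = np.zeros((levels, levels), dtype=float)
    h, w = q.shape
    for dr, dc in offsets:
        dr, dc = dr * step, dc * step
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    total = P.sum()
    if total > 0:
        P /= total
    return P


def haralick_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The eight texture features of a normalized co-occurrence matrix.

    Mean and variance are the marginal moments of the (symmetric) matrix;
    entropy uses the natural logarithm; correlation of a degenerate
    (zero-variance) matrix is NaN.
    """
    levels = P.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    mean = float((P * i).sum())
    var = float((P * (i - mean) ** 2).sum())
    nz = P > 0
    feats = {
        "ME": mean,
        "VA": var,
        "HO": float((P / (1.0 + (i - j) ** 2)).sum()),
        "CO": float((P * (i - j) ** 2).sum()),
        "DI": float((P * np.abs(i - j)).sum()),
        "EN": float(-(P[nz] * np.log(P[nz])).sum()),
        "SM": float((P**2).sum()),
    }
    feats["CR"] = (
        float((P * (i - mean) * (j - mean)).sum() / var) if var > 0 else math.nan
    )
    return feats


def glcm_features(
    band: np.ndarray,
    window: int = 5,
    step: int = 1,
    levels: int = 64,
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS,
) -> dict[str, np.ndarray]:
    """Per-pixel Haralick texture grids from a moving-window GLCM.

    For every pixel, the surrounding ``window x window`` neighborhood
    (mirror-padded at edges) is min-max quantized to ``levels`` gray bins and
    a symmetric normalized co-occurrence matrix is accumulated over the
    configured ``offsets`` at distance ``step``; the eight standard features
    (mean, variance, homogeneity, contrast, dissimilarity, entropy, angular
    second moment, correlation) are emitted as grids.

    The implementation never materializes per-pixel matrices: features are
    direct statistics of the per-window pair lists, with duplicate pair
    counting (for entropy and ASM) done by sorting pair codes.  A constant
    window yields the closed-form extremes CO = DI = EN = 0, SM = HO = 1 and
    NaN correlation.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if step < 1 or step >= window:
        raise ValueError("step must satisfy 1 <= step < window")
    band = np.asarray(band, dtype=float)
    if band.ndim != 2 or min(band.shape) < window:
        raise ValueError("band must be 2-D and at least window-sized")

    half = window // 2
    padded = np.pad(band, half, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    q = _quantize_minmax(win, levels)  # (H, W, window, window)
    H, W = band.shape

    codes = []
    for dr, dc in offsets:
        dr, dc = dr * step, dc * step
        r0, r1 = max(0, -dr), min(window, window - dr)
        c0, c1 = max(0, -dc), min(window, window - dc)
        a = q[:, :, r0:r1, c0:c1].reshape(H, W, -1).astype(np.int32)
        b = (
            q[:, :, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            .reshape(H, W, -1)
            .astype(np.int32)
        )
        codes.append(a * levels + b)
        codes.append(b * levels + a)  # symmetric counterpart
    code = np.concatenate(codes, axis=-1)  # (H, W, M)
    M = code.shape[-1]
    ival = code // levels
    jval = code % levels

    mean = ival.mean(axis=-1, dtype=float)
    dev_i = ival - mean[..., None]
    dev_j = jval - mean[..., None]
    var = np.mean(dev_i**2, axis=-1)
    d = np.abs(ival - jval)
    feats = {
        "ME": mean,
        "VA": var,
        "HO": np.mean(1.0 / (1.0 + d.astype(float) ** 2), axis=-1),
        "CO": np.mean(d.astype(float) ** 2, axis=-1),
        "DI": d.mean(axis=-1, dtype=float),
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        feats["CR"] = np.where(var > 0, np.mean(dev_i * dev_j, axis=-1) / var, np.nan)

    # Entropy and ASM need probabilities of distinct pairs: sort codes per
    # pixel and aggregate run lengths.
    srt = np.sort(code, axis=-1)
    starts = np.ones(srt.shape, dtype=bool)
    starts[..., 1:] = srt[..., 1:] != srt[..., :-1]
    run_id = np.cumsum(starts, axis=-1) - 1  # (H, W, M), values < M
    counts = np.zeros((H * W, M), dtype=np.int32)
    pix = np.repeat(np.arange(H * W), M)
    np.add.at(counts, (pix, run_id.reshape(-1)), 1)
    p = counts / float(M)
    feats["SM"] = (p**2).sum(axis=-1).reshape(H, W)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    feats["EN"] = np.clip(-plogp.sum(axis=-1), 0.0, None).reshape(H, W)
    return {k: feats[k] for k in TEXTURE_NAMES}


def terrain_derivatives(dem: np.ndarray, cell_size: float) -> dict[str, np.ndarray]:
    """Slope, aspect and elevation from a DEM via Horn's 3x3 method.

    Slope is in degrees; aspect is the compass bearing of the downslope
    direction in degrees (0 = north, 90 = east), with flat cells set to the
    sentinel -1; elevation is the DEM passthrough.  Edges are mirror-padded.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < 3:
        raise ValueError("DEM must be 2-D and at least 3 x 3")
    z = np.pad(dem, 1, mode="reflect")
    # 3x3 neighborhood (row 0 = north): a b c / d e f / g h i
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)  # y grows north
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0  # bearing of -grad
    aspect = np.where(grad < 1e-12, -1.0, aspect)
    return {"slope": slope, "aspect": aspect, "elevation": dem.copy()}


def regional_covariates(
    scene,
    texture_bands: tuple[str, ...] = ("green", "nir", "b8a"),
    window: int = 5,
    step: int = 1,
    levels: int = 64,
) -> dict[str, np.ndarray]:
    """The full regional predictor stack for a scene.

    Combines vegetation indices, single-band reflectances, SAR transforms,
    per-band GLCM texture grids (5x5 window, step 1, 64 gray levels by
    default) and terrain derivatives, named by the ``<SOURCE>_<FEATURE>``
    convention.
    """
    bands = {"green": scene.green, "red": scene.red, "nir": scene.nir, "b8a": scene.b8a}
    out: dict[str, np.ndarray] = {}
    out.update(compute_indices(bands))
    out.update({_BAND_ALIAS[k]: v for k, v in bands.items()})
    out.update(sar_transforms(scene.vv, scene.vh))
    for bname in texture_bands:
        tex = glcm_features(bands[bname], window=window, step=step, levels=levels)
        out.update({f"{_BAND_ALIAS[bname]}_{k}": v for k, v in tex.items()})
    out.update(terrain_derivatives(scene.dem, scene.cell_size))
    return out
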