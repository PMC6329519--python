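"""Contrast statistics of natural scenes.

A scene's local-contrast distribution is summarised by two numbers that
index its visual complexity:

* **contrast energy (CE)** — the spatial average of local contrast
  magnitude, approximating the scale (width) parameter ``beta`` of a
  Weibull fit to the contrast histogram;
* **spatial coherence (SC)** — a divisively normalised pooling of the
  same magnitudes (mean / sd, an inverse coefficient of variation),
  approximating the Weibull shape parameter ``gamma``.

Sparse scenes with a single segmentable object sit at low CE/SC;
cluttered, fragmented scenes at high CE/SC.  Local contrast is measured
with Gaussian first-derivative filters, a linear stand-in for
contrast-sensitive receptive fields in early visual cortex.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, stats

__all__ = [
    "LuminanceMap",
    "ContrastMap",
    "WeibullFit",
    "SceneStatistics",
    "SceneStatsConfig",
    "to_luminance",
    "compute_contrast_map",
    "fit_weibull",
    "compute_ce",
    "compute_sc",
    "scene_statistics",
    "batch_statistics",
]

#: Rec. 601 luma weights used to collapse RGB to a single channel.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Floor added to the contrast dispersion when computing SC.
SC_EPSILON = 1e-12


@dataclass(frozen=True)
class LuminanceMap:
    """Single-channel luminance image rescaled to the unit interval."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"luminance map must be 2-D, got shape {v.shape}")
        if v.size == 0:
            raise ValueError("luminance map is empty")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("luminance values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ContrastMap:
    """Per-pixel local-contrast magnitudes at one filter scale.

    ``border_margin`` pixels at each edge are contaminated by the filter
    support and are excluded from all pooled statistics.
    """

    magnitudes: np.ndarray
    scale: float
    border_margin: int

    def interior(self) -> np.ndarray:
        """Magnitudes of the non-border region, flattened."""
        m = self.border_margin
        h, w = self.magnitudes.shape
        if 2 * m >= h or 2 * m >= w:
            raise ValueError("border margin swallows the whole map")
        return self.magnitudes[m : h - m, m : w - m].ravel()


@dataclass(frozen=True)
class WeibullFit:
    beta: float    # scale, > 0
    gamma: float   # shape, > 0
    loglik: float
    n: int
    n_zeros_discarded: int = 0


@dataclass(frozen=True)
class SceneStatistics:
    image_id: str
    ce: float
    sc: float
    weibull: WeibullFit | None = None


@dataclass(frozen=True)
class SceneStatsConfig:
    """Configuration of the contrast operator.

    ``scales`` lists Gaussian-derivative sigmas in pixels; with several
    scales the pooled map is the per-pixel maximum across scales.
    """

    scales: Sequence[float] = (1.5,)
    fit_weibull: bool = False
    max_weibull_samples: int = 20000

    def config_hash(self) -> str:
        payload = json.dumps(
            {"scales": list(self.scales), "fit_weibull": self.fit_weibull},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def to_luminance(image: np.ndarray | Image.Image) -> LuminanceMap:
    """Convert a raster image to a unit-range luminance map.

    Accepts 2-D grayscale or 3-channel RGB arrays with 8-bit, 16-bit or
    unit-range float channels.  Colour is collapsed with fixed Rec. 601
    weights (0.299, 0.587, 0.114).
    """
    if isinstance(image, Image.Image):
        image = np.asarray(image)
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count: {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"image must be 2-D or 3-D, got ndim={arr.ndim}")

    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"unsupported integer dtype {arr.dtype}; use uint8/uint16")
    else:
        arr = arr.astype(float)
        if arr.max(initial=0.0) > 1.0 + 1e-9 or arr.min(initial=0.0) < 0.0:
            raise ValueError("float images must be in [0, 1]")

    if arr.ndim == 3:
        arr = arr @ _LUMA_WEIGHTS
    return LuminanceMap(arr)


def compute_contrast_map(
    lum: LuminanceMap, scale: float = 1.5, scales: Sequence[float] | None = None
) -> ContrastMap:
    """Local contrast as the gradient magnitude of Gaussian-derivative responses.

    With a list of ``scales`` the per-pixel maximum across scales is
    returned and the border margin follows the largest scale.  The
    operator is linear in luminance, so magnitudes scale with global
    contrast.
    """
    all_scales = [float(scale)] if scales is None else [float(s) for s in scales]
    if any(s < 1.0 for s in all_scales):
        raise ValueError("filter scale must be >= 1 pixel")
    max_scale = max(all_scales)
    margin = int(np.ceil(3.0 * max_scale))
    h, w = lum.values.shape
    if h < 4 * max_scale or w < 4 * max_scale or min(h, w) < 32:
        raise ValueError(
            f"image {h}x{w} too small for scale {max_scale} (need >= 4*scale and >= 32)"
        )
    pooled = None
    for s in all_scales:
        gx = ndimage.gaussian_filter(lum.values, sigma=s, order=(0, 1), mode="nearest")
        gy = ndimage.gaussian_filter(lum.values, sigma=s, order=(1, 0), mode="nearest")
        mag = np.hypot(gx, gy)
        pooled = mag if pooled is None else np.maximum(pooled, mag)
    return ContrastMap(magnitudes=pooled, scale=max_scale, border_margin=margin)


def fit_weibull(samples: np.ndarray, min_samples: int = 100) -> WeibullFit:
    """Maximum-likelihood 2-parameter Weibull fit of contrast magnitudes.

    Zeros are discarded (and counted) before fitting; the location
    parameter is pinned at 0.  Deterministic given the input.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("contrast samples must be finite and non-negative")
    n_zeros = int(np.sum(x == 0))
    x = x[x > 0]
    if x.size < min_samples:
        raise ValueError(
            f"need >= {min_samples} strictly positive samples, got {x.size}"
        )
    gamma_hat, _, beta_hat = stats.weibull_min.fit(x, floc=0)
    if not (beta_hat > 0 and gamma_hat > 0):
        raise RuntimeError(
            f"Weibull fit failed to converge: beta={beta_hat}, gamma={gamma_hat}"
        )
    loglik = float(np.sum(stats.weibull_min.logpdf(x, gamma_hat, 0, beta_hat)))
    if not np.isfinite(loglik):
        raise RuntimeError("Weibull fit produced non-finite log-likelihood")
    return WeibullFit(
        beta=float(beta_hat),
        gamma=float(gamma_hat),
        loglik=loglik,
        n=int(x.size),
        n_zeros_discarded=n_zeros,
    )


def compute_ce(cmap: ContrastMap) -> float:
    """Contrast energy: spatial mean of contrast magnitude (non-border)."""
    return float(np.mean(cmap.interior()))


def compute_sc(cmap: ContrastMap, epsilon: float = SC_EPSILON) -> float:
    """Spatial coherence: divisively normalised contrast pooling.

    mean / (sd + epsilon) over the non-border region — an inverse
    coefficient of variation, invariant to global contrast rescaling.
    High SC means contrast is spread homogeneously (cluttered,
    near-Gaussian contrast distribution); low SC means a few strong
    edges dominate.  A constant non-zero map hits the ``c / epsilon``
    ceiling ("maximally coherent").
    """
    mags = cmap.interior()
    mean = float(np.mean(mags))
    if mean == 0.0:
        raise ValueError("SC undefined for an all-zero contrast map")
    sd = float(np.std(mags))
    return mean / (sd + epsilon)


def scene_statistics(
    image: np.ndarray | Image.Image,
    config: SceneStatsConfig | None = None,
    image_id: str = "",
) -> SceneStatistics:
    """CE, SC and (optionally) the Weibull fit for one image."""
    cfg = config or SceneStatsConfig()
    lum = to_luminance(image)
    cmap = compute_contrast_map(lum, scales=cfg.scales)
    ce = compute_ce(cmap)
    sc = compute_sc(cmap)
    wb = None
    if cfg.fit_weibull:
        samples = cmap.interior()
        if samples.size > cfg.max_weibull_samples:
            # deterministic thinning keeps the fit cheap on large images
            step = samples.size // cfg.max_weibull_samples
            samples = samples[::step]
        wb = fit_weibull(samples)
    return SceneStatistics(image_id=image_id, ce=ce, sc=sc, weibull=wb)


def batch_statistics(
    images_dir: str | Path, config: SceneStatsConfig | None = None
) -> pd.DataFrame:
    """Compute statistics for every PNG/JPEG in a directory.

    Returns a frame with columns image_id, ce, sc, beta, gamma,
    n_contrast_samples, config_hash (beta/gamma NaN unless the config
    requests Weibull fits).
    """
    cfg = config or SceneStatsConfig()
    rows = []
    paths = sorted(
        p for p in Path(images_dir).iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    for p in paths:
        st = scene_statistics(Image.open(p), cfg, image_id=p.stem)
        rows.append(
            {
                "image_id": st.image_id,
                "ce": st.ce,
                "sc": st.sc,
                "beta": st.weibull.beta if st.weibull else np.nan,
                "gamma": st.weibull.gamma if st.weibull else np.nan,
                "n_contrast_samples": st.weibull.n if st.weibull else 0,
                "config_hash": cfg.config_hash(),
            }
        )
    return pd.DataFrame(rows)
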