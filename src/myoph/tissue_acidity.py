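"""Median-normalised pHLIP/Hoechst ratio maps and their histogram decomposition.

Whole-section pHLIP-Cy5.5 fluorescence marks acidic extracellular niches but
is confounded by cell density and dye penetrance; ratioing against a
co-injected Hoechst-33342 image cancels those factors.  The processing chain:

1. background statistics (mean, SD) from a tissue-free region of each channel;
2. background subtraction and bilinear resize by a configurable factor
   (downscale by default — whole-section tiled scans are large and pooling
   also averages noise);
3. pixelwise ratio restricted to pixels above ``mean + k·SD`` of background on
   *both* channels (k = 2 by default);
4. division by the median so the map's median ratio is exactly 1.

The resulting ratio histogram is decomposed by an expectation-maximisation
fit of a k-component univariate Gaussian mixture (k = 3 by default) with
multiple restarts, and the Fisher–Pearson sample skewness of the raw ratios
is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.transform import resize

__all__ = [
    "BackgroundStats",
    "RatioMap",
    "GaussianMixtureFit",
    "estimate_background",
    "preprocess_channel",
    "compute_ratio_map",
    "fit_gaussian_mixture",
    "fit_ratio_histogram",
    "sample_skewness",
]


@dataclass(frozen=True)
class BackgroundStats:
    """Sample mean and SD (denominator n−1) of a tissue-free image region."""

    mean: float
    sd: float
    n_pixels: int
    channel_name: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_pixels < 2:
            raise ValueError("background region must have >= 2 pixels")


@dataclass
class RatioMap:
    """Masked, median-normalised pHLIP/Hoechst ratio image.

    ``ratio`` is NaN where a pixel failed the dual-channel threshold;
    ``mask`` is True exactly where the ratio is defined.
    """

    ratio: np.ndarray
    mask: np.ndarray
    resize_factor: float
    threshold_k: float
    background_phlip: BackgroundStats
    background_hoechst: BackgroundStats
    normalization_median: float

    @property
    def defined_values(self) -> np.ndarray:
        return self.ratio[self.mask]


@dataclass
class GaussianMixtureFit:
    """k-component univariate Gaussian mixture, components sorted by mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    skewness: float
    converged: bool

    @property
    def mixture_mean(self) -> float:
        return float(np.sum(self.weights * self.means))


def estimate_background(image: np.ndarray, bg_region_mask: np.ndarray,
                        channel_name: str = "") -> BackgroundStats:
    """Mean and sample SD (ddof=1) of the masked background pixels."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(bg_region_mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    vals = image[mask]
    if vals.size < 2:
        raise ValueError(f"background mask selects {vals.size} pixels; need >= 2")
    return BackgroundStats(
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        n_pixels=int(vals.size),
        channel_name=channel_name,
    )


def preprocess_channel(
    image: np.ndarray, background: BackgroundStats, resize_factor: float = 10.0
) -> np.ndarray:
    """Background-subtract and bilinearly resample one channel.

    ``resize_factor`` > 1 downscales linear dimensions by that factor
    (values < 1 upscale).  Negative values after subtraction are kept — the
    dual-channel threshold deals with them later.
    """
    if resize_factor <= 0:
        raise ValueError("resize_factor must be > 0")
    image = np.asarray(image, dtype=float) - background.mean
    out_shape = (
        int(round(image.shape[0] / resize_factor)),
        int(round(image.shape[1] / resize_factor)),
    )
    if out_shape[0] < 2 or out_shape[1] < 2:
        raise ValueError(
            f"resized shape {out_shape} is below the 2x2 minimum; "
            "reduce resize_factor"
        )
    if resize_factor == 1:
        return image
    return resize(image, out_shape, order=1, anti_aliasing=False,
                  preserve_range=True, mode="edge")


def compute_ratio_map(
    phlip_pre: np.ndarray,
    hoechst_pre: np.ndarray,
    phlip_bg: BackgroundStats,
    hoechst_bg: BackgroundStats,
    threshold_k: float = 2.0,
    resize_factor: float = 1.0,
) -> RatioMap:
    """Dual-channel thresholded, median-normalised ratio map.

    A pixel is kept iff its background-subtracted value exceeds
    ``threshold_k`` background SDs on *both* channels (equivalently: raw
    value > mean + k·SD).  Kept ratios are divided by their median.
    """
    phlip_pre = np.asarray(phlip_pre, dtype=float)
    hoechst_pre = np.asarray(hoechst_pre, dtype=float)
    if phlip_pre.shape != hoechst_pre.shape:
        raise ValueError("preprocessed channels must share a shape")
    keep_p = phlip_pre > threshold_k * phlip_bg.sd
    keep_h = hoechst_pre > threshold_k * hoechst_bg.sd
    mask = keep_p & keep_h
    if not mask.any():
        raise ValueError(
            "no pixels pass the dual-channel threshold "
            f"(pHLIP channel: {int(keep_p.sum())} pass, "
            f"Hoechst channel: {int(keep_h.sum())} pass)"
        )
    ratio = np.full(phlip_pre.shape, np.nan)
    ratio[mask] = phlip_pre[mask] / hoechst_pre[mask]
    med = float(np.median(ratio[mask]))
    ratio[mask] /= med
    return RatioMap(
        ratio=ratio,
        mask=mask,
        resize_factor=resize_factor,
        threshold_k=threshold_k,
        background_phlip=phlip_bg,
        background_hoechst=hoechst_bg,
        normalization_median=med,
    )


def sample_skewness(x: np.ndarray) -> float:
    """Bias-uncorrected Fisher–Pearson sample skewness m3 / m2^(3/2)."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    m3 = np.mean((x - m) ** 3)
    return float(m3 / m2**1.5)


# ---------------------------------------------------------------------------
# univariate Gaussian-mixture EM
# ---------------------------------------------------------------------------

def _log_gauss(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # x: (n, 1); mu, sd: (k,)
    return (
        -0.5 * np.log(2 * np.pi)
        - np.log(sd)
        - 0.5 * ((x - mu) / sd) ** 2
    )


def _em_run(
    x: np.ndarray,
    means0: np.ndarray,
    *,
    max_iter: int,
    tol: float,
    sd_floor: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """One EM run from given initial means; k-means sharpening then EM.

    The log-likelihood is asserted non-decreasing across EM iterations (to a
    small numerical slack) — a violated bound indicates an implementation
    bug, not a data problem.
    """
    n = x.size
    k = means0.size
    means = means0.astype(float).copy()

    # brief k-means refinement of the initial means
    for _ in range(10):
        assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        for j in range(k):
            sel = assign == j
            if sel.any():
                means[j] = x[sel].mean()

    weights = np.full(k, 1.0 / k)
    global_sd = max(float(np.std(x)), sd_floor)
    sds = np.full(k, global_sd)

    xc = x[:, None]
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_comp = _log_gauss(xc, means, sds) + np.log(weights)
        log_norm = np.logaddexp.reduce(log_comp, axis=1)
        ll = float(log_norm.sum())
        assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), (
            "EM log-likelihood decreased"
        )
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * xc).sum(axis=0) / nk
        var = (resp * (xc - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sd_floor**2))
    return weights, means, sds, prev_ll, converged


def fit_gaussian_mixture(
    values: np.ndarray,
    k: int = 3,
    seed: int = 0,
    *,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> GaussianMixtureFit:
    """EM fit of a k-component Gaussian mixture to 1-D samples.

    Restart initial means are quantile-stratified: the first restart uses the
    central quantiles ((i + 0.5)/k), subsequent restarts draw one random
    quantile position per stratum.  The restart with the highest final
    log-likelihood wins; ties go to the earliest restart.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} samples to fit k={k}")
    rng = np.random.default_rng(seed)
    sd_floor = max(1e-9, 1e-6 * max(float(np.std(x)), 1e-12))

    best = None
    for r in range(n_restarts):
        if r == 0:
            q = (np.arange(k) + 0.5) / k
        else:
            q = np.sort((np.arange(k) + rng.random(k)) / k)
        means0 = np.quantile(x, q)
        w, m, s, ll, conv = _em_run(
            x, means0, max_iter=max_iter, tol=tol, sd_floor=sd_floor
        )
        if best is None or ll > best[3]:
            best = (w, m, s, ll, conv)
    w, m, s, ll, conv = best
    order = np.argsort(m)
    return GaussianMixtureFit(
        k=k,
        weights=w[order],
        means=m[order],
        sds=s[order],
        log_likelihood=float(ll),
        skewness=sample_skewness(x),
        converged=bool(conv),
    )


def fit_ratio_histogram(
    ratio_map: RatioMap, k: int = 3, seed: int = 0, **kwargs
) -> GaussianMixtureFit:
    """Decompose the defined ratio values of a map into k Gaussians.

    Fits raw (unbinned) values.  Non-convergence after all restarts is
    reported through ``converged=False``, never an exception.
    """
    return fit_gaussian_mixture(ratio_map.defined_values, k=k, seed=seed, **kwargs)
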