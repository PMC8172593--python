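"""Variance stabilization and per-pixel baseline/noise estimation.

High-frame-rate two-photon pixel values follow an approximately Gaussian law
whose variance grows linearly with the mean, Var = a·E + b, because of PMT
amplification.  Taking the square root of the (smoothed) gray values makes the
noise variance essentially independent of the signal level (≈ a/4 for large
E), so a single per-pixel noise SD is meaningful.

On the transformed series X_i(t) we estimate, per pixel i:

* the baseline μ̂_i as the mode of the series (the signal sits at baseline for
  most of the recording), computed by histogram;
* the noise SD σ̂_i from the median of squared successive differences,
  σ̂_i² = Median([X_i(t+1) − X_i(t)]²) / c with c = 2·m₁ ≈ 0.9099, where m₁ is
  the median of the χ²(1) distribution.  Successive differencing cancels slow
  baseline drift, and the median makes the estimate robust to sparse
  transients.

The movie-level SNR is Median(μ̂_i) / Median(σ̂_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

logger = logging.getLogger("roakit")


class DomainError(ValueError):
    """Input values outside the operation's domain (e.g. negative counts)."""


class UndefinedSNRError(ZeroDivisionError):
    """Global noise SD is zero, so SNR is undefined."""


@lru_cache(maxsize=1)
def mssd_constant() -> float:
    """Normalizing constant c = 2·m₁ ≈ 0.909873 of the successive-difference
    noise variance estimator, with m₁ the median of χ² with 1 df.

    For iid Gaussian noise, X(t+1) − X(t) ~ N(0, 2σ²), so the median of the
    squared differences is 2σ²·m₁; dividing by c = 2·m₁ makes the estimator
    consistent for σ².
    """
    return 2.0 * float(stats.chi2.ppf(0.5, df=1))


def sqrt_transform(block: np.ndarray) -> np.ndarray:
    """Element-wise square root (variance stabilization for Var = a·E + b)."""
    block = np.asarray(block)
    if block.size and float(block.min()) < 0:
        raise DomainError("sqrt_transform requires non-negative values")
    return np.sqrt(block, dtype=np.result_type(block.dtype, np.float32))


def estimate_noise_map(X: np.ndarray) -> np.ndarray:
    """Per-pixel noise SD σ̂_i from the median squared successive difference.

    X is a (t, y, x) stack in sqrt-transformed units with >= 2 frames.
    Constant pixels get σ̂_i = 0 (flagged downstream as dead/saturated).
    """
    X = np.asarray(X)
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float64)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 frames to estimate noise")
    d = np.diff(X, axis=0)
    np.square(d, out=d)
    sig2 = np.median(d, axis=0) / mssd_constant()
    return np.sqrt(sig2)


def estimate_baseline_map(X: np.ndarray, sigma_map: np.ndarray | None = None,
                          bin_factor: float = 0.2, max_bins: int = 1024,
                          pixel_block: int = 4096) -> np.ndarray:
    """Per-pixel baseline μ̂_i = mode of X_i over time, by histogram.

    The histogram bin width is max(bin_factor·σ̂_i, range/max_bins), i.e.
    scaled to each pixel's own noise level so the mode is stable across gain
    settings; bin edges sit on multiples of the width so the grid phase does
    not depend on the sample extremes.  The winning bin (ties toward the
    lowest bin — the baseline is the low state) is located on lightly
    smoothed counts and refined to the center of mass of the surrounding
    plateau (contiguous bins holding >= 75% of the peak count), which makes
    the estimate sub-bin accurate and insensitive to single-bin count noise.
    Results are clipped to the observed range; constant pixels return their
    constant.
    """
    X = np.asarray(X, dtype=np.float64)
    T = X.shape[0]
    if T < 100:
        logger.warning("baseline estimated from only %d frames; the mode may "
                       "be unstable below ~100", T)
    if sigma_map is None:
        sigma_map = estimate_noise_map(X)
    x = X.reshape(T, -1)
    s = np.asarray(sigma_map, dtype=np.float64).reshape(-1)
    n_px = x.shape[1]
    mu = np.empty(n_px)
    for a in range(0, n_px, pixel_block):
        b = min(a + pixel_block, n_px)
        xb = x[:, a:b]
        lo, hi = xb.min(axis=0), xb.max(axis=0)
        rng = hi - lo
        w = np.maximum(bin_factor * s[a:b], rng / max_bins)
        const = rng <= 0
        w_safe = np.where(w > 0, w, 1.0)
        origin = np.floor(lo / w_safe) * w_safe  # edges on multiples of w
        nbins = np.minimum(np.floor((hi - origin) / w_safe).astype(np.int64) + 1,
                           max_bins + 1)
        nb = max(int(nbins.max(initial=1)), 1)
        idx = np.minimum((xb - origin) / w_safe, nbins - 1).astype(np.int64)
        flat = idx + np.arange(b - a, dtype=np.int64) * nb
        counts = np.bincount(flat.ravel(), minlength=(b - a) * nb) \
            .reshape(b - a, nb).astype(np.float64)
        sm = counts.copy()  # [1, 2, 1]/4 smoothing along the bin axis
        sm[:, 1:] += 0.5 * counts[:, :-1]
        sm[:, :-1] += 0.5 * counts[:, 1:]
        sm *= 0.5
        k = sm.argmax(axis=1)  # first max = lowest bin on ties
        cols = np.arange(b - a)
        thr = 0.75 * sm[cols, k]
        bins = np.arange(nb)[None, :]
        below = sm < thr[:, None]
        left = np.where(below & (bins <= k[:, None]), bins, -1).max(axis=1) + 1
        right = np.where(below & (bins > k[:, None]), bins, nb).min(axis=1) - 1
        in_plateau = (bins >= left[:, None]) & (bins <= right[:, None])
        weights = counts * in_plateau
        den = np.maximum(weights.sum(axis=1), 1e-300)
        com = (weights * (bins + 0.5)).sum(axis=1) / den
        mu_b = origin + com * w_safe
        mu[a:b] = np.where(const, lo, np.clip(mu_b, lo, hi))
    return mu.reshape(X.shape[1:])


@dataclass(frozen=True)
class PixelStatMaps:
    """Per-pixel baseline and noise maps (sqrt units) plus their global medians.

    Pixels with σ̂_i = 0 (dead or saturated) are excluded from the global
    medians; ``n_dead`` counts them.
    """

    mu_map: np.ndarray
    sigma_map: np.ndarray
    mu_global: float
    sigma_global: float
    snr: float
    n_dead: int

    @property
    def valid_mask(self) -> np.ndarray:
        return self.sigma_map > 0


def compute_stat_maps(X: np.ndarray) -> PixelStatMaps:
    """Estimate σ̂_i then μ̂_i from an estimation-path (binned, sqrt) stack and
    aggregate the global medians and SNR."""
    sigma_map = estimate_noise_map(X)
    mu_map = estimate_baseline_map(X, sigma_map=sigma_map)
    valid = sigma_map > 0
    n_dead = int(valid.size - valid.sum())
    if n_dead:
        logger.info("excluding %d dead/saturated pixels (sigma=0) from global "
                    "medians", n_dead)
    if valid.any():
        mu_global = float(np.median(mu_map[valid]))
        sigma_global = float(np.median(sigma_map[valid]))
    else:
        mu_global, sigma_global = float(np.median(mu_map)), 0.0
    snr = mu_global / sigma_global if sigma_global > 0 else float("nan")
    return PixelStatMaps(mu_map=mu_map, sigma_map=sigma_map,
                         mu_global=mu_global, sigma_global=sigma_global,
                         snr=snr, n_dead=n_dead)


def movie_snr(maps: PixelStatMaps) -> float:
    """SNR = Median(μ̂_i) / Median(σ̂_i)."""
    if not maps.sigma_global > 0:
        raise UndefinedSNRError("global noise SD is zero; SNR undefined")
    return maps.mu_global / maps.sigma_global
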