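"""Spatiotemporal smoothing operators and the SNR-targeted parameter search.

Event detection quality depends on the imaging SNR, so before anything else
the movie is smoothed until the SNR (median baseline over median noise SD in
sqrt units) reaches a target, 9 by default.  The search raises the spatial
Gaussian sigma from 0 to 2 px first; if that is not enough, it keeps sigma at
2 px and searches the temporal window in 1..30 frames by interval halving
(bisection under the assumption that SNR is non-decreasing in the window).
If even (2 px, 30 frames) misses the target the configuration is returned
with ``attained=False``.

Two temporal operators exist on purpose: the *estimation* path bins frames
(non-overlapping block means, shortening the series — successive binned
samples stay independent, which the noise estimator needs), while the
*detection* path uses a centered moving average that preserves the frame
count.  Both reduce the noise SD identically, so parameters estimated on the
binned path transfer to the detection path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .movie_io import MovieSource
from .noise_model import compute_stat_maps, sqrt_transform

logger = logging.getLogger("roakit")

SIGMA_MAX = 2.0
N_FRAMES_MAX = 30
DEFAULT_TARGET_SNR = 9.0
DEFAULT_EVAL_FRAMES = 1000
#: spatial search grid; SNR is insensitive below half-pixel granularity
SIGMA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)


class DegenerateInputError(ValueError):
    """Temporal window longer than the movie."""


@dataclass
class SmoothingConfig:
    """Spatial/temporal smoothing level with the SNR it achieved."""

    sigma_px: float = 0.0
    n_frames: int = 1
    target_snr: float = DEFAULT_TARGET_SNR
    achieved_snr: float = float("nan")
    attained: bool = False
    eval_frames: int = DEFAULT_EVAL_FRAMES

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_px <= SIGMA_MAX):
            raise ValueError(f"sigma_px must be in [0, {SIGMA_MAX}]")
        if not (1 <= self.n_frames <= N_FRAMES_MAX):
            raise ValueError(f"n_frames must be in [1, {N_FRAMES_MAX}]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothingConfig":
        return cls(**d)


def smooth_spatial(block: np.ndarray, sigma_px: float) -> np.ndarray:
    """Per-frame 2-D Gaussian filter with reflective padding; sigma 0 is the
    identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    block = np.asarray(block)
    if sigma_px == 0:
        return block.astype(np.float32, copy=True) if block.dtype.kind in "ui" \
            else block.copy()
    out = block.astype(np.float32, copy=False)
    return ndimage.gaussian_filter(out, sigma=(0.0, sigma_px, sigma_px),
                                   mode="reflect", output=np.float32)


def bin_temporal(movie: np.ndarray, n: int) -> np.ndarray:
    """Non-overlapping n-frame block means; trailing remainder dropped."""
    movie = np.asarray(movie)
    T = movie.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > T:
        raise DegenerateInputError(f"bin of {n} frames exceeds movie length {T}")
    T2 = T // n
    return movie[: T2 * n].reshape((T2, n) + movie.shape[1:]) \
        .mean(axis=1, dtype=np.float64).astype(np.float32)


def moving_average_temporal(movie: np.ndarray, n: int) -> np.ndarray:
    """Centered n-frame moving average, same length as the input; the window
    shrinks symmetrically at the movie ends."""
    movie = np.asarray(movie)
    T = movie.shape[0]
    if not 1 <= n <= T:
        raise ValueError(f"window must be in [1, {T}]")
    return _moving_average_window(movie, n, t_abs_start=0, t_total=T)


def _moving_average_window(block: np.ndarray, n: int, t_abs_start: int,
                           t_total: int, out_start: int = 0,
                           out_stop: int | None = None) -> np.ndarray:
    """Moving average of ``block`` frames [out_start, out_stop) where window
    bounds are computed in *absolute* movie coordinates.

    ``block`` holds absolute frames [t_abs_start, t_abs_start + len(block));
    the window of absolute frame t spans [t-k_lo, t+k_hi] with
    k_lo = min((n-1)//2, t, t_total-1-t) and k_hi = k_lo + (1 if n even and
    room remains).  This lets chunked processing with a halo reproduce the
    whole-movie result bit for bit.
    """
    if out_stop is None:
        out_stop = block.shape[0]
    h_lo, h_hi = (n - 1) // 2, n // 2
    c = np.cumsum(block, axis=0, dtype=np.float64)
    c = np.concatenate([np.zeros((1,) + block.shape[1:]), c], axis=0)
    out = np.empty((out_stop - out_start,) + block.shape[1:], dtype=np.float32)
    for j, ti in enumerate(range(out_start, out_stop)):
        t = t_abs_start + ti  # absolute frame index
        k = min(h_lo, t, t_total - 1 - t)
        k_hi = k + 1 if (n % 2 == 0 and t + k + 1 <= t_total - 1) else k
        lo, hi = ti - k, ti + k_hi + 1
        out[j] = (c[hi] - c[lo]) / (hi - lo)
    return out


def detection_halo(n: int) -> int:
    """Frames of context needed on each side of a chunk for the moving
    average to be exact."""
    return n // 2


# ---------------------------------------------------------------------------
# Automatic configuration
# ---------------------------------------------------------------------------

def estimation_path(raw: np.ndarray, sigma_px: float, n: int) -> np.ndarray:
    """Estimation-path transform: spatial Gaussian, n-frame binning, sqrt."""
    return sqrt_transform(np.maximum(bin_temporal(smooth_spatial(raw, sigma_px), n),
                                     0.0))


def _eval_snr(src: MovieSource, sigma_px: float, n: int, eval_frames: int,
              cache: dict) -> float:
    """SNR of the estimation path, on at most the last ``eval_frames`` merged
    frames."""
    T = src.meta.n_frames
    n_raw = min(T, eval_frames * n)
    n_raw -= n_raw % n  # whole bins only
    if n_raw < 2 * n:
        n_raw = min(T, 2 * n)
    key_raw = (n_raw,)
    if key_raw not in cache:
        cache.clear()  # keep at most one tail + one smoothed version
        cache[key_raw] = src.read(T - n_raw, T)
    key_sm = (n_raw, sigma_px)
    if key_sm not in cache:
        cache[key_sm] = smooth_spatial(cache[key_raw], sigma_px)
    X = sqrt_transform(np.maximum(bin_temporal(cache[key_sm], n), 0.0))
    maps = compute_stat_maps(X)
    if not maps.sigma_global > 0:
        return 0.0
    return maps.snr


def auto_configure(src: MovieSource, target_snr: float = DEFAULT_TARGET_SNR,
                   eval_frames: int = DEFAULT_EVAL_FRAMES) -> SmoothingConfig:
    """Find the least smoothing that reaches the target SNR.

    Spatial sigma is raised through ``SIGMA_GRID`` first (window 1 frame); if
    sigma = 2 px is still short, the temporal window is searched in [1, 30]
    by bisection for the minimal n with SNR >= target.  An unattainable
    target yields the maximal configuration (2 px, 30 frames) flagged
    ``attained=False``.
    """
    if src.meta.n_frames < 60:
        raise ValueError("need >= 60 frames to configure smoothing")
    cache: dict = {}
    snrs: dict[tuple[float, int], float] = {}

    def snr(sigma: float, n: int) -> float:
        if (sigma, n) not in snrs:
            snrs[(sigma, n)] = _eval_snr(src, sigma, n, eval_frames, cache)
        return snrs[(sigma, n)]

    for sigma in SIGMA_GRID:
        s = snr(sigma, 1)
        if s >= target_snr:
            return SmoothingConfig(sigma_px=sigma, n_frames=1,
                                   target_snr=target_snr, achieved_snr=s,
                                   attained=True, eval_frames=eval_frames)
    sigma = SIGMA_MAX
    n_hi = min(N_FRAMES_MAX, src.meta.n_frames)
    if snr(sigma, n_hi) < target_snr:
        return SmoothingConfig(sigma_px=sigma, n_frames=N_FRAMES_MAX,
                               target_snr=target_snr,
                               achieved_snr=snr(sigma, n_hi), attained=False,
                               eval_frames=eval_frames)
    lo, hi = 1, n_hi
    while lo < hi:  # interval halving for the minimal sufficient window
        mid = (lo + hi) // 2
        if snr(sigma, mid) >= target_snr:
            hi = mid
        else:
            lo = mid + 1
    achieved = snr(sigma, lo)
    if achieved < target_snr:  # sampling noise broke monotonicity
        logger.warning("SNR not monotone in window length near n=%d; returning "
                       "the bracketing minimum", lo)
    return SmoothingConfig(sigma_px=sigma, n_frames=lo, target_snr=target_snr,
                           achieved_snr=achieved, attained=achieved >= target_snr,
                           eval_frames=eval_frames)
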