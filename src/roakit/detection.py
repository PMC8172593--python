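"""Pixel-wise event detection: threshold, binarize, label, filter, summarize.

Each pixel i of the detection-path movie (spatial Gaussian + centered moving
average + square root) is binarized against its own threshold

    τ_i = μ̂_i + κ·σ̂          (default κ = 4)

where μ̂_i is the pixel's baseline and σ̂ the global median noise SD, both in
sqrt units.  Active x-y-t voxels are then connected into events (regions of
activity, ROAs) with a 26-neighborhood by default, filtered by minimum
footprint and duration, and summarized into an event table plus density and
frequency traces.

Binarization is chunked in time with a (n//2)-frame halo so that chunked and
whole-movie runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie_io import MovieMeta, MovieSource, SidecarStore
from .noise_model import PixelStatMaps, compute_stat_maps, sqrt_transform
from .smoothing import (SmoothingConfig, _moving_average_window, auto_configure,
                        bin_temporal, detection_halo, smooth_spatial)

logger = logging.getLogger("roakit")

CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


class ConsistencyError(ValueError):
    """Shapes or provenance of pipeline inputs disagree."""


@dataclass
class DetectionConfig:
    """Thresholding and event-filtering parameters.

    min_size is an x-y footprint in pixels (min_size_um2 takes precedence
    when set and the pixel size is calibrated); ignored pixels are never
    active.  The default 2-px edge band guards against filter roll-off at
    the FOV border.
    """

    kappa: float = 4.0
    min_size: int = 4
    min_size_um2: float | None = None
    min_duration: int = 2
    edge_ignore: int = 2
    ignore_mask: np.ndarray | None = None
    connectivity: int = 26
    per_pixel_sigma: bool = False

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.connectivity not in CONNECTIVITY_STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")

    def resolve_ignore(self, height: int, width: int) -> np.ndarray:
        """Combined ignore mask: user mask plus the edge band (True = excluded)."""
        ignore = np.zeros((height, width), dtype=bool)
        if self.ignore_mask is not None:
            if self.ignore_mask.shape != (height, width):
                raise ConsistencyError("ignore_mask shape does not match movie")
            ignore |= self.ignore_mask.astype(bool)
        e = self.edge_ignore
        if e > 0:
            ignore[:e, :] = ignore[-e:, :] = True
            ignore[:, :e] = ignore[:, -e:] = True
        return ignore


def threshold_map(maps: PixelStatMaps, kappa: float,
                  ignore: np.ndarray | None = None,
                  per_pixel_sigma: bool = False) -> np.ndarray:
    """Per-pixel threshold τ_i = μ̂_i + κ·σ̂ (global median σ̂ by default).

    Dead pixels (σ̂_i = 0) and ignored pixels get τ = +inf, i.e. never active.
    """
    sigma = maps.sigma_map if per_pixel_sigma else maps.sigma_global
    tau = maps.mu_map + kappa * sigma
    tau = np.where(maps.sigma_map > 0, tau, np.inf)
    if ignore is not None:
        tau = np.where(ignore, np.inf, tau)
    return tau.astype(np.float64)


def binarize_movie(src: MovieSource, smoothing: SmoothingConfig,
                   maps: PixelStatMaps, config: DetectionConfig,
                   chunk_frames: int | None = None) -> np.ndarray:
    """Detection-path binarization F* > τ, chunked in time with a halo.

    The detection path applies the configured spatial Gaussian, then a
    centered moving average of the configured window, then the square root;
    the halo makes the chunked result identical to a single pass.
    """
    meta = src.meta
    if maps.mu_map.shape != (meta.height, meta.width):
        raise ConsistencyError("stat maps do not match movie geometry")
    ignore = config.resolve_ignore(meta.height, meta.width)
    tau = threshold_map(maps, config.kappa, ignore=ignore,
                        per_pixel_sigma=config.per_pixel_sigma)
    T = meta.n_frames
    n = smoothing.n_frames
    halo = detection_halo(n)
    chunk = T if chunk_frames is None else max(int(chunk_frames), 1)
    mask = np.zeros(meta.shape, dtype=bool)
    for a in range(0, T, chunk):
        b = min(a + chunk, T)
        lo, hi = max(0, a - halo), min(T, b + halo)
        block = smooth_spatial(src.read(lo, hi), smoothing.sigma_px)
        ma = _moving_average_window(block, n, t_abs_start=lo, t_total=T,
                                    out_start=a - lo, out_stop=b - lo)
        fstar = sqrt_transform(np.maximum(ma, 0.0))
        mask[a:b] = fstar > tau[None, :, :]
    return mask


def label_events(mask: np.ndarray, connectivity: int = 26
                 ) -> tuple[np.ndarray, int]:
    """Connected x-y-t components of the activity mask, labels 1..K."""
    structure = ndimage.generate_binary_structure(
        3, CONNECTIVITY_STRUCTS[connectivity])
    labels, count = ndimage.label(np.asarray(mask, dtype=bool),
                                  structure=structure)
    return labels, int(count)


def _event_coords(labels: np.ndarray) -> pd.DataFrame:
    t, y, x = np.nonzero(labels)
    return pd.DataFrame({"label": labels[t, y, x], "t": t, "y": y, "x": x})


def filter_events(labels: np.ndarray, config: DetectionConfig,
                  meta: MovieMeta | None = None
                  ) -> tuple[np.ndarray, dict]:
    """Drop events below the minimum footprint or duration; trim ignored
    pixels first (an event left with no voxels is dropped).

    Surviving events keep their original label ids.  Returns the filtered
    label volume and a report of kept/dropped ids.
    """
    labels = np.asarray(labels)
    T, H, W = labels.shape
    out = labels.copy()
    ignore = config.resolve_ignore(H, W)
    if ignore.any():
        out[:, ignore] = 0
    coords = _event_coords(out)
    if coords.empty:
        return out, {"kept": [], "dropped": [], "n_kept": 0, "n_dropped": 0}
    g = coords.groupby("label")
    duration = g["t"].max() - g["t"].min() + 1
    footprint = (coords["y"] * W + coords["x"]).groupby(coords["label"]).nunique()
    min_size = config.min_size
    if config.min_size_um2 is not None and meta is not None:
        min_size = config.min_size_um2 / meta.pixel_size ** 2
    keep = (duration >= config.min_duration) & (footprint >= min_size)
    kept = keep.index[keep].to_numpy()
    dropped = np.setdiff1d(np.unique(labels[labels > 0]), kept)
    if dropped.size:
        lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
        lut[kept] = kept
        out = lut[out]
    report = {"kept": kept.tolist(), "dropped": dropped.tolist(),
              "n_kept": int(kept.size), "n_dropped": int(dropped.size)}
    return out, report


def summarize_events(labels: np.ndarray, meta: MovieMeta) -> pd.DataFrame:
    """Per-event table: centroid, start/end frame, duration, size.

    Size is reported both as the x-y-t voxel count and as the x-y footprint
    area (union over time) in µm²; the centroid is the unweighted mean voxel
    coordinate.
    """
    T, H, W = labels.shape
    coords = _event_coords(labels)
    cols = ["event_id", "x", "y", "t", "start_frame", "end_frame",
            "duration_frames", "duration_s", "n_voxels", "footprint_px",
            "area_um2"]
    if coords.empty:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    g = coords.groupby("label")
    start = g["t"].min()
    end = g["t"].max()
    dur = end - start + 1
    footprint = (coords["y"] * W + coords["x"]).groupby(coords["label"]).nunique()
    table = pd.DataFrame({
        "event_id": start.index.astype(int),
        "x": g["x"].mean(), "y": g["y"].mean(), "t": g["t"].mean(),
        "start_frame": start.astype(int), "end_frame": end.astype(int),
        "duration_frames": dur.astype(int),
        "duration_s": dur / meta.frame_rate,
        "n_voxels": g.size().astype(int),
        "footprint_px": footprint.astype(int),
        "area_um2": footprint * meta.pixel_size ** 2,
    }).reset_index(drop=True)
    return table.sort_values("event_id", ignore_index=True)


@dataclass
class ROATraces:
    """Per-frame event density and frequency, plus the overall event rate."""

    time_s: np.ndarray
    density: np.ndarray        # % of non-ignored pixels active
    frequency: np.ndarray      # events starting in each frame
    rate_per_min_um2: float    # events / minute / µm² of analyzed FOV
    nominal_units: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s,
                             "density_pct": self.density,
                             "frequency": self.frequency})


def compute_traces(mask: np.ndarray, table: pd.DataFrame, meta: MovieMeta,
                   ignore: np.ndarray | None = None) -> ROATraces:
    """Density (% active of non-ignored pixels per frame), frequency (events
    starting per frame), and the rate in events/min/µm²."""
    T, H, W = mask.shape
    if ignore is None:
        ignore = np.zeros((H, W), dtype=bool)
    n_px = int((~ignore).sum())
    if n_px == 0:
        raise ConsistencyError("every pixel is ignored")
    active = mask[:, ~ignore].sum(axis=1)
    density = 100.0 * active / n_px
    frequency = np.bincount(table["start_frame"].to_numpy(dtype=int),
                            minlength=T).astype(float) if len(table) else \
        np.zeros(T)
    minutes = T / meta.frame_rate / 60.0
    area = n_px * meta.pixel_size ** 2
    rate = len(table) / (minutes * area)
    return ROATraces(time_s=np.arange(T) / meta.frame_rate, density=density,
                     frequency=frequency, rate_per_min_um2=rate,
                     nominal_units=meta.nominal_units)


@dataclass
class ROAResult:
    """All outputs of a pipeline run."""

    mask: np.ndarray
    labels: np.ndarray
    table: pd.DataFrame
    traces: ROATraces
    maps: PixelStatMaps
    smoothing: SmoothingConfig
    config: DetectionConfig
    filter_report: dict


def _estimation_stack(src: MovieSource, smoothing: SmoothingConfig,
                      chunk_frames: int) -> np.ndarray:
    """Full-movie estimation path (spatial smooth + bin + sqrt), chunked on
    bin boundaries so chunk size cannot change the result."""
    n = smoothing.n_frames
    T = src.meta.n_frames
    n_bins = T // n
    chunk_bins = max(chunk_frames // n, 1)
    X = np.empty((n_bins, src.meta.height, src.meta.width), dtype=np.float32)
    for b0 in range(0, n_bins, chunk_bins):
        b1 = min(b0 + chunk_bins, n_bins)
        raw = src.read(b0 * n, b1 * n)
        X[b0:b1] = sqrt_transform(
            np.maximum(bin_temporal(smooth_spatial(raw, smoothing.sigma_px), n),
                       0.0))
    return X


def run_roa(src: MovieSource, smoothing: SmoothingConfig | None = None,
            config: DetectionConfig | None = None, chunk_frames: int = 256,
            store: SidecarStore | None = None) -> ROAResult:
    """Full pipeline: estimate → threshold → binarize → label → filter →
    summarize → traces; optionally persisted to the sidecar store.

    Sidecar keys: ``roa_table``, ``roa_traces``, ``roa_mask_ch<channel>``,
    ``roa_mu_map``, ``roa_sigma_map``, ``roa_smoothing_config``.  Nothing is
    persisted unless every stage succeeds.
    """
    config = config or DetectionConfig()
    stage = "configure"
    try:
        if smoothing is None:
            smoothing = auto_configure(src)
        stage = "estimate"
        X = _estimation_stack(src, smoothing, chunk_frames)
        maps = compute_stat_maps(X)
        del X
        stage = "binarize"
        mask = binarize_movie(src, smoothing, maps, config,
                              chunk_frames=chunk_frames)
        stage = "label"
        labels, _ = label_events(mask, config.connectivity)
        stage = "filter"
        labels, report = filter_events(labels, config, meta=src.meta)
        mask = labels > 0
        stage = "summarize"
        table = summarize_events(labels, src.meta)
        stage = "traces"
        ignore = config.resolve_ignore(src.meta.height, src.meta.width)
        traces = compute_traces(mask, table, src.meta, ignore=ignore)
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except TypeError:
            wrapped = RuntimeError(f"[stage: {stage}] {exc}")
        raise wrapped from exc
    if store is not None:
        store.put("roa_table", table)
        store.put("roa_traces", traces.to_frame())
        store.put(f"roa_mask_ch{src.meta.channel}", mask)
        store.put("roa_mu_map", maps.mu_map)
        store.put("roa_sigma_map", maps.sigma_map)
        store.put("roa_smoothing_config", smoothing.to_dict())
    return ROAResult(mask=mask, labels=labels, table=table, traces=traces,
                     maps=maps, smoothing=smoothing, config=config,
                     filter_report=report)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_result(result: ROAResult, out_dir, meta: MovieMeta) -> dict:
    """Write the event table and traces as CSV and the mask as an HDF5
    boolean dataset; returns the paths written."""
    import h5py
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"table": out_dir / "roa_table.csv",
             "traces": out_dir / "roa_traces.csv",
             "mask": out_dir / "roa_mask.h5"}
    result.table.to_csv(paths["table"], index=False)
    result.traces.to_frame().to_csv(paths["traces"], index=False)
    with h5py.File(paths["mask"], "w") as f:
        ds = f.create_dataset("roa_mask", data=result.mask, compression="gzip")
        ds.attrs["frame_rate"] = meta.frame_rate
        ds.attrs["pixel_size_um"] = meta.pixel_size
    return paths
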