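"""Manual-ROI data model, trace extraction and ROA-in-ROI assignment.

ROIs are hand-drawn 2-D masks over anatomical structures (somata, processes,
endfeet).  They are exchanged on disk as a 16-bit label TIFF (0 = background)
plus a CSV table keyed by label value; overlapping ROIs fall back to one page
per ROI.  Traces are the per-frame mean gray value inside each mask, with
ΔF/F₀ computed against a low percentile of the raw trace, and ROA activity is
assigned to ROIs as the percentage of ROI pixels active per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .movie_io import FormatError, MovieSource

logger = logging.getLogger("roakit")

ROI_TYPES = ("soma", "process", "endfoot", "other")


class NormalizationError(ZeroDivisionError):
    """Baseline fluorescence F0 is zero, so dF/F is undefined."""


@dataclass
class ROI:
    id: int
    name: str
    roi_type: str = "other"
    channel: int = 0
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError(f"ROI {self.id}: mask must be 2-D and non-empty")

    @property
    def size_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        y, x = np.nonzero(self.mask)
        return float(x.mean()), float(y.mean())


class ROISet:
    """Ordered collection of ROIs with unique ids and a common geometry."""

    def __init__(self, rois: list[ROI]):
        ids = [r.id for r in rois]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")
        shapes = {r.mask.shape for r in rois}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one shape")
        self.rois = list(rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.rois[0].mask.shape if self.rois else None

    def table(self, pixel_size: float = 1.0) -> pd.DataFrame:
        """Summary table: id, name, type, channel, size and centroid."""
        rows = []
        for r in self.rois:
            cx, cy = r.centroid
            rows.append({"roi_id": r.id, "name": r.name, "type": r.roi_type,
                         "channel": r.channel, "size_px": r.size_px,
                         "area_um2": r.size_px * pixel_size ** 2,
                         "centroid_x": cx, "centroid_y": cy})
        cols = ["roi_id", "name", "type", "channel", "size_px", "area_um2",
                "centroid_x", "centroid_y"]
        return pd.DataFrame(rows, columns=cols)

    def has_overlap(self) -> bool:
        if not self.rois:
            return False
        return bool((np.sum([r.mask for r in self.rois], axis=0) > 1).any())


def write_roi_set(path: str | Path, rois: ROISet) -> tuple[Path, Path]:
    """Write a label TIFF (one page, or one page per ROI when masks overlap)
    plus a CSV table; returns (image path, table path)."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    if rois.shape is None:
        tifffile.imwrite(path, np.zeros((1, 1), dtype=np.uint16))
        rois.table().to_csv(csv_path, index=False)
        return path, csv_path
    if any(r.id <= 0 or r.id > np.iinfo(np.uint16).max for r in rois):
        raise ValueError("ROI ids must fit a positive uint16 label")
    if rois.has_overlap():
        logger.info("overlapping ROIs: writing one label page per ROI")
        pages = np.stack([np.where(r.mask, np.uint16(r.id), np.uint16(0))
                          for r in rois])
        tifffile.imwrite(path, pages)
    else:
        label = np.zeros(rois.shape, dtype=np.uint16)
        for r in rois:
            label[r.mask] = r.id
        tifffile.imwrite(path, label)
    rois.table().to_csv(csv_path, index=False)
    return path, csv_path


def read_roi_set(path: str | Path) -> ROISet:
    """Read a label TIFF + CSV pair written by :func:`write_roi_set`."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    if not path.exists() or not csv_path.exists():
        raise FileNotFoundError(f"need both {path} and {csv_path}")
    table = pd.read_csv(csv_path)
    img = tifffile.imread(path)
    meta = {int(row.roi_id): row for row in table.itertuples()}
    rois: list[ROI] = []
    if img.ndim == 2:
        labels = [int(v) for v in np.unique(img) if v != 0]
        missing = [v for v in labels if v not in meta]
        if missing:
            raise FormatError(f"labels {missing} present in image but absent "
                              f"from {csv_path}")
        for v in labels:
            row = meta[v]
            rois.append(ROI(id=v, name=row.name, roi_type=row.type,
                            channel=int(row.channel), mask=img == v))
    elif img.ndim == 3:
        for page in img:
            vals = [int(v) for v in np.unique(page) if v != 0]
            if not vals:
                continue
            if len(vals) != 1:
                raise FormatError("one-hot ROI pages must hold a single label")
            v = vals[0]
            if v not in meta:
                raise FormatError(f"label {v} present in image but absent "
                                  f"from {csv_path}")
            row = meta[v]
            rois.append(ROI(id=v, name=row.name, roi_type=row.type,
                            channel=int(row.channel), mask=page > 0))
    else:
        raise FormatError(f"unexpected ROI image with {img.ndim} dimensions")
    return ROISet(rois)


def extract_roi_traces(src: MovieSource, rois: ROISet,
                       f0_percentile: float = 20.0,
                       chunk_frames: int = 256
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw and ΔF/F₀ traces per ROI.

    raw(t) is the mean gray value over the ROI mask; F₀ is the
    ``f0_percentile``-th percentile of the raw trace (robust to sparse
    transients) and ΔF/F(t) = (raw(t) − F₀)/F₀.
    """
    meta = src.meta
    if rois.shape is not None and rois.shape != (meta.height, meta.width):
        raise ValueError("ROI masks do not match the movie geometry")
    flat_masks = [r.mask.ravel() for r in rois]
    raw = np.empty((meta.n_frames, len(rois.rois)))
    for t0, t1 in src.iter_chunks(chunk_frames):
        block = src.read(t0, t1).reshape(t1 - t0, -1).astype(np.float64)
        for j, m in enumerate(flat_masks):
            raw[t0:t1, j] = block[:, m].mean(axis=1)
    ids = [r.id for r in rois]
    raw_df = pd.DataFrame(raw, columns=ids)
    raw_df.insert(0, "time_s", np.arange(meta.n_frames) / meta.frame_rate)
    f0 = np.percentile(raw, f0_percentile, axis=0)
    if np.any(f0 == 0):
        bad = [ids[j] for j in np.nonzero(f0 == 0)[0]]
        raise NormalizationError(f"F0 is zero for ROI(s) {bad}")
    dff = (raw - f0) / f0
    dff_df = pd.DataFrame(dff, columns=ids)
    dff_df.insert(0, "time_s", raw_df["time_s"])
    return raw_df, dff_df


def roa_fraction_in_roi(mask: np.ndarray, rois: ROISet) -> pd.DataFrame:
    """Per ROI and frame, the percentage of ROI pixels inside active ROA
    voxels (sidecar key ``roi_signal_rpa``)."""
    mask = np.asarray(mask, dtype=bool)
    if rois.shape is not None and rois.shape != mask.shape[1:]:
        raise ValueError("ROI masks do not match the ROA mask geometry")
    T = mask.shape[0]
    flat = mask.reshape(T, -1)
    out = {}
    for r in rois:
        m = r.mask.ravel()
        out[r.id] = 100.0 * flat[:, m].sum(axis=1) / r.size_px
    df = pd.DataFrame(out, index=pd.RangeIndex(T, name="frame"))
    return df.reset_index()
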