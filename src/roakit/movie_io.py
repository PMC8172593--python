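"""Source-agnostic, lazy access to imaging time series plus sidecar metadata.

Two-photon movies are stored either as multipage grayscale TIFF stacks or as
HDF5 files holding a single 3-D dataset with axis order (t, y, x).  Reads are
block-wise and on demand, so a full recording never has to fit in memory.

Derived data (event tables, masks, traces, configuration) are persisted in a
*sidecar store*: a hidden folder next to the imaging file holding one file per
key.  On first write the store mints a UUID so that data moved on disk can be
re-identified.
"""

from __future__ import annotations

import json
import logging
import uuid as _uuidlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("roakit")

#: name of the 3-D dataset inside roakit-written HDF5 movie files
HDF5_DATASET = "movie"

SUPPORTED_DTYPES = ("uint8", "uint16", "float32")


class FormatError(ValueError):
    """File exists but is not a readable movie in a supported format."""


class DimensionalityError(FormatError):
    """Image data are not a 3-D (t, y, x) stack."""


class BoundsError(IndexError):
    """Requested frame interval falls outside the movie (or is empty)."""


class MissingKeyError(KeyError):
    """Sidecar read of a key that was never written."""


class CollisionError(FileExistsError):
    """Output path exists and overwrite was not requested."""


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieMeta:
    """Acquisition context of a movie.

    frame_rate is in Hz and pixel_size in micrometres per pixel; both default
    to 1.0 (nominal units) when the file carries no calibration, in which case
    per-second / per-µm² outputs are nominal rather than physical.
    """

    n_frames: int
    height: int
    width: int
    frame_rate: float = 1.0
    pixel_size: float = 1.0
    channel: int = 0
    dtype_kind: str = "u"
    nominal_units: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"movie needs >= 2 frames, got {self.n_frames}")
        if self.height * self.width < 1:
            raise ValueError("empty field of view")
        if not (self.frame_rate > 0 and self.pixel_size > 0):
            raise ValueError("frame_rate and pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.height, self.width)

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames, "height": self.height,
            "width": self.width, "frame_rate": self.frame_rate,
            "pixel_size": self.pixel_size, "channel": self.channel,
            "dtype_kind": self.dtype_kind, "nominal_units": self.nominal_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MovieMeta":
        return cls(**d)


# ---------------------------------------------------------------------------
# Movie sources
# ---------------------------------------------------------------------------

@dataclass
class MovieSource:
    """Handle to an on-disk movie; all pixel access goes through read_block."""

    uri: Path
    meta: MovieMeta
    backing: str  # "tiff" | "hdf5"

    def read(self, t_start: int, t_stop: int) -> np.ndarray:
        return read_block(self, t_start, t_stop)

    def iter_chunks(self, chunk_frames: int) -> Iterator[tuple[int, int]]:
        """Yield half-open (t_start, t_stop) intervals covering the movie."""
        if chunk_frames < 1:
            raise ValueError("chunk_frames must be >= 1")
        t = 0
        while t < self.meta.n_frames:
            stop = min(t + chunk_frames, self.meta.n_frames)
            yield t, stop
            t = stop


def _tiff_meta(path: Path) -> MovieMeta:
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        shape = series.shape
        if len(shape) == 2:
            raise DimensionalityError(f"{path}: single 2-D image, not a stack")
        if len(shape) != 3:
            raise DimensionalityError(f"{path}: expected (t, y, x), got shape {shape}")
        n_frames, height, width = shape
        frame_rate = pixel_size = None
        ij = tf.imagej_metadata or {}
        finterval = ij.get("finterval")
        if finterval:
            frame_rate = 1.0 / float(finterval)
        elif ij.get("fps"):
            frame_rate = float(ij["fps"])
        page = tf.pages[0]
        if "XResolution" in page.tags and ij.get("unit") in ("um", "micron", "µm"):
            num, den = page.tags["XResolution"].value
            if num:
                pixel_size = den / num
        nominal = frame_rate is None or pixel_size is None
        if nominal:
            logger.warning("%s: missing frame_rate/pixel_size; defaulting to 1.0 "
                           "(outputs in nominal units)", path)
        return MovieMeta(
            n_frames=n_frames, height=height, width=width,
            frame_rate=frame_rate or 1.0, pixel_size=pixel_size or 1.0,
            dtype_kind=np.dtype(series.dtype).kind, nominal_units=nominal,
        )


def _hdf5_dataset_name(f: h5py.File) -> str:
    if HDF5_DATASET in f:
        return HDF5_DATASET
    names = [k for k in f.keys() if isinstance(f[k], h5py.Dataset) and f[k].ndim == 3]
    if not names:
        raise FormatError(f"{f.filename}: no 3-D dataset found")
    return names[0]


def _hdf5_meta(path: Path) -> MovieMeta:
    with h5py.File(path, "r") as f:
        ds = f[_hdf5_dataset_name(f)]
        if ds.ndim != 3:
            raise DimensionalityError(f"{path}: dataset is {ds.ndim}-D, expected 3-D")
        frame_rate = ds.attrs.get("frame_rate")
        pixel_size = ds.attrs.get("pixel_size_um")
        nominal = frame_rate is None or pixel_size is None
        if nominal:
            logger.warning("%s: missing frame_rate/pixel_size_um attrs; "
                           "defaulting to 1.0 (nominal units)", path)
        return MovieMeta(
            n_frames=ds.shape[0], height=ds.shape[1], width=ds.shape[2],
            frame_rate=float(frame_rate) if frame_rate is not None else 1.0,
            pixel_size=float(pixel_size) if pixel_size is not None else 1.0,
            channel=int(ds.attrs.get("channel", 0)),
            dtype_kind=ds.dtype.kind, nominal_units=nominal,
        )


def open_movie(path: str | Path) -> MovieSource:
    """Open a multipage TIFF or HDF5 movie for lazy block reads."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        return MovieSource(uri=path, meta=_hdf5_meta(path), backing="hdf5")
    try:
        return MovieSource(uri=path, meta=_tiff_meta(path), backing="tiff")
    except DimensionalityError:
        raise
    except Exception as exc:  # tifffile raises a zoo of exceptions on junk input
        raise FormatError(f"{path}: not a readable TIFF or HDF5 movie ({exc})") from exc


def read_block(src: MovieSource, t_start: int, t_stop: int) -> np.ndarray:
    """Read frames [t_start, t_stop) as a (t, y, x) array of stored values."""
    n = src.meta.n_frames
    if not (0 <= t_start < t_stop <= n):
        raise BoundsError(
            f"frame interval [{t_start}, {t_stop}) invalid for movie of {n} frames")
    if src.backing == "hdf5":
        with h5py.File(src.uri, "r") as f:
            block = f[_hdf5_dataset_name(f)][t_start:t_stop]
    else:
        with tifffile.TiffFile(src.uri) as tf:
            block = tf.series[0].asarray(key=range(t_start, t_stop))
            if block.ndim == 2:  # single page collapses
                block = block[None]
    return np.asarray(block)


def write_movie(path: str | Path, data: np.ndarray, meta: MovieMeta,
                overwrite: bool = False, chunk_frames: int = 256) -> MovieSource:
    """Write a (t, y, x) array to TIFF (.tif) or HDF5 (.h5) with metadata."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise CollisionError(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise DimensionalityError(f"expected (t, y, x) array, got {data.shape}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(
                HDF5_DATASET, data=data,
                chunks=(min(chunk_frames, data.shape[0]), data.shape[1], data.shape[2]))
            ds.attrs["frame_rate"] = meta.frame_rate
            ds.attrs["pixel_size_um"] = meta.pixel_size
            ds.attrs["channel"] = meta.channel
        backing = "hdf5"
    else:
        res = 1.0 / meta.pixel_size
        tifffile.imwrite(
            path, data, imagej=True, resolution=(res, res),
            metadata={"finterval": 1.0 / meta.frame_rate, "unit": "um",
                      "axes": "TYX"})
        backing = "tiff"
    return MovieSource(uri=path, meta=replace(meta, dtype_kind=data.dtype.kind),
                       backing=backing)


def convert_movie(src: MovieSource, out_path: str | Path, chunk_frames: int = 256,
                  overwrite: bool = False) -> MovieSource:
    """Convert any movie source to a time-chunked HDF5 file, voxel for voxel."""
    if chunk_frames < 1:
        raise ValueError("chunk_frames must be >= 1")
    out_path = Path(out_path)
    if out_path.exists() and not overwrite:
        raise CollisionError(out_path)
    meta = src.meta
    first = src.read(0, min(chunk_frames, meta.n_frames))
    with h5py.File(out_path, "w") as f:
        ds = f.create_dataset(
            HDF5_DATASET, shape=meta.shape, dtype=first.dtype,
            chunks=(min(chunk_frames, meta.n_frames), meta.height, meta.width))
        ds[: first.shape[0]] = first
        for t0, t1 in src.iter_chunks(chunk_frames):
            if t0 == 0:
                continue
            ds[t0:t1] = src.read(t0, t1)
        ds.attrs["frame_rate"] = meta.frame_rate
        ds.attrs["pixel_size_um"] = meta.pixel_size
        ds.attrs["channel"] = meta.channel
    return MovieSource(uri=out_path, meta=meta, backing="hdf5")


# ---------------------------------------------------------------------------
# Sidecar metadata store
# ---------------------------------------------------------------------------

_UUID_FILE = "_uuid.json"


@dataclass
class SidecarStore:
    """Per-movie key/value store in a hidden folder next to the data.

    One file per key: ndarray -> .npy, DataFrame -> .parquet, anything JSON
    serializable -> .json.  ``engine="off-path"`` keeps the payload under a
    user-chosen root keyed by the store's UUID, with only a small UUID marker
    next to the data.
    """

    data_path: Path
    engine: str = "on-path"
    root: Path | None = None

    def __post_init__(self) -> None:
        self.data_path = Path(self.data_path)
        if self.engine not in ("on-path", "off-path"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "off-path" and self.root is None:
            raise ValueError("off-path engine needs a root directory")

    @property
    def _marker_dir(self) -> Path:
        return self.data_path.parent / f".{self.data_path.name}.meta"

    def _payload_dir(self, create: bool = False) -> Path:
        if self.engine == "on-path":
            d = self._marker_dir
        else:
            d = Path(self.root) / self.uuid if create or self._uuid_path().exists() \
                else None
            if d is None:
                raise MissingKeyError("store never written")
        if create:
            d.mkdir(parents=True, exist_ok=True)
        return d

    def _uuid_path(self) -> Path:
        return self._marker_dir / _UUID_FILE

    @property
    def uuid(self) -> str:
        """Persistent identifier; minted on first use."""
        p = self._uuid_path()
        if p.exists():
            return json.loads(p.read_text())["uuid"]
        self._marker_dir.mkdir(parents=True, exist_ok=True)
        uid = str(_uuidlib.uuid4())
        p.write_text(json.dumps({"uuid": uid, "data_name": self.data_path.name}))
        return uid

    def put(self, key: str, value: Any) -> Any:
        if not key:
            raise ValueError("key must be non-empty")
        _ = self.uuid  # first write mints the UUID
        d = self._payload_dir(create=True)
        for old in d.glob(f"{key}.*"):
            if old.stem == key:
                old.unlink()
        if isinstance(value, np.ndarray):
            np.save(d / f"{key}.npy", value)
        elif isinstance(value, pd.DataFrame):
            value.to_parquet(d / f"{key}.parquet")
        else:
            (d / f"{key}.json").write_text(json.dumps(value))
        return value

    def get(self, key: str) -> Any:
        if not key:
            raise ValueError("key must be non-empty")
        try:
            d = self._payload_dir()
        except MissingKeyError:
            raise MissingKeyError(key)
        for suffix, loader in ((".npy", lambda p: np.load(p, allow_pickle=False)),
                               (".parquet", pd.read_parquet),
                               (".json", lambda p: json.loads(p.read_text()))):
            p = d / f"{key}{suffix}"
            if p.exists():
                return loader(p)
        raise MissingKeyError(key)

    def keys(self) -> list[str]:
        try:
            d = self._payload_dir()
        except MissingKeyError:
            return []
        if not d.exists():
            return []
        return sorted({p.stem for p in d.iterdir()
                       if p.suffix in (".npy", ".parquet", ".json")
                       and p.name != _UUID_FILE})

    def has(self, key: str) -> bool:
        return key in self.keys()


def sidecar(store: SidecarStore, key: str, value: Any = None) -> Any:
    """Write ``value`` under ``key`` if given, else read ``key`` back."""
    if value is not None:
        return store.put(key, value)
    return store.get(key)


def find_by_uuid(search_root: str | Path, uid: str) -> SidecarStore | None:
    """Locate a (possibly moved) on-path store by its persistent UUID."""
    for p in Path(search_root).rglob(_UUID_FILE):
        try:
            rec = json.loads(p.read_text())
        except (OSError, json.JSONDecodeError):
            continue
        if rec.get("uuid") == uid:
            meta_dir = p.parent
            data_path = meta_dir.parent / meta_dir.name[1:].removesuffix(".meta")
            return SidecarStore(data_path)
    return None
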