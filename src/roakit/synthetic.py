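"""Ground-truth movie simulator and detector scoring.

The simulator emulates high-frame-rate (~30 Hz) two-photon recordings: pixel
values are drawn with mean E and variance a·E + b, realized as
a·Poisson(E/a) + Normal(0, √b), which reproduces both the linear
mean–variance relation of PMT-amplified data and the zero-inflated,
right-skewed raw histograms seen at low photon counts.  Sparse Ca²⁺-like
events are planted as disc footprints with trapezoidal temporal profiles
(2-frame linear rise and decay), with radii and durations drawn from bounded
power laws, as astrocytic event sizes and durations are in reality.

Every planted event is recorded in a :class:`GroundTruth` object (voxel sets
plus the noiseless expectation movie) so that detections can be scored by
greedy IoU matching into precision and recall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .movie_io import MovieMeta, MovieSource, write_movie

logger = logging.getLogger("roakit")

RAMP_FRAMES = 2


class SpecError(ValueError):
    """Event specification impossible for the requested geometry."""


@dataclass
class SynthParams:
    """Simulation parameters.

    ``baseline`` is the expected photon count E per pixel (scalar or (H, W)
    map); ``gain_a``/``offset_b`` set the noise law Var = a·E + b.
    ``amplitude_sd`` scales event amplitude in multiples of the local
    baseline SD √(a·E + b), so an amplitude of A raises the sqrt-transformed
    trace by ≈ A noise SDs.  Radius (px) and duration (frames) are drawn
    from power laws with the given exponents, truncated to the given bounds.
    """

    shape: tuple[int, int, int] = (900, 64, 64)
    frame_rate: float = 30.0
    pixel_size: float = 1.0
    baseline: float | np.ndarray = 60.0
    gain_a: float = 2.0
    offset_b: float = 5.0
    event_rate_per_min: float = 30.0
    amplitude_sd: float = 8.0
    radius_bounds: tuple[float, float] = (2.0, 6.0)
    radius_exponent: float = 2.0
    duration_bounds: tuple[int, int] = (5, 40)
    duration_exponent: float = 2.0
    dtype: str = "uint16"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.gain_a > 0 or self.offset_b < 0:
            raise ValueError("need gain a > 0 and offset b >= 0")
        if np.any(np.asarray(self.baseline) < 0):
            raise ValueError("baseline expectation must be >= 0")
        if self.event_rate_per_min > 0:
            if 2 * self.radius_bounds[1] + 1 > min(self.shape[1:]):
                raise SpecError("largest event footprint exceeds the field "
                                "of view")
            if self.duration_bounds[1] > self.shape[0]:
                raise SpecError("longest event exceeds the movie length")

    @property
    def meta(self) -> MovieMeta:
        T, H, W = self.shape
        return MovieMeta(n_frames=T, height=H, width=W,
                         frame_rate=self.frame_rate, pixel_size=self.pixel_size,
                         dtype_kind=np.dtype(self.dtype).kind)

    def baseline_map(self) -> np.ndarray:
        _, H, W = self.shape
        return np.broadcast_to(np.asarray(self.baseline, dtype=np.float64),
                               (H, W)).copy()


@dataclass
class TruthEvent:
    """One planted event: disc footprint × contiguous frame interval."""

    id: int
    onset: int
    duration: int
    center: tuple[float, float]   # (y, x)
    radius: float
    amplitude: float              # ΔE at plateau, raw gray-value units

    t_idx: np.ndarray = field(default=None, repr=False)
    y_idx: np.ndarray = field(default=None, repr=False)
    x_idx: np.ndarray = field(default=None, repr=False)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return set(zip(self.t_idx.tolist(), self.y_idx.tolist(),
                       self.x_idx.tolist()))


@dataclass
class GroundTruth:
    """Planted events plus the noiseless expectation movie E(t, y, x)."""

    events: list[TruthEvent]
    expectation: np.ndarray | None = None  # may be omitted for huge movies

    def voxel_labels(self, shape: tuple[int, int, int]) -> np.ndarray:
        lab = np.zeros(shape, dtype=np.int32)
        for ev in self.events:
            lab[ev.t_idx, ev.y_idx, ev.x_idx] = ev.id
        return lab

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = [{"id": ev.id, "onset": ev.onset, "duration": ev.duration,
                    "center": list(ev.center), "radius": ev.radius,
                    "amplitude": ev.amplitude,
                    "t": ev.t_idx.tolist(), "y": ev.y_idx.tolist(),
                    "x": ev.x_idx.tolist()}
                   for ev in self.events]
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        events = []
        for d in json.loads(Path(path).read_text()):
            events.append(TruthEvent(
                id=d["id"], onset=d["onset"], duration=d["duration"],
                center=tuple(d["center"]), radius=d["radius"],
                amplitude=d["amplitude"],
                t_idx=np.asarray(d["t"]), y_idx=np.asarray(d["y"]),
                x_idx=np.asarray(d["x"])))
        return cls(events=events)


def _bounded_power_law(rng: np.random.Generator, lo: float, hi: float,
                       exponent: float, size: int) -> np.ndarray:
    """Draw from p(x) ∝ x^(−exponent) truncated to [lo, hi] (inverse CDF)."""
    u = rng.random(size)
    if hi <= lo:
        return np.full(size, lo)
    if abs(exponent - 1.0) < 1e-9:
        return lo * (hi / lo) ** u
    g = 1.0 - exponent
    return (u * (hi ** g - lo ** g) + lo ** g) ** (1.0 / g)


def _trapezoid(duration: int) -> np.ndarray:
    """Amplitude fractions: linear 2-frame rise, plateau, 2-frame decay."""
    k = np.arange(duration)
    return np.minimum.reduce([np.ones(duration),
                              (k + 1) / (RAMP_FRAMES + 1),
                              (duration - k) / (RAMP_FRAMES + 1)])


def _draw_events(params: SynthParams, rng: np.random.Generator,
                 base: np.ndarray) -> list[TruthEvent]:
    T, H, W = params.shape
    minutes = T / params.frame_rate / 60.0
    n = rng.poisson(params.event_rate_per_min * minutes)
    r_lo, r_hi = params.radius_bounds
    d_lo, d_hi = params.duration_bounds
    radii = _bounded_power_law(rng, r_lo, r_hi, params.radius_exponent, n)
    durations = np.round(_bounded_power_law(
        rng, d_lo, d_hi, params.duration_exponent, n)).astype(int)
    events: list[TruthEvent] = []
    for i in range(n):
        r = float(radii[i])
        d = int(np.clip(durations[i], 1, T))
        margin = int(np.ceil(r))
        cy = rng.uniform(margin, H - 1 - margin)
        cx = rng.uniform(margin, W - 1 - margin)
        onset = int(rng.integers(0, max(T - d, 0) + 1))
        yy, xx = np.mgrid[0:H, 0:W]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        fy, fx = np.nonzero(disc)
        e0 = float(base[int(round(cy)), int(round(cx))])
        amp = params.amplitude_sd * np.sqrt(params.gain_a * e0 + params.offset_b)
        # ground-truth extent follows the FWHM convention: frames at >= half
        # the plateau amplitude (ramp tails below half max are sub-threshold
        # for any sensible detector and are not part of the scored event)
        frames = onset + np.nonzero(_trapezoid(d) >= 0.5)[0]
        tt = np.repeat(frames, fy.size)
        events.append(TruthEvent(
            id=i + 1, onset=onset, duration=d, center=(cy, cx), radius=r,
            amplitude=float(amp),
            t_idx=tt, y_idx=np.tile(fy, frames.size),
            x_idx=np.tile(fx, frames.size)))
    return events


def _expectation_chunk(params: SynthParams, base: np.ndarray,
                       events: list[TruthEvent], t0: int, t1: int
                       ) -> np.ndarray:
    E = np.broadcast_to(base, (t1 - t0,) + base.shape).copy()
    for ev in events:
        a, b = max(ev.onset, t0), min(ev.onset + ev.duration, t1)
        if a >= b:
            continue
        profile = _trapezoid(ev.duration)
        n_truth_frames = np.unique(ev.t_idx).size
        foot = ev.y_idx.size // n_truth_frames
        fy, fx = ev.y_idx[:foot], ev.x_idx[:foot]
        for t in range(a, b):
            E[t - t0, fy, fx] += ev.amplitude * profile[t - ev.onset]
    return E


def _noise_chunk(E: np.ndarray, params: SynthParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw gray values with mean E and variance a·E + b, then clip and
    quantize."""
    a, b = params.gain_a, params.offset_b
    z = a * rng.poisson(E / a).astype(np.float64)
    if b > 0:
        z += rng.normal(0.0, np.sqrt(b), size=E.shape)
    z = np.clip(z, 0.0, None)
    dt = np.dtype(params.dtype)
    if dt.kind in "ui":
        z = np.clip(np.rint(z), 0, np.iinfo(dt).max)
    return z.astype(dt)


def simulate_movie(params: SynthParams, out_path: str | Path | None = None,
                   chunk_frames: int = 256
                   ) -> tuple[np.ndarray | MovieSource, GroundTruth]:
    """Simulate a movie with planted events; reproducible for a fixed seed.

    Returns the movie as an in-memory (t, y, x) array, or as a lazily
    readable :class:`MovieSource` when ``out_path`` (TIFF/HDF5) is given, in
    which case the expectation movie is not kept.
    """
    rng = np.random.default_rng(params.seed)
    base = params.baseline_map()
    events = _draw_events(params, rng, base) if params.event_rate_per_min > 0 \
        else []
    T, H, W = params.shape
    keep_expectation = out_path is None
    if keep_expectation:
        movie = np.empty(params.shape, dtype=params.dtype)
        expectation = np.empty(params.shape, dtype=np.float32)
        for t0 in range(0, T, chunk_frames):
            t1 = min(t0 + chunk_frames, T)
            E = _expectation_chunk(params, base, events, t0, t1)
            expectation[t0:t1] = E
            movie[t0:t1] = _noise_chunk(E, params, rng)
        return movie, GroundTruth(events=events, expectation=expectation)
    out_path = Path(out_path)
    import h5py

    from .movie_io import HDF5_DATASET
    if out_path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(out_path, "w") as f:
            ds = f.create_dataset(HDF5_DATASET, shape=params.shape,
                                  dtype=params.dtype,
                                  chunks=(min(chunk_frames, T), H, W))
            for t0 in range(0, T, chunk_frames):
                t1 = min(t0 + chunk_frames, T)
                E = _expectation_chunk(params, base, events, t0, t1)
                ds[t0:t1] = _noise_chunk(E, params, rng)
            ds.attrs["frame_rate"] = params.frame_rate
            ds.attrs["pixel_size_um"] = params.pixel_size
            ds.attrs["channel"] = 0
        src = MovieSource(uri=out_path, meta=params.meta, backing="hdf5")
    else:
        movie = np.empty(params.shape, dtype=params.dtype)
        for t0 in range(0, T, chunk_frames):
            t1 = min(t0 + chunk_frames, T)
            E = _expectation_chunk(params, base, events, t0, t1)
            movie[t0:t1] = _noise_chunk(E, params, rng)
        src = write_movie(out_path, movie, params.meta, overwrite=True)
    return src, GroundTruth(events=events, expectation=None)


def simulate_noise_only(params: SynthParams,
                        out_path: str | Path | None = None,
                        chunk_frames: int = 256):
    """Event-free movie: :func:`simulate_movie` with the rate forced to 0."""
    movie, _ = simulate_movie(replace(params, event_rate_per_min=0.0),
                              out_path=out_path, chunk_frames=chunk_frames)
    return movie


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    precision: float
    recall: float
    n_detected: int
    n_truth: int
    pairs: list[tuple[int, int, float]]   # (detected id, truth id, IoU)
    precision_undefined: bool = False


def match_events(detected_labels: np.ndarray, truth: GroundTruth,
                 iou_min: float = 0.3,
                 ignore_mask: np.ndarray | None = None) -> MatchResult:
    """Greedy one-to-one matching of detected events to planted events by
    descending voxel IoU; pairs with IoU >= iou_min count as hits.

    precision = hits / detected, recall = hits / truth.  With no detections
    and non-empty truth, precision is reported as 0 and flagged undefined.
    ``ignore_mask`` restricts scoring to the analyzed region: voxels on
    ignored pixels are removed from both detected and truth sets, and truth
    events left without voxels do not count toward recall (a detector cannot
    be asked to find events in regions it was configured to ignore).
    """
    detected_labels = np.asarray(detected_labels)
    truth_lab = truth.voxel_labels(detected_labels.shape)
    if ignore_mask is not None:
        keep2d = ~np.asarray(ignore_mask, dtype=bool)
        detected_labels = detected_labels * keep2d[None, :, :]
        truth_lab = truth_lab * keep2d[None, :, :]
    det_ids, det_sizes = np.unique(detected_labels[detected_labels > 0],
                                   return_counts=True)
    tru_ids, tru_counts = np.unique(truth_lab[truth_lab > 0],
                                    return_counts=True)
    tru_sizes = dict(zip(tru_ids.tolist(), tru_counts.tolist()))
    n_det, n_tru = det_ids.size, tru_ids.size
    if n_det == 0 or n_tru == 0:
        return MatchResult(
            precision=0.0 if n_tru else 1.0, recall=0.0 if n_tru else 1.0,
            n_detected=int(n_det), n_truth=int(n_tru), pairs=[],
            precision_undefined=n_det == 0 and n_tru > 0)
    both = (detected_labels > 0) & (truth_lab > 0)
    pairs_d = detected_labels[both].astype(np.int64)
    pairs_t = truth_lab[both].astype(np.int64)
    key = pairs_d * (truth_lab.max() + 1) + pairs_t
    uk, inter = np.unique(key, return_counts=True)
    d_of = (uk // (truth_lab.max() + 1)).astype(int)
    t_of = (uk % (truth_lab.max() + 1)).astype(int)
    size_d = dict(zip(det_ids.tolist(), det_sizes.tolist()))
    cand = []
    for d, t, ov in zip(d_of, t_of, inter):
        iou = ov / (size_d[d] + tru_sizes[t] - ov)
        cand.append((float(iou), int(d), int(t)))
    cand.sort(reverse=True)
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for iou, d, t in cand:
        if iou < iou_min:
            break
        if d in used_d or t in used_t:
            continue
        used_d.add(d)
        used_t.add(t)
        pairs.append((d, t, iou))
    hits = len(pairs)
    return MatchResult(precision=hits / n_det, recall=hits / n_tru,
                       n_detected=int(n_det), n_truth=int(n_tru), pairs=pairs)
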