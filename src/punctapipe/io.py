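"""Image, trace and table I/O, plus the coordinate conventions of the pipeline.

Conventions used everywhere in this package:

* pixel indices are 0-based; ``x`` runs along columns, ``y`` along rows,
  with ``y`` increasing downward (image convention);
* the centre of pixel ``(row, col)`` sits at
  ``x = (col + 0.5) * pixel_size``, ``y = (row + 0.5) * pixel_size``
  in micrometres;
* every physical quantity (areas, distances, arc lengths, densities)
  derives from this single mapping.

Calibration (µm/pixel) is supplied out-of-band rather than parsed from TIFF
tags, whose dialects are unreliable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelImage",
    "ProcessTraces",
    "PUNCTUM_COLUMNS",
    "TRACE_COLUMNS",
    "read_channel_image",
    "write_channel_image",
    "read_traces",
    "write_traces",
    "write_punctum_table",
    "read_punctum_table",
    "write_keyvalue",
    "read_keyvalue",
    "point_segment_distance",
]

FLOAT_FORMAT = "%.9g"  # fixed everywhere so writers are byte-deterministic

TRACE_COLUMNS = ["process_id", "vertex_index", "x_um", "y_um"]

PUNCTUM_COLUMNS = [
    "punctum_id",
    "image_id",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "distance_um",
    "process_id",
    "mean_marker",
    "mean_signal",
    "signal_over_marker",
]


# ---------------------------------------------------------------------------
# geometry helpers (shared by rasterization, detection and quantification)
# ---------------------------------------------------------------------------

def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distances from each point to each segment ``a[j]->b[j]``.

    Parameters
    ----------
    points : (n, 2) array
    a, b : (m, 2) arrays of segment endpoints

    Returns
    -------
    dist : (n, m) array of Euclidean distances
    t : (n, m) array of clamped projection parameters in [0, 1]
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ab = b - a                                     # (m, 2)
    denom = (ab ** 2).sum(axis=1)                  # (m,)
    safe = np.where(denom == 0.0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]        # (n, m, 2)
    t = (ap * ab[None, :, :]).sum(axis=-1) / safe[None, :]
    t = np.where(denom[None, :] == 0.0, 0.0, np.clip(t, 0.0, 1.0))
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - proj, axis=-1)
    return dist, t


# ---------------------------------------------------------------------------
# ChannelImage
# ---------------------------------------------------------------------------

@dataclass
class ChannelImage:
    """A single-channel 2-D intensity grid with pixel-size calibration.

    ``pixels`` keeps the dtype it was constructed with (integer TIFF data
    stays integer, simulated data stays float32); computations cast to float
    internally.
    """

    pixels: np.ndarray
    pixel_size: float  # µm per pixel
    channel_label: str = ""
    source_dtype: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"expected a 2-D single-channel image, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("empty image (zero-size grid)")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        arr = self.pixels
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)):
                raise ValueError("image contains non-finite intensities")
        elif not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"unsupported image dtype {arr.dtype}")
        if arr.min() < 0:
            raise ValueError("image contains negative intensities")
        if not self.source_dtype:
            self.source_dtype = str(arr.dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in µm."""
        rows, cols = self.pixels.shape
        return cols * self.pixel_size, rows * self.pixel_size

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64, copy=False)


def read_channel_image(path, pixel_size: float, channel_label: str = "") -> ChannelImage:
    """Load a single-channel 2-D TIFF with the stated µm/pixel calibration."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    return ChannelImage(arr, pixel_size, channel_label, source_dtype=str(arr.dtype))


def write_channel_image(img: ChannelImage, path) -> None:
    tifffile.imwrite(path, img.pixels)


# ---------------------------------------------------------------------------
# ProcessTraces
# ---------------------------------------------------------------------------

@dataclass
class ProcessTraces:
    """Neuronal-process geometry: polylines (µm) and a rasterized mask.

    A polyline is an ``(n, 2)`` array of ``[x_um, y_um]`` vertices.  The mask
    marks every pixel whose centre lies within ``pixel_size / 2`` of a line.
    """

    polylines: list
    pixel_size: float
    image_shape: tuple[int, int]
    _mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"invalid (zero-area) image shape {self.image_shape}")
        clean = []
        w, h = cols * self.pixel_size, rows * self.pixel_size
        for k, poly in enumerate(self.polylines):
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError(f"polyline {k}: expected an (n, 2) array")
            if poly.shape[0] < 2:
                raise ValueError(f"polyline {k}: fewer than 2 vertices")
            if (poly[:, 0].min() < 0 or poly[:, 0].max() > w
                    or poly[:, 1].min() < 0 or poly[:, 1].max() > h):
                raise ValueError(f"polyline {k}: vertex outside the image bounds")
            clean.append(poly)
        self.polylines = clean

    # -- basic geometry ----------------------------------------------------

    @property
    def n_processes(self) -> int:
        return len(self.polylines)

    def lengths(self) -> np.ndarray:
        """Arc length of each polyline in µm."""
        return np.array(
            [np.linalg.norm(np.diff(p, axis=0), axis=1).sum() for p in self.polylines]
        )

    @property
    def total_length(self) -> float:
        return float(self.lengths().sum()) if self.polylines else 0.0

    def _segments(self):
        """All segments stacked: (A, B, seg_process, seg_arc_start)."""
        A, B, pid, s0 = [], [], [], []
        for k, poly in enumerate(self.polylines):
            seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            starts = np.concatenate([[0.0], np.cumsum(seg_len)[:-1]])
            A.append(poly[:-1])
            B.append(poly[1:])
            pid.append(np.full(len(seg_len), k))
            s0.append(starts)
        if not A:
            return (np.empty((0, 2)), np.empty((0, 2)),
                    np.empty(0, dtype=int), np.empty(0))
        return (np.concatenate(A), np.concatenate(B),
                np.concatenate(pid), np.concatenate(s0))

    def min_distance(self, points: np.ndarray):
        """Minimum distance (µm) from each point to any polyline.

        Returns ``(dist, process_id)`` arrays; with no polylines, distances
        are ``+inf`` and process ids ``-1``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = points.shape[0]
        A, B, pid, _ = self._segments()
        if len(A) == 0:
            return np.full(n, np.inf), np.full(n, -1, dtype=int)
        dist = np.empty((n, len(A)))
        step = max(1, int(2e6 // max(len(A), 1)))  # bound temporary memory
        for i in range(0, n, step):
            dist[i:i + step], _ = point_segment_distance(points[i:i + step], A, B)
        j = dist.argmin(axis=1)
        return dist[np.arange(n), j], pid[j]

    def arc_position(self, points: np.ndarray, process_id: int) -> np.ndarray:
        """Arc-length position (µm) of the closest point on one polyline."""
        poly = self.polylines[process_id]
        dist, t = point_segment_distance(points, poly[:-1], poly[1:])
        seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        starts = np.concatenate([[0.0], np.cumsum(seg_len)[:-1]])
        j = dist.argmin(axis=1)
        return starts[j] + t[np.arange(len(j)), j] * seg_len[j]

    def point_at(self, process_id: int, s: np.ndarray) -> np.ndarray:
        """Interpolated (x, y) µm coordinates at arc positions ``s``."""
        poly = self.polylines[process_id]
        seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
        j = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
        denom = np.where(seg_len[j] == 0, 1.0, seg_len[j])
        t = (s - cum[j]) / denom
        return poly[j] + t[:, None] * (poly[j + 1] - poly[j])

    # -- rasterization -----------------------------------------------------

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid: pixel centres within ``pixel_size/2`` of a line."""
        if self._mask is None:
            self._mask = self._rasterize()
        return self._mask

    def _rasterize(self) -> np.ndarray:
        rows, cols = self.image_shape
        ps = self.pixel_size
        out = np.zeros((rows, cols), dtype=bool)
        reach = 0.5 * ps
        for poly in self.polylines:
            for a, b in zip(poly[:-1], poly[1:]):
                lo_x, hi_x = min(a[0], b[0]) - reach, max(a[0], b[0]) + reach
                lo_y, hi_y = min(a[1], b[1]) - reach, max(a[1], b[1]) + reach
                c0 = max(int(np.floor(lo_x / ps - 0.5)), 0)
                c1 = min(int(np.ceil(hi_x / ps - 0.5)) + 1, cols)
                r0 = max(int(np.floor(lo_y / ps - 0.5)), 0)
                r1 = min(int(np.ceil(hi_y / ps - 0.5)) + 1, rows)
                if c0 >= c1 or r0 >= r1:
                    continue
                cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
                pts = np.column_stack([(cc.ravel() + 0.5) * ps,
                                       (rr.ravel() + 0.5) * ps])
                d, _ = point_segment_distance(pts, a[None, :], b[None, :])
                hit = (d[:, 0] <= reach).reshape(rr.shape)
                out[r0:r1, c0:c1] |= hit
        return out


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

_MASK_SUFFIXES = {".tif", ".tiff", ".png"}


def read_traces(path, pixel_size: float, image_shape=None) -> ProcessTraces:
    """Read process traces from a polyline CSV or a binary mask image.

    The CSV schema is ``process_id, vertex_index, x_um, y_um``.  A mask image
    is skeletonized and traced back to polylines so both representations are
    always populated.
    """
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()
    if suffix in _MASK_SUFFIXES:
        if suffix == ".png":
            import imageio.v3 as iio
            mask = np.asarray(iio.imread(path))
        else:
            mask = tifffile.imread(path)
        if mask.ndim != 2:
            raise ValueError(f"{path}: mask must be 2-D, got shape {mask.shape}")
        polylines = _mask_to_polylines(mask > 0, pixel_size)
        return ProcessTraces(polylines, pixel_size, mask.shape)

    if os.path.getsize(path) == 0:
        if image_shape is None:
            raise ValueError("image_shape is required for empty trace files")
        return ProcessTraces([], pixel_size, image_shape)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trace columns {missing}")
    polylines = []
    for pid, grp in df.groupby("process_id", sort=True):
        grp = grp.sort_values("vertex_index")
        poly = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        if poly.shape[0] < 2:
            raise ValueError(f"{path}: process {pid} has fewer than 2 vertices")
        polylines.append(poly)
    if image_shape is None:
        # minimal enclosing grid if the caller supplies no shape
        w = max(p[:, 0].max() for p in polylines)
        h = max(p[:, 1].max() for p in polylines)
        image_shape = (int(np.ceil(h / pixel_size)) + 1,
                       int(np.ceil(w / pixel_size)) + 1)
    return ProcessTraces(polylines, pixel_size, tuple(image_shape))


def write_traces(traces: ProcessTraces, path) -> None:
    rows = []
    for pid, poly in enumerate(traces.polylines):
        for vi, (x, y) in enumerate(poly):
            rows.append((pid, vi, x, y))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _mask_to_polylines(mask: np.ndarray, pixel_size: float) -> list:
    """Trace a binary mask: skeletonize, then walk skeleton paths."""
    from skimage.morphology import skeletonize

    skel = skeletonize(mask)
    coords = {tuple(rc) for rc in np.argwhere(skel)}
    if not coords:
        return []
    nbrs = {}
    for (r, c) in coords:
        nbrs[(r, c)] = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in coords
        ]
    visited_edges = set()
    polylines = []

    def walk(start, first):
        """Follow a path from `start` through `first` until a junction/end."""
        path = [start, first]
        visited_edges.add((start, first))
        visited_edges.add((first, start))
        prev, cur = start, first
        while len(nbrs[cur]) == 2:
            nxt = nbrs[cur][0] if nbrs[cur][0] != prev else nbrs[cur][1]
            if (cur, nxt) in visited_edges:
                break
            visited_edges.add((cur, nxt))
            visited_edges.add((nxt, cur))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    # start walks at endpoints and junctions first, then mop up cycles
    starts = [p for p in coords if len(nbrs[p]) != 2] or list(coords)
    for start in sorted(starts):
        for first in sorted(nbrs[start]):
            if (start, first) not in visited_edges:
                path = walk(start, first)
                if len(path) >= 2:
                    polylines.append(np.array(
                        [((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)
                         for (r, c) in path]))
    return polylines


# ---------------------------------------------------------------------------
# punctum tables and flat key-value files
# ---------------------------------------------------------------------------

def write_punctum_table(table, path) -> None:
    """Write a punctum table as CSV with the fixed column order."""
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    df = df.reindex(columns=PUNCTUM_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_punctum_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PUNCTUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing punctum columns {missing}")
    return df[PUNCTUM_COLUMNS]


def write_keyvalue(mapping: dict, path) -> None:
    """Write a flat ``key = value`` config/manifest file (sorted, stable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(mapping):
            fh.write(f"{key} = {mapping[key]}\n")


def read_keyvalue(path) -> dict:
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
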