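"""Presynaptic-site detection: normalize -> threshold -> label -> filter.

The segmentation runs on the presynaptic-marker (synaptophysin) channel:

1. linear normalization of the image to the [0, 255] range;
2. global threshold binarization (automatic inter-class-variance
   maximization over the 256-bin histogram, or a fixed value);
3. 8-connected component labeling;
4. filtering by component area (kept iff 0.35 µm² <= area <= 10 µm²) and by
   minimum distance to a traced neuronal process (kept iff <= 1 µm).

All filter bounds are inclusive.  Kept components become puncta whose mean
intensities are measured on the *raw* marker and signal channels, so that
between-condition intensity comparisons are not erased by the per-image
normalization used for detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import PUNCTUM_COLUMNS, ChannelImage, ProcessTraces

__all__ = [
    "DetectionParams",
    "Punctum",
    "PunctumTable",
    "DetectionLog",
    "normalize_image",
    "otsu_threshold",
    "threshold_value",
    "binarize",
    "label_components",
    "component_distance",
    "detect_puncta",
]

logger = logging.getLogger("punctapipe")

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionParams:
    """Segmentation parameters (defaults follow the published procedure)."""

    threshold_mode: str = "auto"          # {"auto", "fixed"}
    fixed_threshold: float | None = None  # on the normalized 0-255 scale
    connectivity: int = 8                 # fixed; kept explicit
    min_area: float = 0.35                # µm²
    max_area: float = 10.0                # µm²
    max_distance: float = 1.0             # µm
    distance_mode: str = "min_pixel"      # {"min_pixel", "centroid"}

    def __post_init__(self):
        if self.threshold_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None:
                raise ValueError("fixed threshold_mode requires fixed_threshold")
            if not 0.0 <= self.fixed_threshold <= 255.0:
                raise ValueError(
                    f"fixed_threshold must lie in [0, 255], got {self.fixed_threshold}")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity is supported")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not self.max_distance > 0:
            raise ValueError("max_distance must be > 0")
        if self.distance_mode not in ("min_pixel", "centroid"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


@dataclass
class Punctum:
    """One detected presynaptic site."""

    punctum_id: int
    image_id: str
    pixels: np.ndarray          # (k, 2) array of (row, col) indices
    area_um2: float
    centroid_um: tuple          # (x, y) µm
    distance_um: float
    process_id: int             # -1 when no traces
    mean_marker: float
    mean_signal: float

    @property
    def signal_over_marker(self) -> float:
        if self.mean_marker <= 0:
            return float("nan")
        return self.mean_signal / self.mean_marker


class PunctumTable:
    """Detected puncta of one image, with pixel sets kept in memory."""

    def __init__(self, puncta, image_id: str, pixel_size: float,
                 image_shape: tuple):
        self.puncta = list(puncta)
        self.image_id = image_id
        self.pixel_size = pixel_size
        self.image_shape = tuple(image_shape)

    def __len__(self):
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (p.punctum_id, p.image_id, p.centroid_um[0], p.centroid_um[1],
             p.area_um2, p.distance_um, p.process_id, p.mean_marker,
             p.mean_signal, p.signal_over_marker)
            for p in self.puncta
        ]
        return pd.DataFrame(rows, columns=PUNCTUM_COLUMNS)

    def label_image(self) -> np.ndarray:
        """Punctum-id-valued grid (0 = background, id+1 elsewhere)."""
        lab = np.zeros(self.image_shape, dtype=np.int32)
        for p in self.puncta:
            lab[p.pixels[:, 0], p.pixels[:, 1]] = p.punctum_id + 1
        return lab


@dataclass
class DetectionLog:
    """Per-run audit record: threshold used and what each filter removed."""

    image_id: str
    threshold: float
    threshold_mode: str
    n_components: int
    n_removed_area: int
    n_removed_distance: int
    n_kept: int
    total_foreground_area_um2: float
    kept_area_um2: float
    removed_area_um2: float
    removed: list = field(default_factory=list)  # (idx, area, dist, reasons)

    def as_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "threshold": self.threshold,
            "threshold_mode": self.threshold_mode,
            "n_components": self.n_components,
            "n_removed_area": self.n_removed_area,
            "n_removed_distance": self.n_removed_distance,
            "n_kept": self.n_kept,
            "total_foreground_area_um2": self.total_foreground_area_um2,
            "kept_area_um2": self.kept_area_um2,
            "removed_area_um2": self.removed_area_um2,
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def normalize_image(img: ChannelImage) -> ChannelImage:
    """Linearly rescale intensities to [0, 255]; constant images map to 0."""
    arr = img.as_float()
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        out = np.zeros_like(arr)
    else:
        out = np.clip((arr - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return ChannelImage(out, img.pixel_size, img.channel_label,
                        source_dtype=img.source_dtype)


def otsu_threshold(pixels: np.ndarray) -> int:
    """Inter-class-variance-maximizing threshold over the 256-bin histogram.

    The histogram bins the [0, 255] scale at unit width; the returned
    integer ``t`` separates background (<= t) from foreground (> t).  Ties
    resolve to the lowest candidate.
    """
    arr = np.asarray(pixels, dtype=float).ravel()
    hist, _ = np.histogram(arr, bins=256, range=(0.0, 256.0))
    hist = hist.astype(float)
    total = hist.sum()
    if total == 0:
        raise ValueError("empty image")
    p = hist / total
    levels = np.arange(256, dtype=float)
    omega0 = np.cumsum(p)                     # weight of class {0..t}
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    between = np.zeros(256)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
    between[valid] = (omega0[valid] * omega1[valid]
                      * (mu0[valid] - mu1[valid]) ** 2)
    if not valid.any():
        return 0
    return int(np.argmax(between))


def threshold_value(img: ChannelImage, params: DetectionParams) -> float:
    """The global threshold that :func:`binarize` will apply."""
    arr = img.as_float()
    if arr.min() < 0 or arr.max() > 255 * (1 + 1e-12):
        raise ValueError("binarize expects an image normalized to [0, 255]")
    if params.threshold_mode == "fixed":
        return float(params.fixed_threshold)
    return float(otsu_threshold(arr))


def binarize(img: ChannelImage, params: DetectionParams) -> np.ndarray:
    """Global-threshold binarization: foreground iff intensity > threshold."""
    t = threshold_value(img, params)
    return img.as_float() > t


def label_components(mask: np.ndarray, connectivity: int = 8):
    """8-connected component labeling with deterministic raster-order labels.

    Returns ``(labels, components)`` where ``labels`` is an int grid
    (0 = background) and ``components`` a list of ``(k, 2)`` pixel-index
    arrays, ordered by the raster position of each component's first pixel.
    """
    if connectivity != 8:
        raise ValueError("only 8-connectivity is supported")
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return lab, []
    flat = lab.ravel()
    fg = np.flatnonzero(flat)
    # order labels by first raster occurrence (fg indices are already sorted)
    first_seen = {}
    order = []
    for idx in fg:
        lv = flat[idx]
        if lv not in first_seen:
            first_seen[lv] = len(order)
            order.append(lv)
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    lab = remap[lab]
    comps = [[] for _ in range(n)]
    rr, cc = np.nonzero(lab)
    for r, c, lv in zip(rr, cc, lab[rr, cc]):
        comps[lv - 1].append((r, c))
    components = [np.array(c, dtype=np.intp) for c in comps]
    return lab, components


def component_distance(pixels: np.ndarray, traces: ProcessTraces,
                       pixel_size: float, mode: str = "min_pixel"):
    """Minimum distance (µm) from a component to any traced process.

    ``min_pixel`` takes the minimum over all pixel centres of the component
    (the default); ``centroid`` measures from the component centroid.  With
    no traces the distance is ``+inf`` and the process id ``-1``.
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty component")
    pts = np.column_stack([(pixels[:, 1] + 0.5) * pixel_size,
                           (pixels[:, 0] + 0.5) * pixel_size])
    if mode == "centroid":
        pts = pts.mean(axis=0, keepdims=True)
    elif mode != "min_pixel":
        raise ValueError(f"unknown distance mode {mode!r}")
    dist, pid = traces.min_distance(pts)
    k = int(np.argmin(dist))
    return float(dist[k]), int(pid[k])


def detect_puncta(marker: ChannelImage, signal: ChannelImage,
                  traces: ProcessTraces, params: DetectionParams | None = None,
                  image_id: str = "image"):
    """Full detection pipeline on the marker channel.

    Components are kept iff ``min_area <= area <= max_area`` *and*
    ``distance <= max_distance`` (both bounds inclusive); mean intensities of
    kept puncta are measured on the raw marker and signal channels.

    Returns ``(PunctumTable, DetectionLog)``.
    """
    params = params or DetectionParams()
    if marker.shape != signal.shape:
        raise ValueError(
            f"channel shapes differ: {marker.shape} vs {signal.shape}")
    if marker.pixel_size != signal.pixel_size:
        raise ValueError("channel pixel sizes differ")
    if traces.pixel_size != marker.pixel_size:
        raise ValueError("trace/channel pixel sizes differ")
    ps = marker.pixel_size
    norm = normalize_image(marker)
    t = threshold_value(norm, params)
    mask = norm.as_float() > t
    _, components = label_components(mask, params.connectivity)

    marker_raw = marker.as_float()
    signal_raw = signal.as_float()
    puncta, removed = [], []
    kept_area = removed_area = 0.0
    n_rm_area = n_rm_dist = 0
    for ci, pix in enumerate(components):
        area = len(pix) * ps * ps
        dist, pid = component_distance(pix, traces, ps, params.distance_mode)
        pass_area = params.min_area <= area <= params.max_area
        pass_dist = dist <= params.max_distance
        if pass_area and pass_dist:
            cx = float((pix[:, 1] + 0.5).mean() * ps)
            cy = float((pix[:, 0] + 0.5).mean() * ps)
            puncta.append(Punctum(
                punctum_id=len(puncta), image_id=image_id, pixels=pix,
                area_um2=area, centroid_um=(cx, cy), distance_um=dist,
                process_id=pid,
                mean_marker=float(marker_raw[pix[:, 0], pix[:, 1]].mean()),
                mean_signal=float(signal_raw[pix[:, 0], pix[:, 1]].mean())))
            kept_area += area
        else:
            reasons = []
            if not pass_area:
                reasons.append("area")
                n_rm_area += 1
            if not pass_dist:
                reasons.append("distance")
                n_rm_dist += 1
            removed.append((ci, area, dist, tuple(reasons)))
            removed_area += area

    log = DetectionLog(
        image_id=image_id, threshold=t, threshold_mode=params.threshold_mode,
        n_components=len(components), n_removed_area=n_rm_area,
        n_removed_distance=n_rm_dist, n_kept=len(puncta),
        total_foreground_area_um2=kept_area + removed_area,
        kept_area_um2=kept_area, removed_area_um2=removed_area,
        removed=removed)
    logger.info(
        "%s: threshold=%.6g (%s), %d components, kept %d, "
        "removed %d by area, %d by distance",
        image_id, t, params.threshold_mode, len(components), len(puncta),
        n_rm_area, n_rm_dist)
    return (PunctumTable(puncta, image_id, ps, marker.shape), log)
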