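"""Per-punctum and per-image summaries.

Covers the quantities reported for presynaptic SNAP29: puncta density per
micron of traced process, two-channel colocalization counts, the
signal/marker intensity ratio per punctum, and the accumulation index (AI)
of punctum signal relative to the inter-punctum shaft signal along each
process.

The accumulation index of punctum *k* on a process is the bounded
enrichment ratio ``AI_k = I_k / (I_k + B_k)``, where ``I_k`` is the mean
signal intensity over the punctum's arc-length span and ``B_k`` the mean
over the non-punctum (shaft) positions of the same process.  A spatially
uniform signal gives AI = 0.5; AI is invariant to rescaling the whole
profile and monotone in punctum enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .detection import PunctumTable
from .io import ChannelImage, ProcessTraces

__all__ = [
    "DensityResult",
    "ColocResult",
    "RatioResult",
    "AccumulationProfile",
    "ImageSummary",
    "density_per_micron",
    "colocalize",
    "signal_over_marker",
    "build_profiles",
    "accumulation_index",
    "summarize_image",
    "sem",
]


def sem(values) -> float:
    """Standard error of the mean (s.d./sqrt(n), ddof=1); NaN for n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

@dataclass
class DensityResult:
    per_micron: float                 # kept puncta / total process length
    n_puncta: int
    total_length_um: float
    per_process: dict                 # process_id -> puncta per µm


def density_per_micron(table, traces: ProcessTraces) -> DensityResult:
    """Puncta per micron of traced process, per image and per process."""
    total = traces.total_length
    if total <= 0:
        raise ValueError("traces are empty: density per micron is undefined")
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    lengths = traces.lengths()
    per_process = {}
    for pid in range(traces.n_processes):
        n = int((df["process_id"] == pid).sum()) if len(df) else 0
        per_process[pid] = n / lengths[pid] if lengths[pid] > 0 else float("nan")
    return DensityResult(per_micron=len(df) / total, n_puncta=len(df),
                         total_length_um=total, per_process=per_process)


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    pairs: list                       # (signal_id, marker_id, overlap_px)
    n_colocalized: int
    coloc_per_micron: float           # NaN when no traces supplied


def colocalize(signal_puncta: PunctumTable, marker_puncta: PunctumTable,
               traces: ProcessTraces | None = None) -> ColocResult:
    """Pixel-overlap colocalization between independently detected channels.

    A signal punctum is colocalized iff its pixel set overlaps a marker
    punctum by >= 1 pixel; each signal punctum matches at most one marker
    punctum (largest overlap, ties to the lowest marker label).
    """
    if signal_puncta.image_shape != marker_puncta.image_shape:
        raise ValueError(
            f"image shapes differ: {signal_puncta.image_shape} "
            f"vs {marker_puncta.image_shape}")
    if signal_puncta.pixel_size != marker_puncta.pixel_size:
        raise ValueError("pixel sizes differ between the two tables")
    marker_lab = marker_puncta.label_image()
    pairs = []
    for p in signal_puncta:
        labels = marker_lab[p.pixels[:, 0], p.pixels[:, 1]]
        labels = labels[labels > 0]
        if labels.size == 0:
            continue
        ids, counts = np.unique(labels, return_counts=True)
        best = counts.max()
        winner = int(ids[counts == best].min()) - 1   # ties -> lowest label
        pairs.append((p.punctum_id, winner, int(best)))
    if traces is not None and traces.total_length > 0:
        rate = len(pairs) / traces.total_length
    else:
        rate = float("nan")
    return ColocResult(pairs=pairs, n_colocalized=len(pairs),
                       coloc_per_micron=rate)


# ---------------------------------------------------------------------------
# intensity ratio
# ---------------------------------------------------------------------------

@dataclass
class RatioResult:
    ratios: np.ndarray                # per kept punctum
    punctum_ids: np.ndarray
    n_excluded: int                   # puncta with mean_marker <= 0
    mean: float
    sem: float


def signal_over_marker(table) -> RatioResult:
    """Per-punctum signal/marker intensity ratio distribution.

    Puncta with non-positive marker mean are excluded (and counted), since
    the ratio is undefined for them.
    """
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    if len(df) == 0:
        return RatioResult(np.empty(0), np.empty(0, dtype=int), 0,
                           float("nan"), float("nan"))
    ok = df["mean_marker"] > 0
    ratios = (df.loc[ok, "mean_signal"] / df.loc[ok, "mean_marker"]).to_numpy()
    ids = df.loc[ok, "punctum_id"].to_numpy()
    n_excl = int((~ok).sum())
    mean = float(ratios.mean()) if ratios.size else float("nan")
    return RatioResult(ratios, ids, n_excl, mean, sem(ratios))


# ---------------------------------------------------------------------------
# accumulation index
# ---------------------------------------------------------------------------

@dataclass
class AccumulationProfile:
    """Signal intensity sampled along one process at a fixed arc-length step.

    ``punctum_ids`` holds, per position, the id of the covering punctum or
    -1 on the shaft.
    """

    process_id: int
    positions: np.ndarray             # strictly increasing, µm
    intensities: np.ndarray
    punctum_ids: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.punctum_ids = np.asarray(self.punctum_ids, dtype=int)
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("profile positions must be strictly increasing")
        if not (len(self.positions) == len(self.intensities)
                == len(self.punctum_ids)):
            raise ValueError("profile arrays must have equal length")


def build_profiles(signal: ChannelImage, traces: ProcessTraces,
                   table: PunctumTable, step: float | None = None) -> list:
    """Sample the signal channel along each process (bilinear interpolation).

    ``step`` defaults to ``pixel_size / 2`` (below the pixel Nyquist
    spacing).  Each detected punctum is projected onto its assigned process:
    its pixel centres map to arc positions, and the spanned interval flags
    the profile positions it covers.
    """
    ps = signal.pixel_size
    step = ps / 2.0 if step is None else step
    if step > ps:
        raise ValueError("profile step must be <= pixel_size")
    arr = signal.as_float()
    # per-process punctum spans
    spans = {pid: [] for pid in range(traces.n_processes)}
    for p in table:
        if p.process_id < 0 or p.process_id >= traces.n_processes:
            continue
        pts = np.column_stack([(p.pixels[:, 1] + 0.5) * ps,
                               (p.pixels[:, 0] + 0.5) * ps])
        s = traces.arc_position(pts, p.process_id)
        spans[p.process_id].append((float(s.min()), float(s.max()),
                                    p.punctum_id))
    profiles = []
    lengths = traces.lengths()
    for pid in range(traces.n_processes):
        L = lengths[pid]
        pos = np.arange(0.0, L + step / 2.0, step)
        pos = pos[pos <= L]
        xy = traces.point_at(pid, pos)
        coords = np.vstack([xy[:, 1] / ps - 0.5, xy[:, 0] / ps - 0.5])
        inten = map_coordinates(arr, coords, order=1, mode="nearest")
        ids = np.full(len(pos), -1, dtype=int)
        for s0, s1, punctum_id in sorted(spans[pid], key=lambda t: t[2],
                                         reverse=True):
            ids[(pos >= s0) & (pos <= s1)] = punctum_id  # lowest id wins
        profiles.append(AccumulationProfile(pid, pos, inten, ids))
    return profiles


def accumulation_index(profile: AccumulationProfile) -> pd.DataFrame:
    """Per-punctum AI = I / (I + B) for one process profile.

    ``I`` is the punctum's mean profile intensity, ``B`` the mean over the
    shaft positions of the same process.  AI is NaN (flagged) when the
    process has no shaft positions or when ``I + B = 0``.
    """
    shaft = profile.intensities[profile.punctum_ids < 0]
    ids = np.unique(profile.punctum_ids[profile.punctum_ids >= 0])
    rows = []
    for pid in ids:
        I = float(profile.intensities[profile.punctum_ids == pid].mean())
        if shaft.size == 0:
            rows.append((int(pid), float("nan"), True))
            continue
        B = float(shaft.mean())
        if I + B == 0:
            rows.append((int(pid), float("nan"), True))
        else:
            rows.append((int(pid), I / (I + B), False))
    return pd.DataFrame(rows, columns=["punctum_id", "ai", "flagged"])


# ---------------------------------------------------------------------------
# image summary
# ---------------------------------------------------------------------------

@dataclass
class ImageSummary:
    image_id: str
    condition: str
    n_puncta: int
    total_length_um: float
    puncta_per_micron: float
    coloc_per_micron: float
    mean_signal_mean: float
    mean_signal_sem: float
    ratio_mean: float
    ratio_sem: float
    ai_mean: float
    ai_sem: float
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "image_id", "condition", "n_puncta", "total_length_um",
            "puncta_per_micron", "coloc_per_micron", "mean_signal_mean",
            "mean_signal_sem", "ratio_mean", "ratio_sem", "ai_mean",
            "ai_sem")}
        d["flags"] = ";".join(self.flags)
        return d


def summarize_image(table, traces: ProcessTraces, profiles=None,
                    condition: str = "", image_id: str | None = None,
                    coloc_per_micron: float = float("nan")) -> ImageSummary:
    """Aggregate one image's puncta into an :class:`ImageSummary`.

    An empty table yields count 0 with flagged (NaN) means rather than an
    error; SEM is NaN for n < 2.
    """
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    if image_id is None:
        image_id = str(df["image_id"].iloc[0]) if len(df) else ""
    flags = []
    total = traces.total_length
    if total > 0:
        rate = len(df) / total
    else:
        rate = float("nan")
        flags.append("no_traces")
    if len(df) == 0:
        flags.append("no_puncta")
        sig_mean = sig_sem = r_mean = r_sem = float("nan")
        rate = 0.0 if total > 0 else rate
    else:
        sig = df["mean_signal"].to_numpy(dtype=float)
        sig_mean, sig_sem = float(sig.mean()), sem(sig)
        rr = signal_over_marker(df)
        r_mean, r_sem = rr.mean, rr.sem
        if len(df) == 1:
            flags.append("sem_undefined_n1")
    ai_vals = np.empty(0)
    if profiles:
        parts = [accumulation_index(p) for p in profiles]
        ai_df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        if len(ai_df):
            ai_vals = ai_df.loc[~ai_df["flagged"], "ai"].to_numpy(dtype=float)
            if ai_df["flagged"].any():
                flags.append("ai_flagged")
    ai_mean = float(ai_vals.mean()) if ai_vals.size else float("nan")
    return ImageSummary(
        image_id=image_id, condition=condition, n_puncta=len(df),
        total_length_um=total, puncta_per_micron=rate,
        coloc_per_micron=coloc_per_micron, mean_signal_mean=sig_mean,
        mean_signal_sem=sig_sem, ratio_mean=r_mean, ratio_sem=r_sem,
        ai_mean=ai_mean, ai_sem=sem(ai_vals), flags=flags)
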