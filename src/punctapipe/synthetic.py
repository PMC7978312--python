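"""Ground-truthed two-channel synthetic fluorescence micrographs.

The generator emulates confocal images of cultured neurons stained for a
presynaptic marker (synaptophysin, "marker" channel) and a quantified
protein (SNAP29, "signal" channel):

* smooth neuronal processes (random curvature-correlated polylines);
* presynaptic puncta placed along the processes by a stationary hard-core
  renewal process (inter-punctum spacing = ``min_separation_um`` plus an
  exponential; mean rate exactly ``puncta_per_micron``; pure Poisson when
  the separation is 0);
* each punctum is a disk of per-spot radius (its true area) convolved with
  an isotropic Gaussian PSF; it appears in both channels with independent
  log-normal amplitudes, and the signal-channel amplitude is multiplied by
  ``condition_factor`` (1 = control, <1 = knockdown / ischemia-like);
* off-process distractor spots, placed far enough from every process that
  the 1 µm distance filter removes them by construction;
* sub-area-threshold speckles (true area < 0.35 µm²) that the area filter
  removes;
* additive Gaussian background noise, clipped at zero.

Identical configuration + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import ChannelImage, ProcessTraces, write_channel_image, write_traces

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_process_traces",
    "render_image_pair",
    "generate_experiment",
    "replay_experiment",
    "match_to_ground_truth",
]

TRUTH_COLUMNS = [
    "spot_id", "kind", "process_id", "x_um", "y_um", "radius_um", "area_um2",
    "amp_marker", "amp_signal", "mean_marker_true", "mean_signal_true",
    "on_process",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated imaging condition.

    Intensity distributions are ``(mu, sigma)`` of the underlying normal of
    a log-normal on arbitrary-unit amplitudes.  Defaults describe a typical
    confocal field: 51.2 µm × 51.2 µm at 0.1 µm/px, puncta of core area
    0.45-0.79 µm² at 0.4 per µm of process.
    """

    image_shape: tuple = (512, 512)          # (rows, cols)
    pixel_size: float = 0.1                  # µm / pixel
    n_processes: int = 3
    process_length_um: float = 40.0
    process_smoothness: float = 8.0          # curvature correlation length, µm
    puncta_per_micron: float = 0.4
    min_separation_um: float = 1.5           # hard-core spacing (0 -> Poisson)
    punctum_radius_um: tuple = (0.38, 0.5)   # uniform range of core radii
    psf_sigma: float = 0.2                   # µm
    marker_intensity_dist: tuple = (5.0, 0.25)
    signal_intensity_dist: tuple = (5.0, 0.25)
    condition_factor: float = 1.0            # scales on-process signal amps
    distractor_rate: float = 3.0             # off-process spots per image
    speckle_rate: float = 10.0               # sub-threshold specks per image
    speckle_radius_um: tuple = (0.06, 0.12)
    speckle_amp_factor: float = 1.0
    background_sigma: float = 7.5            # additive Gaussian noise s.d.
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"zero-area image shape {self.image_shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.puncta_per_micron < 0:
            raise ValueError("puncta_per_micron must be >= 0")
        if not 0.0 <= self.condition_factor <= 1.0:
            raise ValueError("condition_factor must lie in [0, 1]")
        if self.distractor_rate < 0 or self.speckle_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")
        if (self.puncta_per_micron > 0 and self.min_separation_um > 0
                and self.puncta_per_micron * self.min_separation_um >= 1.0):
            raise ValueError(
                "puncta_per_micron * min_separation_um must be < 1 "
                "(hard-core renewal feasibility)")
        if self.n_processes < 0:
            raise ValueError("n_processes must be >= 0")


class GroundTruth:
    """The simulator's record of every rendered spot.

    One row per spot: true centroid (µm), core radius and area (µm²),
    per-channel amplitude and pre-noise mean intensity over the core pixels,
    an ``on_process`` flag, and the process index (-1 for off-process spots).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reindex(columns=TRUTH_COLUMNS)

    def __len__(self):
        return len(self.df)

    @property
    def puncta(self) -> pd.DataFrame:
        """Only the true on-process presynaptic puncta."""
        return self.df[self.df["on_process"] == 1].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# process traces
# ---------------------------------------------------------------------------

def make_process_traces(config: SimulationConfig, rng=None) -> ProcessTraces:
    """Generate ``n_processes`` smooth polylines fully inside the image.

    Curvature follows an Ornstein-Uhlenbeck process with correlation length
    ``process_smoothness``; near the border the heading is steered back
    toward the image centre so traces stay inside a safety margin.
    """
    rng = _as_rng(rng, config.seed)
    rows, cols = config.image_shape
    ps = config.pixel_size
    w, h = cols * ps, rows * ps
    margin = min(2.5, 0.25 * min(w, h))
    polylines = []
    ds = 2.0 * ps
    n_steps = max(int(round(config.process_length_um / ds)), 1)
    ell = max(config.process_smoothness, ds)
    kappa_sd = 1.0 / ell                      # rad/µm, gentle curvature
    rho = np.exp(-ds / ell)
    for _ in range(config.n_processes):
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        kappa = rng.normal(0.0, kappa_sd)
        pts = [(x, y)]
        cx, cy = w / 2.0, h / 2.0
        soft = margin + 1.5  # start steering before the hard margin
        for _ in range(n_steps):
            kappa = rho * kappa + np.sqrt(1 - rho ** 2) * rng.normal(0.0, kappa_sd)
            theta += kappa * ds
            nx, ny = x + ds * np.cos(theta), y + ds * np.sin(theta)
            if not (soft <= nx <= w - soft and soft <= ny <= h - soft):
                # steer toward the centre at a bounded turn rate, so traces
                # curve away from the border instead of kinking
                target = np.arctan2(cy - y, cx - x)
                dtheta = (target - theta + np.pi) % (2 * np.pi) - np.pi
                theta += np.clip(dtheta, -0.15, 0.15)
                nx, ny = x + ds * np.cos(theta), y + ds * np.sin(theta)
                nx = float(np.clip(nx, margin, w - margin))
                ny = float(np.clip(ny, margin, h - margin))
            x, y = nx, ny
            pts.append((x, y))
        polylines.append(np.asarray(pts))
    return ProcessTraces(polylines, ps, (rows, cols))


# ---------------------------------------------------------------------------
# spot placement and rendering
# ---------------------------------------------------------------------------

def _as_rng(rng, seed):
    if rng is None:
        return np.random.default_rng(seed)
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _hardcore_positions(length: float, rate: float, delta: float, rng) -> np.ndarray:
    """Stationary hard-core renewal points on [0, length].

    Spacings are ``delta + Exp(theta)`` with ``theta = 1/rate - delta``; the
    first point uses the equilibrium delay distribution so that
    ``E[N] = rate * length`` exactly.  ``delta = 0`` gives a homogeneous
    Poisson process.
    """
    if rate <= 0 or length <= 0:
        return np.empty(0)
    theta = 1.0 / rate - delta
    mean_gap = delta + theta
    # equilibrium delay: U(0, delta) w.p. delta/mean_gap, else delta + Exp(theta)
    if rng.uniform() < delta / mean_gap:
        s = rng.uniform(0.0, delta)
    else:
        s = delta + rng.exponential(theta)
    out = []
    while s <= length:
        out.append(s)
        s += delta + rng.exponential(theta)
    return np.asarray(out)


def _add_disk(img: np.ndarray, cx: float, cy: float, r: float, amp: float,
              ps: float) -> None:
    """Add an anti-aliased disk of radius ``r`` µm and height ``amp``."""
    rows, cols = img.shape
    reach = r + 1.5 * ps
    c0 = max(int(np.floor((cx - reach) / ps - 0.5)), 0)
    c1 = min(int(np.ceil((cx + reach) / ps - 0.5)) + 1, cols)
    r0 = max(int(np.floor((cy - reach) / ps - 0.5)), 0)
    r1 = min(int(np.ceil((cy + reach) / ps - 0.5)) + 1, rows)
    if c0 >= c1 or r0 >= r1:
        return
    xs = (np.arange(c0, c1) + 0.5) * ps
    ys = (np.arange(r0, r1) + 0.5) * ps
    d = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    cov = np.clip((r - d) / ps + 0.5, 0.0, 1.0)   # soft-edge pixel coverage
    img[r0:r1, c0:c1] += amp * cov


def _core_pixels(shape, cx, cy, r, ps):
    """(rows, cols) of pixels whose centre lies inside the core disk."""
    rows, cols = shape
    c0 = max(int(np.floor((cx - r) / ps - 0.5)), 0)
    c1 = min(int(np.ceil((cx + r) / ps - 0.5)) + 1, cols)
    r0 = max(int(np.floor((cy - r) / ps - 0.5)), 0)
    r1 = min(int(np.ceil((cy + r) / ps - 0.5)) + 1, rows)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    if rr.size:
        d = np.hypot((cc + 0.5) * ps - cx, (rr + 0.5) * ps - cy)
        keep = d <= r
        rr, cc = rr[keep], cc[keep]
    if rr.size == 0:  # sub-pixel spot: fall back to the nearest pixel
        rr = np.array([int(np.clip(round(cy / ps - 0.5), 0, rows - 1))])
        cc = np.array([int(np.clip(round(cx / ps - 0.5), 0, cols - 1))])
    return rr.ravel(), cc.ravel()


def render_image_pair(traces: ProcessTraces, config: SimulationConfig, rng=None):
    """Render the two channels plus the ground-truth table.

    Returns ``(marker, signal, truth)``.  The marker channel is entirely
    independent of ``condition_factor``: all random draws happen before the
    factor is applied, so the same seed with a different factor yields an
    identical marker channel and exactly rescaled on-process signal
    amplitudes.
    """
    if config.psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    rng = _as_rng(rng, config.seed)
    rows, cols = config.image_shape
    ps = config.pixel_size
    w, h = cols * ps, rows * ps
    mu_m, sd_m = config.marker_intensity_dist
    mu_s, sd_s = config.signal_intensity_dist

    spots = []  # (kind, process_id, x, y, r, amp_m, amp_s_raw)
    # --- on-process puncta (hard-core renewal along arc length) ----------
    # The separation is also enforced in 2-D across processes: where traces
    # cross or hairpin, a candidate closer than min_separation_um to an
    # already-placed punctum is dropped (boutons do not overlap).
    accepted_xy: list = []
    delta = config.min_separation_um
    for pid, _poly in enumerate(traces.polylines):
        length = float(np.linalg.norm(np.diff(_poly, axis=0), axis=1).sum())
        s_pos = _hardcore_positions(length, config.puncta_per_micron,
                                    delta, rng)
        if len(s_pos) == 0:
            continue
        xy = traces.point_at(pid, s_pos)
        for (x, y) in xy:
            r = rng.uniform(*config.punctum_radius_um)
            amp_m = float(np.exp(rng.normal(mu_m, sd_m)))
            amp_s = float(np.exp(rng.normal(mu_s, sd_s)))
            if delta > 0 and accepted_xy:
                d2 = np.linalg.norm(np.asarray(accepted_xy)
                                    - np.array([x, y]), axis=1)
                if d2.min() < delta:
                    continue
            accepted_xy.append((float(x), float(y)))
            spots.append(("punctum", pid, float(x), float(y), r, amp_m, amp_s))

    # --- off-process distractors -----------------------------------------
    n_distr = rng.poisson(config.distractor_rate)
    for _ in range(n_distr):
        r = rng.uniform(*config.punctum_radius_um)
        amp_m = float(np.exp(rng.normal(mu_m, sd_m)))
        amp_s = float(np.exp(rng.normal(mu_s, sd_s)))
        placed = False
        for _attempt in range(1000):
            x = rng.uniform(0.5, w - 0.5)
            y = rng.uniform(0.5, h - 0.5)
            if traces.n_processes == 0:
                placed = True
                break
            d, _ = traces.min_distance(np.array([[x, y]]))
            # far enough that even the blurred footprint stays > 1 µm away
            if d[0] > 1.0 + r + 0.5:
                placed = True
                break
        if placed:
            spots.append(("distractor", -1, x, y, r, amp_m, amp_s))

    # --- sub-threshold speckles ------------------------------------------
    n_speck = rng.poisson(config.speckle_rate)
    for _ in range(n_speck):
        r = rng.uniform(*config.speckle_radius_um)
        amp_m = config.speckle_amp_factor * float(np.exp(rng.normal(mu_m, sd_m)))
        amp_s = config.speckle_amp_factor * float(np.exp(rng.normal(mu_s, sd_s)))
        x = rng.uniform(0.3, w - 0.3)
        y = rng.uniform(0.3, h - 0.3)
        spots.append(("speckle", -1, x, y, r, amp_m, amp_s))

    # --- render: puncta and non-puncta separately (blur is linear) -------
    marker_p = np.zeros((rows, cols))
    marker_o = np.zeros((rows, cols))
    signal_p = np.zeros((rows, cols))
    signal_o = np.zeros((rows, cols))
    f = config.condition_factor
    for kind, pid, x, y, r, amp_m, amp_s in spots:
        if kind == "punctum":
            _add_disk(marker_p, x, y, r, amp_m, ps)
            _add_disk(signal_p, x, y, r, amp_s * f, ps)
        else:
            _add_disk(marker_o, x, y, r, amp_m, ps)
            _add_disk(signal_o, x, y, r, amp_s, ps)
    sig_px = config.psf_sigma / ps
    marker_p = gaussian_filter(marker_p, sig_px, mode="constant")
    marker_o = gaussian_filter(marker_o, sig_px, mode="constant")
    signal_p = gaussian_filter(signal_p, sig_px, mode="constant")
    signal_o = gaussian_filter(signal_o, sig_px, mode="constant")

    # --- ground truth (pre-noise means over core pixels) ------------------
    records = []
    for sid, (kind, pid, x, y, r, amp_m, amp_s) in enumerate(spots):
        rr, cc = _core_pixels((rows, cols), x, y, r, ps)
        if kind == "punctum":
            mm = float(marker_p[rr, cc].mean())
            ms = float(signal_p[rr, cc].mean())
            amp_s_out = amp_s * f
        else:
            mm = float(marker_o[rr, cc].mean())
            ms = float(signal_o[rr, cc].mean())
            amp_s_out = amp_s
        records.append((sid, kind, pid, x, y, r, np.pi * r * r,
                        amp_m, amp_s_out, mm, ms, int(kind == "punctum")))
    truth = GroundTruth(pd.DataFrame(records, columns=TRUTH_COLUMNS))

    marker = marker_p + marker_o
    signal = signal_p + signal_o
    if config.background_sigma > 0:
        marker = marker + rng.normal(0.0, config.background_sigma, (rows, cols))
        signal = signal + rng.normal(0.0, config.background_sigma, (rows, cols))
    marker = np.clip(marker, 0.0, None).astype(np.float32)
    signal = np.clip(signal, 0.0, None).astype(np.float32)
    return (ChannelImage(marker, ps, "synaptophysin"),
            ChannelImage(signal, ps, "SNAP29"),
            truth)


# ---------------------------------------------------------------------------
# experiments on disk
# ---------------------------------------------------------------------------

def _derive_seed(base_seed: int, cond_index: int, image_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), cond_index, image_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_experiment(configs: dict, n_images_per_condition: int, out_dir,
                        seed: int | None = None) -> str:
    """Write a multi-condition dataset (TIFF pairs, traces, truth, manifest).

    ``configs`` maps condition name -> :class:`SimulationConfig`.  Per-image
    seeds are derived from ``seed`` (default: the first config's seed) and
    recorded in the manifest; re-running from the manifest reproduces every
    file bit-exactly.
    """
    if not configs:
        raise ValueError("at least one condition is required")
    if n_images_per_condition < 1:
        raise ValueError("n_images_per_condition must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    base_seed = int(seed) if seed is not None else next(iter(configs.values())).seed
    manifest = {"n_images_per_condition": n_images_per_condition,
                "base_seed": base_seed,
                "conditions": ",".join(configs)}
    for ci, (name, cfg) in enumerate(configs.items()):
        manifest[f"config.{name}"] = json.dumps(
            dataclasses.asdict(cfg), sort_keys=True)
        for ii in range(n_images_per_condition):
            img_seed = _derive_seed(base_seed, ci, ii)
            manifest[f"seed.{name}.{ii}"] = img_seed
            _write_one_image(cfg, name, ii, img_seed, out_dir)
    manifest_path = os.path.join(out_dir, "manifest.txt")
    from .io import write_keyvalue
    write_keyvalue(manifest, manifest_path)
    return manifest_path


def _write_one_image(cfg: SimulationConfig, name: str, index: int,
                     img_seed: int, out_dir) -> None:
    cfg_i = replace(cfg, seed=img_seed)
    rng = np.random.default_rng(img_seed)
    traces = make_process_traces(cfg_i, rng)
    marker, signal, truth = render_image_pair(traces, cfg_i, rng)
    stem = os.path.join(out_dir, f"{name}_{index:03d}")
    write_channel_image(marker, stem + "_marker.tif")
    write_channel_image(signal, stem + "_signal.tif")
    write_traces(traces, stem + "_traces.csv")
    truth.to_csv(stem + "_truth.csv")


def replay_experiment(manifest_path, out_dir) -> str:
    """Regenerate a dataset from its manifest (bit-identical files)."""
    from .io import read_keyvalue
    manifest = read_keyvalue(manifest_path)
    n = int(manifest["n_images_per_condition"])
    names = manifest["conditions"].split(",")
    configs = {}
    for name in names:
        raw = json.loads(manifest[f"config.{name}"])
        for key in ("image_shape", "punctum_radius_um", "speckle_radius_um",
                    "marker_intensity_dist", "signal_intensity_dist"):
            raw[key] = tuple(raw[key])
        configs[name] = SimulationConfig(**raw)
    return generate_experiment(configs, n, out_dir,
                               seed=int(manifest["base_seed"]))


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

def match_to_ground_truth(table, truth: GroundTruth, max_dist_um: float = 0.6):
    """Greedy 1:1 matching of detected puncta to true on-process puncta.

    Pairs are formed in order of increasing centroid distance, each side used
    at most once, up to ``max_dist_um``.  Returns a dict with ``pairs``,
    ``recall`` (matched / true on-process puncta) and ``precision``
    (matched / detected).
    """
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    tp = truth.puncta
    n_det, n_true = len(df), len(tp)
    if n_det == 0 or n_true == 0:
        return {"pairs": [], "recall": 0.0 if n_true else float("nan"),
                "precision": 0.0 if n_det else float("nan")}
    det = df[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=float)
    tru = tp[["x_um", "y_um"]].to_numpy(dtype=float)
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=-1)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_d, used_t, pairs = set(), set(), []
    for i, j in order:
        if d[i, j] > max_dist_um:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((int(df["punctum_id"].iloc[i]), int(tp["spot_id"].iloc[j]),
                      float(d[i, j])))
    return {"pairs": pairs,
            "recall": len(pairs) / n_true,
            "precision": len(pairs) / n_det}
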