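# Methods

## Coordinate and calibration conventions

Pixel indices are 0-based with x along columns and y along rows
(increasing downward). The centre of pixel (row, col) is at
((col + 0.5)·p, (row + 0.5)·p) µm, where p is the pixel size in µm/pixel,
supplied out-of-band (TIFF tag dialects are unreliable and carry no
guarantee of calibration). Every physical quantity — component areas
(pixel count · p²), point-to-process distances, arc lengths, densities —
derives from this one mapping. Process traces are polylines in µm; the
rasterized trace marks each pixel whose centre lies within p/2 of a line.

## Detection model

Detection runs on the presynaptic-marker channel only; the signal channel
is measured at the detected sites.

1. **Normalization.** Linear rescale of the image to [0, 255]. A constant
   image maps to all zeros: it carries no detectable structure and the
   choice avoids a 0/0 rescale.
2. **Global threshold.** Foreground is `intensity > t` (strictly greater,
   so an all-background image yields an empty mask for any t ≥ 0). In
   `auto` mode t maximizes the inter-class variance over the 256-bin
   histogram of the [0, 255] scale, with ties resolved to the lowest
   candidate; this is implemented in-package because the binning is pinned
   to unit-width bins on the fixed 0–255 scale rather than to the data
   range. A fixed-value override exists because the original procedure
   does not state whether its global threshold was automatic; the mode
   and value used are always recorded in the run log.
3. **Labeling.** 8-connectivity (horizontal, vertical and diagonal
   neighbours join), via `scipy.ndimage.label`, with labels re-ordered by
   the raster position of each component's first pixel so output is
   deterministic.
4. **Filters.** A component is kept iff 0.35 µm² ≤ area ≤ 10 µm² and its
   distance to a traced process is ≤ 1 µm. All bounds are inclusive:
   the stated removal rules ("smaller than", "larger than", "within")
   read as strict removals, so equality is kept. Distance is the minimum
   over the component's pixel centres to any polyline point
   (`min_pixel` mode); a `centroid` mode is provided since the original
   description does not fix the reference point. The log counts removals
   per rule separately (a component can fail both) and carries the kept /
   removed area totals, which partition the foreground exactly.

Mean punctum intensities are measured on the **raw** input channels.
Normalizing the signal channel per image would rescale its maximum to 255
and thereby divide out exactly the between-condition intensity reduction
the analysis is meant to measure; normalization is therefore a detection
preprocessing step only.

## Quantification

- **Density**: kept puncta divided by total traced length (µm), also per
  process. Undefined (error) without traces.
- **Colocalization**: puncta are detected independently in each channel;
  a signal punctum colocalizes with a marker punctum iff their pixel sets
  overlap by ≥ 1 pixel — the weakest criterion consistent with
  "colocalizing", stated explicitly so stricter fractional-overlap rules
  can be added. Each signal punctum matches at most one marker punctum
  (largest overlap, ties to the lowest label).
- **Signal/marker ratio**: per-punctum mean_signal / mean_marker; puncta
  with non-positive marker mean are excluded and counted.
- **Accumulation index**: the cited index has no published closed form in
  the source procedure, so the bounded enrichment ratio AI = I/(I+B) is
  adopted: I is the mean signal intensity over the punctum's arc-length
  span on its process, B the mean over the shaft (non-punctum) positions
  of the same process. AI is dimensionless, bounded in [0, 1], invariant
  to rescaling the whole profile, monotone in enrichment, and equals 0.5
  on a uniform profile. Profiles sample the signal channel by bilinear
  interpolation at arc-length step p/2 (below the pixel Nyquist spacing);
  punctum spans are the arc intervals covered by the projected pixel
  centres. AI is flagged undefined when a process has no shaft positions
  or when I + B = 0. Absolute AI values are therefore internally
  consistent but not comparable to other accumulation-index definitions.
  Note that a *uniform multiplicative* reduction of the signal channel
  leaves AI unchanged (scale invariance); AI responds to spatial
  redistribution, not to overall intensity loss.
- **SEM** (s.d./√n, ddof = 1) is reported rather than s.d. to match the
  mean ± SEM reporting convention; it is NaN-flagged for n < 2.

## Distribution comparison

Per-punctum signal intensities are pooled per condition (per-image means
are available as an option; pooling is the default because distributional
comparison needs the per-punctum sample). The two-sample KS statistic is
the supremum of |F₁ − F₂| over the pooled sample points, computed
tie-safely. The p-value uses the asymptotic Kolmogorov distribution
Q(λ) = 2Σ_{k≥1}(−1)^{k−1}e^{−2k²λ²} evaluated at
λ = D(√nₑ + 0.12 + 0.11/√nₑ), nₑ = n₁n₂/(n₁+n₂) — the standard
small-sample correction, accurate at the hundreds-of-puncta scale this
pipeline produces. An exact conditional p-value is available for tie-free
samples with n₁·n₂ ≤ 4·10⁴, computed by integer lattice-path counting
over the permutation null (no floating-point comparisons inside the
recursion). The pairwise matrix reports one row per unordered condition
pair at α = 0.05 (two-sided) with **no multiplicity correction**,
mirroring the presentation it reproduces; this is recorded in the output
metadata. Kernel density estimates use a Gaussian kernel with Silverman's
rule h = 0.9·min(sd, IQR/1.34)·n^{−1/5} on a grid spanning ±3h beyond the
data range; a zero-variance sample is an error suggesting a fixed
bandwidth.

## The simulator

The generator emulates confocal fields of cultured neurons; defaults are
a 51.2 µm × 51.2 µm field at 0.1 µm/pixel.

- **Processes** are random polylines with Ornstein–Uhlenbeck curvature
  (correlation length `process_smoothness`, default 8 µm), steered gently
  back toward the field centre near the border. Default: 3 processes of
  40 µm.
- **Puncta placement** is a stationary hard-core renewal process on arc
  length: spacings are `min_separation_um` + Exp(1/rate − min_separation),
  with the first point drawn from the equilibrium delay distribution, so
  the expected count is exactly rate · length; `min_separation_um = 0`
  recovers a homogeneous Poisson process. The default rate is 0.4 puncta
  per µm with 1.5 µm separation — discrete, resolvable boutons. The
  separation is additionally enforced in 2-D across processes (candidates
  closer than the separation to an already-placed punctum are dropped),
  so realized density can fall slightly below nominal where traces cross,
  hairpin, or pass near themselves; recovery tests therefore use straight
  or gently curved trace geometries, where placement is unbiased.
- **Spots** are disks of per-spot core radius (true area = πr², default
  radius U(0.38, 0.5) µm, i.e. areas 0.45–0.79 µm², inside the filter
  window) convolved with an isotropic Gaussian PSF (σ = 0.2 µm). Each
  spot appears in both channels with independent log-normal amplitudes
  (default ln-scale µ = 5.0, σ = 0.25, i.e. median ≈ 148 a.u.). The
  signal-channel amplitude of **on-process puncta only** is multiplied by
  `condition_factor` (1 = control; 0.5 emulates the knockdown /
  ischemia-like reduction). All random draws happen before the factor is
  applied, so identical seeds with different factors yield bit-identical
  marker channels and exactly rescaled signal amplitudes.
- **Distractors** (default 3/image) are punctum-like spots rejection-
  sampled to lie farther than 1 µm + radius + 0.5 µm (centre distance)
  from every process, so the pixel-level distance filter removes them by
  construction. **Speckles** (default 10/image) have core radius
  U(0.06, 0.12) µm — true area well below 0.35 µm², and a blurred
  above-threshold footprint that also stays below the window — so the
  area filter removes whichever of them are detected.
- **Noise** is additive Gaussian (default σ = 7.5 a.u. ≈ 5 % of the
  median amplitude), clipped at zero. This tests threshold robustness; it
  is not a photon-statistics model.
- Ground truth records every rendered spot: centroid, core radius/area,
  per-channel amplitude, pre-noise mean intensity over the core pixels
  (computed from the puncta-only rendering, so condition scaling is
  exact), the on/off-process flag and process index.

What the simulator does **not** emulate: 3-D structure, photobleaching,
chromatic shift, camera-specific noise, spatially varying background,
partially overlapping boutons, and spatial *redistribution* of signal
within a process (the condition effect is purely multiplicative). Passing
tests therefore demonstrate correctness of the measurement chain under a
controlled image-formation model, not performance on real micrographs —
in particular, real knockdown data can change AI, while uniform simulated
scaling cannot.

## Problem sizes and numerical choices

Tests and the acceptance script run on reduced but statistically adequate
sizes chosen for desk-scale reproducibility: 256×256 fields, 20-image
fidelity seed sets, 60 images for density recovery, ≥ 200 puncta per
condition for factor recovery, 500 null replicates (n = 500/arm) for KS
calibration and 100 replicates for power. Fixture tests that exercise the
inclusive filter boundaries use exactly representable geometry (35- and
1000-pixel components at 0.1 µm/px; a 0.125 µm/px grid for the 1.0 µm
distance boundary, where 8 rows × 0.125 µm is binary-exact). Detection
fidelity fixtures use a fixed threshold (25 on the normalized scale) so
the measured property is the filter chain, not threshold selection; the
auto mode is validated separately against a brute-force inter-class
variance scan.

## Known limitations

- Touching puncta are not split (no watershed); closer-than-separation
  boutons merge into one component, as in the original procedure.
- The trace rasterization is single-pixel-width by construction and is
  not used for distance computation (polylines are, exactly).
- Mask-derived traces (skeleton tracing) approximate polylines at pixel
  resolution; branch points split paths at junction pixels.
- The exact KS option requires tie-free data; intensities from simulated
  or real-valued images satisfy this in practice.
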