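"""Synthetic microscopy data with fully known ground truth.

Three generators mirror the three measurement modalities of the study:

``generate_scene``
    Multi-channel photon-count images of cells (elliptical DAPI-like nuclei,
    a cytosolic rim, bright endo-lysosomal vesicles, an injected-cell tracer
    channel and a target channel with per-cell knockdown).  Every pixel is a
    Poisson draw with mean ``background + gain * local concentration``, the
    linear photon-counting regime of a hybrid detector.

``generate_frap_trace``
    Three-ROI recovery traces following F(t) = a(1 - exp(-t/tau)) + c with
    acquisition bleaching, an immobile fraction and Gaussian read noise, on
    the study's acquisition grid (10 prebleach + 70 recovery frames, 97 ms).

``generate_fcs_trace``
    Binned photon traces from 2D Brownian point emitters crossing a Gaussian
    detection profile in a periodic box, with Poisson emission and a
    dark-state (triplet) duty cycle.

All randomness flows from the explicit ``seed`` of each specification; equal
specs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import lfilter

from .errors import InvalidParameterError, OverlappingNucleiError
from .fcs import IntensityTrace
from .frap import RecoveryTrace

# --------------------------------------------------------------------------
# scenes


@dataclass(frozen=True)
class NucleusSpec:
    """One elliptical nucleus: center (row, col) px, semi-axes px, orientation rad."""
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0


@dataclass(frozen=True)
class VesicleSpec:
    """One bright vesicle: center (row, col) px, radius px, concentration mol/L."""
    center: tuple[float, float]
    radius: float
    concentration: float


@dataclass
class SceneSpec:
    """Declarative description of a synthetic multi-channel field of cells.

    ``compartment_concentrations`` maps channel name -> {"nucleus": c,
    "cytosol": c} in mol/L.  Channels listed in ``injected_only_channels``
    (the microinjection tracer) are rendered only inside injected cells;
    channels in ``knockdown_channels`` have their concentration multiplied by
    ``knockdown_factor`` in injected cells.  Vesicles are rendered on
    ``vesicle_channel`` as Gaussian-blurred disks added on top of the
    cytosolic level.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.3  # um / px
    nuclei: Sequence[NucleusSpec] = field(default_factory=list)
    cytosol_margin: int = 12  # px dilation beyond the nucleus
    vesicles: Sequence[VesicleSpec] = field(default_factory=list)
    compartment_concentrations: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    injected_cell_ids: frozenset[int] = field(default_factory=frozenset)
    injected_only_channels: frozenset[str] = frozenset({"tracer"})
    knockdown_channels: frozenset[str] = frozenset({"target"})
    knockdown_factor: float = 1.0
    counts_per_molar: float = 5e8  # counts L / mol  (50 counts per 100 nM)
    background_counts: float = 0.5
    bit_depth: int = 16
    vesicle_channel: str = "lna"
    vesicle_blur_sigma: float = 1.0
    overlap_tolerance: float = 0.2  # fraction of the smaller nucleus area
    seed: int = 0

    def __post_init__(self):
        self.nuclei = [n if isinstance(n, NucleusSpec) else NucleusSpec(*n)
                       for n in self.nuclei]
        self.vesicles = [v if isinstance(v, VesicleSpec) else VesicleSpec(*v)
                         for v in self.vesicles]
        if not 0.0 <= self.knockdown_factor <= 1.0:
            raise InvalidParameterError("knockdown_factor must lie in [0, 1]")
        if self.counts_per_molar <= 0:
            raise InvalidParameterError("counts_per_molar must be > 0")
        if self.background_counts < 0:
            raise InvalidParameterError("background_counts must be >= 0")
        for ch, comps in self.compartment_concentrations.items():
            for comp, c in comps.items():
                if c < 0:
                    raise InvalidParameterError(
                        f"negative concentration for {ch}/{comp}")
        rows, cols = self.image_shape
        for n in self.nuclei:
            r, c = n.center
            rad = max(n.semi_axes)
            if not (rad <= r <= rows - rad and rad <= c <= cols - rad):
                raise InvalidParameterError(
                    f"nucleus at {n.center} extends beyond image bounds")
        for v in self.vesicles:
            r, c = v.center
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvalidParameterError(
                    f"vesicle at {v.center} outside image bounds")
            if v.concentration < 0:
                raise InvalidParameterError("vesicle concentration must be >= 0")


@dataclass
class Scene:
    """Generated scene: photon-count images plus ground truth."""

    images: dict[str, np.ndarray]
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    vesicle_labels: np.ndarray
    truth: "object"  # pandas.DataFrame: per-nucleus ground truth
    vesicle_truth: "object"  # pandas.DataFrame: per-vesicle ground truth
    spec: SceneSpec


def _ellipse_distance_field(spec: NucleusSpec, shape):
    """Normalized elliptical distance (<= 1 inside) over a bounding window."""
    (r0, c0), (sa, sb), th = spec.center, spec.semi_axes, spec.orientation
    pad = int(math.ceil(max(sa, sb))) + 2
    rlo, rhi = max(0, int(r0) - pad), min(shape[0], int(r0) + pad + 1)
    clo, chi = max(0, int(c0) - pad), min(shape[1], int(c0) + pad + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(th) + dc * math.sin(th)
    v = -dr * math.sin(th) + dc * math.cos(th)
    d = np.sqrt((u / sa) ** 2 + (v / sb) ** 2)
    return (slice(rlo, rhi), slice(clo, chi)), d


def _render_nuclei(spec: SceneSpec):
    """Label map of nuclei; overlap conflicts go to the nearer (normalized)
    center.  Rejects the scene if any pair overlaps beyond tolerance."""
    shape = spec.image_shape
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float64)
    areas = []
    for k, nuc in enumerate(spec.nuclei, start=1):
        window, d = _ellipse_distance_field(nuc, shape)
        inside = d <= 1.0
        areas.append(int(inside.sum()))
        sub_lab = labels[window]
        sub_best = best[window]
        overlap = inside & (sub_lab > 0)
        if overlap.any():
            other = np.bincount(sub_lab[overlap]).argmax()
            frac = overlap.sum() / min(areas[k - 1], areas[other - 1])
            if frac > spec.overlap_tolerance:
                raise OverlappingNucleiError(
                    f"nuclei {other} and {k} overlap by {frac:.0%} "
                    f"(> tolerance {spec.overlap_tolerance:.0%})")
        claim = inside & (d < sub_best)
        sub_lab[claim] = k
        sub_best[claim] = d[claim]
    return labels


def generate_scene(spec: SceneSpec) -> Scene:
    """Render photon-count images and ground truth for a scene.

    Returns a :class:`Scene` whose per-channel images are independent Poisson
    draws with mean ``background_counts + counts_per_molar * concentration``,
    clipped to the configured bit depth.
    """
    import pandas as pd
    from skimage.segmentation import expand_labels

    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    nucleus_labels = _render_nuclei(spec)
    cell_labels = expand_labels(nucleus_labels, distance=spec.cytosol_margin)

    vesicle_labels = np.zeros(shape, dtype=np.int32)
    vesicle_map = np.zeros(shape, dtype=np.float64)
    for k, ves in enumerate(spec.vesicles, start=1):
        (r0, c0), rad = ves.center, ves.radius
        pad = int(math.ceil(rad)) + 3
        rlo, rhi = max(0, int(r0) - pad), min(shape[0], int(r0) + pad + 1)
        clo, chi = max(0, int(c0) - pad), min(shape[1], int(c0) + pad + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
        vesicle_map[rlo:rhi, clo:chi][disk] += ves.concentration
        vesicle_labels[rlo:rhi, clo:chi][disk] = k
    if spec.vesicles and spec.vesicle_blur_sigma > 0:
        vesicle_map = ndi.gaussian_filter(vesicle_map, spec.vesicle_blur_sigma)

    nucleus_mask = nucleus_labels > 0
    cytosol_mask = (cell_labels > 0) & ~nucleus_mask
    injected_mask = np.isin(cell_labels, list(spec.injected_cell_ids)) & (cell_labels > 0)

    max_count = 2 ** spec.bit_depth - 1
    images: dict[str, np.ndarray] = {}
    conc_maps: dict[str, np.ndarray] = {}
    channels = set(spec.compartment_concentrations) | (
        {spec.vesicle_channel} if spec.vesicles else set())
    for ch in sorted(channels):
        comps = spec.compartment_concentrations.get(ch, {})
        conc = np.zeros(shape, dtype=np.float64)
        conc[nucleus_mask] = comps.get("nucleus", 0.0)
        conc[cytosol_mask] = comps.get("cytosol", 0.0)
        if ch in spec.injected_only_channels:
            conc *= injected_mask
        if ch in spec.knockdown_channels:
            conc[injected_mask] *= spec.knockdown_factor
        if ch == spec.vesicle_channel:
            conc = conc + vesicle_map
        lam = spec.background_counts + spec.counts_per_molar * conc
        img = rng.poisson(lam)
        np.clip(img, 0, max_count, out=img)
        dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
        images[ch] = img.astype(dtype)
        conc_maps[ch] = conc

    rows = []
    for k in range(1, len(spec.nuclei) + 1):
        m = nucleus_labels == k
        com = ndi.center_of_mass(m)
        row = {"object_id": k, "area_px": int(m.sum()),
               "centroid_row": com[0], "centroid_col": com[1],
               "injected": k in spec.injected_cell_ids}
        for ch in sorted(channels):
            row[f"conc_{ch}"] = float(conc_maps[ch][m].mean()) if m.any() else 0.0
            row[f"expected_counts_{ch}"] = (spec.background_counts +
                                            spec.counts_per_molar * row[f"conc_{ch}"])
        rows.append(row)
    truth = pd.DataFrame(rows)

    vrows = [{"object_id": k, "concentration": v.concentration,
              "radius_px": v.radius,
              "center_row": v.center[0], "center_col": v.center[1]}
             for k, v in enumerate(spec.vesicles, start=1)]
    vesicle_truth = pd.DataFrame(vrows)

    return Scene(images=images, nucleus_labels=nucleus_labels,
                 cell_labels=cell_labels, vesicle_labels=vesicle_labels,
                 truth=truth, vesicle_truth=vesicle_truth, spec=spec)


def random_nuclei(n: int, image_shape: tuple[int, int],
                  diameter_range: tuple[float, float] = (25.0, 100.0),
                  rng: np.random.Generator | None = None,
                  n_touching_pairs: int = 0,
                  max_tries: int = 20000) -> list[NucleusSpec]:
    """Place ``n`` non-overlapping elliptical nuclei, optionally with touching
    pairs (centers at ~0.95x the sum of radii so the disks just fuse).

    Used to build fields resembling a confluent culture: diameters uniform in
    ``diameter_range``, mild eccentricity, random orientation.
    """
    rng = rng or np.random.default_rng(0)
    placed: list[NucleusSpec] = []
    rows, cols = image_shape

    def mean_radius(nuc):
        return 0.5 * (nuc.semi_axes[0] + nuc.semi_axes[1])

    def fits(center, rad, gap=4.0):
        for other in placed:
            d = math.hypot(center[0] - other.center[0], center[1] - other.center[1])
            if d < rad + max(other.semi_axes) + gap:
                return False
        return True

    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        d = rng.uniform(*diameter_range)
        ecc = rng.uniform(0.75, 1.0)
        sa, sb = d / 2, d / 2 * ecc
        rad = max(sa, sb)
        pair = len(placed) < 2 * n_touching_pairs and placed and len(placed) % 2 == 1
        if pair:
            anchor = placed[-1]
            ang = rng.uniform(0, 2 * math.pi)
            dist = 0.95 * (max(anchor.semi_axes) + min(sa, sb))
            center = (anchor.center[0] + dist * math.sin(ang),
                      anchor.center[1] + dist * math.cos(ang))
            if not (rad <= center[0] <= rows - rad and rad <= center[1] <= cols - rad):
                continue
            ok = True
            for other in placed[:-1]:
                dd = math.hypot(center[0] - other.center[0], center[1] - other.center[1])
                if dd < rad + max(other.semi_axes) + 4.0:
                    ok = False
                    break
            if not ok:
                continue
        else:
            center = (rng.uniform(rad + 1, rows - rad - 1),
                      rng.uniform(rad + 1, cols - rad - 1))
            if not fits(center, rad):
                continue
        placed.append(NucleusSpec(center, (sa, sb), rng.uniform(0, math.pi)))
    if len(placed) < n:
        raise InvalidParameterError(
            f"could not place {n} nuclei in {image_shape} after {max_tries} tries")
    return placed


# --------------------------------------------------------------------------
# FRAP traces


@dataclass
class FrapGroundTruth:
    """True parameters behind a synthetic FRAP experiment.

    The recovery inside the bleached spot follows, in prebleach-normalized
    units, F(t) = c + a(1 - exp(-t/tau)) with c = 1 - bleach_depth and
    a = mobile_fraction * bleach_depth, modulated by acquisition bleaching
    exp(-acquisition_bleach_rate * t) that also affects the reference ROI.
    Frame timing defaults to the study's acquisition: 10 prebleach and 70
    recovery frames at 97 ms.
    """

    mobile_fraction: float = 0.71
    tau: float = 1.8137  # s
    bleach_depth: float = 0.8
    prebleach_level: float = 100.0  # counts
    background_level: float = 5.0  # counts
    acquisition_bleach_rate: float = 0.01  # 1/s
    frame_interval: float = 0.097  # s
    n_prebleach: int = 10
    n_postbleach: int = 70
    bleach_radius: float = 2.0  # um
    reference_level: float | None = None  # counts; defaults to 0.8x prebleach
    noise_sd: float = 0.0  # counts, Gaussian, on bleach and reference ROIs
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError("tau must be > 0")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise InvalidParameterError("mobile_fraction must lie in [0, 1]")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise InvalidParameterError("bleach_depth must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_prebleach < 1 or self.n_postbleach < 1:
            raise InvalidParameterError("frame counts must be >= 1")


def generate_frap_trace(gt: FrapGroundTruth) -> RecoveryTrace:
    """Simulate the three-ROI recovery trace implied by ``gt``.

    The bleached-spot ROI carries the recovery model plus background and
    noise; the reference ROI carries only acquisition bleaching; the
    background ROI is flat with reduced noise (large, structure-free area).
    """
    rng = np.random.default_rng(gt.seed)
    n = gt.n_prebleach + gt.n_postbleach
    t = np.arange(n) * gt.frame_interval
    f0 = 1.0 - gt.bleach_depth
    a = gt.mobile_fraction * gt.bleach_depth
    model = np.ones(n)
    tp = t[gt.n_prebleach:] - t[gt.n_prebleach]
    model[gt.n_prebleach:] = f0 + a * (1.0 - np.exp(-tp / gt.tau))
    decay = np.exp(-gt.acquisition_bleach_rate * t)
    ref_level = gt.reference_level if gt.reference_level is not None \
        else 0.8 * gt.prebleach_level
    roi_bleach = gt.prebleach_level * model * decay + gt.background_level
    roi_reference = ref_level * decay + gt.background_level
    roi_background = np.full(n, gt.background_level)
    if gt.noise_sd > 0:
        # shot-noise scaling: noise_sd is the SD at the prebleach level and
        # each sample's SD follows the square root of its expected signal
        def shot(mean):
            scale = np.sqrt(np.clip(mean, 0.0, None) / gt.prebleach_level)
            return rng.normal(0.0, 1.0, n) * gt.noise_sd * scale
        roi_bleach = roi_bleach + shot(roi_bleach)
        roi_reference = roi_reference + shot(roi_reference)
        roi_background = roi_background + shot(roi_background)
    return RecoveryTrace(time=t, roi_bleach=roi_bleach,
                         roi_reference=roi_reference,
                         roi_background=roi_background,
                         n_prebleach=gt.n_prebleach,
                         bleach_radius=gt.bleach_radius)


# --------------------------------------------------------------------------
# FCS traces


@dataclass
class FcsGroundTruth:
    """True parameters behind a simulated FCS intensity trace.

    ``n_particles_mean`` is the mean number of emitters apparent in the
    detection area (the N an ideal fit returns); the simulation populates a
    periodic box of side ``box_size`` (default 8 x w0) at the matching
    density.  ``dynamics_stride`` controls the Brownian propagation step
    (``stride * bin_time``); positions are exact at multiples of that step,
    so fits should use lags above ~2 steps.  A slow Ornstein-Uhlenbeck
    modulation of relative variance 1/n_particles restores the global
    concentration-fluctuation mode a closed box lacks.
    """

    n_particles_mean: float = 10.0
    D_true: float = 15.625  # um^2/s  (tau_D = w0^2 / 4D = 1 ms at w0 = 0.25)
    w0: float = 0.25  # um, lateral 1/e^2 radius
    box_size: float | None = None  # um; default 8 * w0
    brightness: float = 1.0  # expected counts per particle per bin at focus
    bin_time: float = 1e-5  # s
    duration: float = 30.0  # s
    triplet_fraction: float = 0.0
    triplet_lifetime: float = 4e-6  # s
    dynamics_stride: int | None = None  # default: step <= tau_D / 10
    number_mode_time: float | None = None  # s, OU time of the global mode
    seed: int = 0

    def __post_init__(self):
        if self.D_true <= 0:
            raise InvalidParameterError("D_true must be > 0")
        if self.box_size is None:
            self.box_size = 8.0 * self.w0
        if not self.w0 < self.box_size / 4:
            raise InvalidParameterError("w0 must be < box_size / 4")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise InvalidParameterError("triplet_fraction must lie in [0, 1)")
        if self.brightness < 0:
            raise InvalidParameterError("brightness must be >= 0")
        if self.bin_time <= 0 or self.duration <= 0:
            raise InvalidParameterError("bin_time and duration must be > 0")

    @property
    def tau_D(self) -> float:
        """Diffusion time w0^2 / (4 D), s."""
        return self.w0 ** 2 / (4.0 * self.D_true)

    @property
    def n_particles_box(self) -> int:
        """Particles simulated in the periodic box at the matching density."""
        density = self.n_particles_mean / (math.pi * self.w0 ** 2)
        return max(1, int(round(density * self.box_size ** 2)))


def generate_fcs_trace(gt: FcsGroundTruth) -> IntensityTrace:
    """Simulate a binned photon-count trace from 2D Brownian emitters.

    Each particle performs a periodic-box random walk with per-step standard
    deviation sqrt(2 D dt); the expected count per bin is ``brightness *
    sum_i exp(-2 r_i^2 / w0^2)`` thinned by the triplet duty cycle, and the
    emitted count is Poisson.  Raises if the step SD exceeds box/10
    (discretization invalid).
    """
    rng = np.random.Generator(np.random.SFC64(gt.seed))
    n_bins = int(round(gt.duration / gt.bin_time))
    stride = gt.dynamics_stride
    if stride is None:
        stride = max(1, min(10, int(gt.tau_D / (10.0 * gt.bin_time))))
    stride = max(1, int(stride))
    n_coarse = n_bins // stride
    dt = gt.bin_time * stride
    n_p = gt.n_particles_box
    box = gt.box_size
    sd = math.sqrt(2.0 * gt.D_true * dt)
    if sd > box / 10.0:
        raise InvalidParameterError(
            f"Brownian step SD {sd:.3g} um exceeds box/10 = {box / 10:.3g} um; "
            "discretization invalid")

    lam = np.empty(n_coarse, dtype=np.float32)
    wsq = np.empty(n_coarse, dtype=np.float32) if gt.triplet_fraction > 0 else None
    pos = rng.uniform(0, box, size=(2 * n_p, 1)).astype(np.float32)
    half = np.float32(box / 2)
    inv = np.float32(-2.0 / gt.w0 ** 2)
    sd32 = np.float32(sd)
    box32 = np.float32(box)
    chunk = max(1, min(n_coarse, int(2e7 // (2 * n_p)) or 1))
    for s in range(0, n_coarse, chunk):
        m = min(chunk, n_coarse - s)
        steps = rng.standard_normal((2 * n_p, m), dtype=np.float32)
        steps *= sd32
        np.cumsum(steps, axis=1, out=steps)
        steps += pos
        steps %= box32
        pos = steps[:, -1:].copy()
        d = steps - half
        d *= d
        w = np.exp(inv * (d[:n_p] + d[n_p:]))
        lam[s:s + m] = w.sum(axis=0)
        if wsq is not None:
            wsq[s:s + m] = (w * w).sum(axis=0)

    # grand-canonical correction: slow global number-fluctuation mode.
    # The OU time must sit well above the fit lag window (so the restored
    # q=0 mode looks flat there) yet well below the trace duration (so the
    # running means used for ACF normalization average over it).
    theta = gt.number_mode_time
    if theta is None:
        theta = min(0.3, max(0.1, 1000.0 * gt.tau_D))
    if n_p > 0 and theta > 0:
        rho = math.exp(-dt / theta)
        eps = rng.standard_normal(n_coarse) * math.sqrt((1 - rho ** 2) / n_p)
        x0 = rng.standard_normal() / math.sqrt(n_p)
        xi = lfilter([1.0], [1.0, -rho], eps, zi=[rho * x0])[0]
        lam = lam * np.clip(1.0 + xi, 0.0, None).astype(np.float32)
        if wsq is not None:
            wsq = wsq * np.clip(1.0 + xi, 0.0, None).astype(np.float32) ** 2

    T = gt.triplet_fraction
    lam_b = np.repeat(lam, stride)[:n_bins].astype(np.float64) * gt.brightness
    if T > 0:
        # dark-state duty cycle: equilibrium thinning plus variance-matched
        # per-bin occupancy noise (telegraph unresolvable below bin_time)
        tau_c = gt.triplet_lifetime * (1.0 - T)
        var_occ = 2.0 * T * (1.0 - T) * tau_c / gt.bin_time
        wsq_b = np.repeat(wsq, stride)[:n_bins].astype(np.float64)
        occ_noise = rng.standard_normal(n_bins) * np.sqrt(
            var_occ * wsq_b) * gt.brightness
        lam_b = np.clip(lam_b * (1.0 - T) + occ_noise, 0.0, None)
    counts = rng.poisson(lam_b)
    return IntensityTrace(counts=counts, bin_time=gt.bin_time)
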