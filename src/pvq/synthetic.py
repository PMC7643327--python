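"""Ground-truth-annotated synthetic inputs for every pipeline stage.

No imaging data from the original experiments are publicly deposited, so
this module emulates the inputs the analysis assumes, with known answers:

* line-scan kymographs of a pulsating vessel whose diameter follows a
  sinusoid at cardiac frequency plus slow linear drift, rendered with a
  bright lumen (intravascular dextran convention), area-weighted sub-pixel
  wall edges, optional wall blur and noise;
* multi-channel coronal-slice images with smooth-muscle (SMA) rings,
  complementary amyloid (MX04) arcs at known coverage fractions, a
  collagen-IV network at a known area fraction, parenchymal plaques at a
  known burden, and tracer-filled arteries for drainage counting;
* semicircular-cortex slices with a known dorsal/lateral/ventral tracer
  gradient, per-region plaque burden and radially oriented penetrating
  vessels;
* tabular regional datasets with anticorrelated plaque-burden and influx
  gradients for the regression stage.

Every generator is seeded and bit-deterministic, and returns the rendered
data together with a ground-truth record measured from what was actually
drawn, so noise-free outputs are exactly recoverable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from .errors import ValidationError
from .pulsatility import DiameterTrace, Kymograph
from .quant import ChannelImage

REGIONS = ("dorsal", "lateral", "ventral")
NOISE_MODELS = ("none", "gaussian", "poisson")


def _apply_noise(img: np.ndarray, model: str, param: float, rng: np.random.Generator) -> np.ndarray:
    if model == "none":
        return img
    if model == "gaussian":
        # detector clamp: intensities cannot go negative
        return np.clip(img + rng.normal(0.0, param, img.shape), 0.0, None)
    if model == "poisson":
        # param = photons per intensity unit
        return rng.poisson(np.clip(img, 0, None) * param) / param
    raise ValidationError(f"unknown noise model {model!r}; expected one of {NOISE_MODELS}")


def _check_noise(model: str, param: float) -> None:
    if model not in NOISE_MODELS:
        raise ValidationError(f"unknown noise model {model!r}; expected one of {NOISE_MODELS}")
    if model != "none" and param <= 0:
        raise ValidationError(f"{model} noise requires a positive parameter")


# ---------------------------------------------------------------------------
# kymographs


@dataclass
class KymographSpec:
    """Generative model of a line-scan record across one pulsating vessel.

    The diameter trajectory is
    ``D(t) = baseline + amplitude * sin(2 pi f t) + drift * t``:
    a sinusoid at cardiac frequency (5-10 Hz in the mouse) is the minimal
    waveform exercising both pulsatility formulas, and the drift term lets
    tests separate the moving-average baseline from the oscillation.
    """

    baseline_diameter_um: float = 10.0
    pulse_amplitude_um: float = 1.0
    pulse_frequency_hz: float = 6.0
    duration_ms: float = 4000.0
    line_period_ms: float = 1.0
    pixel_size_um: float = 0.25
    wall_blur_sigma_px: float = 1.0
    noise_model: str = "none"
    noise_param: float = 0.0
    drift_um_per_s: float = 0.0
    background_level: float = 100.0
    lumen_level: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_diameter_um", "pulse_frequency_hz", "duration_ms",
                     "line_period_ms", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.pulse_amplitude_um < 0:
            raise ValidationError("pulse_amplitude_um must be non-negative")
        if self.wall_blur_sigma_px < 0:
            raise ValidationError("wall_blur_sigma_px must be non-negative")
        if self.lumen_level <= self.background_level:
            raise ValidationError("lumen_level must exceed background_level")
        min_diam = (
            self.baseline_diameter_um
            - self.pulse_amplitude_um
            - abs(self.drift_um_per_s) * self.duration_ms / 1000.0
        )
        if min_diam <= 0:
            raise ValidationError(
                "baseline_diameter_um minus pulse amplitude and drift must stay positive"
            )
        if 1000.0 / self.line_period_ms < 2 * self.pulse_frequency_hz:
            raise ValidationError(
                "line rate must give at least 2 samples per pulse period"
            )
        _check_noise(self.noise_model, self.noise_param)

    def diameter_um(self, t_ms: np.ndarray) -> np.ndarray:
        """Analytic ground-truth diameter at times ``t_ms``."""
        t = np.asarray(t_ms, dtype=float)
        return (
            self.baseline_diameter_um
            + self.pulse_amplitude_um * np.sin(2 * np.pi * self.pulse_frequency_hz * t / 1000.0)
            + self.drift_um_per_s * t / 1000.0
        )


def make_kymograph(spec: KymographSpec, vessel_id: str = "synthetic",
                   vessel_type: str = "surface_artery") -> tuple[Kymograph, DiameterTrace]:
    """Render a kymograph and return it with the exact analytic diameter trace.

    Each time line holds a bright lumen of width ``D(t)`` centred on the scan
    line; edge pixels are area-weighted so wall positions are sub-pixel, then
    blurred by ``wall_blur_sigma_px`` along the spatial axis and corrupted by
    the configured noise.  Because the blur is symmetric about each wall, the
    half-maximum crossings of the noiseless profile sit exactly at the
    analytic wall positions.
    """
    spec.validate()
    n_t = int(round(spec.duration_ms / spec.line_period_ms))
    t = np.arange(n_t) * spec.line_period_ms
    D = spec.diameter_um(t)

    max_d = D.max()
    margin_um = max(4.0, 0.5 * max_d) + 4 * spec.wall_blur_sigma_px * spec.pixel_size_um
    n_px = int(math.ceil((max_d + 2 * margin_um) / spec.pixel_size_um))
    n_px += 1 - n_px % 2  # odd, so the scan line has a centre pixel
    center = (n_px - 1) / 2.0

    # area-weighted lumen coverage per pixel: pixel i spans [i-0.5, i+0.5] px
    half_px = D / (2.0 * spec.pixel_size_um)
    rows = np.arange(n_px)[:, None]
    lo = center - half_px[None, :]
    hi = center + half_px[None, :]
    cov = np.clip(np.minimum(rows + 0.5, hi) - np.maximum(rows - 0.5, lo), 0.0, 1.0)
    img = spec.background_level + (spec.lumen_level - spec.background_level) * cov

    if spec.wall_blur_sigma_px > 0:
        img = gaussian_filter1d(img, spec.wall_blur_sigma_px, axis=0, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    img = _apply_noise(img, spec.noise_model, spec.noise_param, rng)

    kymo = Kymograph(
        intensities=img.astype(np.float32),
        pixel_size_um=spec.pixel_size_um,
        line_period_ms=spec.line_period_ms,
        vessel_id=vessel_id,
        vessel_type=vessel_type,
    )
    truth = DiameterTrace(
        t_ms=t,
        D_um=D,
        valid=np.ones(n_t, dtype=bool),
        line_period_ms=spec.line_period_ms,
        provenance={"source": "analytic ground truth", "spec_seed": spec.seed},
    )
    return kymo, truth


# ---------------------------------------------------------------------------
# slice images


@dataclass
class SliceVessel:
    """One vessel cross-section: an annular wall of smooth muscle with an
    optional amyloid arc and an optional tracer fill."""

    center: tuple[int, int]
    radius_px: int
    vessel_type: str = "surface_artery"
    wall_px: int = 3
    mx04_fraction: float = 0.0
    sma_fraction: float | None = None  # None -> complement of the MX04 arc
    tracer_positive: bool = False


@dataclass
class SliceSpec:
    """Layout and channel ground truth of a synthetic immunofluorescence slice."""

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    vessels: list[SliceVessel] = field(default_factory=list)
    collagen_density_fraction: float = 0.0
    density_roi_center: tuple[int, int] | None = None
    density_roi_um: float = 400.0
    plaque_fraction: float = 0.0
    background_level: float = 10.0
    foreground_level: float = 200.0
    noise_model: str = "none"
    noise_param: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.foreground_level <= self.background_level:
            raise ValidationError("foreground_level must exceed background_level")
        for frac_name in ("collagen_density_fraction", "plaque_fraction"):
            frac = getattr(self, frac_name)
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{frac_name} must lie in [0, 1]")
        h, w = self.shape
        for i, v in enumerate(self.vessels):
            if not 0.0 <= v.mx04_fraction <= 1.0:
                raise ValidationError(f"vessel {i}: mx04_fraction must lie in [0, 1]")
            if v.sma_fraction is not None and not 0.0 <= v.sma_fraction <= 1.0:
                raise ValidationError(f"vessel {i}: sma_fraction must lie in [0, 1]")
            if v.radius_px <= 0 or v.wall_px <= 0:
                raise ValidationError(f"vessel {i}: radius and wall must be positive")
            r, c = v.center
            ext = v.radius_px + v.wall_px
            if r - ext < 0 or c - ext < 0 or r + ext >= h or c + ext >= w:
                raise ValidationError(f"vessel {i}: layout overflows the canvas")
        for i, a in enumerate(self.vessels):
            for j, b in enumerate(self.vessels[i + 1:], start=i + 1):
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d <= a.radius_px + a.wall_px + b.radius_px + b.wall_px + 2:
                    raise ValidationError(f"vessels {i} and {j} overlap")
        _check_noise(self.noise_model, self.noise_param)


def _ring_mask(shape, center, radius, wall) -> np.ndarray:
    outer = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius + wall, shape=shape)
    outer[rr, cc] = True
    inner = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    inner[rr, cc] = True
    return outer & ~inner


def _arc_pixels(mask: np.ndarray, center, start_deg: float, n_pixels: int):
    """The `n_pixels` mask pixels whose polar angle follows `start_deg`,
    in angular order (deterministic arc selection)."""
    rr, cc = np.nonzero(mask)
    ang = (np.degrees(np.arctan2(rr - center[0], cc - center[1])) - start_deg) % 360.0
    order = np.argsort(ang, kind="stable")
    take = order[:n_pixels]
    return rr[take], cc[take]


def make_slice_image(spec: SliceSpec) -> tuple[ChannelImage, pd.DataFrame, dict]:
    """Render a multi-channel slice and its per-vessel ground-truth table.

    Per vessel, the annular wall carries an MX04 arc occupying
    ``mx04_fraction`` of the wall pixels and an SMA arc that is its
    complement unless ``sma_fraction`` is given explicitly; tracer-positive
    vessels are additionally filled with 3k-FITC over the lumen and wall.
    The collagen-IV channel holds a stroke network whose positive-pixel
    count inside the density ROI is trimmed to exactly the requested
    fraction, and parenchymal MX04 plaques are added until the whole-image
    MX04 fraction is exact.  Ground truth is measured from the rendered
    boolean masks, so noise-free recovery is exact by construction.

    Returns the image, the per-vessel table, and a dict of slice-level
    truths (collagen density %, plaque burden %, tracer-positive count).
    """
    spec.validate()
    h, w = spec.shape
    shape = (h, w)
    rng = np.random.default_rng(spec.seed)
    bg, fg = spec.background_level, spec.foreground_level

    sma = np.zeros(shape, dtype=bool)
    mx04 = np.zeros(shape, dtype=bool)
    coliv = np.zeros(shape, dtype=bool)
    fitc = np.zeros(shape, dtype=bool)

    rows = []
    for i, v in enumerate(spec.vessels):
        wall = _ring_mask(shape, v.center, v.radius_px, v.wall_px)
        n_wall = int(wall.sum())
        start = float(rng.uniform(0, 360))
        k_m = int(round(v.mx04_fraction * n_wall))
        rr, cc = _arc_pixels(wall, v.center, start, k_m)
        mx_px = np.zeros(shape, dtype=bool)
        mx_px[rr, cc] = True
        if v.sma_fraction is None:
            sma_px = wall & ~mx_px
        else:
            k_s = int(round(v.sma_fraction * n_wall))
            rr, cc = _arc_pixels(wall, v.center, start + 360.0 * v.mx04_fraction, k_s)
            sma_px = np.zeros(shape, dtype=bool)
            sma_px[rr, cc] = True
        sma |= sma_px
        mx04 |= mx_px
        if v.tracer_positive:
            fill = np.zeros(shape, dtype=bool)
            rr, cc = draw_disk(v.center, v.radius_px + v.wall_px, shape=shape)
            fill[rr, cc] = True
            fitc |= fill
        union = sma_px | mx_px
        n_union = int(union.sum())
        rows.append(
            {
                "vessel_id": f"v{i}",
                "vessel_type": v.vessel_type,
                "center_row": v.center[0],
                "center_col": v.center[1],
                "radius_px": v.radius_px,
                "n_wall_px": n_wall,
                "n_mask_px": n_union,
                "sma_coverage_pct": 100.0 * sma_px.sum() / max(n_union, 1),
                "mx04_coverage_pct": 100.0 * mx_px.sum() / max(n_union, 1),
                "tracer_positive": v.tracer_positive,
            }
        )
    truth_table = pd.DataFrame(
        rows,
        columns=[
            "vessel_id", "vessel_type", "center_row", "center_col", "radius_px",
            "n_wall_px", "n_mask_px", "sma_coverage_pct", "mx04_coverage_pct",
            "tracer_positive",
        ],
    )

    # collagen-IV stroke network, exact area fraction inside the density ROI
    if spec.density_roi_center is None:
        roi_center = (h // 2, w // 2)
    else:
        roi_center = spec.density_roi_center
    side = int(round(spec.density_roi_um / spec.pixel_size_um))
    if spec.collagen_density_fraction == 0:
        side = min(side, h, w)  # no network requested; keep the ROI in-canvas
        roi_center = (h // 2, w // 2)
    r0, c0 = roi_center[0] - side // 2, roi_center[1] - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
        raise ValidationError("collagen density ROI overflows the canvas")
    roi_box = np.zeros(shape, dtype=bool)
    roi_box[r0:r0 + side, c0:c0 + side] = True
    target_px = int(round(spec.collagen_density_fraction * side * side))
    guard = 0
    while int((coliv & roi_box).sum()) < target_px:
        guard += 1
        if guard > 10_000:
            raise ValidationError("could not reach requested collagen density")
        p0 = rng.integers(0, h, 2)
        p1 = rng.integers(0, w, 2)
        stroke = np.zeros(shape, dtype=bool)
        rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
        stroke[rr, cc] = True
        stroke = dilation(stroke, disk_footprint(1))
        new_px = stroke & roi_box & ~coliv
        excess = int((coliv & roi_box).sum() + new_px.sum()) - target_px
        if excess > 0:  # trim the last stroke to hit the target exactly
            rr, cc = np.nonzero(new_px)
            drop = np.arange(len(rr))[-excess:]
            new_px[rr[drop], cc[drop]] = False
        coliv |= (stroke & ~roi_box) | new_px

    collagen_density_pct = 100.0 * (coliv & roi_box).sum() / (side * side)

    # parenchymal plaques: trim total MX04 count to the exact burden fraction.
    # Plaques are kept clear of the vessels so vascular amyloid and
    # parenchymal deposits remain distinct objects.
    vessel_clearance = np.zeros(shape, dtype=bool)
    for v in spec.vessels:
        rr, cc = draw_disk(v.center, v.radius_px + v.wall_px + 10, shape=shape)
        vessel_clearance[rr, cc] = True
    total_px = h * w
    target_mx = int(round(spec.plaque_fraction * total_px))
    if spec.plaque_fraction > 0 and target_mx < int(mx04.sum()):
        raise ValidationError(
            "plaque_fraction smaller than vascular amyloid already drawn"
        )
    guard = 0
    while spec.plaque_fraction > 0 and int(mx04.sum()) < target_mx:
        guard += 1
        if guard > 100_000:
            raise ValidationError("could not reach requested plaque fraction")
        r = int(rng.integers(3, 9))
        cen = (int(rng.integers(r, h - r)), int(rng.integers(r, w - r)))
        blob = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk(cen, r, shape=shape)
        blob[rr, cc] = True
        new_px = blob & ~mx04 & ~vessel_clearance
        excess = int(mx04.sum() + new_px.sum()) - target_mx
        if excess > 0:
            rr, cc = np.nonzero(new_px)
            drop = np.arange(len(rr))[-excess:]
            new_px[rr[drop], cc[drop]] = False
        mx04 |= new_px
    plaque_pct = 100.0 * mx04.sum() / total_px

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.full(shape, bg, dtype=float)
        img[mask] = fg
        return _apply_noise(img, spec.noise_model, spec.noise_param, rng).astype(np.float32)

    image = ChannelImage(
        channels={
            "SMA": render(sma),
            "MX04": render(mx04),
            "COLIV": render(coliv),
            "FITC3K": render(fitc),
        },
        pixel_size_um=spec.pixel_size_um,
    )
    slice_truth = {
        "collagen_density_pct": float(collagen_density_pct),
        "plaque_coverage_pct": float(plaque_pct),
        "n_tracer_positive_arteries": int(sum(v.tracer_positive for v in spec.vessels)),
        "density_roi_center": roi_center,
        "density_roi_side_px": side,
    }
    return image, truth_table, slice_truth


def random_slice_spec(
    n_arteries: int = 10,
    n_tracer_positive: int = 7,
    mx04_fraction: float = 0.25,
    collagen_density_fraction: float = 0.12,
    plaque_fraction: float = 0.03,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    **kwargs,
) -> SliceSpec:
    """Non-overlapping random vessel layout via rejection sampling."""
    if n_tracer_positive > n_arteries:
        raise ValidationError("n_tracer_positive cannot exceed n_arteries")
    rng = np.random.default_rng(seed)
    h, w = shape
    vessels: list[SliceVessel] = []
    guard = 0
    while len(vessels) < n_arteries:
        guard += 1
        if guard > 50_000:
            raise ValidationError("could not place all vessels without overlap")
        radius = int(rng.integers(8, 16))
        wall = 3
        ext = radius + wall + 2
        center = (int(rng.integers(ext, h - ext)), int(rng.integers(ext, w - ext)))
        ok = all(
            math.hypot(center[0] - v.center[0], center[1] - v.center[1])
            > radius + wall + v.radius_px + v.wall_px + 4
            for v in vessels
        )
        if ok:
            vessels.append(
                SliceVessel(
                    center=center,
                    radius_px=radius,
                    wall_px=wall,
                    mx04_fraction=mx04_fraction,
                    tracer_positive=len(vessels) < n_tracer_positive,
                )
            )
    return SliceSpec(
        shape=shape,
        vessels=vessels,
        collagen_density_fraction=collagen_density_fraction,
        plaque_fraction=plaque_fraction,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# cortical slices with regional structure


@dataclass
class CorticalSliceSpec:
    """Semicircular-cortex phantom with a dorsoventral tracer gradient.

    The brain is a disk; the cortical band is the outer annulus of
    ``band_depth_um``.  Angles are measured from the dorsal midline, so the
    analysed hemisphere spans 0-180 degrees with the two landmark angles
    splitting it into dorsal / lateral / ventral sectors.  Tracer influx is
    rendered as a per-sector intensity step over the band (influx decreases
    ventral to dorsal in the emulated data), per-region plaque burden as
    MX04 blobs, and penetrating vessels as bright radial stripes.
    """

    shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 10.0
    brain_radius_px: int = 170
    band_depth_um: float = 400.0
    landmarks_deg: tuple[float, float] = (60.0, 120.0)
    influx_means: dict = field(
        default_factory=lambda: {
            "FITC3K": {"dorsal": 20.0, "lateral": 45.0, "ventral": 80.0},
            "TMR40K": {"dorsal": 15.0, "lateral": 35.0, "ventral": 60.0},
        }
    )
    plaque_burden_pct: dict = field(
        default_factory=lambda: {"dorsal": 6.0, "lateral": 4.0, "ventral": 1.5}
    )
    n_penetrating_vessels: int = 0
    penetrating_level: float = 400.0
    background_level: float = 10.0
    noise_model: str = "none"
    noise_param: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        if self.brain_radius_px + 2 > min(h, w) // 2:
            raise ValidationError("brain disk overflows the canvas")
        l1, l2 = self.landmarks_deg
        if not 0.0 < l1 < l2 < 180.0:
            raise ValidationError("landmarks must be strictly ordered inside (0, 180)")
        if self.band_depth_um <= 0:
            raise ValidationError("band_depth_um must be positive")
        if self.band_depth_um / self.pixel_size_um >= self.brain_radius_px:
            raise ValidationError("cortical band deeper than the brain radius")
        for ch, means in self.influx_means.items():
            for region in REGIONS:
                if means.get(region, 0.0) < 0:
                    raise ValidationError(f"{ch} {region} mean must be non-negative")
        for region in REGIONS:
            if not 0.0 <= self.plaque_burden_pct.get(region, 0.0) <= 100.0:
                raise ValidationError("regional plaque burden must lie in [0, 100]")
        if self.n_penetrating_vessels < 0:
            raise ValidationError("n_penetrating_vessels must be non-negative")
        _check_noise(self.noise_model, self.noise_param)


def _cortex_geometry(spec: CorticalSliceSpec):
    h, w = spec.shape
    center = (h // 2, w // 2)
    rr, cc = np.mgrid[0:h, 0:w]
    radius = np.hypot(rr - center[0], cc - center[1])
    brain = radius <= spec.brain_radius_px
    band_px = spec.band_depth_um / spec.pixel_size_um
    band = brain & (radius >= spec.brain_radius_px - band_px)
    # angle from the dorsal midline (pointing up = -row), through the right
    # hemisphere (+col): 0 deg dorsal apex, 180 deg ventral apex
    theta = np.degrees(np.arctan2(cc - center[1], -(rr - center[0])))
    return center, brain, band, theta


def _sector_masks(spec: CorticalSliceSpec, band: np.ndarray, theta: np.ndarray) -> dict:
    l1, l2 = spec.landmarks_deg
    right = (theta >= 0) & (theta <= 180.0)
    return {
        "dorsal": band & right & (theta < l1),
        "lateral": band & right & (theta >= l1) & (theta < l2),
        "ventral": band & right & (theta >= l2),
    }


def make_cortical_slice(spec: CorticalSliceSpec):
    """Render a cortical slice phantom.

    Returns ``(cortical_slice, truth)`` where truth records, per region and
    channel, the background-subtracted mean rendered over the noiseless
    image (exact recovery target), the per-region plaque burden and the
    per-region penetrating-vessel count.  Intensities on the mirrored
    hemisphere copy the analysed one so the phantom looks like a full
    coronal slice, but ground truth refers to the analysed (right)
    hemisphere only.
    """
    from .clearance import CorticalSlice  # local import: avoid module cycle

    spec.validate()
    h, w = spec.shape
    center, brain, band, theta = _cortex_geometry(spec)
    sectors = _sector_masks(spec, band, theta)
    mirrored = {
        region: band & (theta < 0)
        & (np.abs(theta) >= {"dorsal": 0.0, "lateral": spec.landmarks_deg[0],
                             "ventral": spec.landmarks_deg[1]}[region])
        & (np.abs(theta) < {"dorsal": spec.landmarks_deg[0],
                            "lateral": spec.landmarks_deg[1], "ventral": 180.1}[region])
        for region in REGIONS
    }
    rng = np.random.default_rng(spec.seed)

    channels: dict[str, np.ndarray] = {}
    for ch, means in spec.influx_means.items():
        # uniform base level everywhere (camera offset / autofluorescence), so
        # the outside-brain median downstream matches the in-brain baseline
        img = np.full((h, w), spec.background_level, dtype=float)
        for region in REGIONS:
            img[sectors[region]] += means.get(region, 0.0)
            img[mirrored[region]] += means.get(region, 0.0)
        channels[ch] = img

    # penetrating vessels: radial stripes in the band of the analysed side
    band_px = spec.band_depth_um / spec.pixel_size_um
    stripe_angles = []
    region_counts = dict.fromkeys(REGIONS, 0)
    guard = 0
    while len(stripe_angles) < spec.n_penetrating_vessels:
        guard += 1
        if guard > 10_000:
            raise ValidationError("could not place all penetrating vessels")
        ang = float(rng.uniform(5.0, 175.0))
        if any(abs(ang - a) < 6.0 for a in stripe_angles):
            continue
        stripe_angles.append(ang)
        l1, l2 = spec.landmarks_deg
        region = "dorsal" if ang < l1 else ("lateral" if ang < l2 else "ventral")
        region_counts[region] += 1
        rad = math.radians(ang)
        direction = np.array([-math.cos(rad), math.sin(rad)])  # (row, col), outward
        r_out = spec.brain_radius_px - 2
        r_in = spec.brain_radius_px - 0.85 * band_px
        p0 = np.array(center) + r_in * direction
        p1 = np.array(center) + r_out * direction
        stripe = np.zeros((h, w), dtype=bool)
        rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
        stripe[rr, cc] = True
        stripe = dilation(stripe, disk_footprint(1))
        for ch in channels:
            channels[ch][stripe] = spec.penetrating_level

    # per-region plaque burden in the MX04 channel
    mx04 = np.zeros((h, w), dtype=bool)
    for region in REGIONS:
        mask = sectors[region]
        n_region = int(mask.sum())
        target = int(round(spec.plaque_burden_pct.get(region, 0.0) / 100.0 * n_region))
        guard = 0
        while int((mx04 & mask).sum()) < target:
            guard += 1
            if guard > 100_000:
                raise ValidationError("could not reach requested plaque burden")
            rows_idx, cols_idx = np.nonzero(mask)
            j = int(rng.integers(0, len(rows_idx)))
            r = int(rng.integers(2, 6))
            blob = np.zeros((h, w), dtype=bool)
            rr, cc = draw_disk((rows_idx[j], cols_idx[j]), r, shape=(h, w))
            blob[rr, cc] = True
            new_px = blob & mask & ~mx04
            excess = int((mx04 & mask).sum() + new_px.sum()) - target
            if excess > 0:
                rr, cc = np.nonzero(new_px)
                drop = np.arange(len(rr))[-excess:]
                new_px[rr[drop], cc[drop]] = False
            mx04 |= new_px
    mx_img = np.full((h, w), spec.background_level, dtype=float)
    mx_img[mx04] = spec.background_level + 200.0
    channels["MX04"] = mx_img

    # ground truth from the noiseless rendering
    truth_rows = []
    for region in REGIONS:
        mask = sectors[region]
        n_region = int(mask.sum())
        for ch in spec.influx_means:
            truth_rows.append(
                {
                    "region": region,
                    "channel": ch,
                    "mean_signal": float(channels[ch][mask].mean() - spec.background_level),
                    "plaque_burden_pct": 100.0 * (mx04 & mask).sum() / n_region,
                    "n_penetrating_vessels": region_counts[region],
                }
            )
    truth = pd.DataFrame(truth_rows)

    for ch in channels:
        channels[ch] = _apply_noise(
            channels[ch], spec.noise_model, spec.noise_param, rng
        ).astype(np.float32)

    image = ChannelImage(channels=channels, pixel_size_um=spec.pixel_size_um)
    cslice = CorticalSlice(
        image=image,
        brain_mask=brain,
        midline_point=(float(center[0] - spec.brain_radius_px), float(center[1])),
        midline_dir=(-1.0, 0.0),
        landmarks_deg=spec.landmarks_deg,
        band_depth_um=spec.band_depth_um,
    )
    return cslice, truth


# ---------------------------------------------------------------------------
# tabular regional datasets


@dataclass
class RegionalGradientSpec:
    """Per-region means for plaque burden and tracer influx across slices.

    Defaults mirror the pattern the analysis is built around: tracer influx
    highest ventrally and decreasing toward the dorsal cortex, plaque
    burden following the opposite gradient, so burden and influx are
    anticorrelated across slice-region rows by construction.
    """

    plaque_means: dict = field(
        default_factory=lambda: {"dorsal": 6.0, "lateral": 4.0, "ventral": 1.5}
    )
    influx_means: dict = field(
        default_factory=lambda: {
            "FITC3K": {"dorsal": 20.0, "lateral": 45.0, "ventral": 80.0},
            "TMR40K": {"dorsal": 15.0, "lateral": 35.0, "ventral": 60.0},
        }
    )
    noise_sd: float = 5.0
    plaque_noise_sd: float = 0.8
    n_slices: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 2:
            raise ValidationError("n_slices must be at least 2 (regression undefined)")
        if self.noise_sd < 0 or self.plaque_noise_sd < 0:
            raise ValidationError("noise sds must be non-negative")
        for region in REGIONS:
            if self.plaque_means.get(region, 0.0) < 0:
                raise ValidationError("plaque means must be non-negative")
            for ch, means in self.influx_means.items():
                if not np.isfinite(means.get(region, 0.0)) or means.get(region, 0.0) < 0:
                    raise ValidationError(f"{ch} {region} mean must be finite and >= 0")


REGIONAL_COLUMNS = [
    "slice_id",
    "region",
    "channel",
    "mean_signal",
    "integrated_signal",
    "plaque_burden_pct",
    "n_penetrating_vessels",
    "clipped",
]


def make_regional_dataset(spec: RegionalGradientSpec) -> pd.DataFrame:
    """Draw a per-slice, per-region signal table from the regional means.

    One row per slice x region x channel with gaussian within-region noise;
    negative draws are clipped to zero and flagged in the ``clipped``
    column.  With the default anticorrelated gradients the population
    regression of influx on burden has a negative slope by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for s in range(spec.n_slices):
        for region in REGIONS:
            burden = spec.plaque_means[region] + rng.normal(0.0, spec.plaque_noise_sd)
            burden_clipped = burden < 0
            burden = max(burden, 0.0)
            for ch, means in spec.influx_means.items():
                signal = means[region] + rng.normal(0.0, spec.noise_sd)
                clipped = signal < 0 or burden_clipped
                signal = max(signal, 0.0)
                rows.append(
                    {
                        "slice_id": f"s{s}",
                        "region": region,
                        "channel": ch,
                        "mean_signal": signal,
                        "integrated_signal": np.nan,
                        "plaque_burden_pct": burden,
                        "n_penetrating_vessels": 0,
                        "clipped": clipped,
                    }
                )
    return pd.DataFrame(rows, columns=REGIONAL_COLUMNS)
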