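"""Mask-based immunofluorescence quantification.

Per-vessel coverage of vascular smooth muscle (SMA) and amyloid (MX04),
vascular density in a fixed 0.4 x 0.4 mm collagen-IV region of interest,
parenchymal plaque burden, and sub-pixel line intensity profiles.

All metrics follow the same convention: a vessel mask is the set of
in-ROI pixels whose merged SMA/MX04 intensity exceeds a threshold, and a
coverage value is the percentage of mask pixels positive in a given
channel.  Thresholds are policy objects (fixed value, Otsu, percentile)
and the resolved value is always recorded, since a coverage number is
meaningless without the threshold that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .errors import ValidationError

CHANNEL_ROLES = ("SMA", "MX04", "COLIV", "GFAP", "FITC3K", "TMR40K")


@dataclass
class ChannelImage:
    """Multi-channel 2-D slice image with named channel roles."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    slice_id: str = ""
    mouse_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ChannelImage requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        shapes = set()
        for role, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValidationError(f"channel {role!r} must be 2-D")
            if np.nanmin(arr) < 0:
                raise ValidationError(f"channel {role!r} holds negative intensities")
            self.channels[role] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValidationError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise ValidationError(
                f"channel role {role!r} not present (have {sorted(self.channels)})"
            ) from None


@dataclass
class VesselROI:
    """Labelled vessel region: a polygon (row, col vertices) or an explicit
    boolean mask.  Polygon rasterization uses the pixel-center rule."""

    id: str = "roi"
    vessel_type: str = "surface_artery"
    polygon: Sequence[tuple[float, float]] | None = None
    mask: np.ndarray | None = None
    depth_class: str | None = None

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise ValidationError(f"ROI {self.id!r}: mask shape mismatch")
            return m
        if self.polygon is None or len(self.polygon) < 3:
            raise ValidationError(f"ROI {self.id!r}: need a mask or >= 3 polygon vertices")
        poly = np.asarray(self.polygon, dtype=float)
        if poly.min() < -0.5 or (poly[:, 0] > shape[0] - 0.5).any() or (
            poly[:, 1] > shape[1] - 0.5
        ).any():
            raise ValidationError(f"ROI {self.id!r}: polygon outside image bounds")
        m = polygon2mask(shape, poly)
        if not m.any():
            raise ValidationError(f"ROI {self.id!r}: rasterized mask is empty")
        return m


@dataclass
class ThresholdPolicy:
    """How a positive-pixel threshold is chosen.

    kind "fixed"     : ``value`` used as-is;
    kind "otsu"      : Otsu's method over the supplied pixels;
    kind "percentile": the ``value``-th percentile of the supplied pixels.

    ``resolve`` returns the concrete threshold; callers record it so every
    coverage number carries the threshold that produced it.  A pixel is
    positive when strictly greater than the threshold.
    """

    kind: str = "otsu"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "otsu", "percentile"):
            raise ValidationError(f"unknown threshold policy {self.kind!r}")
        if self.kind in ("fixed", "percentile") and self.value is None:
            raise ValidationError(f"{self.kind} policy requires a value")

    def resolve(self, pixels: np.ndarray) -> float:
        pixels = np.asarray(pixels, dtype=float).ravel()
        if self.kind == "fixed":
            return float(self.value)
        if pixels.size == 0:
            raise ValidationError("cannot resolve a threshold on zero pixels")
        if self.kind == "percentile":
            return float(np.percentile(pixels, self.value))
        if np.ptp(pixels) == 0:  # otsu undefined on a constant field
            return float(pixels[0])
        return float(threshold_otsu(pixels))


@dataclass
class IntensityProfile:
    """Per-channel intensity sampled along a polyline."""

    positions_um: np.ndarray
    values: dict[str, np.ndarray]
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValidationError("profile positions must be strictly increasing")
        for role, vals in self.values.items():
            if len(vals) != len(self.positions_um):
                raise ValidationError(f"channel {role!r}: one value per position required")


# ---------------------------------------------------------------------------


def vessel_mask(
    image: ChannelImage,
    roi: VesselROI,
    threshold_policy: ThresholdPolicy | None = None,
    merge: str = "max",
) -> tuple[np.ndarray, float]:
    """Vessel mask from the merged SMA/MX04 channels inside an ROI.

    The two channels are merged pixel-wise (``max`` preserves either signal;
    ``sum`` is offered as an alternative), the threshold policy is resolved
    on the merged in-ROI pixels, and the mask is the in-ROI pixels strictly
    above the resolved threshold.  Returns ``(mask, resolved_threshold)``.
    """
    if threshold_policy is None:
        threshold_policy = ThresholdPolicy("otsu")
    if merge not in ("max", "sum"):
        raise ValidationError(f"unknown merge mode {merge!r}")
    sma = image.channel("SMA").astype(float)
    mx = image.channel("MX04").astype(float)
    merged = np.maximum(sma, mx) if merge == "max" else sma + mx
    roi_mask = roi.to_mask(image.shape)
    thr = threshold_policy.resolve(merged[roi_mask])
    mask = roi_mask & (merged > thr)
    if not mask.any():
        raise ValidationError(f"ROI {roi.id!r}: vessel mask is empty at threshold {thr:g}")
    return mask, thr


def channel_coverage(
    image: ChannelImage,
    mask: np.ndarray,
    channel_role: str,
    threshold_policy: ThresholdPolicy | None = None,
) -> tuple[float, float]:
    """Percent of mask pixels positive in one channel.

    ``100 * (positive pixels of the channel within the mask) / (mask pixels)``.
    Returns ``(percent, resolved_threshold)``.
    """
    if threshold_policy is None:
        threshold_policy = ThresholdPolicy("otsu")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("coverage undefined on an empty mask")
    arr = image.channel(channel_role).astype(float)
    thr = threshold_policy.resolve(arr[mask])
    positive = int((arr[mask] > thr).sum())
    return 100.0 * positive / int(mask.sum()), thr


def vascular_density(
    image: ChannelImage,
    roi_center: tuple[int, int],
    roi_size_um: float = 400.0,
    channel_role: str = "COLIV",
    threshold_policy: ThresholdPolicy | None = None,
) -> tuple[float, float]:
    """Percent of a fixed square ROI occupied by collagen-IV-positive pixels.

    The ROI is a ``roi_size_um`` x ``roi_size_um`` square (default
    0.4 x 0.4 mm) centred on ``roi_center``; it must fit inside the image.
    Returns ``(percent, resolved_threshold)``.
    """
    if threshold_policy is None:
        threshold_policy = ThresholdPolicy("otsu")
    side = int(round(roi_size_um / image.pixel_size_um))
    if side < 1:
        raise ValidationError("density ROI smaller than one pixel")
    h, w = image.shape
    r0, c0 = roi_center[0] - side // 2, roi_center[1] - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
        raise ValidationError("density ROI exceeds the image bounds")
    patch = image.channel(channel_role).astype(float)[r0:r0 + side, c0:c0 + side]
    thr = threshold_policy.resolve(patch)
    return 100.0 * (patch > thr).sum() / patch.size, thr


def subtract_background(
    arr: np.ndarray,
    background: float | np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Background-subtract an intensity image, clipping at zero.

    ``background`` may be a scalar estimate, a boolean mask of a background
    region (its median is used), or None (median of the whole image — a
    robust choice when most pixels are background).  Returns the subtracted
    image and the background value used.
    """
    arr = np.asarray(arr, dtype=float)
    if background is None:
        bg = float(np.median(arr))
    elif np.isscalar(background):
        bg = float(background)
    else:
        region = np.asarray(background, dtype=bool)
        if not region.any():
            raise ValidationError("background region is empty")
        bg = float(np.median(arr[region]))
    return np.clip(arr - bg, 0.0, None), bg


def plaque_coverage(
    image: ChannelImage,
    brain_roi: np.ndarray,
    threshold_policy: ThresholdPolicy | None = None,
    background: float | np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Parenchymal amyloid burden as a percentage of the brain ROI.

    The MX04 channel is background-subtracted, a constant threshold is
    applied, and the burden is
    ``100 * thresholded MX04 pixels / brain ROI pixels``.
    Returns ``(percent, resolved_threshold, background_used)``.
    """
    if threshold_policy is None:
        threshold_policy = ThresholdPolicy("otsu")
    brain_roi = np.asarray(brain_roi, dtype=bool)
    if not brain_roi.any():
        raise ValidationError("brain ROI is empty")
    arr = image.channel("MX04")
    sub, bg = subtract_background(arr, background)
    thr = threshold_policy.resolve(sub[brain_roi])
    positive = int((sub[brain_roi] > thr).sum())
    return 100.0 * positive / int(brain_roi.sum()), thr, bg


def line_profile(
    image: ChannelImage,
    polyline: Sequence[tuple[float, float]],
    channels: Sequence[str] | None = None,
    normalize: bool = False,
    step_px: float = 0.5,
) -> IntensityProfile:
    """Bilinear-interpolated intensity along a polyline of (row, col) points.

    Samples are spaced at most ``step_px`` pixels apart along the polyline
    arclength; positions are reported in micrometres.  With ``normalize``
    each channel is divided by its own maximum along the line.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValidationError("polyline needs at least two (row, col) points")
    h, w = image.shape
    if pts.min() < 0 or (pts[:, 0] > h - 1).any() or (pts[:, 1] > w - 1).any():
        raise ValidationError("polyline outside image bounds")
    seg_len = np.hypot(*np.diff(pts, axis=0).T)
    total = float(seg_len.sum())
    if total <= 0:
        raise ValidationError("degenerate (zero-length) polyline")
    if step_px <= 0:
        raise ValidationError("step_px must be positive")
    n_samples = int(np.ceil(total / step_px)) + 1
    s = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rows = np.interp(s, cum, pts[:, 0])
    cols = np.interp(s, cum, pts[:, 1])

    roles = list(channels) if channels is not None else sorted(image.channels)
    values = {}
    for role in roles:
        sampled = map_coordinates(
            image.channel(role).astype(float), [rows, cols], order=1, mode="nearest"
        )
        if normalize:
            peak = sampled.max()
            if peak > 0:
                sampled = sampled / peak
        values[role] = sampled
    return IntensityProfile(
        positions_um=s * image.pixel_size_um,
        values=values,
        normalized=normalize,
        provenance={"step_px": step_px, "n_points": len(pts)},
    )
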