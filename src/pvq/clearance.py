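"""Tracer-based clearance read-outs on coronal brain slices.

Covers four measurements made after intracisternal or intraparenchymal
tracer delivery:

* counting arteries that carry both smooth-muscle (SMA) and tracer signal
  — the read-out of intramural periarterial drainage (IPAD);
* whole-slice CSF-influx signal (background-subtracted mean and sum over
  the brain mask);
* counting tracer-positive penetrating vessels, operationalized as
  elongated components whose principal axis is near the local cortical
  normal;
* dorsal / lateral / ventral partition of the cortical band and its
  linearization into a 1-D arclength profile starting at the dorsal
  midline.

Cortical geometry is derived from the brain mask: band depth from the
distance transform of the mask boundary, angular position from the mask
centroid relative to a midline direction supplied as input (the manual
template registration of the original workflow is replaced by explicit
landmark angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label, regionprops

from .errors import ValidationError
from .quant import ChannelImage, ThresholdPolicy, plaque_coverage, subtract_background

REGIONS = ("dorsal", "lateral", "ventral")
TRACER_ROLES = ("FITC3K", "TMR40K")


@dataclass
class CorticalSlice:
    """One coronal slice with the geometry needed for regional analysis.

    ``midline_point``/``midline_dir`` anchor the dorsal midline (direction
    points from the brain centroid toward the dorsal surface);
    ``landmarks_deg`` are the two angular boundaries, measured along the
    cortical band from the midline, standing in for the anatomical
    landmarks that separate dorsal / lateral / ventral cortex.
    """

    image: ChannelImage
    brain_mask: np.ndarray
    midline_point: tuple[float, float]
    midline_dir: tuple[float, float]
    landmarks_deg: tuple[float, float] = (60.0, 120.0)
    band_depth_um: float = 400.0
    slice_id: str = ""
    ap_position: str = ""

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.image.shape:
            raise ValidationError("brain_mask shape must match the image")
        if not self.brain_mask.any():
            raise ValidationError("brain_mask is empty")
        norm = float(np.hypot(*self.midline_dir))
        if norm == 0:
            raise ValidationError("midline_dir must be a non-zero vector")
        self.midline_dir = (self.midline_dir[0] / norm, self.midline_dir[1] / norm)
        if self.band_depth_um <= 0:
            raise ValidationError("band_depth_um must be positive")

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.brain_mask)
        return float(rr.mean()), float(cc.mean())

    def band_mask(self, band_depth_um: float | None = None) -> np.ndarray:
        """Cortical band: brain pixels within ``band_depth_um`` of the surface."""
        depth_um = self.band_depth_um if band_depth_um is None else band_depth_um
        if depth_um <= 0:
            raise ValidationError("band depth must be positive")
        depth_px = ndimage.distance_transform_edt(self.brain_mask)
        return self.brain_mask & (depth_px <= depth_um / self.image.pixel_size_um)

    def angle_map(self) -> np.ndarray:
        """Signed angle (deg) of every pixel about the centroid, measured from
        the midline direction; positive angles sweep the analysed hemisphere."""
        cr, cc = self.centroid
        rr, cols = np.mgrid[0 : self.brain_mask.shape[0], 0 : self.brain_mask.shape[1]]
        vr, vc = rr - cr, cols - cc
        mr, mc = self.midline_dir
        # angle between pixel vector and midline direction, signed by the
        # perpendicular (so one hemisphere is positive)
        dot = vr * mr + vc * mc
        cross = mc * vr - mr * vc
        return np.degrees(np.arctan2(cross, dot))

    def surface_normal_deg(self, point: tuple[float, float]) -> float:
        """Direction (deg, image convention atan2(drow, dcol)) of the outward
        cortical normal at a point, approximated radially from the centroid."""
        cr, cc = self.centroid
        return float(np.degrees(np.arctan2(point[0] - cr, point[1] - cc)))


@dataclass
class VesselCount:
    """A count of accepted vessel components plus the audit trail."""

    slice_id: str
    count: int
    components: pd.DataFrame
    criteria: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# IPAD artery counting


def count_ipad_arteries(
    image: ChannelImage,
    sma_policy: ThresholdPolicy | None = None,
    tracer_policy: ThresholdPolicy | None = None,
    tracer_role: str = "FITC3K",
    min_area_px: int = 20,
    colocal_fraction: float = 0.3,
    hemisphere_mask: np.ndarray | None = None,
    slice_id: str = "",
) -> VesselCount:
    """Count arteries carrying both SMA and tracer signal.

    Connected components of the thresholded SMA channel with area at least
    ``min_area_px`` are accepted when the fraction of their pixels that are
    tracer-positive reaches ``colocal_fraction``.  With
    ``colocal_fraction=0`` every SMA component counts (upper bound).  An
    optional hemisphere mask restricts the analysis to the injected side.
    """
    if sma_policy is None:
        sma_policy = ThresholdPolicy("otsu")
    if tracer_policy is None:
        tracer_policy = ThresholdPolicy("otsu")
    if not 0.0 <= colocal_fraction <= 1.0:
        raise ValidationError("colocal_fraction must lie in [0, 1]")
    sma = image.channel("SMA").astype(float)
    tracer = image.channel(tracer_role).astype(float)
    if hemisphere_mask is not None:
        hemisphere_mask = np.asarray(hemisphere_mask, dtype=bool)
        if hemisphere_mask.shape != image.shape:
            raise ValidationError("hemisphere_mask shape mismatch")
    sma_thr = sma_policy.resolve(sma)
    tracer_thr = tracer_policy.resolve(tracer)
    sma_bin = sma > sma_thr
    tracer_bin = tracer > tracer_thr
    if hemisphere_mask is not None:
        sma_bin &= hemisphere_mask

    labels = label(sma_bin, connectivity=2)
    rows = []
    count = 0
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        comp = labels == prop.label
        frac = float(tracer_bin[comp].mean())
        accepted = frac >= colocal_fraction
        count += int(accepted)
        rows.append(
            {
                "label": prop.label,
                "area_px": int(prop.area),
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "tracer_fraction": frac,
                "accepted": accepted,
            }
        )
    return VesselCount(
        slice_id=slice_id,
        count=count,
        components=pd.DataFrame(
            rows,
            columns=["label", "area_px", "centroid_row", "centroid_col",
                     "tracer_fraction", "accepted"],
        ),
        criteria={
            "sma_threshold": sma_thr,
            "tracer_threshold": tracer_thr,
            "tracer_role": tracer_role,
            "min_area_px": min_area_px,
            "colocal_fraction": colocal_fraction,
        },
    )


# ---------------------------------------------------------------------------
# whole-slice influx signal


def total_influx_signal(
    cslice: CorticalSlice,
    channel_role: str,
    background: float | np.ndarray | str = "outside",
) -> dict:
    """Background-subtracted tracer signal over the whole brain mask.

    ``background="outside"`` estimates the background as the median
    intensity outside the brain mask (self-consistent: adding a constant
    offset to the whole image leaves the result unchanged); a scalar or a
    boolean region may be supplied instead.  Both the mean and the
    integrated (sum) signal are reported.
    """
    mask = cslice.brain_mask
    arr = cslice.image.channel(channel_role)
    if isinstance(background, str):
        if background != "outside":
            raise ValidationError(f"unknown background mode {background!r}")
        outside = ~mask
        if not outside.any():
            raise ValidationError("no outside-brain pixels to estimate background")
        sub, bg = subtract_background(arr, outside)
    else:
        sub, bg = subtract_background(arr, background)
    vals = sub[mask]
    return {
        "mean_signal": float(vals.mean()),
        "integrated_signal": float(vals.sum()),
        "background": bg,
        "n_pixels": int(mask.sum()),
    }


# ---------------------------------------------------------------------------
# penetrating-vessel counting


def count_penetrating_vessels(
    cslice: CorticalSlice,
    channel_roles: tuple[str, ...] = TRACER_ROLES,
    threshold_policy: ThresholdPolicy | None = None,
    min_aspect: float = 2.0,
    angle_tol_deg: float = 30.0,
    min_area_px: int = 6,
    tophat_radius_px: int = 5,
) -> VesselCount:
    """Count tracer-positive vessels oriented perpendicular to the cortex.

    The available tracer channels are merged pixel-wise (max), flattened
    with a white top-hat of radius ``tophat_radius_px`` (suppresses the
    smooth regional influx background while keeping thin bright vessels;
    set 0 to skip), thresholded over the cortical band, and each connected
    component is accepted when its aspect ratio reaches ``min_aspect`` and
    its principal axis lies within ``angle_tol_deg`` of the local cortical
    normal (radial direction from the brain centroid).
    """
    from skimage.morphology import disk as disk_footprint, white_tophat

    if threshold_policy is None:
        threshold_policy = ThresholdPolicy("otsu")
    available = [r for r in channel_roles if r in cslice.image.channels]
    if not available:
        raise ValidationError(f"none of the tracer channels {channel_roles} present")
    merged = np.maximum.reduce([cslice.image.channel(r).astype(float) for r in available])
    if tophat_radius_px > 0:
        merged = white_tophat(merged, disk_footprint(tophat_radius_px))
    band = cslice.band_mask()
    thr = threshold_policy.resolve(merged[band])
    binary = band & (merged > thr)
    labels = label(binary, connectivity=2)
    rows = []
    count = 0
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        minor = prop.axis_minor_length
        aspect = prop.axis_major_length / minor if minor > 0 else np.inf
        # skimage orientation: angle between major axis and the row axis
        axis_deg = float(np.degrees(prop.orientation))
        axis_image_deg = 90.0 - axis_deg  # to atan2(drow, dcol) convention
        normal_deg = cslice.surface_normal_deg(prop.centroid)
        diff = abs((axis_image_deg - normal_deg + 90.0) % 180.0 - 90.0)
        accepted = aspect >= min_aspect and diff <= angle_tol_deg
        count += int(accepted)
        rows.append(
            {
                "label": prop.label,
                "area_px": int(prop.area),
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "aspect_ratio": float(aspect),
                "normal_misalignment_deg": float(diff),
                "accepted": accepted,
            }
        )
    return VesselCount(
        slice_id=cslice.slice_id,
        count=count,
        components=pd.DataFrame(
            rows,
            columns=["label", "area_px", "centroid_row", "centroid_col",
                     "aspect_ratio", "normal_misalignment_deg", "accepted"],
        ),
        criteria={
            "channels": available,
            "threshold": thr,
            "min_aspect": min_aspect,
            "angle_tol_deg": angle_tol_deg,
            "min_area_px": min_area_px,
        },
    )


# ---------------------------------------------------------------------------
# cortical partition and linearization


def partition_cortex(
    cslice: CorticalSlice, band_depth_um: float | None = None
) -> dict[str, np.ndarray]:
    """Split the cortical band of the analysed hemisphere into the dorsal,
    lateral and ventral sectors delimited by the landmark angles.

    The three masks are disjoint and their union is exactly the band of the
    analysed hemisphere (angles 0-180 degrees from the midline).  Degenerate
    landmark placements yielding an empty region are allowed but flagged
    with a warning.
    """
    import warnings

    l1, l2 = cslice.landmarks_deg
    if not 0.0 <= l1 <= l2 <= 180.0:
        raise ValidationError("landmarks must be ordered within [0, 180] degrees")
    band = cslice.band_mask(band_depth_um)
    theta = cslice.angle_map()
    hemi = band & (theta >= 0.0) & (theta <= 180.0)
    masks = {
        "dorsal": hemi & (theta < l1),
        "lateral": hemi & (theta >= l1) & (theta < l2),
        "ventral": hemi & (theta >= l2),
    }
    for region, m in masks.items():
        if not m.any():
            warnings.warn(f"degenerate landmark placement: {region} region is empty",
                          stacklevel=2)
    return masks


def linearize_cortex(
    cslice: CorticalSlice,
    band_depth_um: float | None = None,
    bin_deg: float = 2.0,
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Unroll the cortical band along arclength from the dorsal midline.

    Band pixels of the analysed hemisphere are binned by angular position;
    each bin reports its arclength coordinate (angle times the mean surface
    radius), region label, and mean intensity per channel.  Arclength runs
    dorsal (0) to ventral.
    """
    if bin_deg <= 0:
        raise ValidationError("bin_deg must be positive")
    band = cslice.band_mask(band_depth_um)
    theta = cslice.angle_map()
    hemi = band & (theta >= 0.0) & (theta <= 180.0)
    if not hemi.any():
        raise ValidationError("empty cortical band on the analysed hemisphere")
    roles = list(channels) if channels is not None else sorted(cslice.image.channels)
    cr, cc = cslice.centroid
    rr, cols = np.nonzero(hemi)
    radius = np.hypot(rr - cr, cols - cc)
    mean_radius_um = float(radius.mean()) * cslice.image.pixel_size_um
    ang = theta[hemi]
    bins = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    which = np.clip(np.digitize(ang, bins) - 1, 0, len(bins) - 2)
    l1, l2 = cslice.landmarks_deg
    rows_out = []
    for b in range(len(bins) - 1):
        sel = which == b
        if not sel.any():
            continue
        center_deg = 0.5 * (bins[b] + bins[b + 1])
        region = "dorsal" if center_deg < l1 else ("lateral" if center_deg < l2 else "ventral")
        row = {
            "arclength_um": np.radians(center_deg) * mean_radius_um,
            "angle_deg": center_deg,
            "region": region,
            "n_pixels": int(sel.sum()),
        }
        for role in roles:
            row[role] = float(cslice.image.channel(role)[hemi][sel].mean())
        rows_out.append(row)
    return pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# regional table

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


def regional_table(
    slices: list[CorticalSlice],
    channels: tuple[str, ...] = TRACER_ROLES,
    plaque_policy: ThresholdPolicy | None = None,
    background: float | np.ndarray | str = "outside",
    count_penetrating: bool = True,
) -> pd.DataFrame:
    """Per-slice, per-region clearance table.

    For every slice x region: background-subtracted mean and integrated
    tracer signal for each requested channel, plaque burden (amyloid
    coverage restricted to the region mask), and the number of accepted
    penetrating vessels whose centroid falls in the region.
    """
    if not slices:
        return pd.DataFrame(columns=REGIONAL_COLUMNS)
    channel_sets = {tuple(sorted(set(channels) & set(s.image.channels))) for s in slices}
    if len(channel_sets) != 1:
        raise ValidationError("inconsistent tracer channel sets across slices")
    present = list(channel_sets.pop())
    if not present:
        raise ValidationError(f"no requested channel {channels} present in the slices")

    rows = []
    for i, cslice in enumerate(slices):
        slice_id = cslice.slice_id or f"s{i}"
        masks = partition_cortex(cslice)
        counts = dict.fromkeys(REGIONS, 0)
        if count_penetrating:
            vc = count_penetrating_vessels(cslice, channel_roles=tuple(present))
            theta = cslice.angle_map()
            l1, l2 = cslice.landmarks_deg
            for _, comp in vc.components[vc.components.accepted].iterrows():
                ang = theta[int(round(comp.centroid_row)), int(round(comp.centroid_col))]
                if 0.0 <= ang <= 180.0:
                    region = "dorsal" if ang < l1 else ("lateral" if ang < l2 else "ventral")
                    counts[region] += 1
        for region in REGIONS:
            mask = masks[region]
            if not mask.any():
                continue
            if "MX04" in cslice.image.channels:
                burden, _, _ = plaque_coverage(
                    cslice.image, mask, plaque_policy, background=_bg_value(cslice, background)
                )
            else:
                burden = np.nan
            for role in present:
                arr = cslice.image.channel(role)
                sub, _ = subtract_background(arr, _bg_region(cslice, background))
                vals = sub[mask]
                rows.append(
                    {
                        "slice_id": slice_id,
                        "region": region,
                        "channel": role,
                        "mean_signal": float(vals.mean()),
                        "integrated_signal": float(vals.sum()),
                        "plaque_burden_pct": burden,
                        "n_penetrating_vessels": counts[region],
                        "clipped": bool((arr[mask] < _scalar_bg(cslice, arr, background)).any()),
                    }
                )
    return pd.DataFrame(rows, columns=REGIONAL_COLUMNS).sort_values(
        ["slice_id", "region", "channel"], ignore_index=True
    )


def _bg_region(cslice: CorticalSlice, background):
    if isinstance(background, str) and background == "outside":
        return ~cslice.brain_mask
    return background


def _bg_value(cslice: CorticalSlice, background):
    if isinstance(background, str) and background == "outside":
        return ~cslice.brain_mask
    return background


def _scalar_bg(cslice: CorticalSlice, arr: np.ndarray, background) -> float:
    region = _bg_region(cslice, background)
    if region is None:
        return float(np.median(arr))
    if np.isscalar(region):
        return float(region)
    return float(np.median(arr[np.asarray(region, dtype=bool)]))
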