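"""Reading and writing the pipeline's file formats.

Kymographs travel as single-page TIFF plus a YAML sidecar carrying the
calibration (pixel size, line period) and vessel annotations.
Multi-channel slice images are multi-page TIFFs with the channel-role map
stored as JSON in the ImageDescription tag (and optionally as a YAML
sidecar).  ROIs and cortical landmarks are JSON; tables are CSV.
All image data are written as float32, which round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import ValidationError
from .pulsatility import Kymograph
from .quant import ChannelImage, VesselROI


def write_kymograph(kymo: Kymograph, tiff_path, meta_path=None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(kymo.intensities, dtype=np.float32))
    meta = {
        "pixel_size_um": float(kymo.pixel_size_um),
        "line_period_ms": float(kymo.line_period_ms),
        "vessel_id": kymo.vessel_id,
        "vessel_type": kymo.vessel_type,
        "depth_um": None if kymo.depth_um is None else float(kymo.depth_um),
        "annotations": kymo.annotations,
    }
    meta_path = Path(meta_path) if meta_path else tiff_path.with_suffix(".yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_kymograph(tiff_path, meta_path=None) -> Kymograph:
    tiff_path = Path(tiff_path)
    meta_path = Path(meta_path) if meta_path else tiff_path.with_suffix(".yaml")
    if not meta_path.exists():
        raise ValidationError(f"missing calibration sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    for key in ("pixel_size_um", "line_period_ms"):
        if key not in meta:
            raise ValidationError(f"sidecar {meta_path} lacks {key!r}")
    return Kymograph(
        intensities=tifffile.imread(tiff_path),
        pixel_size_um=float(meta["pixel_size_um"]),
        line_period_ms=float(meta["line_period_ms"]),
        vessel_id=meta.get("vessel_id", tiff_path.stem),
        vessel_type=meta.get("vessel_type", "surface_artery"),
        depth_um=meta.get("depth_um"),
        annotations=meta.get("annotations") or {},
    )


def write_channel_image(image: ChannelImage, tiff_path) -> None:
    tiff_path = Path(tiff_path)
    roles = sorted(image.channels)
    stack = np.stack([np.asarray(image.channels[r], dtype=np.float32) for r in roles])
    description = json.dumps(
        {
            "channels": roles,
            "pixel_size_um": float(image.pixel_size_um),
            "slice_id": image.slice_id,
            "mouse_id": image.mouse_id,
            "group": image.group,
        }
    )
    tifffile.imwrite(tiff_path, stack, photometric="minisblack", description=description)


def read_channel_image(tiff_path, channel_map=None) -> ChannelImage:
    """Read a multi-page TIFF; channel roles come from the embedded
    description or from a YAML ``channel_map`` file listing page roles."""
    tiff_path = Path(tiff_path)
    with tifffile.TiffFile(tiff_path) as tf:
        stack = tf.asarray()
        description = tf.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if channel_map is not None:
        meta = yaml.safe_load(Path(channel_map).read_text())
    elif description:
        try:
            meta = json.loads(description)
        except json.JSONDecodeError:
            meta = {}
    roles = meta.get("channels")
    if not roles or len(roles) != stack.shape[0]:
        raise ValidationError(
            f"{tiff_path}: channel-role map absent or wrong length "
            f"({roles} for {stack.shape[0]} pages)"
        )
    return ChannelImage(
        channels={role: stack[i] for i, role in enumerate(roles)},
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        slice_id=meta.get("slice_id", ""),
        mouse_id=meta.get("mouse_id", ""),
        group=meta.get("group", ""),
    )


def read_rois(json_path) -> list[VesselROI]:
    """ROIs from a JSON list of {id, vessel_type, polygon: [[row, col], ...]}."""
    records = json.loads(Path(json_path).read_text())
    if not isinstance(records, list):
        raise ValidationError("ROI file must hold a JSON list")
    rois = []
    for rec in records:
        if "polygon" not in rec:
            raise ValidationError(f"ROI record {rec.get('id')!r} lacks a polygon")
        rois.append(
            VesselROI(
                id=str(rec.get("id", f"roi{len(rois)}")),
                vessel_type=rec.get("vessel_type", "surface_artery"),
                polygon=[tuple(p) for p in rec["polygon"]],
                depth_class=rec.get("depth_class"),
            )
        )
    return rois


def read_landmarks(json_path) -> dict:
    """Cortical geometry from JSON: midline point/direction, landmark angles,
    band depth."""
    meta = json.loads(Path(json_path).read_text())
    for key in ("midline_point", "midline_dir"):
        if key not in meta:
            raise ValidationError(f"landmark file lacks {key!r}")
    return {
        "midline_point": tuple(meta["midline_point"]),
        "midline_dir": tuple(meta["midline_dir"]),
        "landmarks_deg": tuple(meta.get("landmarks_deg", (60.0, 120.0))),
        "band_depth_um": float(meta.get("band_depth_um", 400.0)),
    }
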