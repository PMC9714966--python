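"""TIFF + sidecar-metadata I/O.

Acquisition metadata lives in a YAML (or JSON) sidecar next to each TIFF
stack rather than in TIFF tags — dialect-proof and human-diffable. Physical
metadata (pixel size, angles, wavelength, NA, z step) is never defaulted
silently: a missing mandatory field is an error naming the field, and
internally inconsistent timing metadata is rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
import yaml

from .types import BeadStack, MetadataError, ScanImage

__all__ = [
    "write_stack",
    "read_stack",
    "sidecar_path",
    "load_scan_images",
    "load_bead_stack",
]


def sidecar_path(path: Union[str, Path]) -> Path:
    return Path(path).with_suffix(".yaml")


def write_stack(
    path: Union[str, Path],
    frames: Union[np.ndarray, Sequence[np.ndarray]],
    metadata: Dict,
) -> Path:
    """Write a multi-page TIFF plus its YAML metadata sidecar; returns the
    sidecar path."""
    path = Path(path)
    arr = np.asarray(frames, dtype=np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    sc = sidecar_path(path)
    with open(sc, "w") as fh:
        yaml.safe_dump(_plain(metadata), fh, sort_keys=False)
    return sc


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_stack(
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
    required: Sequence[str] = (),
) -> Tuple[np.ndarray, Dict]:
    """Read a TIFF stack and its metadata sidecar, validating that every
    field in ``required`` is present and that timing metadata is
    self-consistent."""
    path = Path(path)
    arr = tifffile.imread(path)
    sc = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not sc.exists():
        raise MetadataError(f"metadata sidecar not found: {sc}")
    text = sc.read_text()
    meta = json.loads(text) if sc.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(meta, dict):
        raise MetadataError(f"sidecar {sc} did not parse to a mapping")
    for field in required:
        if field not in meta or meta[field] is None:
            raise MetadataError(f"mandatory metadata field missing: {field!r}")
    _check_timing(meta, arr)
    return arr, meta


def _check_timing(meta: Dict, arr: np.ndarray) -> None:
    """Cross-check dwell/line/frame time against the pixel grid (tolerance
    0.1% relative)."""
    shape = arr.shape[-2:]
    n_rows, n_cols = shape
    retrace = float(meta.get("retrace_fraction", 0.0))
    dwell = meta.get("dwell_time")
    line = meta.get("line_time")
    frame = meta.get("frame_time")
    if dwell is not None and line is not None and np.isscalar(dwell):
        expected = float(dwell) * n_cols * (1.0 + retrace)
        if not np.isclose(float(line), expected, rtol=1e-3):
            raise MetadataError(
                f"inconsistent metadata field 'line_time': got {line}, "
                f"expected dwell_time*n_cols*(1+retrace) = {expected}"
            )
    if line is not None and frame is not None and np.isscalar(line):
        expected = float(line) * n_rows
        if not np.isclose(float(frame), expected, rtol=1e-3):
            raise MetadataError(
                f"inconsistent metadata field 'frame_time': got {frame}, "
                f"expected line_time*n_rows = {expected}"
            )


def load_scan_images(
    path: Union[str, Path], sidecar: Optional[Union[str, Path]] = None
) -> List[ScanImage]:
    """Load a scan-image series. The sidecar must provide pixel_size plus
    dwell_time (scalar or one per page); scan_rotation defaults to 0 only
    because it is an acquisition choice, not a physical calibration."""
    arr, meta = read_stack(path, sidecar, required=("pixel_size", "dwell_time"))
    if arr.ndim == 2:
        arr = arr[None]
    dwell = meta["dwell_time"]
    dwells = [float(dwell)] * len(arr) if np.isscalar(dwell) else [float(d) for d in dwell]
    if len(dwells) != len(arr):
        raise MetadataError("dwell_time list length does not match page count")
    rot = float(meta.get("scan_rotation", 0.0))
    retrace = float(meta.get("retrace_fraction", 0.0))
    return [
        ScanImage(
            pixels=page,
            dwell_time=d,
            pixel_size=float(meta["pixel_size"]),
            scan_rotation=rot,
            retrace_fraction=retrace,
        )
        for page, d in zip(arr, dwells)
    ]


def load_bead_stack(
    path: Union[str, Path], sidecar: Optional[Union[str, Path]] = None
) -> BeadStack:
    arr, meta = read_stack(
        path, sidecar, required=("pixel_size", "z_step", "wavelength", "na")
    )
    return BeadStack(
        volume=arr,
        pixel_size=float(meta["pixel_size"]),
        z_step=float(meta["z_step"]),
        wavelength=float(meta["wavelength"]),
        na=float(meta["na"]),
    )
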