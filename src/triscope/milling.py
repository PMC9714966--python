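"""FIB-milling progress monitoring from two-channel (reflection +
fluorescence) image series.

Within the milling ROI the intensity is integrated along X and normalized
per profile; as the lamella thins, the central reflected peak narrows, and
the (pre-normalization) fluorescence integral tracks how much of the target
remains.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import MillingProfile

__all__ = ["integrate_profile", "profile_series", "profile_fwhm", "CHANNELS"]

CHANNELS = {"reflection": 0, "fluorescence": 1}


def _channel_plane(image: np.ndarray, channel: Union[str, int]) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3:
        idx = CHANNELS[channel] if isinstance(channel, str) else int(channel)
        return img[idx]
    raise ValueError("image must be 2D or (channels, H, W)")


def integrate_profile(
    image: np.ndarray,
    roi: Tuple[int, int, int, int],
    channel: Union[str, int] = "reflection",
    timestamp: float = 0.0,
) -> MillingProfile:
    """Per-row sum over the ROI columns, normalized to its maximum.

    ``roi`` is (x0, y0, w, h), 0-based, half-open. An all-zero ROI is an
    error (the normalization is undefined).
    """
    plane = _channel_plane(image, channel)
    x0, y0, w, h = (int(v) for v in roi)
    ny, nx = plane.shape
    if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
        raise ValueError(f"roi {roi} lies outside the {ny}x{nx} image")
    block = plane[y0 : y0 + h, x0 : x0 + w]
    sums = block.sum(axis=1)
    peak = sums.max()
    if peak <= 0:
        raise ValueError("all-zero ROI: profile normalization undefined")
    name = channel if isinstance(channel, str) else list(CHANNELS)[channel]
    return MillingProfile(
        y_positions=np.arange(y0, y0 + h),
        intensity=sums / peak,
        channel=name,
        timestamp=timestamp,
    )


def profile_fwhm(profile: MillingProfile) -> float:
    """Full width at half maximum of a single-peaked profile, in px, with
    linear interpolation of the half-max crossings."""
    y = profile.intensity
    peak = int(np.argmax(y))
    half = y[peak] / 2.0
    left = peak
    while left > 0 and y[left] > half:
        left -= 1
    right = peak
    n = len(y)
    while right < n - 1 and y[right] > half:
        right += 1
    if y[left] > half or y[right] > half:
        raise ValueError("profile does not drop below half maximum inside the ROI")
    xl = left + (half - y[left]) / (y[left + 1] - y[left])
    xr = right - 1 + (y[right - 1] - half) / (y[right - 1] - y[right])
    return float(xr - xl)


def profile_series(
    images: Sequence[np.ndarray],
    roi: Tuple[int, int, int, int],
    timestamps: Optional[Sequence[float]] = None,
) -> Tuple[List[dict], pd.DataFrame]:
    """Profiles per timepoint plus a summary table.

    Returns (profiles, summary): ``profiles`` is a list of
    {channel: MillingProfile} dicts; ``summary`` tabulates the reflection
    peak FWHM (px) and the total pre-normalization fluorescence inside the
    ROI versus time. The fluorescence total is reported before
    normalization because per-profile normalization erases absolute loss.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 timepoints")
    if timestamps is None:
        timestamps = list(range(len(images)))
    if len(timestamps) != len(images):
        raise ValueError("one timestamp per image required")
    profiles: List[dict] = []
    rows = []
    x0, y0, w, h = (int(v) for v in roi)
    for img, t in zip(images, timestamps):
        per_channel = {
            ch: integrate_profile(img, roi, ch, timestamp=t) for ch in CHANNELS
        }
        profiles.append(per_channel)
        fluo_plane = _channel_plane(img, "fluorescence")
        rows.append(
            {
                "timestamp": t,
                "reflection_fwhm_px": profile_fwhm(per_channel["reflection"]),
                "fluorescence_total": float(
                    fluo_plane[y0 : y0 + h, x0 : x0 + w].sum()
                ),
            }
        )
    return profiles, pd.DataFrame(rows)
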