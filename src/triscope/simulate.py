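"""Seeded synthetic-data generators.

Every generator returns its ground truth alongside the data, so each
analysis pipeline can be verified offline by parameter recovery. The
defaults encode the conditions the instrument characterization reports:
bead z-stacks from -3.5 to +3.5 um in 50 nm steps at lambda = 520 nm and
NA 0.85; SEM/FIB views at 62/10 degrees incidence; stage repositioning
spreads of 41/43/291 nm per axis; objective-stage drift of order
0.7/-0.2/-0.05 um/h.

The forward projection used to render reposition trials is
:func:`triscope.stage.project_displacement` — the exact operation the
dual-view inversion solves, by construction.
"""

from __future__ import annotations

import math
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .psf import FWHM_PER_SIGMA, subvolume_halfwidth
from .stage import project_displacement
from .types import (
    BeadStack,
    OpticalConfig,
    RepositionScenario,
    ScanImage,
    VibrationScene,
)

__all__ = [
    "sim_scan_images",
    "sim_bead_stack",
    "sim_reposition_trials",
    "sim_drift_series",
    "sim_milling_series",
    "edge_trajectory",
]

EDGE_DARK = 0.2
EDGE_BRIGHT = 0.8


def edge_trajectory(
    scene: VibrationScene, n_rows: int, n_cols: int, line_time: float
) -> np.ndarray:
    """Ground-truth per-line edge position in px: static edge + parabolic
    bow + the sum of sinusoidal components sampled at each line's start
    time (line k starts at k * line_time)."""
    k = np.arange(n_rows, dtype=float)
    t = k * line_time
    pos = np.full(n_rows, scene.edge_position_px, dtype=float)
    pos += scene.curvature_coeff * (k - n_rows / 2.0) ** 2 / scene.pixel_size
    for i, (f, pp, phase) in enumerate(scene.components):
        amp_px = 0.5 * pp / scene.pixel_size
        if (
            scene.edge_position_px + amp_px > n_cols - 2
            or scene.edge_position_px - amp_px < 1
        ):
            raise ValueError(
                f"component {i} (f={f} Hz, pp={pp} nm) displaces the edge "
                "outside the image"
            )
        pos += amp_px * np.sin(2.0 * math.pi * f * t + phase)
    if pos.min() < 0.5 or pos.max() > n_cols - 1.5:
        raise ValueError("combined displacement moves the edge outside the image")
    return pos


def _render_edge_image(
    pos: np.ndarray, n_cols: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Dark-to-bright step with fractional (anti-aliased) pixel coverage."""
    j = np.arange(n_cols, dtype=float)
    cover = np.clip(j[None, :] + 0.5 - pos[:, None], 0.0, 1.0)
    img = EDGE_DARK + (EDGE_BRIGHT - EDGE_DARK) * cover
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def sim_scan_images(
    scene: VibrationScene,
    dwell_times: Sequence[float],
    resolutions: Sequence[Tuple[int, int]],
    seed: int = 0,
    retrace_fraction: float = 0.0,
    scan_rotation: float = 0.0,
) -> Tuple[List[ScanImage], List[np.ndarray]]:
    """Render SEM scan images of a vibrating step edge.

    ``dwell_times`` and ``resolutions`` are cross-producted: one image per
    (dwell, resolution) combination, in that nesting order. Returns the
    images and, per image, the ground-truth per-line edge trajectory (px).
    """
    if not dwell_times or not resolutions:
        raise ValueError("dwell_times and resolutions must be non-empty")
    rng = np.random.default_rng(seed)
    images: List[ScanImage] = []
    truths: List[np.ndarray] = []
    for dwell in dwell_times:
        for (n_rows, n_cols) in resolutions:
            line_time = dwell * n_cols * (1.0 + retrace_fraction)
            pos = edge_trajectory(scene, n_rows, n_cols, line_time)
            pixels = _render_edge_image(pos, n_cols, scene.noise_sd, rng)
            images.append(
                ScanImage(
                    pixels=pixels,
                    dwell_time=dwell,
                    pixel_size=scene.pixel_size,
                    scan_rotation=scan_rotation,
                    retrace_fraction=retrace_fraction,
                )
            )
            truths.append(pos)
    return images, truths


def _place_points(
    rng: np.random.Generator,
    n: int,
    lo: Tuple[float, float],
    hi: Tuple[float, float],
    min_sep: float,
    existing: List[Tuple[float, float]],
    max_tries: int = 20000,
) -> List[Tuple[float, float]]:
    placed: List[Tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise ValueError(
                "field too small to place the requested beads at the "
                "minimum-separation rule"
            )
        tries += 1
        x = rng.uniform(lo[0], hi[0])
        y = rng.uniform(lo[1], hi[1])
        if all(
            math.hypot(x - px, y - py) >= min_sep
            for px, py in placed + existing
        ):
            placed.append((x, y))
    return placed


def sim_bead_stack(
    config: OpticalConfig,
    n_beads: int = 20,
    bead_sd_px: Optional[float] = None,
    n_clusters: int = 0,
    n_border: int = 0,
    noise_sd: float = 2.0,
    field_shape: Tuple[int, int] = (256, 256),
    amplitude: float = 1000.0,
    background: float = 100.0,
    axial_fwhm_nm: float = 1000.0,
    rayleigh_range_nm: float = 600.0,
    astig_offset_nm_per_deg: float = 150.0,
    z_jitter_planes: float = 1.0,
    seed: int = 0,
) -> Tuple[BeadStack, pd.DataFrame]:
    """Render a fluorescent-bead z-stack through a separable 3D Gaussian PSF.

    Beads sit at continuous sub-pixel/sub-plane positions. Lateral widths
    follow the defocus hyperbola w(z) = sigma0 * sqrt(1 + ((z - z_off)/zR)^2)
    with focal offsets z_off = +-astig_offset_nm_per_deg * (cyl_theta - 90)
    of opposite sign for X and Y (crossed-cylinder astigmatism; 90 degrees
    means no astigmatism and a circular PSF at every defocus). The axial
    envelope is Gaussian with FWHM ``axial_fwhm_nm``. ``bead_sd_px`` is the
    in-focus lateral sigma in px (default: a 370 nm FWHM spot).

    Clusters are double-intensity beads; border beads sit within the default
    border margin of an edge. Ground truth columns: x_px, y_px, z_plane,
    amplitude, sigma_px, kind (clean|cluster|border).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    ny, nx = field_shape
    nz = config.n_planes
    if bead_sd_px is None:
        bead_sd_px = 370.0 / FWHM_PER_SIGMA / config.pixel_size
    sigma_z_nm = axial_fwhm_nm / FWHM_PER_SIGMA
    z_span = config.z_range[1] - config.z_range[0]
    if z_span < 3.0 * axial_fwhm_nm:
        warnings.warn(
            "z_range is short relative to the axial PSF support; "
            "the axial profile will be truncated"
        )
    hxy, _hz = subvolume_halfwidth(config)
    # 2 px above the analysis threshold (2*hxy) so detection jitter cannot
    # push a clean pair below it: filters are exercised deterministically
    min_sep = 2.0 * hxy + 2.0
    margin = hxy + 2.0
    if nx - 2 * margin <= 0 or ny - 2 * margin <= 0:
        raise ValueError("field too small for the subvolume margin")

    interior = _place_points(
        rng, n_beads + n_clusters, (margin, margin),
        (nx - 1 - margin, ny - 1 - margin), min_sep, [],
    )
    rows = []
    for i, (x, y) in enumerate(interior):
        kind = "clean" if i < n_beads else "cluster"
        rows.append((x, y, 1.0 if kind == "clean" else 2.0, kind))
    placed = list(interior)
    for _ in range(n_border):
        for _try in range(20000):
            side = rng.integers(0, 4)
            off = rng.uniform(1.0, 0.5 * hxy)
            if side == 0:
                x, y = off, rng.uniform(margin, ny - 1 - margin)
            elif side == 1:
                x, y = nx - 1 - off, rng.uniform(margin, ny - 1 - margin)
            elif side == 2:
                x, y = rng.uniform(margin, nx - 1 - margin), off
            else:
                x, y = rng.uniform(margin, nx - 1 - margin), ny - 1 - off
            if all(math.hypot(x - px, y - py) >= min_sep for px, py in placed):
                break
        else:
            raise ValueError("field too small to place border beads")
        placed.append((x, y))
        rows.append((x, y, 1.0, "border"))
    if not rows:
        raise ValueError("zero beads after placement")

    z_center = (nz - 1) / 2.0
    zoff_nm = astig_offset_nm_per_deg * (config.cyl_theta - 90.0)
    volume = np.zeros((nz, ny, nx), dtype=float)
    truth = []
    w_max = bead_sd_px * math.sqrt(
        1.0 + ((0.5 * z_span + abs(zoff_nm)) / rayleigh_range_nm) ** 2
    )
    r_px = int(math.ceil(4.0 * w_max))
    for (x, y, rel_amp, kind) in rows:
        z0 = z_center + rng.uniform(-z_jitter_planes, z_jitter_planes)
        amp = amplitude * rel_amp
        x_lo, x_hi = max(0, int(x) - r_px), min(nx, int(x) + r_px + 1)
        y_lo, y_hi = max(0, int(y) - r_px), min(ny, int(y) + r_px + 1)
        xs = np.arange(x_lo, x_hi, dtype=float)
        ys = np.arange(y_lo, y_hi, dtype=float)
        dz_nm = (np.arange(nz) - z0) * config.z_step
        wx = bead_sd_px * np.sqrt(1.0 + ((dz_nm - zoff_nm) / rayleigh_range_nm) ** 2)
        wy = bead_sd_px * np.sqrt(1.0 + ((dz_nm + zoff_nm) / rayleigh_range_nm) ** 2)
        env = amp * np.exp(-(dz_nm**2) / (2.0 * sigma_z_nm**2))
        gx = np.exp(-((xs[None, :] - x) ** 2) / (2.0 * wx[:, None] ** 2))
        gy = np.exp(-((ys[None, :] - y) ** 2) / (2.0 * wy[:, None] ** 2))
        volume[:, y_lo:y_hi, x_lo:x_hi] += (
            env[:, None, None] * gy[:, :, None] * gx[:, None, :]
        )
        truth.append(
            {"x_px": x, "y_px": y, "z_plane": z0, "amplitude": amp,
             "sigma_px": bead_sd_px, "kind": kind}
        )
    volume += background
    if noise_sd > 0:
        volume += rng.normal(0.0, noise_sd, volume.shape)
    volume = np.clip(volume, 0.0, None).astype(np.float32)
    stack = BeadStack(
        volume=volume, pixel_size=config.pixel_size, z_step=config.z_step,
        wavelength=config.wavelength, na=config.na,
    )
    return stack, pd.DataFrame(truth)


def sim_reposition_trials(
    scenario: RepositionScenario,
    image_shape: Tuple[int, int] = (256, 256),
    pixel_size_sem: float = 20.0,
    pixel_size_fib: float = 20.0,
    template_sigma_px: float = 3.0,
    trial_interval_s: float = 60.0,
    seed: int = 0,
) -> Tuple[List[Tuple[ScanImage, ScanImage, float]], pd.DataFrame]:
    """Render a timestamped SEM/FIB image-pair series of repositioning trials.

    Each image-to-image displacement is drawn per axis from
    N(0, displacement_sd); positions accumulate (random walk). A fixed
    high-contrast template (band-limited noise, periodic) is translated by
    the forward projection of each trial's cumulative position, plus
    per-image localization jitter. Returns the series and the ground-truth
    position table (columns trial, t_s, x_nm, y_nm, z_nm); image-to-image
    displacements are its first differences.
    """
    rng = np.random.default_rng(seed)
    n = scenario.n_trials
    d = rng.normal(0.0, scenario.displacement_sd, size=(n - 1, 3))
    positions = np.vstack([np.zeros(3), np.cumsum(d, axis=0)])
    base = {
        "sem": ndimage.gaussian_filter(
            rng.standard_normal(image_shape), template_sigma_px, mode="wrap"
        ),
        "fib": ndimage.gaussian_filter(
            rng.standard_normal(image_shape), template_sigma_px, mode="wrap"
        ),
    }
    px_size = {"sem": pixel_size_sem, "fib": pixel_size_fib}
    # the template is periodic, so absolute positions wrap harmlessly; only
    # the image-to-image shift must stay unambiguous (< a quarter period)
    max_step = min(image_shape) / 4.0
    prev_shift = {"sem": (0.0, 0.0), "fib": (0.0, 0.0)}
    series: List[Tuple[ScanImage, ScanImage, float]] = []
    for i in range(n):
        rendered = {}
        for view in ("sem", "fib"):
            ix, iy = project_displacement(positions[i], scenario.geometry, view)
            sx = ix / px_size[view]
            sy = iy / px_size[view]
            if scenario.localization_noise_px > 0:
                sx += rng.normal(0.0, scenario.localization_noise_px)
                sy += rng.normal(0.0, scenario.localization_noise_px)
            step = math.hypot(sx - prev_shift[view][0], sy - prev_shift[view][1])
            if step > max_step:
                raise ValueError(
                    f"trial {i}: projected image-to-image shift {step:.1f} px "
                    "exceeds the template margin"
                )
            prev_shift[view] = (sx, sy)
            if sx == 0.0 and sy == 0.0:
                img = base[view].copy()
            else:
                img = ndimage.shift(base[view], (sy, sx), order=3, mode="grid-wrap")
            rendered[view] = ScanImage(
                pixels=img, dwell_time=1e-6, pixel_size=px_size[view],
            )
        series.append((rendered["sem"], rendered["fib"], i * trial_interval_s))
    truth = pd.DataFrame(
        {
            "trial": np.arange(n),
            "t_s": np.arange(n) * trial_interval_s,
            "x_nm": positions[:, 0],
            "y_nm": positions[:, 1],
            "z_nm": positions[:, 2],
        }
    )
    return series, truth


def sim_drift_series(
    rates_nm_per_h: Tuple[float, float, float] = (700.0, -200.0, -50.0),
    duration_h: float = 4.0,
    n_samples: int = 60,
    sample_times_h: Optional[np.ndarray] = None,
    gaps_h: Optional[Sequence[Tuple[float, float]]] = None,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative-shift series shift(t) = rate * t + noise, with optional
    recording gaps (e.g. breaks) removed from the timestamps. Columns:
    t_h, x_nm, y_nm, z_nm."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if sample_times_h is None:
        t = np.linspace(0.0, duration_h, n_samples)
    else:
        t = np.asarray(sample_times_h, dtype=float)
    if gaps_h:
        keep = np.ones(len(t), dtype=bool)
        for lo, hi in gaps_h:
            keep &= ~((t > lo) & (t < hi))
        t = t[keep]
    rates = np.asarray(rates_nm_per_h, dtype=float)
    xyz = t[:, None] * rates[None, :]
    if noise_sd_nm > 0:
        xyz = xyz + rng.normal(0.0, noise_sd_nm, xyz.shape)
    return pd.DataFrame(
        {"t_h": t, "x_nm": xyz[:, 0], "y_nm": xyz[:, 1], "z_nm": xyz[:, 2]}
    )


def sim_milling_series(
    band_widths_px: Sequence[float],
    image_shape: Tuple[int, int] = (128, 128),
    band_center_row: Optional[float] = None,
    band_edge_sigma_px: float = 1.5,
    blob_sigma_px: float = 4.0,
    reflection_amplitude: float = 1.0,
    blob_amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> List[np.ndarray]:
    """Two-channel milling snapshots: channel 0 (reflection) holds a bright
    horizontal band narrowing step by step; channel 1 (fluorescence) holds a
    compact target blob clipped by the same band.

    The band is a boxcar of the given width smoothed by an erf edge of
    ``band_edge_sigma_px``, so its half-max width equals the nominal width.
    The blob has compact support (truncated at 3 sigma), so its integral
    stays constant (to numerical precision) as long as the band clears the
    blob support by several edge widths. Band widths must be monotonically
    non-increasing.
    """
    widths = np.asarray(band_widths_px, dtype=float)
    if len(widths) < 2:
        raise ValueError("need at least 2 milling steps")
    if np.any(np.diff(widths) > 0):
        raise ValueError("band widths must be monotonically non-increasing")
    from scipy.special import erf

    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    c = (ny - 1) / 2.0 if band_center_row is None else float(band_center_row)
    y = np.arange(ny, dtype=float)
    xx, yy = np.meshgrid(np.arange(nx, dtype=float), y)
    r2 = (xx - (nx - 1) / 2.0) ** 2 + (yy - c) ** 2
    g = np.exp(-r2 / (2.0 * blob_sigma_px**2))
    cut = math.exp(-4.5)  # 3 sigma truncation -> compact support
    blob = np.clip(g - cut, 0.0, None) * blob_amplitude
    frames: List[np.ndarray] = []
    for w in widths:
        s = band_edge_sigma_px * math.sqrt(2.0)
        prof = 0.5 * (erf((y - (c - w / 2.0)) / s) - erf((y - (c + w / 2.0)) / s))
        mask = prof / prof.max()
        refl = reflection_amplitude * np.tile(prof[:, None], (1, nx))
        fluo = blob * mask[:, None]
        frame = np.stack([refl, fluo])
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        frames.append(frame)
    return frames
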