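"""Bead-based PSF extraction.

Builds an averaged 3D point spread function from a fluorescent-bead z-stack:
maximum-intensity projection, blob detection with mass/border/proximity
filters, Pearson-correlation outlier rejection, sub-pixel Gaussian
localization, 5x upsampled alignment and averaging, and FWHM/ellipticity
metrics for both widefield and astigmatic imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .types import AveragedPSF, BeadCandidate, BeadStack, FitError, OpticalConfig, PSFMetrics

__all__ = [
    "max_project_z",
    "find_beads",
    "subvolume_halfwidth",
    "extract_subvolume",
    "filter_outliers_pearson",
    "localize_bead",
    "average_psf",
    "measure_psf",
    "run_psf_pipeline",
    "PSFResult",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def max_project_z(stack: Union[BeadStack, np.ndarray]) -> np.ndarray:
    """Per-pixel maximum intensity projection along z."""
    vol = stack.volume if isinstance(stack, BeadStack) else np.asarray(stack, dtype=float)
    if vol.ndim != 3 or vol.shape[0] < 1:
        raise ValueError("expected a non-empty 3D stack")
    return vol.max(axis=0)


def subvolume_halfwidth(
    config: OpticalConfig, k_xy: float = 3.0, k_z: float = 2.0
) -> Tuple[int, int]:
    """Half-widths (lateral px, axial planes) of the per-bead subvolume.

    Lateral: ceil(k_xy * lambda / (2 NA) / pixel_size); axial:
    ceil(k_z * lambda / NA^2 / z_step). The k factors count diffraction
    resolution units per half-width.
    """
    if k_xy <= 0 or k_z <= 0:
        raise ValueError("k factors must be positive (degenerate window otherwise)")
    hxy = int(math.ceil(k_xy * config.wavelength / (2.0 * config.na) / config.pixel_size))
    hz = int(math.ceil(k_z * config.wavelength / config.na**2 / config.z_step))
    if 2 * hz + 1 > config.n_planes:
        raise ValueError(
            f"axial half-width {hz} planes exceeds the stack extent "
            f"({config.n_planes} planes); extend z_range or reduce k_z"
        )
    return hxy, hz


def find_beads(
    projection: np.ndarray,
    min_separation_px: float,
    border_margin_px: float,
    min_mass: Optional[float] = None,
    max_mass: Optional[float] = None,
    detection_sigma: float = 1.5,
    mass_radius_px: Optional[int] = None,
    threshold_mads: float = 5.0,
) -> List[BeadCandidate]:
    """Detect bead candidates on a z-projection and flag the unusable ones.

    Candidates outside [min_mass, max_mass] are flagged mass_low/mass_high
    (defaults: 0.3x / 1.7x the median candidate mass — scale-free); pairs
    closer than ``min_separation_px`` are both flagged proximal; candidates
    within ``border_margin_px`` of any edge are flagged border.
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2:
        raise ValueError("projection must be 2D")
    if min_mass is not None and max_mass is not None and min_mass >= max_mass:
        raise ValueError("min_mass must be < max_mass")
    bg = float(np.median(proj))
    mad = 1.4826 * float(np.median(np.abs(proj - bg)))
    smoothed = ndimage.gaussian_filter(proj, detection_sigma)
    thr = bg + threshold_mads * max(mad, 1e-12)
    peaks = peak_local_max(
        smoothed, min_distance=max(2, int(round(detection_sigma * 2))),
        threshold_abs=thr, exclude_border=False,
    )
    if mass_radius_px is None:
        mass_radius_px = max(3, int(math.ceil(min_separation_px / 2.0)))
    ny, nx = proj.shape
    sub = np.clip(proj - bg, 0, None)
    candidates: List[BeadCandidate] = []
    for py, px in peaks:
        # center-of-mass refinement in a small window
        r = 3
        ys, xs = slice(max(0, py - r), min(ny, py + r + 1)), slice(max(0, px - r), min(nx, px + r + 1))
        w = sub[ys, xs]
        tot = w.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[ys, xs]
        cy = float((w * yy).sum() / tot)
        cx = float((w * xx).sum() / tot)
        mr = int(mass_radius_px)
        ys2 = slice(max(0, int(round(cy)) - mr), min(ny, int(round(cy)) + mr + 1))
        xs2 = slice(max(0, int(round(cx)) - mr), min(nx, int(round(cx)) + mr + 1))
        mass = float(sub[ys2, xs2].sum())
        candidates.append(BeadCandidate(x=cx, y=cy, mass=mass))

    if candidates:
        masses = np.array([c.mass for c in candidates])
        med = float(np.median(masses))
        lo = min_mass if min_mass is not None else 0.3 * med
        hi = max_mass if max_mass is not None else 1.7 * med
        for c in candidates:
            if c.mass < lo:
                c.flags.add("mass_low")
            elif c.mass > hi:
                c.flags.add("mass_high")
            if (
                c.x < border_margin_px
                or c.y < border_margin_px
                or c.x > nx - 1 - border_margin_px
                or c.y > ny - 1 - border_margin_px
            ):
                c.flags.add("border")
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                d = math.hypot(candidates[i].x - candidates[j].x,
                               candidates[i].y - candidates[j].y)
                if d < min_separation_px:
                    candidates[i].flags.add("proximal")
                    candidates[j].flags.add("proximal")
    if not any(c.clean for c in candidates):
        raise ValueError(
            "no unflagged bead candidates found; review detection/mass thresholds"
        )
    return candidates


def extract_subvolume(
    volume: np.ndarray, x: float, y: float, hxy: int, hz: int
) -> Tuple[np.ndarray, Tuple[int, int, int]]:
    """Cut the (2hz+1, 2hxy+1, 2hxy+1) subvolume around a candidate.

    The axial center is the brightest plane of the (smoothed) intensity
    column at the candidate's pixel, clamped so the window fits the stack.
    Returns the subvolume and its (z0, y0, x0) corner in stack coordinates.
    """
    nz, ny, nx = volume.shape
    xi, yi = int(round(x)), int(round(y))
    if not (hxy <= xi <= nx - 1 - hxy and hxy <= yi <= ny - 1 - hxy):
        raise ValueError("lateral subvolume window exceeds the stack extent")
    col = ndimage.gaussian_filter1d(volume[:, yi, xi].astype(float), 1.0)
    zc = int(np.argmax(col))
    zc = min(max(zc, hz), nz - 1 - hz)
    z0, y0, x0 = zc - hz, yi - hxy, xi - hxy
    sv = volume[z0 : z0 + 2 * hz + 1, y0 : y0 + 2 * hxy + 1, x0 : x0 + 2 * hxy + 1]
    return np.array(sv, dtype=float), (z0, y0, x0)


def filter_outliers_pearson(
    subvolumes: Sequence[np.ndarray], threshold: float = 0.8
) -> Tuple[List[np.ndarray], List[int]]:
    """Reject doublets/faulty localizations by mutual Pearson correlation.

    Computes pairwise Pearson r between the z-MIPs of all subvolumes and
    rejects candidates whose median r to all others falls below
    ``threshold``. With exactly two dissimilar subvolumes both fall below the
    threshold and an error is raised (degenerate case: no majority to vote).
    """
    if len(subvolumes) < 2:
        raise ValueError("need at least 2 subvolumes for outlier filtering")
    mips = np.stack([sv.max(axis=0).ravel() for sv in subvolumes])
    mips = mips - mips.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mips, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance subvolume projection")
    r = (mips @ mips.T) / np.outer(norms, norms)
    n = len(subvolumes)
    med = np.array([np.median(np.delete(r[i], i)) for i in range(n)])
    kept = [i for i in range(n) if med[i] >= threshold]
    rejected = [i for i in range(n) if med[i] < threshold]
    if not kept:
        raise ValueError("all candidates rejected by the Pearson outlier filter")
    return [subvolumes[i] for i in kept], rejected


def _gauss1d(x, a, x0, s, c):
    return c + a * np.exp(-((x - x0) ** 2) / (2.0 * s**2))


def fit_gaussian_1d(y: np.ndarray, x: Optional[np.ndarray] = None) -> Tuple[float, float, float, float]:
    """Least-squares 1D Gaussian fit; returns (amplitude, center, sigma, offset)."""
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(len(y), dtype=float)
    if y.max() - y.min() <= 0:
        raise FitError("flat profile: 1D Gaussian fit is undefined")
    c0 = float(y.min())
    a0 = float(y.max() - c0)
    x0 = float(x[np.argmax(y)])
    w = np.clip(y - c0, 0, None)
    s0 = math.sqrt(max(float((w * (x - x0) ** 2).sum() / max(w.sum(), 1e-12)), 0.25))
    try:
        popt, _ = optimize.curve_fit(
            _gauss1d, x, y, p0=(a0, x0, s0, c0),
            bounds=([0, x.min() - 1, 1e-3, -np.inf], [np.inf, x.max() + 1, np.ptp(x) + 1, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"1D Gaussian fit failed: {exc}") from exc
    return tuple(float(v) for v in popt)


def _gauss2d(coords, a, x0, y0, sx, sy, c):
    x, y = coords
    return c + a * np.exp(
        -((x - x0) ** 2) / (2.0 * sx**2) - ((y - y0) ** 2) / (2.0 * sy**2)
    )


def fit_gaussian_2d(img: np.ndarray) -> Dict[str, float]:
    """2D elliptical Gaussian fit (nonlinear least squares) on an image."""
    img = np.asarray(img, dtype=float)
    if img.max() - img.min() <= 0:
        raise FitError("flat image: 2D Gaussian fit is undefined")
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    c0 = float(img.min())
    a0 = float(img.max() - c0)
    iy, ix = np.unravel_index(np.argmax(img), img.shape)
    w = np.clip(img - c0, 0, None)
    tot = max(w.sum(), 1e-12)
    sx0 = math.sqrt(max(float((w * (xx - ix) ** 2).sum() / tot), 0.25))
    sy0 = math.sqrt(max(float((w * (yy - iy) ** 2).sum() / tot), 0.25))
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            img.ravel(),
            p0=(a0, float(ix), float(iy), sx0, sy0, c0),
            bounds=(
                [0, -1, -1, 1e-3, 1e-3, -np.inf],
                [np.inf, nx, ny, 2 * nx, 2 * ny, np.inf],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"2D Gaussian fit failed: {exc}") from exc
    keys = ("amplitude", "x0", "y0", "sx", "sy", "offset")
    out = dict(zip(keys, (float(v) for v in popt)))
    if not (0 <= out["x0"] <= nx - 1 and 0 <= out["y0"] <= ny - 1):
        raise FitError("fitted center lies outside the subvolume")
    return out


def localize_bead(
    subvolume: np.ndarray, use_interpolated_column: bool = False
) -> Tuple[float, float, float]:
    """Sub-pixel (x, y) and sub-plane z of a single bead.

    x, y come from a 2D Gaussian fit on the z-MIP; z from a 1D Gaussian fit
    on the axial intensity profile through the fitted (x, y) — by default the
    nearest integer pixel column, optionally a bilinearly interpolated one.
    """
    sv = np.asarray(subvolume, dtype=float)
    if sv.ndim != 3:
        raise ValueError("subvolume must be 3D")
    fit = fit_gaussian_2d(sv.max(axis=0))
    x0, y0 = fit["x0"], fit["y0"]
    if use_interpolated_column:
        nz = sv.shape[0]
        coords = np.vstack(
            [np.arange(nz), np.full(nz, y0), np.full(nz, x0)]
        )
        profile = ndimage.map_coordinates(sv, coords, order=1, mode="nearest")
    else:
        profile = sv[:, int(round(y0)), int(round(x0))]
    _a, z0, _s, _c = fit_gaussian_1d(profile)
    if not 0 <= z0 <= sv.shape[0] - 1:
        raise FitError("axial center lies outside the subvolume")
    return x0, y0, z0


def upsample_volume(volume: np.ndarray, factor: int = 5, interpolation: str = "cubic") -> np.ndarray:
    """Upsample so that upsampled index u maps exactly to native coordinate
    u / factor (output length (n-1)*factor + 1 per axis).

    Cubic/linear modes interpolate separably axis by axis with a spline;
    nearest mode reproduces blockier behavior exactly.
    """
    vol = np.asarray(volume, dtype=float)
    if interpolation == "nearest":
        out = vol
        for ax, n in enumerate(vol.shape):
            idx = np.round(np.arange((n - 1) * factor + 1) / factor).astype(int)
            out = np.take(out, idx, axis=ax)
        return out
    if interpolation not in ("cubic", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    from scipy.interpolate import make_interp_spline

    k = 3 if interpolation == "cubic" else 1
    out = vol
    for ax, n in enumerate(vol.shape):
        coords = np.arange((n - 1) * factor + 1, dtype=float) / factor
        spl = make_interp_spline(np.arange(n, dtype=float), out, k=k, axis=ax)
        out = spl(coords)
    return out


def average_psf(
    subvolumes: Sequence[np.ndarray],
    positions: Sequence[Tuple[float, float, float]],
    pixel_size: float,
    z_step: float,
    upsample: int = 5,
    interpolation: str = "cubic",
) -> AveragedPSF:
    """Upsample, align and average localized bead subvolumes.

    Each subvolume is upsampled by ``upsample`` and translated so its fitted
    (x, y, z) position, rounded to the nearest upsampled voxel, lands on the
    subvolume center; the aligned volumes are voxel-wise averaged and
    peak-normalized.
    """
    if len(subvolumes) < 1:
        raise ValueError("need at least one subvolume")
    shape = subvolumes[0].shape
    if any(sv.shape != shape for sv in subvolumes):
        raise ValueError("subvolumes must share a common shape")
    if len(subvolumes) != len(positions):
        raise ValueError("need one position per subvolume")
    center = tuple((n - 1) / 2.0 for n in shape)  # (z, y, x) native
    acc = None
    for sv, (x, y, z) in zip(subvolumes, positions):
        up = upsample_volume(sv, upsample, interpolation)
        shifts = [
            int(round(upsample * (c - p)))
            for c, p in zip(center, (z, y, x))
        ]
        up = np.roll(up, shifts, axis=(0, 1, 2))
        acc = up if acc is None else acc + up
    avg = acc / len(subvolumes)
    peak = avg.max()
    if peak <= 0:
        raise ValueError("averaged PSF has non-positive peak")
    return AveragedPSF(
        volume=avg / peak,
        voxel_size=(z_step / upsample, pixel_size / upsample, pixel_size / upsample),
        n_beads=len(subvolumes),
    )


def _check_single_peak(profile: np.ndarray) -> None:
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(profile, height=0.7 * profile.max(),
                          prominence=0.3 * (profile.max() - profile.min()))
    if len(peaks) > 1:
        raise ValueError("multi-peaked profile: PSF metrics are undefined")


def measure_psf(psf: AveragedPSF, ellipticity_floor: float = 0.3) -> PSFMetrics:
    """FWHM along x, y (in-focus plane) and z (through the peak), plus an
    ellipticity (wx/wy) table per z plane with sufficient signal."""
    vol = psf.volume
    vz, vy, vx = psf.voxel_size
    pz, py, px = np.unravel_index(np.argmax(vol), vol.shape)
    prof_x = vol[pz, py, :]
    prof_y = vol[pz, :, px]
    prof_z = vol[:, py, px]
    for p in (prof_x, prof_y, prof_z):
        _check_single_peak(p)
    _, _, sx, _ = fit_gaussian_1d(prof_x)
    _, _, sy, _ = fit_gaussian_1d(prof_y)
    _, _, sz, _ = fit_gaussian_1d(prof_z)
    rows = []
    peakval = float(vol.max())
    for iz in range(vol.shape[0]):
        plane = vol[iz]
        if plane.max() < ellipticity_floor * peakval:
            continue
        iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
        try:
            _, _, wx, _ = fit_gaussian_1d(plane[iy, :])
            _, _, wy, _ = fit_gaussian_1d(plane[:, ix])
        except FitError:
            continue
        rows.append({"defocus_nm": (iz - pz) * vz, "ellipticity": wx / wy})
    return PSFMetrics(
        fwhm_x=FWHM_PER_SIGMA * sx * vx,
        fwhm_y=FWHM_PER_SIGMA * sy * vy,
        fwhm_z=FWHM_PER_SIGMA * sz * vz,
        ellipticity_vs_z=pd.DataFrame(rows),
    )


@dataclass
class PSFResult:
    psf: AveragedPSF
    metrics: PSFMetrics
    qc: Dict[str, int]
    candidates: pd.DataFrame


def run_psf_pipeline(
    stack: BeadStack,
    config: Optional[OpticalConfig] = None,
    thresholds: Optional[Dict[str, float]] = None,
    k_xy: float = 3.0,
    k_z: float = 2.0,
    upsample: int = 5,
    pearson_threshold: float = 0.8,
    interpolation: str = "cubic",
) -> PSFResult:
    """Full PSF extraction chain with a per-stage QC report.

    QC counts: found (all detected candidates), mass_low/mass_high, border,
    proximal (flagged at detection), decorrelated (Pearson-rejected or failed
    localization) and averaged (contributing to the final PSF).
    """
    if config is None:
        config = OpticalConfig(
            na=stack.na, wavelength=stack.wavelength, pixel_size=stack.pixel_size,
            z_range=(0.0, (stack.n_planes - 1) * stack.z_step), z_step=stack.z_step,
        )
    thresholds = dict(thresholds or {})
    hxy, hz = subvolume_halfwidth(config, k_xy=k_xy, k_z=k_z)
    min_sep = thresholds.pop("min_separation_px", 2.0 * hxy)
    border = thresholds.pop("border_margin_px", float(hxy))

    proj = max_project_z(stack)
    candidates = find_beads(proj, min_separation_px=min_sep, border_margin_px=border,
                            **thresholds)
    qc = {
        "found": len(candidates),
        "mass_low": sum("mass_low" in c.flags for c in candidates),
        "mass_high": sum("mass_high" in c.flags for c in candidates),
        "border": sum("border" in c.flags for c in candidates),
        "proximal": sum("proximal" in c.flags for c in candidates),
        "decorrelated": 0,
    }
    clean = [c for c in candidates if c.clean]
    subvols = []
    owners = []
    for c in clean:
        try:
            sv, _corner = extract_subvolume(stack.volume, c.x, c.y, hxy, hz)
        except ValueError:
            c.flags.add("border")
            qc["border"] += 1
            continue
        subvols.append(sv)
        owners.append(c)
    if len(subvols) >= 2:
        kept, rejected = filter_outliers_pearson(subvols, threshold=pearson_threshold)
        for idx in rejected:
            owners[idx].flags.add("decorrelated")
        qc["decorrelated"] += len(rejected)
        keep_idx = [i for i in range(len(subvols)) if i not in set(rejected)]
        subvols = [subvols[i] for i in keep_idx]
        owners = [owners[i] for i in keep_idx]
    final_svs, positions = [], []
    for sv, c in zip(subvols, owners):
        try:
            x, y, z = localize_bead(sv)
        except FitError:
            c.flags.add("decorrelated")
            qc["decorrelated"] += 1
            continue
        c.z = z
        final_svs.append(sv)
        positions.append((x, y, z))
    if not final_svs:
        raise ValueError("PSF averaging stage received zero beads")
    psf = average_psf(final_svs, positions, pixel_size=config.pixel_size,
                      z_step=config.z_step, upsample=upsample,
                      interpolation=interpolation)
    qc["averaged"] = psf.n_beads
    metrics = measure_psf(psf)
    table = pd.DataFrame(
        {
            "x_px": [c.x for c in candidates],
            "y_px": [c.y for c in candidates],
            "z_plane": [c.z for c in candidates],
            "mass": [c.mass for c in candidates],
            "flags": ["|".join(sorted(c.flags)) for c in candidates],
        }
    )
    return PSFResult(psf=psf, metrics=metrics, qc=qc, candidates=table)
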