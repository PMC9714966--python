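"""Core data containers shared across the analysis modules.

Conventions used throughout the package: pixel coordinates are 0-based with
pixel centers at integer coordinates (x along image columns, y along rows);
ROIs are half-open; physical quantities are in nm, s, Hz and degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class TriscopeError(Exception):
    """Base class for errors raised by this package."""


class MetadataError(TriscopeError):
    """Missing or internally inconsistent acquisition metadata."""


class FitError(TriscopeError):
    """A model fit failed to converge or produced an out-of-range center."""


# --------------------------------------------------------------------------
# raster scanning


@dataclass
class ScanImage:
    """A 2D SEM/FIB raster image plus the acquisition timing that determines
    how image rows map to sample times.

    The raster model is: line k starts at ``k * line_time`` with
    ``line_time = dwell_time * n_cols * (1 + retrace_fraction)`` and the
    frame time ``Tf = line_time * n_rows``.
    """

    pixels: np.ndarray
    dwell_time: float  # s / px
    pixel_size: float  # nm / px
    scan_rotation: float = 0.0  # degrees; 0 samples X, 90 samples Y
    retrace_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.retrace_fraction < 0:
            raise ValueError("retrace_fraction must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def line_time(self) -> float:
        """Seconds per scanned line (sets the edge-trace sampling rate)."""
        return self.dwell_time * self.n_cols * (1.0 + self.retrace_fraction)

    @property
    def frame_time(self) -> float:
        """Total frame time Tf in seconds."""
        return self.line_time * self.n_rows


@dataclass
class EdgeTrace:
    """Edge position versus time, one sample per scanned line.

    ``positions`` are in pixels (NaN marks a line whose best correlation fell
    below the quality floor); ``quality`` is the per-line max \\|Pearson r\\|.
    """

    times: np.ndarray  # s
    positions: np.ndarray  # px; NaN = invalid line
    quality: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if not (len(self.times) == len(self.positions) == len(self.quality)):
            raise ValueError("times, positions and quality must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_lines(self) -> int:
        return len(self.times)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.positions)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least two samples for a sampling interval")
        return float(self.times[1] - self.times[0])


@dataclass
class VibrationSpectrum:
    """Peak-to-peak displacement amplitude (nm) per frequency bin."""

    frequencies: np.ndarray  # Hz
    amplitudes_pp: np.ndarray  # nm peak-to-peak
    band: tuple  # (f_min, f_max) Hz over which this trace is trusted

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes_pp = np.asarray(self.amplitudes_pp, dtype=float)
        if len(self.frequencies) != len(self.amplitudes_pp):
            raise ValueError("frequencies and amplitudes_pp must have equal length")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if len(self.frequencies) > 1 and not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.amplitudes_pp < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def df(self) -> float:
        """Frequency bin width in Hz."""
        if len(self.frequencies) < 2:
            return float("nan")
        return float(self.frequencies[1] - self.frequencies[0])


# --------------------------------------------------------------------------
# fluorescence / PSF


@dataclass
class BeadStack:
    """A fluorescence bead z-stack with the optical metadata the PSF
    pipeline needs (axes ordered z, y, x)."""

    volume: np.ndarray
    pixel_size: float  # nm / px, sample plane
    z_step: float  # nm
    wavelength: float  # nm, emission
    na: float

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D (z, y, x)")
        if self.volume.shape[0] < 3:
            raise ValueError("stack needs at least 3 z planes")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if not 0 < self.na <= 1:
            raise ValueError("NA must be in (0, 1]")
        if self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_size and wavelength must be positive")

    @property
    def n_planes(self) -> int:
        return self.volume.shape[0]


@dataclass
class BeadCandidate:
    """A detected blob; it enters PSF averaging only with an empty flag set."""

    x: float  # px, sub-pixel
    y: float
    mass: float  # background-subtracted integrated intensity
    flags: set = field(default_factory=set)
    z: Optional[float] = None  # planes, filled in after axial localization

    @property
    def clean(self) -> bool:
        return not self.flags


@dataclass
class AveragedPSF:
    """An upsampled, bead-averaged 3D PSF (peak-normalized to 1)."""

    volume: np.ndarray  # (z, y, x) at upsampled resolution
    voxel_size: tuple  # (z, y, x) nm per upsampled voxel
    n_beads: int

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")


@dataclass
class PSFMetrics:
    """FWHM metrics of an averaged PSF plus ellipticity vs defocus."""

    fwhm_x: float  # nm
    fwhm_y: float  # nm
    fwhm_z: float  # nm
    ellipticity_vs_z: pd.DataFrame  # columns: defocus_nm, ellipticity (wx/wy)

    @property
    def fwhm_xy(self) -> float:
        return 0.5 * (self.fwhm_x + self.fwhm_y)


# --------------------------------------------------------------------------
# stage metrology


@dataclass
class ViewGeometry:
    """Incidence angles of the SEM and FIB views to the sample plane.

    Sign convention: positive dz (toward the light-microscope objective)
    produces positive image-y shift in both views; ``sign_sem``/``sign_fib``
    flip it per view if an instrument is wired the other way.
    """

    alpha_sem: float = 62.0  # degrees
    alpha_fib: float = 10.0
    sign_sem: float = 1.0
    sign_fib: float = 1.0

    def __post_init__(self) -> None:
        for a in (self.alpha_sem, self.alpha_fib):
            if not 0 < a < 90:
                raise ValueError("incidence angles must lie strictly in (0, 90) degrees")
        if abs(self.alpha_sem - self.alpha_fib) < 1e-9:
            raise ValueError("SEM and FIB angles must differ, otherwise Z is unobservable")
        if abs(self.sign_sem) != 1 or abs(self.sign_fib) != 1:
            raise ValueError("sign conventions must be +1 or -1")


@dataclass
class DisplacementRecord:
    """One recovered sample-frame displacement with its least-squares misfit."""

    dx: float  # nm
    dy: float
    dz: float
    residual: float  # nm, >= 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


@dataclass
class RepositioningSummary:
    """Per-axis standard deviation (ddof=1) of n displacement records."""

    sigma_x: float  # nm
    sigma_y: float
    sigma_z: float
    n: int


@dataclass
class DriftEstimate:
    """Per-axis drift rates from an OLS fit of cumulative shift vs time."""

    rates: np.ndarray  # nm / h, per axis (x, y, z)
    intercepts: np.ndarray  # nm
    fit_window: tuple  # (t0, t1) hours

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")


# --------------------------------------------------------------------------
# milling monitor


@dataclass
class MillingProfile:
    """Normalized integrated intensity across the milling ROI (one channel)."""

    y_positions: np.ndarray  # px (rows of the ROI)
    intensity: np.ndarray  # normalized to max = 1
    channel: str
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.y_positions = np.asarray(self.y_positions)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.y_positions) != len(self.intensity):
            raise ValueError("y_positions and intensity must have equal length")


# --------------------------------------------------------------------------
# synthetic scene descriptions


@dataclass
class VibrationScene:
    """Description of a vibrating step-edge scene (tin ball on carbon style):
    a dark-to-bright edge with slow parabolic bow plus sinusoidal displacement
    components.

    ``components`` is a list of (frequency Hz, peak-to-peak amplitude nm,
    phase rad); ``curvature_coeff`` is nm per line^2.
    """

    edge_position_px: float
    components: Sequence = ()
    curvature_coeff: float = 0.0
    noise_sd: float = 0.0
    pixel_size: float = 1.0  # nm / px

    def __post_init__(self) -> None:
        for i, (f, pp, _phase) in enumerate(self.components):
            if f <= 0:
                raise ValueError(f"component {i}: frequency must be > 0 (got {f})")
            if pp < 0:
                raise ValueError(f"component {i}: peak-to-peak amplitude must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class OpticalConfig:
    """Optical acquisition parameters of the fluorescence path.

    ``cyl_theta`` is the crossed-cylinder angle in degrees; 90 deg introduces
    no astigmatism, deviations from 90 deg add astigmatism with magnitude
    proportional to \\|cyl_theta - 90\\|.
    """

    na: float = 0.85
    wavelength: float = 520.0  # nm
    pixel_size: float = 65.0  # nm / px in the sample plane
    z_range: tuple = (-3500.0, 3500.0)  # nm
    z_step: float = 50.0  # nm
    cyl_theta: float = 90.0  # degrees
    astig_mlambda: Optional[float] = None  # milli-waves, metadata only

    def __post_init__(self) -> None:
        if not 0 < self.na <= 1:
            raise ValueError("NA must be in (0, 1]")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if not 0 < self.cyl_theta < 180:
            raise ValueError("cyl_theta must lie in (0, 180) degrees")
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("z_range must be increasing")
        if self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_size and wavelength must be positive")

    @property
    def z_positions(self) -> np.ndarray:
        """Plane z positions in nm, inclusive of both range ends."""
        return np.arange(self.z_range[0], self.z_range[1] + 0.5 * self.z_step, self.z_step)

    @property
    def n_planes(self) -> int:
        return len(self.z_positions)


@dataclass
class RepositionScenario:
    """Conditions of a stage repositioning experiment.

    ``displacement_sd`` is the per-axis standard deviation (nm) of each
    image-to-image displacement; image positions follow the cumulative walk.
    ``move_limits`` records the commanded random-move range ((+-nm XY, +-nm Z))
    and is carried as metadata. Defaults emulate the characterized stage
    (sigma 41/43/291 nm; moves +-100 um XY, +-30 um Z).
    """

    n_trials: int = 100
    move_limits: tuple = (100_000.0, 30_000.0)  # +-nm for XY, +-nm for Z
    displacement_sd: tuple = (41.0, 43.0, 291.0)  # nm per axis
    localization_noise_px: float = 0.0
    geometry: ViewGeometry = field(default_factory=ViewGeometry)

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if any(s < 0 for s in self.displacement_sd):
            raise ValueError("displacement sds must be >= 0")
        if self.localization_noise_px < 0:
            raise ValueError("localization_noise_px must be >= 0")
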