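"""Dual-view stage metrology.

The SEM and FIB view the sample plane at different incidence angles (62 and
10 degrees by default), so an image-plane shift along image-y mixes sample-y
and sample-z motion differently in the two views. Registering consecutive
image pairs in both views and solving the small linear system per pair
recovers the full 3D sample-frame displacement; their spread summarizes
stage repositioning precision, and the cumulative shift versus time gives
drift rates.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .types import (
    DisplacementRecord,
    DriftEstimate,
    RepositioningSummary,
    ScanImage,
    ViewGeometry,
)

__all__ = [
    "register_images",
    "project_displacement",
    "design_matrix",
    "invert_dual_view",
    "analyze_repositioning",
    "drift_from_series",
    "predicted_sigma_ratio",
]


def register_images(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample_factor: int = 100,
    normalization: Optional[str] = None,
) -> Tuple[float, float]:
    """Translation of ``moving`` relative to ``reference`` by phase cross
    correlation with sub-pixel refinement.

    Returns ``(shift_x, shift_y)`` in px such that ``moving`` equals
    ``reference`` translated by ``(+shift_x, +shift_y)`` (content moved right
    and down for positive shifts).
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must have the same shape")
    if reference.std() == 0 or moving.std() == 0:
        raise ValueError("zero-variance image cannot be registered")
    shift, _error, _phase = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=normalization
    )
    # skimage returns the shift that registers moving onto reference, i.e.
    # minus the translation applied to the content.
    return float(-shift[1]), float(-shift[0])


def project_displacement(
    d: Sequence[float], geometry: ViewGeometry, view: str
) -> Tuple[float, float]:
    """Forward-project a sample-frame displacement (dx, dy, dz) in nm onto
    the image plane of one view (scan rotation 0 assumed).

    image_x = dx;  image_y = sin(alpha) * dy + sign * cos(alpha) * dz.
    """
    dx, dy, dz = (float(v) for v in d)
    if view == "sem":
        alpha, sign = geometry.alpha_sem, geometry.sign_sem
    elif view == "fib":
        alpha, sign = geometry.alpha_fib, geometry.sign_fib
    else:
        raise ValueError("view must be 'sem' or 'fib'")
    a = math.radians(alpha)
    return dx, math.sin(a) * dy + sign * math.cos(a) * dz


def design_matrix(geometry: ViewGeometry) -> np.ndarray:
    """4x3 linear map from (dx, dy, dz) to (x_sem, x_fib, y_sem, y_fib)."""
    a_s = math.radians(geometry.alpha_sem)
    a_f = math.radians(geometry.alpha_fib)
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, math.sin(a_s), geometry.sign_sem * math.cos(a_s)],
            [0.0, math.sin(a_f), geometry.sign_fib * math.cos(a_f)],
        ]
    )


def invert_dual_view(
    shift_sem: Sequence[float],
    shift_fib: Sequence[float],
    geometry: ViewGeometry,
    trial_index: int = 0,
) -> DisplacementRecord:
    """Least-squares recovery of the 3D sample displacement from the two
    image shifts (both in nm, ordered (x, y)).

    Solves the 4-equation, 3-unknown system given by :func:`design_matrix`;
    the residual is the Euclidean misfit in nm.
    """
    A = design_matrix(geometry)
    b = np.array([shift_sem[0], shift_fib[0], shift_sem[1], shift_fib[1]], dtype=float)
    sol, _res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate viewing geometry: displacement not recoverable")
    residual = float(np.linalg.norm(A @ sol - b))
    return DisplacementRecord(
        dx=float(sol[0]), dy=float(sol[1]), dz=float(sol[2]),
        residual=residual, trial_index=trial_index,
    )


def _pixels(img: Union[np.ndarray, ScanImage]) -> np.ndarray:
    if isinstance(img, ScanImage):
        if abs(img.scan_rotation) > 1e-9:
            raise ValueError(
                "non-zero scan rotation is not supported by the dual-view inversion"
            )
        return img.pixels
    return np.asarray(img, dtype=float)


def analyze_repositioning(
    image_series_sem: Sequence[Union[np.ndarray, ScanImage]],
    image_series_fib: Sequence[Union[np.ndarray, ScanImage]],
    geometry: ViewGeometry,
    pixel_size_sem: float,
    pixel_size_fib: float,
    upsample_factor: int = 100,
) -> Tuple[List[DisplacementRecord], RepositioningSummary]:
    """Consecutive image-to-image shifts per view, inverted pair by pair.

    An N-image series yields N-1 displacement records; the summary reports
    the per-axis standard deviation with ddof=1.
    """
    if len(image_series_sem) != len(image_series_fib):
        raise ValueError("SEM and FIB series must have equal length")
    n = len(image_series_sem)
    if n < 2:
        raise ValueError("need at least two images per view")
    records: List[DisplacementRecord] = []
    for i in range(n - 1):
        sx_s, sy_s = register_images(
            _pixels(image_series_sem[i]), _pixels(image_series_sem[i + 1]),
            upsample_factor=upsample_factor,
        )
        sx_f, sy_f = register_images(
            _pixels(image_series_fib[i]), _pixels(image_series_fib[i + 1]),
            upsample_factor=upsample_factor,
        )
        rec = invert_dual_view(
            (sx_s * pixel_size_sem, sy_s * pixel_size_sem),
            (sx_f * pixel_size_fib, sy_f * pixel_size_fib),
            geometry,
            trial_index=i,
        )
        records.append(rec)
    arr = np.array([[r.dx, r.dy, r.dz] for r in records])
    if len(records) > 1:
        sig = arr.std(axis=0, ddof=1)
    else:
        sig = np.zeros(3)
    summary = RepositioningSummary(
        sigma_x=float(sig[0]), sigma_y=float(sig[1]), sigma_z=float(sig[2]),
        n=len(records),
    )
    return records, summary


def drift_from_series(
    shifts: Union[pd.DataFrame, np.ndarray],
    times_h: Optional[np.ndarray] = None,
    breakpoints_h: Optional[Iterable[float]] = None,
) -> Union[DriftEstimate, List[DriftEstimate]]:
    """Per-axis OLS drift rates (nm/h) of a cumulative-shift time series.

    ``shifts`` is either a DataFrame with columns t_h, x_nm, y_nm, z_nm or an
    (n, 3) array accompanied by ``times_h``. Gaps in the timestamps are fine:
    the fit uses only the observed points. If ``breakpoints_h`` is given
    (e.g. a known mid-session relocation), an independent fit is returned for
    each segment.
    """
    if isinstance(shifts, pd.DataFrame):
        t = shifts["t_h"].to_numpy(dtype=float)
        xyz = shifts[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    else:
        if times_h is None:
            raise ValueError("times_h required when shifts is an array")
        t = np.asarray(times_h, dtype=float)
        xyz = np.asarray(shifts, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError("shifts array must have shape (n, 3)")
    if len(t) != len(xyz):
        raise ValueError("timestamps and shifts must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    def _fit(ts: np.ndarray, vals: np.ndarray) -> DriftEstimate:
        if len(ts) < 3:
            raise ValueError("drift fit needs at least 3 time points")
        rates = np.empty(3)
        intercepts = np.empty(3)
        for ax in range(3):
            rates[ax], intercepts[ax] = np.polyfit(ts, vals[:, ax], 1)
        return DriftEstimate(rates=rates, intercepts=intercepts,
                             fit_window=(float(ts[0]), float(ts[-1])))

    if breakpoints_h is None:
        return _fit(t, xyz)
    edges = [t[0] - 1e-12] + sorted(float(b) for b in breakpoints_h) + [t[-1] + 1e-12]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (t >= lo) & (t < hi) if hi != edges[-1] else (t >= lo) & (t <= hi)
        out.append(_fit(t[m], xyz[m]))
    return out


def predicted_sigma_ratio(geometry: ViewGeometry) -> float:
    """Closed-form sigma_Z / sigma_X under isotropic image-shift noise.

    With unit-variance iid noise on the four shift observations, the
    least-squares covariance is (A^T A)^{-1}; the ratio of the z and x
    standard deviations is the geometry's noise-amplification factor — the
    structural reason the recovered Z spread exceeds X/Y.
    """
    A = design_matrix(geometry)
    cov = np.linalg.inv(A.T @ A)
    return float(math.sqrt(cov[2, 2] / cov[0, 0]))
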