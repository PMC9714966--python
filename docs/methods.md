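# Methods

This note documents the models behind each analysis, the defaults and why
they were chosen, what the synthetic generators emulate (and what they do
not), and the numerical choices that matter for reproducing results.

## Vibration spectroscopy

**Model.** A raster scan across a static, high-contrast edge converts sample
vibration into per-line edge displacement. Line k is treated as sampled at
t_k = k·t_line with t_line = t_dwell·n_cols·(1 + retrace_fraction); the
retrace overhead defaults to 0 and is configurable. An image is therefore a
displacement time series with sampling rate 1/t_line and record length
T_f = t_line·n_rows; acquiring images at several dwell times tiles a
frequency range from ~1/T_f of the slowest scan up to the Nyquist rate of
the fastest.

**Edge tracking.** For every line, the position estimate is the Heaviside
step template (one per possible column) maximizing the absolute Pearson
correlation with the line. Using |r| makes the tracker polarity-agnostic.
Positions are integer column indices; a parabolic sub-pixel refinement of
the correlation peak exists but is off by default, so the tracker's output
is exactly an argmax and can be checked against exhaustive enumeration.
Lines whose best |r| falls below a quality floor (default 0.3) are marked
invalid; up to 5% of invalid lines are linearly interpolated (the FFT
requires uniform sampling), more rejects the image.

Integer tracking quantizes the trace. The quantization error of a sampled
sinusoid is signal-correlated: at 3 px amplitude it perturbs the recovered
fundamental by up to ~7%, at 15 px by under 1%. Recovery guarantees are
therefore stated for peak-to-peak excursions of tens of pixels — the regime
a real measurement operates in, where sub-nm vibrations are imaged at
ultra-high magnification (~0.1 nm pixels).

**Detrending.** Slow edge bow (e.g. the curvature of a sphere used as the
edge target) is removed with a Butterworth high-pass at f_c = 5/T_f. The
order (3) is not dictated by the procedure itself; order 3 applied
forward-backward (zero phase) suppresses a frame-spanning parabola to <5%
while its squared magnitude response returns to within 0.03% of unity at
4·f_c, which sets the trusted band's lower edge at 20/T_f.

**Spectrum.** The amplitude FFT uses a flat-top window scaled by the
coherent gain (2|X_k|/Σw, doubled for peak-to-peak). The flat-top window's
scalloping loss is ~0.01%, so off-bin sinusoids read correctly without
further correction. A Hann alternative corrects each local spectral maximum
by estimating the fractional bin offset from its two neighbours and
dividing by the window's amplitude response at that offset; both modes
satisfy the same fidelity bounds in the tests. The trusted band stops 5
bins short of Nyquist, where the window main lobe would straddle the
conjugate image. Per scan rotation (0° → X, 90° → Y), spectra with an
identical bin layout are reduced by a per-bin median (robust to transient
contamination) and bands are composited, the finer frequency resolution
winning where bands overlap. No masking of mains-interference peaks is
applied.

## PSF extraction

**Chain.** Maximum z-projection → blob detection → mass/border/proximity
flags → per-candidate subvolumes → Pearson outlier filter → Gaussian
localization → upsample, align, average → metrics.

**Detection and flags.** Blob detection smooths the projection (σ = 1.5 px)
and takes local maxima above median + 5 robust standard deviations (MAD).
Mass is the background-subtracted sum in a window of half the minimum
separation. Mass bounds default to 0.3×/1.7× the median candidate mass —
relative rather than absolute, so they are exposure-invariant; a
double-intensity bead cluster always lands above 1.7× when most candidates
are single beads. Candidates within the border margin (default: the lateral
subvolume half-width) or closer than the minimum separation (default: twice
that half-width) to another candidate are excluded.

**Subvolume size.** Half-widths are k_xy·λ/(2NA) laterally and k_z·λ/NA²
axially, in resolution units, with k_xy = 3 and k_z = 2 (the dependency on
NA, λ and pixel size is prescribed; the constants are this package's
choice). At λ = 520 nm, NA 0.85, 65 nm pixels and 50 nm steps this gives
15 px and 29 planes.

**Outlier filter.** Pairwise Pearson r between the subvolume z-projections;
a candidate whose median r to all others is below 0.8 is rejected. With
exactly two dissimilar candidates there is no majority and the case is an
error. The 0.8 threshold separates doublets cleanly in simulation while
never rejecting clean beads at the tested noise levels.

**Localization and averaging.** (x, y) come from an elliptical 2D Gaussian
fit (nonlinear least squares, moment-based initialization) on the
projection; z from a 1D Gaussian fit on the axial profile through the
nearest integer pixel to (x, y) (an interpolated-column option exists but
is off by default). Subvolumes are upsampled 5× by separable cubic-spline
interpolation (a nearest-neighbour mode reproduces blockier behaviour), the
mapping chosen so upsampled index u corresponds exactly to native
coordinate u/5; each is translated by the negated position rounded to the
nearest upsampled voxel and averaged, then peak-normalized. Rounding bounds
any alignment-induced widening by one upsampled voxel (13 nm laterally at
65 nm pixels), which the tests verify.

**Metrics.** FWHM = 2√(2 ln 2)·σ from 1D Gaussian fits along x, y (in-focus
plane) and z (through the peak); the ellipticity table lists w_x/w_y per
plane holding at least 30% of the peak intensity. Multi-peaked profiles are
an error, not a silent fit.

## Stage metrology

**Forward model.** With the sample plane viewed at incidence α, a sample
displacement (dx, dy, dz) produces image shifts (dx, sin α·dy ± cos α·dz)
at scan rotation 0; non-zero scan rotation is rejected rather than
mishandled. The sign convention — positive dz gives positive image-y in
both views — is a package convention used consistently by the simulator and
the inverter; either sign can be flipped per view. The simulator calls the
same `project_displacement` the inverter solves, so forward and inverse
cannot drift apart.

**Inversion.** The four observations (two x, two y) and three unknowns form
a linear least-squares problem solved by `numpy.linalg.lstsq`; the x
observations are equally weighted (so inconsistent x shifts average), and
the Euclidean misfit is reported per record. Consecutive (i→i+1) image
shifts are used — an N-image series yields N−1 records — and the summary
standard deviation uses ddof = 1.

**Error anisotropy.** With iid noise on all four shift observations, the
solution covariance is σ²(AᵀA)⁻¹. At (62°, 10°) the implied amplification
relative to X (sd √½σ) is ≈1.61 for Z and ≈1.39 for Y. The geometry alone
therefore degrades Z (and Y) relative to X, but a large measured σ_Z/σ_Y
ratio on a real instrument additionally reflects that Z error is dominated
by manual refocusing rather than by registration noise; the package's
simulator exposes independent per-axis spreads instead of modelling the
focusing process.

**Drift.** Per-axis OLS slope of cumulative shift versus time (nm/h),
fitted on observed timestamps only, so recording gaps need no special
handling. Breakpoints (e.g. a mid-session move to a fresh sample position)
are user-declared and yield independent per-segment fits; no change-point
detection is attempted.

## Milling monitor

Per-row sums over the ROI columns, normalized per profile and per channel
(each curve's own maximum; a series-global mode is available). Per-profile
normalization erases absolute intensity loss, so the remaining-fluorescence
summary reports the pre-normalization integral. The reflection peak width
is the linearly interpolated full width at half maximum.

## Synthetic data: what it emulates, what it does not

All generators are seeded (`numpy.random.default_rng`), bit-reproducible,
and return ground-truth tables; recovery tests compare against those tables
only. Defaults encode the study conditions of the characterized instrument:
62°/10° view angles, 41/43/291 nm per-axis repositioning spreads (89 nm
along Z with astigmatic focusing), 0.7/−0.2/−0.05 µm/h drift rates, bead
stacks from −3.5 to +3.5 µm in 50 nm steps at λ = 520 nm and NA 0.85, and a
370 nm lateral / 1000 nm axial PSF. The sample-plane pixel size defaults to
65 nm/px (plausible for a 100× system) and is configurable everywhere,
never hard-coded in analysis.

- *Scan images* render a dark (0.2) to bright (0.8) step with fractional
  pixel coverage, parabolic bow (nm/line²) and sinusoidal displacement
  components sampled at line start times, plus additive Gaussian noise.
  This emulates secondary-electron contrast of a metal edge qualitatively;
  it does not model beam-sample interaction, detector shot statistics, or
  within-line displacement.
- *Bead stacks* use a separable 3D Gaussian PSF: lateral widths follow the
  defocus hyperbola w(z) = σ₀√(1 + ((z − z_off)/z_R)²) with z_R = 600 nm
  and focal offsets z_off = ±150 nm/deg · (θ − 90°) of opposite sign for X
  and Y (a small-angle linear model of crossed-cylinder astigmatism; the
  two stated acquisition angles of 92° and 93.7° are both accepted, the
  discrepancy between them is left to the caller). The axial envelope is
  Gaussian. No vectorial or Gibson–Lanni optics, aberrations, or bead-size
  convolution: a passing recovery test shows the pipeline is unbiased for
  blob-like emitters, not that a real PSF is Gaussian.
- *Reposition trials* draw each image-to-image displacement iid
  N(0, displacement_sd) per axis, so positions follow the cumulative walk.
  (A return-to-origin protocol would make consecutive differences
  anticorrelated at lag 1; the iid model keeps the sampling distribution of
  the recovered sigma exactly χ², which the recovery tests rely on.) Images
  are a fixed band-limited periodic pattern translated by the projected
  position with optional per-view localization jitter; commanded move
  limits (±100 µm XY, ±30 µm Z) are carried as metadata.
- *Drift series* are rate·t plus optional noise with gap-masked
  timestamps. *Milling series* render an erf-edged band (half-max width
  equal to the nominal width) and a compact (3σ-truncated) fluorescent
  blob clipped by the band.

## Problem sizes and tolerances in the tests

The test suite and the acceptance script run entirely on synthetic data at
sizes chosen to exercise every code path while staying lightweight: 128-line
scans for spectra, 20-bead stacks at the full 141-plane acquisition for PSF
recovery (a 31-plane configuration for unit tests), 100-trial image series
for repositioning, 1000-sample Monte Carlo batches for the noise-anisotropy
comparison. Amplitude fidelity is asserted at ≤1% for bin-centered and ≤5%
for off-bin sinusoids; FWHM recovery at the larger of 5% and two upsampled
voxels; sigma recovery inside the 99% χ² interval at ν = 98. Where a
quantity is a ratio of sample standard deviations, comparisons use means
over replicate batches, since a single n = 1000 sd ratio carries ~3.5%
sampling error.

## Known limitations

- The vibration tracker is 1D per line; simultaneous X+Y tracking and
  attribution of spectral peaks to mechanical sources are out of scope.
- The PSF module does not invert the astigmatic ellipticity-defocus curve
  into a z-lookup calibration, and does no deconvolution or multi-channel
  chromatic analysis.
- The stage module estimates 3-DOF translations only; rotations, scale
  changes and automated re-alignment are out of scope.
- Lamella thickness in nanometres is not estimated from the milling
  profiles; the monitor reports relative narrowing and fluorescence
  retention only.
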