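# triscope

Image-based metrology for coincident fluorescence / electron / ion beam
(FM/SEM/FIB) cryo-microscopes.

In fluorescence-guided cryo-FIB lamella preparation, a widefield fluorescence
microscope, an SEM (62° incidence to the sample plane) and a FIB (10°
incidence) image the same spot on a vitrified sample. Whether such an
instrument can target a ~150 nm-thick lamella onto a fluorescent structure
depends on a handful of measurable numbers: how much the sample vibrates, how
sharp the optical PSF is, how precisely the stage returns to a position, how
fast the alignment drifts, and whether milling progress can be read off the
live optical feed. `triscope` implements the image-analysis procedures that
extract these numbers, plus seeded synthetic-data generators that make every
pipeline verifiable by parameter recovery without access to an instrument.

## The four analyses

**Vibration spectroscopy from SEM raster scans.** A raster scan across a
high-contrast edge samples the sample displacement once per scan line, at
times t_k = k·t_line. Each line is matched against Heaviside step templates
at every possible column; the template maximizing |Pearson r| gives the edge
position. Slow edge bow (sample curvature) is removed with a zero-phase
3rd-order Butterworth high-pass at f_c = 5/T_f (T_f = frame time), and a
flat-top-windowed amplitude FFT — scaled so a sinusoid of peak-to-peak A nm
reads A nm in its peak bin regardless of bin alignment — gives the
displacement spectrum. Medians over many images at several dwell times
compose a spectrum over ~0.1 Hz up to the highest line-rate Nyquist
frequency, separately for 0° and 90° scan rotation (sample X and Y).

**Bead-based PSF extraction.** From a fluorescent-bead z-stack: maximum
intensity projection → blob detection with mass, border and proximity
filters → Pearson-correlation outlier rejection between candidate
subvolume projections → 2D + 1D Gaussian sub-pixel localization → 5×
upsampling, alignment to the nearest upsampled voxel, and voxel-wise
averaging. FWHM along x, y, z and the ellipticity-versus-defocus table
(w_x/w_y per plane) characterize widefield and astigmatic (crossed-cylinder,
θ ≠ 90°) imaging.

**Dual-view stage metrology.** An image shift in one view constrains the 3D
sample displacement d = (dx, dy, dz) through

    image_x = dx
    image_y = sin(α_view)·dy ± cos(α_view)·dz

with α = 62° (SEM) and 10° (FIB). Registering consecutive image pairs in
both views (sub-pixel phase cross-correlation) and solving the resulting
4-equation, 3-unknown least-squares system per pair recovers each
displacement; the per-axis spread (ddof = 1) of the N−1 records summarizes
repositioning precision, and per-axis OLS slopes of cumulative shift versus
time give drift rates in nm/h (recording gaps and declared breakpoints are
handled).

**Milling monitor.** Within the milling ROI of a two-channel
reflection/fluorescence series, intensity is integrated along X and
normalized per profile; the reflection peak FWHM tracks lamella thinning and
the pre-normalization fluorescence integral tracks how much of the target
survives.

## Worked example

Simulate a 100-trial stage-repositioning experiment at per-axis spreads of
41/43/291 nm, then recover those spreads from the images alone:

```python
import numpy as np
import triscope as t
from triscope.simulate import sim_reposition_trials
from triscope.stage import analyze_repositioning

scenario = t.RepositionScenario(n_trials=100, displacement_sd=(41.0, 43.0, 291.0))
series, truth = sim_reposition_trials(scenario, seed=7)
records, summary = analyze_repositioning(
    [s.pixels for s, _f, _t in series],
    [f.pixels for _s, f, _t in series],
    t.ViewGeometry(), pixel_size_sem=20.0, pixel_size_fib=20.0,
)
print(f"n = {summary.n} displacement records")
print(f"sigma_x = {summary.sigma_x:.1f} nm, sigma_y = {summary.sigma_y:.1f} nm, "
      f"sigma_z = {summary.sigma_z:.1f} nm")
d = np.diff(truth[["x_nm", "y_nm", "z_nm"]].to_numpy(), axis=0)
print("ground-truth spread:", np.round(d.std(axis=0, ddof=1), 1))
```

prints

```
n = 99 displacement records
sigma_x = 37.7 nm, sigma_y = 42.2 nm, sigma_z = 257.6 nm
ground-truth spread: [ 37.7  42.2 257.6]
```

The 100 image pairs yield exactly 99 consecutive displacements, and the
recovered per-axis sigmas equal the ground-truth spread of this particular
random draw to 0.1 nm — the analysis error is far below the sampling
variability of a 99-sample standard deviation. Note the recovered σ_z is
noisier and larger than σ_x, σ_y: at (62°, 10°) the inversion amplifies
image-shift noise along Z by a factor ≈1.6 relative to X
(`triscope.stage.predicted_sigma_ratio`).

The same workflows are scriptable from the shell:

```sh
triscope simulate scan --seed 3 --component 200,3.0,0.4 --pixel-size 0.1 \
    --dwell 1e-5 --out sim/
triscope vibration --images sim/scans.tif --out vib/   # spectrum.csv
```

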