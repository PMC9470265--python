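# Methods

`memprobe` implements the quantitative analyses used to characterize
environment-sensitive ("solvatochromic") membrane probes such as Pro12A,
NR12S and NR12A: generalized-polarization (GP) imaging of vesicles,
time-dependent fluorescence shift (TDFS) analysis of wavelength-resolved
TCSPC decays, and orientation/location observables from planar bilayer
trajectories. Because raw microscope, TCSPC and molecular-dynamics data are
not desk-recomputable, every pipeline is paired with a seeded synthetic
generator that emulates the statistical structure of the corresponding
measurement and carries analytic ground truth, so accuracy is demonstrated
by parameter recovery rather than by re-deriving published experimental
values.

## GP imaging

**Model.** A spectral image is a channel x row x col stack; each channel
integrates a ~9 nm emission window (default grids: 20 channels spanning
423-601 nm for Pro12A, 22 channels spanning 503-700 nm for the Nile Red
probes). The pixel-wise statistic is

    GP = (I_B - I_R) / (I_B + I_R)

with `I_B`, `I_R` the background-corrected intensities at a blue (ordered,
lambda_Lo) and red (disordered, lambda_Ld) reference wavelength. Probe
presets: 423/494 nm (Pro12A), 557/664 nm (NR12S), 583/673 nm (NR12A),
shipped as data so users can add their own. GP is undefined (NaN) where
`I_B + I_R <= 0`; undefined pixels are excluded from statistics rather than
set to 0, because 0 is a meaningful GP value.

**Detection chain.** Per image: Otsu threshold on the channel-summed
intensity (per image, 256-bin histogram; foreground is strictly above the
threshold) -> the complement of the mask provides the background region,
whose per-channel mean is subtracted with clamping at zero (an uncorrected
uniform background demonstrably pulls GP toward 0) -> DBSCAN on foreground
pixel coordinates (defaults eps = 3 px, min_samples = 8: bridges 1-px gaps
in a vesicle ring without merging neighbouring vesicles at typical GUV
scales) -> per object, the eccentricity of the ellipse sharing the pixel
set's second central moments; objects with eccentricity >= 0.5 are flagged
not-retained -> median and standard deviation of GP over each retained
object's defined pixels (all object pixels, not only a fitted rim).

**Membrane profiles.** The membrane centerline is an algebraic (Kasa)
circle fit to the object's pixels; a 3 px (radial) x 1 px (tangential)
integrating element slides along the rim in 1 degree steps. Intensities are
summed over the element per reference channel *before* the ratio is taken
(shot-noise optimal). Non-circular membranes are out of scope; the
eccentricity filter guarantees near-circular objects.

**Internalization index.** From a line profile crossing the cell twice:
mean background-corrected internal intensity divided by mean membrane-peak
intensity; 1 means equal distribution between plasma membrane and interior.

## TDFS

**Model.** After excitation the environment reorients around the probe's
excited-state dipole and the emission band red-shifts. The observables are
the total dynamic shift `Delta_nu = nu(0) - nu(inf)` (polarity readout) and
the integrated relaxation time `tau_R = integral C(t) dt` with
`C(t) = (nu(t) - nu(inf)) / Delta_nu` (fluidity readout), where `nu(t)` is
the peak position of the time-resolved emission spectrum (TRES).

**Deconvolution.** Decays (10 nm wavelength steps, each acquired until the
peak bin holds 5000 counts) are fitted by reconvolution against the
measured IRF. Two representations are provided:

* `fit_decay_reconvolution` — free multi-exponential (3 components by
  default) with a fitted sub-bin IRF shift and an explicit IRF-proportional
  scattered-light term. Amplitudes are solved linearly at each step
  (variable projection) with a mild ridge on the column-normalized basis;
  without the scatter term and the bin-width lower bound on lifetimes,
  near-degenerate components acquire huge cancelling amplitudes that fit
  the counts but corrupt the deconvolved model at t = 0. A final amplitude
  pass uses model-based Poisson weights: weighting by observed counts
  biases low-count (tail) amplitudes downward.
* `fit_decay_lifetime_grid` — projection onto a fixed grid of 16
  log-spaced lifetimes (0.03-15 ns), ridge-regularized linear amplitudes
  (+ scatter), two-pass model-based weighting. This convex, deterministic
  representation tracks the continuously evolving decays of a relaxing
  band far more faithfully than any small free multi-exponential and is
  the default engine for TRES reconstruction; the free 3-exponential fit
  remains the tool for per-decay lifetime summaries. (Individual grid
  amplitudes are not physically interpretable; only their sum — the
  deconvolved decay — is used.)

**Reconstruction.** Standard spectral reconstruction: each deconvolved
decay is rescaled so its time integral equals the steady-state intensity at
that wavelength; the per-wavelength time-integral identity therefore holds
to machine precision by construction and is asserted in the tests. Slices
are converted to wavenumber with the lambda^2 Jacobian (configurable,
default on) and resampled to a uniform wavenumber axis. Edge wavelengths
whose fitted decay integrates to a nonpositive value (pure fit noise at
negligible steady-state weight) are dropped with a warning.

**Windowing.** TRES slices are inspected only while emission remains: the
usable window ends where the steady-state-weighted total decay falls to 1%
of its peak. Beyond that the "slices" are extrapolated fit tails; including
them demonstrably corrupts the plateau. The slice time grid is dense early
(20 ps) and 0.1 ns late.

**Peak extraction.** Each slice is fitted with an asymmetric log-normal
band restricted to the band core (>= 10% of the slice maximum; far tails
inherit the largest deconvolution artefacts). A slice peaking at the grid
edge falls back to the argmax and is flagged. FWHM(t) is reported from the
same fits and not thresholded.

**nu(inf), completeness, tau_R.** An exponential is regressed on the
well-measured part of C (0.05 < C < 0.7). Relaxation counts as observed
("complete") only if the predicted unrelaxed shift at the window end is
below the method resolution (50 cm^-1) *and* the window spans at least five
apparent relaxation times. When complete, nu(inf) is the asymptote: the
mean of nu(t) over the tail after subtracting the regression-predicted
remaining relaxation (an unbiased, lower-noise refinement of a plain
last-10% plateau mean). C(t) is integrated by trapezoid out to the point
where the fitted C reaches 0.005 and closed with the analytic exponential
tail from the same regression — fitting the tail to the noisy last decade
of C itself proved far less robust. When relaxation is incomplete, nu(inf)
falls back to the last available nu(t) values, tau_R is integrated over the
full window only, and the result is flagged: tau_R is then a lower bound
(the emission dies before the environment finishes reorienting), so slow
relaxation is systematically underestimated — the expected direction of
bias.

**Time zero.** Emission relaxing faster than the instrument response never
reaches the detector, so nu(0) is preferably supplied externally: either
directly (low-temperature glass arithmetic: emission maximum corrected by a
user-supplied excitation-maximum offset) or via the Lippert-Mataga route —
a least-squares line of the solvent Stokes shift against the polarity
function `Delta_f = (eps-1)/(2eps+1) - (n^2-1)/(2n^2+1)`, whose intercept
gives the polarity-free Stokes shift, subtracted from the system's
absorption maximum. Without an external estimate the pipeline extrapolates
the fitted C(t) to t = 0, which recovers only the instrumentally resolved
part of the shift.

**Recovery study.** The generator builds decays from
`nu(t) = nu_inf + Delta_nu * exp(-t/tau_rel)` with a log-normal
instantaneous band (default FWHM 2500 cm^-1, skew 0.2, time-constant),
fluorescence lifetime 4 ns, Gaussian IRF (sigma 50 ps), 25 ps channels over
a 50 ns window, every decay Poisson-sampled at 5000 peak counts, and the
wavelength series spanning the time-zero through relaxed bands in 10 nm
steps — the acquisition conditions of the emulated experiment. The
acceptance suite plants a 3 x 3 grid (Delta_nu in {500, 1500, 3000} cm^-1 x
tau_rel in {0.2, 1, 3} ns) and requires mean recovery, over six replicate
acquisitions per condition, within the method's intrinsic uncertainties of
50 cm^-1 and 0.05 ns. Replicate averaging reflects how such uncertainties
are quoted; single-acquisition scatter of tau_R grows toward small
Delta_nu and slow tau_rel (about 0.09 ns at Delta_nu = 500 cm^-1,
tau_rel = 3 ns — the band shifts by only a fifth of its width there, and
the relaxation integral spans four lifetimes of accumulated slice noise).
A separate condition with tau_rel = 20 ns (five times the lifetime)
verifies the documented underestimation direction.

## Bilayer observables

The membrane normal is the box z axis (the simulated systems are planar).
Atom roles come from a JSON role map, not force-field names: probe long
axes are defined by `probe_axis_head`/`probe_axis_tail` pairs (paired in
atom-index order), and the bilayer midplane is the mean z of
`chain_terminal` atoms per frame. Tilt is the angle between the head->tail
axis and the inward leaflet normal (leaflet assigned per frame from the
head atom's side of the midplane), folded to [0, 90] degrees by default
(theta -> min(theta, 180 - theta)); the unfolded convention is available
since the sign convention of reported tilts is ambiguous. Distributions are
normalized histograms (default 2.5 degree bins); modes are local maxima
after a 3-bin moving average, ignoring maxima below 5% of the global one.
Partial density profiles histogram selected atoms' midplane-recentered z
per frame (default 0.1 nm bins), averaged over frames, as number density
per nm^3 (mass-weighting optional); the profile integrates exactly to the
selected atom count per frame. Profiles are not symmetrized across leaflets.
A composition helper reports the probe mole percent of a simulated bilayer,
`100 * n_probes / (n_lipids + n_probes)`.

The trajectory generator samples polar tilt angles from a (mixture of)
wrapped normal(s) — or isotropically for calibration, reproducing the
sin(theta) folded density — azimuth uniform, probes anchored in the upper
leaflet, and role depths from Gaussians mirrored across the midplane;
coordinates travel as multi-frame XYZ (or single-frame GRO) plus a JSON
sidecar for roles and box.

## What the synthetic data does and does not capture

The generators reproduce the estimation-relevant statistics: Poisson shot
noise at realistic count levels, ring geometry with genuinely elliptical
decoys, per-phase emission spectra sampled at the real channel grids, IRF
convolution and peak-normalized acquisition, wavelength-step discretization,
and prescribed orientation/depth distributions. They do not model optics
beyond Gaussian blur (no PSF sidelobes, no depth-dependent aberration),
detector afterpulsing or dead time, dye photobleaching, spectral bleed
between channels, membrane undulations or non-circular vesicles, or
lipid-force-field realism. Passing recovery tests therefore demonstrates
the correctness and calibration of the *analysis* under the stated noise
models, not robustness to every instrumental artefact of real data.

## Numerical choices and degenerate inputs

* Channel lookup: nearest center, ties toward the bluer channel; queries
  further than one spacing outside the grid are rejected.
* Background subtraction clamps negatives at zero, keeping GP in [-1, 1].
* Constant images are rejected by Otsu (degenerate histogram); an empty
  mask yields an empty object list, not an error.
* Collinear pixel sets return eccentricity 1.0 with a warning.
* Reconvolution fits are deterministic: lifetimes initialized log-spaced
  over 0.05-10 ns, equal amplitudes, no stochastic restarts; lifetime
  bounds [bin width, 50 ns].
* Problem sizes in tests and analyses (256 px scenes, 2000-bin decays,
  ~20 wavelengths, hundreds of trajectory frames) mirror single-sample
  experiment scale.
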