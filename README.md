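# memprobe

Quantitative analysis of environment-sensitive membrane probes (Pro12A,
NR12S, NR12A and kin): spectral-imaging generalized polarization (GP) of
vesicles, time-dependent fluorescence shift (TDFS) of wavelength-resolved
TCSPC decays, and bilayer-trajectory observables — with seeded synthetic
generators replacing microscope, TCSPC and MD raw data so every analysis is
validated by parameter recovery against known ground truth.

Solvatochromic probes shift their emission with the polarity and dynamics
of their surroundings, which makes them reporters of membrane order. Three
quantities anchor the package:

* **GP** — the two-channel emission contrast
  `GP = (I_B − I_R)/(I_B + I_R) ∈ [−1, +1]`, computed pixel-wise at a blue
  (liquid-ordered) and red (liquid-disordered) reference wavelength; higher
  GP means a more ordered, less polar environment.
* **Δν and τ_R** — from TRES reconstruction of TCSPC decays: the total
  dynamic Stokes shift `Δν = ν(0) − ν(∞)` (hydration/polarity) and the
  integrated relaxation time `τ_R = ∫ C(t) dt`,
  `C(t) = (ν(t) − ν(∞))/Δν` (fluidity/mobility).
* **Tilt and depth** — the angle between a probe's fluorophore long axis
  and the membrane normal, and partial density profiles along the bilayer
  normal, from labelled planar-bilayer trajectories.

The science and the numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Layout

* `src/memprobe/` — the library: `image_model` (spectral stacks, ROIs,
  spectra), `gp_pipeline` (GP maps, Otsu + DBSCAN vesicle detection,
  eccentricity filter, membrane profiles, internalization index), `tdfs`
  (reconvolution fitting, TRES, Lippert–Mataga time zero, Δν, τ_R),
  `trajectory` (tilt and density observables, GRO/XYZ I/O), `synthetic`
  (seeded generators with ground truth), `pipeline`/`cli` (end-to-end
  runners with manifests; `memprobe` console script).
* `analysis/` — numbered drivers reproducing the package's workflow on
  synthetic data; tables land in `results/`.
* `tests/` — unit, property and acceptance suites.

## Worked example

```sh
python analysis/01_simulate_datasets.py
python analysis/02_gp_vesicle_analysis.py
python analysis/03_tdfs_analysis.py
python analysis/04_bilayer_observables.py
```

The first script renders a 22-channel vesicle scene (three circular
vesicles — one phase-separated — plus a 2:1 elliptical decoy, Poisson shot
noise at peak S/N 30), a 20-wavelength TCSPC decay set (5000 peak counts
per decay, Gaussian IRF) from the relaxation model
`ν(t) = 16500 + 1500·e^(−t/1 ns) cm⁻¹`, and a 300-frame bilayer trajectory
with a bimodal planted tilt distribution. The analyses then print:

```
detected 5 objects, retained 3 (eccentricity < 0.5); planted true vesicles: 3
uniform-phase GP recovery (analytic vs median):
   center  analytic_gp  recovered_gp_median   gp_sd   error
 [60, 60]      +0.2703              +0.2717 +0.0332 +0.0013
[60, 190]      -0.6303              -0.6318 +0.0635 -0.0015
phase-separated vesicle: planted phase GPs +0.270/-0.630 (delta GP 0.901); ...
```

— the elliptical decoy is rejected by the 0.5 eccentricity cutoff and the
recovered per-vesicle GP medians sit within ±0.002 of the analytic values
(the generator computes each phase's GP from its emission spectrum at the
NR12S reference channels, 557/664 nm);

```
    quantity   planted  recovered  error
delta_nu_cm1  1500.000   1504.845  4.845
    tau_r_ns     1.000      0.992 -0.008
```

— the TDFS chain recovers the planted dynamic Stokes shift within
5 cm⁻¹ and the relaxation time within 0.01 ns, well inside the method's
intrinsic uncertainties (50 cm⁻¹, 0.05 ns);

```
tilt: mean 41.6 deg, modes at [23.8 86.2] deg (planted modes [23.0, 87.0] deg)
density[cholesterol_oh]: upper-leaflet peak at z = +1.45 nm (planted +1.40 nm)
```

— both tilt modes and the planted cholesterol-OH depth are recovered within
one histogram bin.

The same pipelines run from the shell on your own data, e.g.

```sh
memprobe vesicles scene.tiff --probe nr12s --out out/
memprobe tdfs --decays decays.csv --irf irf.csv --steady-state ss.csv --nu0 18000
memprobe tilt trajectory.xyz --bin 2.5
```

(spectral stacks travel as multi-page TIFF with a JSON sidecar of channel
centers; decays as long-format CSV `wavelength_nm,time_ns,counts`;
trajectories as XYZ with a JSON role map.)

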