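"""Seeded synthetic-data generators with attached ground truth.

Every input the analysis pipelines consume can be generated here at desk
scale, emulating the statistical structure of the corresponding
experiment:

* spectral microscope stacks of phase-separated vesicle rings (per-phase
  Gaussian emission spectra, background, shot noise, elliptical decoys),
* wavelength-resolved TCSPC decay sets produced by a continuous
  spectral-relaxation model convolved with a Gaussian IRF and Poisson
  counting noise, acquired to a fixed peak count per decay,
* bilayer trajectories with prescribed probe tilt distributions and atom
  depth distributions, and
* membrane line profiles for the internalization index.

All generators are deterministic given their seed; ground truth (analytic
GP per phase, planted Delta_nu / tau_R, planted tilt modes and depths) is
returned alongside the data so recovery can be tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_model import EmissionSpectrum, SpectralImage
from .tdfs import DecaySet, lognormal_lineshape, nm_to_wavenumber
from .trajectory import Trajectory

__all__ = [
    "GaussianSpectrum",
    "VesicleSpec",
    "VesicleSceneSpec",
    "DecaySimSpec",
    "TrajectorySimSpec",
    "make_vesicle_image",
    "make_decay_set",
    "make_trajectory",
    "make_internalization_profile",
    "nr_channel_grid",
    "pro12a_channel_grid",
]


def nr_channel_grid() -> np.ndarray:
    """22 detection channels spanning 503-700 nm (Nile Red probes)."""
    return np.linspace(503.0, 700.0, 22)


def pro12a_channel_grid() -> np.ndarray:
    """20 detection channels spanning 423-601 nm (Pro12A)."""
    return np.linspace(423.0, 601.0, 20)


@dataclass
class GaussianSpectrum:
    """Gaussian emission band: peak (nm), 1/e half-width sigma (nm), amplitude."""

    peak_nm: float
    sigma_nm: float
    amplitude: float

    def at(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((wl - self.peak_nm) / self.sigma_nm) ** 2)

    def analytic_gp(self, channel_centers: np.ndarray, lambda_lo: float, lambda_ld: float) -> float:
        """GP this spectrum produces at the nearest reference channels."""
        centers = np.asarray(channel_centers, dtype=float)
        i_b = self.at(centers[np.argmin(np.abs(centers - lambda_lo))])
        i_r = self.at(centers[np.argmin(np.abs(centers - lambda_ld))])
        return float((i_b - i_r) / (i_b + i_r))


@dataclass
class VesicleSpec:
    """One planted vesicle ring; axis_ratio > 1 makes an elliptical decoy."""

    center: tuple[float, float]  # (row, col), px
    radius: float  # px (semi-major axis for ellipses)
    ring_thickness: float = 3.0  # px
    axis_ratio: float = 1.0  # major/minor; 1 = circle
    angle_deg: float = 0.0  # major-axis orientation
    # phase layout: list of (start_angle_deg, end_angle_deg, spectrum);
    # a single entry covering 0-360 is a uniform vesicle
    phases: list[tuple[float, float, GaussianSpectrum]] = field(default_factory=list)

    @property
    def planted_eccentricity(self) -> float:
        return math.sqrt(1.0 - 1.0 / self.axis_ratio**2)


@dataclass
class VesicleSceneSpec:
    image_size: tuple[int, int] = (256, 256)
    vesicles: list[VesicleSpec] = field(default_factory=list)
    channel_centers: np.ndarray = field(default_factory=nr_channel_grid)
    background: float = 20.0
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_sigma: float = 5.0
    blur_sigma: float = 0.0
    seed: int = 0
    lambda_lo: float = 557.0
    lambda_ld: float = 664.0


def _validate_no_overlap(spec: VesicleSceneSpec) -> None:
    vs = spec.vesicles
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            d = math.hypot(
                vs[i].center[0] - vs[j].center[0], vs[i].center[1] - vs[j].center[1]
            )
            reach_i = vs[i].radius + vs[i].ring_thickness
            reach_j = vs[j].radius + vs[j].ring_thickness
            if d < reach_i + reach_j:
                raise ValueError(f"vesicles {i} and {j} overlap")


def make_vesicle_image(spec: VesicleSceneSpec) -> tuple[SpectralImage, dict]:
    """Render a spectral stack of vesicle rings and return ground truth.

    Each ring pixel's per-channel expected intensity follows its phase's
    emission spectrum sampled at the channel centers, on top of a uniform
    background; noise is Poisson shot noise (or additive Gaussian).
    Ground truth carries the pixel label map, each vesicle's planted
    eccentricity, and the analytic GP of every phase at the configured
    reference channels.
    """
    _validate_no_overlap(spec)
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.image_size
    centers = np.asarray(spec.channel_centers, dtype=float)
    nchan = len(centers)
    expected = np.full((nchan, nrow, ncol), float(spec.background))
    label_map = np.full((nrow, ncol), -1, dtype=int)
    phase_map = np.full((nrow, ncol), -1, dtype=int)

    rows, cols = np.mgrid[0:nrow, 0:ncol]
    truth_vesicles = []
    for vi, v in enumerate(spec.vesicles):
        if not v.phases:
            raise ValueError(f"vesicle {vi} has no phase spectra")
        th = math.radians(v.angle_deg)
        dy = rows - v.center[0]
        dx = cols - v.center[1]
        # coordinates in the ellipse frame; minor axis = radius / axis_ratio
        u = dx * math.cos(th) + dy * math.sin(th)
        w = -dx * math.sin(th) + dy * math.cos(th)
        b = v.radius / v.axis_ratio
        r_eff = np.sqrt((u / v.radius) ** 2 + (w / b) ** 2) * v.radius
        ring = np.abs(r_eff - v.radius) <= v.ring_thickness / 2
        if not ring.any():
            raise ValueError(f"vesicle {vi} renders no pixels")
        ang = (np.degrees(np.arctan2(dy, dx)) + 360.0) % 360.0
        phase_gps = []
        for pi, (a0, a1, spectrum) in enumerate(v.phases):
            a0m, a1m = a0 % 360.0, a1 % 360.0
            if math.isclose((a1 - a0) % 360.0, 0.0) or (a1 - a0) >= 360.0:
                in_arc = np.ones_like(ang, dtype=bool)
            elif a0m <= a1m:
                in_arc = (ang >= a0m) & (ang < a1m)
            else:
                in_arc = (ang >= a0m) | (ang < a1m)
            sel = ring & in_arc
            expected[:, sel] += spectrum.at(centers)[:, None]
            phase_map[sel] = pi
            phase_gps.append(
                spectrum.analytic_gp(centers, spec.lambda_lo, spec.lambda_ld)
            )
        label_map[ring] = vi
        truth_vesicles.append(
            {
                "center": v.center,
                "radius": v.radius,
                "planted_eccentricity": v.planted_eccentricity,
                "is_decoy": v.planted_eccentricity >= 0.5,
                "phase_gp": phase_gps,
            }
        )

    if spec.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for c in range(nchan):
            expected[c] = gaussian_filter(expected[c], spec.blur_sigma)

    if spec.noise == "poisson":
        data = rng.poisson(expected).astype(float)
    elif spec.noise == "gaussian":
        data = expected + rng.normal(0.0, spec.gaussian_sigma, expected.shape)
        data = np.clip(data, 0.0, None)
    elif spec.noise == "none":
        data = expected
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")

    truth = {
        "label_map": label_map,
        "phase_map": phase_map,
        "vesicles": truth_vesicles,
        "n_true_vesicles": sum(1 for t in truth_vesicles if not t["is_decoy"]),
        "lambda_lo": spec.lambda_lo,
        "lambda_ld": spec.lambda_ld,
    }
    return SpectralImage(data, centers), truth


@dataclass
class DecaySimSpec:
    """Continuous spectral-relaxation model for TCSPC simulation.

    The instantaneous spectrum is a log-normal band whose peak follows
    nu(t) = nu_inf + delta_nu * C(t) with
    C(t) = sum_j w_j exp(-t / tau_rel_j); the total emission decays with
    the fluorescence lifetime(s). Decays are recorded on a uniform time
    axis, convolved with a Gaussian IRF, each scaled to the acquisition
    peak-count target, and Poisson sampled.
    """

    nu_inf: float = 16500.0  # cm^-1
    delta_nu: float = 1500.0  # cm^-1
    tau_rel: tuple[float, ...] = (1.0,)  # ns
    rel_weights: tuple[float, ...] = (1.0,)
    lifetimes: tuple[float, ...] = (4.0,)  # ns
    lifetime_weights: tuple[float, ...] = (1.0,)
    fwhm: float = 2500.0  # cm^-1, time-constant by default
    asymmetry: float = 0.2
    irf_center: float = 2.0  # ns
    irf_sigma: float = 0.05  # ns
    window: float = 50.0  # ns
    dt: float = 0.025  # ns (typical TCSPC channel width)
    peak_counts: int = 5000
    irf_peak_counts: int = 10000
    # None: span the emission from above the time-zero band to below the
    # relaxed band (how an experimenter picks the series, knowing nu(0)
    # from the time-zero estimate)
    wavelength_range: tuple[float, float] | None = None
    wavelength_step: float = 10.0
    min_ss_fraction: float = 1e-3  # drop decays in the spectrum's far tails
    poisson_noise: bool = True  # disable for noiseless round-trip checks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_nu < 0:
            raise ValueError("delta_nu must be >= 0")
        if any(t <= 0 for t in self.tau_rel):
            raise ValueError("relaxation times must be positive")
        if self.window < 10 * max(self.lifetimes):
            raise ValueError("time window must cover >= 10x the longest lifetime")
        if not math.isclose(sum(self.rel_weights), 1.0):
            raise ValueError("relaxation weights must sum to 1")
        if self.wavelength_range is None:
            nu_hi = self.nu_inf + self.delta_nu + 0.8 * self.fwhm
            nu_lo = self.nu_inf - 0.8 * self.fwhm
            lo = math.floor(1e7 / nu_hi / self.wavelength_step) * self.wavelength_step
            hi = math.ceil(1e7 / nu_lo / self.wavelength_step) * self.wavelength_step
            self.wavelength_range = (lo, hi)

    def correlation(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(
            w * np.exp(-t / tau) for w, tau in zip(self.rel_weights, self.tau_rel)
        )

    def nu_of_t(self, t: np.ndarray) -> np.ndarray:
        return self.nu_inf + self.delta_nu * self.correlation(t)

    def population(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(
            w * np.exp(-t / tau)
            for w, tau in zip(self.lifetime_weights, self.lifetimes)
        )

    @property
    def analytic_tau_r(self) -> float:
        """Integral of C(t): sum of w_j * tau_rel_j."""
        return float(sum(w * tau for w, tau in zip(self.rel_weights, self.tau_rel)))


def make_decay_set(spec: DecaySimSpec) -> tuple[DecaySet, EmissionSpectrum, dict]:
    """Simulate a wavelength-resolved TCSPC acquisition from the relaxation model.

    Returns the decay set (counts), the steady-state emission spectrum
    (the exact time integral of the noiseless emission, on a 1 nm grid),
    and the ground truth (nu(0), nu(inf), Delta_nu, analytic tau_R).
    """
    rng = np.random.default_rng(spec.seed)
    time_axis = np.arange(0.0, spec.window + spec.dt / 2, spec.dt)
    t_model = time_axis  # emission model from t = 0 on the same grid

    # emission rate per wavelength: population decay x moving log-normal band,
    # expressed per unit wavelength (1/lambda^2 Jacobian from the
    # wavenumber-domain lineshape)
    wl_grid = np.arange(spec.wavelength_range[0], spec.wavelength_range[1] + 0.5, 1.0)
    nu_grid = nm_to_wavenumber(wl_grid)
    pop = spec.population(t_model)
    nu_t = spec.nu_of_t(t_model)
    rate = np.empty((len(t_model), len(wl_grid)))
    for i, (p, nu_peak) in enumerate(zip(pop, nu_t)):
        band = lognormal_lineshape(nu_grid, nu_peak, 1.0, spec.fwhm, spec.asymmetry)
        rate[i] = p * band / wl_grid**2

    steady = np.trapezoid(rate, t_model, axis=0)
    steady_state = EmissionSpectrum(wl_grid, steady)

    # Gaussian IRF on the acquisition axis, Poisson sampled
    irf_shape = np.exp(-0.5 * ((time_axis - spec.irf_center) / spec.irf_sigma) ** 2)
    irf_expected = irf_shape / irf_shape.max() * spec.irf_peak_counts
    if spec.poisson_noise:
        irf = rng.poisson(irf_expected).astype(float)
    else:
        irf = np.round(irf_expected)

    wavelengths = np.arange(
        spec.wavelength_range[0], spec.wavelength_range[1] + 1e-9, spec.wavelength_step
    )
    ss_at = np.interp(wavelengths, wl_grid, steady)
    keep = ss_at >= spec.min_ss_fraction * steady.max()

    decays: dict[float, np.ndarray] = {}
    for wl, ok in zip(wavelengths, keep):
        if not ok:
            continue
        j = int(np.argmin(np.abs(wl_grid - wl)))
        emission = rate[:, j]
        measured = np.convolve(irf_expected, emission)[: len(time_axis)]
        if measured.max() <= 0:
            continue
        expected_counts = measured / measured.max() * spec.peak_counts
        if spec.poisson_noise:
            decays[float(wl)] = rng.poisson(expected_counts).astype(float)
        else:
            decays[float(wl)] = np.round(expected_counts)

    ds = DecaySet(time_axis=time_axis, irf=irf, decays=decays)
    truth = {
        "nu0": spec.nu_inf + spec.delta_nu,
        "nu_inf": spec.nu_inf,
        "delta_nu": spec.delta_nu,
        "tau_r": spec.analytic_tau_r,
        "tau_rel": spec.tau_rel,
        "lifetimes": spec.lifetimes,
    }
    return ds, steady_state, truth


@dataclass
class TrajectorySimSpec:
    """Planted bilayer-observable distributions.

    ``tilt_modes`` is a mixture of wrapped-normal components
    (mean_deg, sigma_deg, weight); sigma 0 plants a delta. Set
    ``uniform_sphere`` to sample axis orientations isotropically instead.
    ``depth_roles`` maps a role name to (mean_z_nm, sigma_nm, n_atoms);
    atoms are mirrored across the midplane when mean_z != 0 to populate
    both leaflets.
    """

    n_frames: int = 100
    n_probes: int = 8
    tilt_modes: tuple[tuple[float, float, float], ...] = ((38.5, 8.0, 1.0),)
    uniform_sphere: bool = False
    axis_length: float = 1.0  # nm
    probe_head_depth: float = 1.0  # nm above midplane (upper leaflet)
    depth_roles: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    n_midplane_atoms: int = 32
    box: tuple[float, float, float] = (6.0, 6.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        wsum = sum(w for _, _, w in self.tilt_modes)
        if not math.isclose(wsum, 1.0):
            raise ValueError("tilt mode weights must sum to 1")
        for role, (mu, sigma, n) in self.depth_roles.items():
            if abs(mu) + 3 * sigma > self.box[2] / 2:
                raise ValueError(f"depth distribution for {role!r} exceeds the box")


def make_trajectory(spec: TrajectorySimSpec) -> tuple[Trajectory, dict]:
    """Sample a planar-bilayer trajectory with planted tilt and depth truth.

    All probes sit in the upper leaflet (head above the midplane); the
    head -> tail axis points inward with the sampled polar angle to the
    inward normal and uniform azimuth. Terminal-chain atoms scatter
    tightly around z = 0 and define the midplane for the analysis.
    """
    rng = np.random.default_rng(spec.seed)
    nf, npb = spec.n_frames, spec.n_probes

    if spec.uniform_sphere:
        cos_t = rng.uniform(-1.0, 1.0, size=(nf, npb))
        theta = np.degrees(np.arccos(cos_t))  # in [0, 180] vs inward normal
    else:
        means = np.array([m for m, _, _ in spec.tilt_modes])
        sigmas = np.array([s for _, s, _ in spec.tilt_modes])
        weights = np.array([w for _, _, w in spec.tilt_modes])
        comp = rng.choice(len(means), size=(nf, npb), p=weights)
        theta = means[comp] + rng.normal(0.0, 1.0, size=(nf, npb)) * sigmas[comp]
        # fold into [0, 90]: reflect at both boundaries
        theta = np.abs(theta)
        theta = np.where(theta > 90.0, 180.0 - theta, theta)

    phi = rng.uniform(0.0, 2 * math.pi, size=(nf, npb))
    th = np.radians(theta)
    # inward normal in the upper leaflet is -z
    axis = np.stack(
        [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), -np.cos(th)], axis=-1
    )

    coords = []
    roles: dict[int, str] = {}
    idx = 0
    head_idx, tail_idx = [], []
    for _ in range(npb):
        roles[idx] = "probe_axis_head"
        head_idx.append(idx)
        idx += 1
        roles[idx] = "probe_axis_tail"
        tail_idx.append(idx)
        idx += 1
    mid_idx = list(range(idx, idx + spec.n_midplane_atoms))
    for i in mid_idx:
        roles[i] = "chain_terminal"
    idx += spec.n_midplane_atoms
    depth_idx: dict[str, list[int]] = {}
    for role, (_, _, n) in spec.depth_roles.items():
        depth_idx[role] = list(range(idx, idx + n))
        for i in depth_idx[role]:
            roles[i] = role
        idx += n

    n_atoms = idx
    box = np.asarray(spec.box, dtype=float)
    frames = np.zeros((nf, n_atoms, 3))
    for f in range(nf):
        xy = rng.uniform(0.0, box[0], size=(npb, 2))
        heads = np.column_stack([xy, np.full(npb, spec.probe_head_depth)])
        tails = heads + spec.axis_length * axis[f]
        frames[f, head_idx] = heads
        frames[f, tail_idx] = tails
        frames[f, mid_idx, :2] = rng.uniform(0.0, box[0], size=(len(mid_idx), 2))
        frames[f, mid_idx, 2] = rng.normal(0.0, 0.15, size=len(mid_idx))
        for role, (mu, sigma, n) in spec.depth_roles.items():
            ids = depth_idx[role]
            frames[f, ids, :2] = rng.uniform(0.0, box[0], size=(n, 2))
            # mirror half the atoms into the lower leaflet
            signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0) if mu != 0 else 1.0
            frames[f, ids, 2] = signs * rng.normal(mu, sigma, size=n)

    traj = Trajectory(coordinates=frames, roles=roles, box=box)
    truth = {
        "tilt_modes": [m for m, _, _ in spec.tilt_modes] if not spec.uniform_sphere else None,
        "mean_tilt": (
            None
            if spec.uniform_sphere
            else float(sum(w * m for m, _, w in spec.tilt_modes))
        ),
        "uniform_sphere": spec.uniform_sphere,
        "depth_means": {r: mu for r, (mu, _, _) in spec.depth_roles.items()},
        "planted_angles": theta,
    }
    return traj, truth


def make_internalization_profile(
    fraction: float,
    noise_sigma: float = 0.0,
    n: int = 200,
    peak_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Line profile across a cell: two unit membrane peaks, interior plateau.

    Returns (profile, membrane_peak_indices, internal_region_indices,
    truth); the planted truth is the internal/membrane intensity ratio
    ``fraction``.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    p1, p2 = n // 4, 3 * n // 4
    profile = np.exp(-0.5 * ((x - p1) / peak_sigma) ** 2) + np.exp(
        -0.5 * ((x - p2) / peak_sigma) ** 2
    )
    interior = (x > p1 + 6 * peak_sigma) & (x < p2 - 6 * peak_sigma)
    profile[interior] += fraction
    if noise_sigma > 0:
        profile = profile + rng.normal(0.0, noise_sigma, n)
    membrane_peaks = np.array([p1, p2])
    internal_region = np.flatnonzero(interior)
    truth = {"fraction": fraction}
    return profile, membrane_peaks, internal_region, truth
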