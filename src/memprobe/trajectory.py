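"""Bilayer trajectory observables for membrane probes.

Post-processing of (desk-scale) planar lipid-bilayer trajectories:

* tilt-angle distributions of a probe's fluorophore long axis relative to
  the membrane normal (0 deg = along the normal pointing into the
  membrane, 90 deg = lying in the membrane plane), and
* partial density profiles of selected atoms along the bilayer normal,
  recentered on the bilayer midplane, which localize a probe's depth.

The membrane normal is the box z axis (planar bilayer assumption). Atom
roles (probe axis endpoints, lipid reference atoms, terminal chain atoms
defining the midplane) come from a role map rather than from force-field
atom names, so any labelling convention can be used. Lengths are in nm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TiltDistribution",
    "DensityProfile",
    "tilt_angles",
    "tilt_distribution",
    "partial_density_profile",
    "mean_tilt_shift",
    "probe_mole_percent",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_frame_gro",
    "read_frame_gro",
]

MIDPLANE_ROLE = "chain_terminal"


@dataclass
class Trajectory:
    """Frames of labelled coordinates in a periodic box.

    ``coordinates`` is (n_frames, n_atoms, 3) in nm; ``box`` is
    (n_frames, 3) in nm; ``roles`` maps atom index to a role string.
    Probe copies are the i-th ``probe_axis_head`` paired with the i-th
    ``probe_axis_tail`` in atom-index order.
    """

    coordinates: np.ndarray
    roles: dict[int, str]
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        self.box = np.atleast_2d(np.asarray(self.box, dtype=float))
        if self.box.shape[0] == 1:
            self.box = np.repeat(self.box, self.n_frames, axis=0)
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must be (n_frames, 3) or (3,)")
        heads = self.atoms_with_role("probe_axis_head")
        tails = self.atoms_with_role("probe_axis_tail")
        if len(heads) != len(tails):
            raise ValueError("each probe copy needs exactly one head and one tail atom")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_probes(self) -> int:
        return len(self.atoms_with_role("probe_axis_head"))

    def atoms_with_role(self, role: str) -> list[int]:
        return sorted(i for i, r in self.roles.items() if r == role)

    def midplane(self) -> np.ndarray:
        """Per-frame bilayer midplane: mean z of the terminal-chain atoms."""
        ref = self.atoms_with_role(MIDPLANE_ROLE)
        if not ref:
            raise ValueError(f"no {MIDPLANE_ROLE!r} atoms to define the midplane")
        return self.coordinates[:, ref, 2].mean(axis=1)


@dataclass
class TiltDistribution:
    """Normalized tilt-angle histogram with mean and detected modes."""

    bin_edges: np.ndarray  # degrees
    frequencies: np.ndarray  # sum to 1
    mean: float  # degrees
    modes: np.ndarray  # degrees (bin centers of local maxima)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not math.isclose(self.frequencies.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("frequencies must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle_deg": self.bin_centers, "freq": self.frequencies})


@dataclass
class DensityProfile:
    """Number (or mass) density along the bilayer normal, midplane at z = 0."""

    z_centers: np.ndarray  # nm
    density: np.ndarray  # per nm^3 (times amu if mass-weighted)
    bin_width: float
    mean_area: float  # nm^2, mean in-plane box area

    def integral(self) -> float:
        """Total content: integral of density over the box volume
        (= selected atoms per frame for number densities)."""
        return float(self.density.sum() * self.bin_width * self.mean_area)

    @property
    def peak_z(self) -> float:
        return float(self.z_centers[int(np.argmax(self.density))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.z_centers, "density": self.density})


def tilt_angles(traj: Trajectory, probe_copy: int, fold: bool = True) -> np.ndarray:
    """Per-frame tilt of one probe copy's long axis vs the membrane normal.

    The axis runs head -> tail; the reference is the inward-pointing
    leaflet normal (-z for a probe anchored in the upper leaflet, +z for
    the lower), assigned per frame from the head atom's z relative to the
    midplane. Folding maps theta -> min(theta, 180 - theta) so angles lie
    in [0, 90].
    """
    heads = traj.atoms_with_role("probe_axis_head")
    tails = traj.atoms_with_role("probe_axis_tail")
    if not 0 <= probe_copy < len(heads):
        raise IndexError(f"probe copy {probe_copy} of {len(heads)}")
    h, t = heads[probe_copy], tails[probe_copy]
    axis = traj.coordinates[:, t, :] - traj.coordinates[:, h, :]
    norms = np.linalg.norm(axis, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length probe axis vector")
    mid = traj.midplane()
    upper = traj.coordinates[:, h, 2] >= mid
    normal_z = np.where(upper, -1.0, 1.0)  # inward-pointing
    cos_t = np.clip(axis[:, 2] * normal_z / norms, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    if fold:
        theta = np.minimum(theta, 180.0 - theta)
    return theta


def tilt_distribution(
    angles: np.ndarray,
    bin_width: float = 2.5,
    angle_max: float = 90.0,
    smooth_window: int = 3,
    min_mode_fraction: float = 0.05,
) -> TiltDistribution:
    """Normalized tilt histogram with mean and smoothed local maxima.

    Modes are local maxima of the histogram after a light moving-average
    smoothing (``smooth_window`` bins); maxima below ``min_mode_fraction``
    of the global maximum are ignored. Edge bins count as modes when they
    dominate their interior neighbour.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    edges = np.arange(0.0, angle_max + bin_width / 2, bin_width)
    if edges[-1] < angle_max:
        edges = np.append(edges, angle_max)
    counts, edges = np.histogram(angles, bins=edges)
    freqs = counts / counts.sum()

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(freqs, kernel, mode="same")
    else:
        smoothed = freqs
    padded = np.concatenate([[-np.inf], smoothed, [-np.inf]])
    is_max = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] > padded[2:])
    is_max &= smoothed >= min_mode_fraction * smoothed.max()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TiltDistribution(
        bin_edges=edges,
        frequencies=freqs,
        mean=float(np.mean(angles)),
        modes=centers[is_max],
    )


def partial_density_profile(
    traj: Trajectory,
    selection: str | list[str],
    bin_width: float = 0.1,
    masses: dict[str, float] | None = None,
) -> DensityProfile:
    """Density of selected atoms along z, averaged over frames.

    Atom z coordinates are recentered so the bilayer midplane (mean z of
    the terminal-chain reference atoms) sits at 0; bins span the full box
    z extent. Pass ``masses`` (role -> amu) for a mass density; otherwise
    a number density per nm^3 is returned.
    """
    roles = [selection] if isinstance(selection, str) else list(selection)
    atoms = sorted(i for i, r in traj.roles.items() if r in roles)
    if not atoms:
        raise ValueError(f"empty selection: no atoms with roles {roles}")
    weights = np.array(
        [masses.get(traj.roles[i], 1.0) if masses else 1.0 for i in atoms]
    )
    mid = traj.midplane()
    half = traj.box[:, 2].max() / 2
    edges = np.arange(-half, half + bin_width / 2, bin_width)
    acc = np.zeros(len(edges) - 1)
    areas = traj.box[:, 0] * traj.box[:, 1]
    for f in range(traj.n_frames):
        z = traj.coordinates[f, atoms, 2] - mid[f]
        hist, _ = np.histogram(z, bins=edges, weights=weights)
        acc += hist / (areas[f] * bin_width)
    density = acc / traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, bin_width, float(areas.mean()))


def mean_tilt_shift(dist_a: TiltDistribution, dist_b: TiltDistribution) -> float:
    """Difference of mean tilts (degrees): e.g. cholesterol-induced straightening."""
    return dist_a.mean - dist_b.mean


def probe_mole_percent(n_lipids: int, n_probes: int) -> float:
    """Probe mole percent of a simulated bilayer: 100 * n_probes / (n_lipids + n_probes)."""
    if n_lipids < 0 or n_probes < 0:
        raise ValueError("counts must be nonnegative")
    total = n_lipids + n_probes
    if total == 0:
        raise ValueError("empty system")
    return 100.0 * n_probes / total


# ---------------------------------------------------------------------------
# I/O: XYZ for multi-frame trajectories, GRO for single frames, each with a
# JSON sidecar carrying the role map and box (neither format stores roles;
# XYZ stores no box). MDAnalysis handles the coordinate formats themselves.


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.add_TopologyAttr("names", [f"A{i}" for i in range(traj.n_atoms)])
    with mda.Writer(str(path), traj.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[f] * 10.0  # nm -> Angstrom
            w.write(u.atoms)
    _sidecar(path).write_text(
        json.dumps(
            {
                "roles": {str(k): v for k, v in traj.roles.items()},
                "box_nm": traj.box.tolist(),
            }
        )
    )


def read_trajectory_xyz(path: str | Path) -> Trajectory:
    import MDAnalysis as mda

    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    u = mda.Universe(str(path), format="XYZ")
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory]) / 10.0
    return Trajectory(
        coordinates=coords,
        roles={int(k): v for k, v in meta["roles"].items()},
        box=np.asarray(meta["box_nm"], dtype=float),
    )


def write_frame_gro(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.add_TopologyAttr("names", [f"A{i}" for i in range(traj.n_atoms)])
    u.add_TopologyAttr("resnames", ["SYS"])
    u.atoms.positions = traj.coordinates[frame] * 10.0
    u.dimensions = [*(traj.box[frame] * 10.0), 90.0, 90.0, 90.0]
    u.atoms.write(str(path))
    _sidecar(path).write_text(
        json.dumps(
            {
                "roles": {str(k): v for k, v in traj.roles.items()},
                "box_nm": traj.box[frame].tolist(),
            }
        )
    )


def read_frame_gro(path: str | Path) -> Trajectory:
    import MDAnalysis as mda

    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    u = mda.Universe(str(path))
    coords = (u.atoms.positions / 10.0)[None]
    return Trajectory(
        coordinates=coords,
        roles={int(k): v for k, v in meta["roles"].items()},
        box=np.asarray(meta["box_nm"], dtype=float),
    )
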