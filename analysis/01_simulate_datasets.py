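"""Generate the three synthetic datasets the downstream analyses consume.

Writes microscope-style spectral stacks (multi-page TIFF), TCSPC decay
tables (CSV) and a bilayer trajectory (XYZ) under scratch/sim/, with
ground-truth JSON sidecars under results/ so the recovery analyses can
score themselves.
"""

import json
from pathlib import Path

import pandas as pd

from memprobe import synthetic
from memprobe.image_model import write_spectral_tiff
from memprobe.trajectory import write_trajectory_xyz

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
SEED = 2022


def simulate_vesicle_scenes() -> None:
    """Three scenes: Lo-like, Ld-like and a phase-separated vesicle, plus
    elliptical decoys that the eccentricity filter must reject."""
    band_lo = synthetic.GaussianSpectrum(600.0, 45.0, 900.0)
    band_ld = synthetic.GaussianSpectrum(640.0, 45.0, 900.0)
    spec = synthetic.VesicleSceneSpec(
        image_size=(256, 256),
        vesicles=[
            synthetic.VesicleSpec(center=(60, 60), radius=30, phases=[(0, 360, band_lo)]),
            synthetic.VesicleSpec(center=(60, 190), radius=30, phases=[(0, 360, band_ld)]),
            synthetic.VesicleSpec(
                center=(190, 60), radius=30,
                phases=[(0, 180, band_lo), (180, 360, band_ld)],
            ),
            synthetic.VesicleSpec(
                center=(190, 190), radius=36, axis_ratio=2.0, phases=[(0, 360, band_lo)]
            ),
        ],
        seed=SEED,
    )
    img, truth = synthetic.make_vesicle_image(spec)
    write_spectral_tiff(img, SIM / "scene.tiff")
    payload = {k: v for k, v in truth.items() if k not in ("label_map", "phase_map")}
    (RESULTS / "scene_truth.json").write_text(json.dumps(payload, indent=2, default=str))
    print(f"scene: {len(spec.vesicles)} planted objects "
          f"({truth['n_true_vesicles']} true vesicles) -> {SIM / 'scene.tiff'}")


def simulate_decays() -> None:
    spec = synthetic.DecaySimSpec(delta_nu=1500.0, tau_rel=(1.0,), seed=SEED)
    ds, steady, truth = synthetic.make_decay_set(spec)
    rows = [
        {"wavelength_nm": wl, "time_ns": t, "counts": int(c)}
        for wl, y in ds.decays.items()
        for t, c in zip(ds.time_axis, y)
    ]
    pd.DataFrame(rows).to_csv(SIM / "decays.csv", index=False)
    pd.DataFrame({"time_ns": ds.time_axis, "counts": ds.irf}).to_csv(
        SIM / "irf.csv", index=False
    )
    steady.to_frame()[["wavelength_nm", "intensity"]].to_csv(
        SIM / "steady_state.csv", index=False
    )
    (RESULTS / "decays_truth.json").write_text(json.dumps(truth, indent=2, default=str))
    print(f"decays: {len(ds.decays)} wavelengths, peak 5000 counts "
          f"(planted delta_nu={truth['delta_nu']:.0f} cm^-1, "
          f"tau_R={truth['tau_r']:.2f} ns) -> {SIM}")


def simulate_trajectory() -> None:
    spec = synthetic.TrajectorySimSpec(
        n_frames=300,
        n_probes=8,
        tilt_modes=((23.0, 5.0, 0.7), (87.0, 4.0, 0.3)),
        depth_roles={"cholesterol_oh": (1.4, 0.08, 16), "probe_sulfur": (1.1, 0.15, 8)},
        seed=SEED,
    )
    traj, truth = synthetic.make_trajectory(spec)
    write_trajectory_xyz(traj, SIM / "trajectory.xyz")
    truth.pop("planted_angles")
    (RESULTS / "trajectory_truth.json").write_text(
        json.dumps(truth, indent=2, default=str)
    )
    print(f"trajectory: {traj.n_frames} frames, {traj.n_probes} probes, "
          f"planted tilt modes {truth['tilt_modes']} deg -> {SIM / 'trajectory.xyz'}")


if __name__ == "__main__":
    SIM.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    simulate_vesicle_scenes()
    simulate_decays()
    simulate_trajectory()
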