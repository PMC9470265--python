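"""End-to-end pipeline runners tying the analysis stages together.

Two pipelines mirror the two experimental workflows: spectral image
stacks -> per-vesicle GP tables (+ GP maps and membrane profiles), and
wavelength-resolved decay sets -> TDFS relaxation parameters. Every run
writes a manifest (inputs with content hashes, configuration, package
version) so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gp_pipeline import (
    GPConfig,
    detect_vesicles,
    gp_map,
    membrane_profile,
    vesicle_table,
)
from .image_model import EmissionSpectrum, read_spectral_tiff
from .tdfs import DecaySet, LippertSeries, analyze_decay_set, estimate_time_zero

logger = logging.getLogger("memprobe")

__all__ = ["RunConfig", "load_probe_presets", "run_gp_pipeline", "run_tdfs_pipeline"]


def load_probe_presets() -> dict:
    """Probe presets (reference wavelengths, channel grids) shipped as data."""
    with resources.files("memprobe.data").joinpath("probes.json").open() as fh:
        return json.load(fh)


@dataclass
class RunConfig:
    """Shared configuration for the pipeline runners."""

    probe: str = "nr12s"
    lambda_lo: float | None = None  # override the preset
    lambda_ld: float | None = None
    eps: float = 3.0
    min_samples: int = 8
    max_eccentricity: float = 0.5
    n_components: int = 3
    apply_jacobian: bool = True
    write_profiles: bool = True
    seed: int = 0
    out_dir: str = "memprobe_out"

    def gp_config(self) -> GPConfig:
        presets = load_probe_presets()
        base = presets.get(self.probe.lower(), {})
        lo = self.lambda_lo if self.lambda_lo is not None else base.get("lambda_lo")
        ld = self.lambda_ld if self.lambda_ld is not None else base.get("lambda_ld")
        if lo is None or ld is None:
            raise ValueError(
                f"no preset for probe {self.probe!r}; give lambda_lo and lambda_ld"
            )
        return GPConfig(float(lo), float(ld), probe=self.probe.lower())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, inputs: list[Path]) -> None:
    manifest = {
        "memprobe_version": __version__,
        "config": asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_gp_pipeline(config: RunConfig, image_paths: list[str | Path]) -> pd.DataFrame:
    """Spectral stacks -> GP maps, vesicle table, membrane profiles.

    Per-image failures are logged and skipped; the run fails only when
    every image fails. Returns the combined vesicle table (also written
    as ``vesicles.csv``).
    """
    import tifffile

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.gp_config()
    tables = []
    paths = [Path(p) for p in image_paths]
    n_failed = 0
    for path in paths:
        try:
            img = read_spectral_tiff(path)
            records = detect_vesicles(
                img,
                cfg,
                eps=config.eps,
                min_samples=config.min_samples,
                max_eccentricity=config.max_eccentricity,
            )
            gp = gp_map(img, cfg)
            gp_out = np.where(gp.defined_mask, gp.values, np.nan).astype(np.float32)
            tifffile.imwrite(out_dir / f"{path.stem}_gp.tiff", gp_out)
            table = vesicle_table(records)
            table.insert(0, "image", path.name)
            tables.append(table)
            if config.write_profiles:
                for rec in records:
                    if not rec.retained:
                        continue
                    try:
                        prof = membrane_profile(img, cfg, rec)
                    except ValueError:
                        continue
                    prof_df = pd.DataFrame(
                        {"angle_deg": prof.positions, "gp": prof.gp_values}
                    )
                    prof_df.to_csv(
                        out_dir / f"{path.stem}_vesicle{rec.label}_profile.csv",
                        index=False,
                    )
            n_det = int(table["retained"].sum()) if len(table) else 0
            logger.info("%s: %d vesicles retained", path.name, n_det)
        except Exception:
            n_failed += 1
            logger.exception("failed to process %s; skipping", path)
    if paths and n_failed == len(paths):
        raise RuntimeError("all images failed")
    combined = (
        pd.concat(tables, ignore_index=True)
        if tables
        else vesicle_table([]).assign(image=pd.Series(dtype=str))
    )
    combined.to_csv(out_dir / "vesicles.csv", index=False)
    _write_manifest(out_dir, config, paths)
    return combined


def read_decays_csv(path: str | Path) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Long-format decay table: columns wavelength_nm, time_ns, counts."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "time_ns", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: decay CSV needs columns {sorted(required)}")
    decays: dict[float, np.ndarray] = {}
    time_axis = None
    for wl, grp in df.groupby("wavelength_nm", sort=True):
        grp = grp.sort_values("time_ns")
        t = grp["time_ns"].to_numpy(dtype=float)
        if time_axis is None:
            time_axis = t
        elif not np.allclose(t, time_axis):
            raise ValueError(f"{path}: wavelength {wl} is not on the shared time axis")
        decays[float(wl)] = grp["counts"].to_numpy(dtype=float)
    return time_axis, decays


def run_tdfs_pipeline(
    config: RunConfig,
    decays_path: str | Path,
    irf_path: str | Path,
    steady_state_path: str | Path,
    nu0: float | None = None,
    solvent_series_path: str | Path | None = None,
    nu_a_in_system: float | None = None,
):
    """Decay CSVs -> RelaxationResult JSON + nu(t)/FWHM(t)/C(t) CSV.

    nu(0) comes, in order of precedence, from ``nu0`` directly (e.g. the
    low-temperature glass arithmetic), from a Lippert-Mataga solvent
    series (+ the system's absorption maximum), or from the reconstructed
    nu(t) at t = 0.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    time_axis, decays = read_decays_csv(decays_path)
    irf_df = pd.read_csv(irf_path)
    if not {"time_ns", "counts"}.issubset(irf_df.columns):
        raise ValueError(f"{irf_path}: IRF CSV needs columns time_ns, counts")
    irf = np.interp(
        time_axis, irf_df["time_ns"].to_numpy(float), irf_df["counts"].to_numpy(float)
    )
    ss_df = pd.read_csv(steady_state_path)
    if not {"wavelength_nm", "intensity"}.issubset(ss_df.columns):
        raise ValueError(
            f"{steady_state_path}: steady-state CSV needs wavelength_nm, intensity"
        )
    steady = EmissionSpectrum(
        ss_df["wavelength_nm"].to_numpy(float), ss_df["intensity"].to_numpy(float)
    )

    if nu0 is None and solvent_series_path is not None:
        if nu_a_in_system is None:
            raise ValueError("solvent-series time zero needs the system's nu_A")
        series = LippertSeries.from_frame(pd.read_csv(solvent_series_path))
        nu0 = estimate_time_zero(series, nu_a_in_system)

    ds = DecaySet(time_axis=time_axis, irf=irf, decays=decays)
    result, tres, fits = analyze_decay_set(
        ds,
        steady,
        n_components=config.n_components,
        nu0=nu0,
        apply_jacobian=config.apply_jacobian,
    )
    (out_dir / "relaxation.json").write_text(json.dumps(result.summary(), indent=2))
    result.to_frame().to_csv(out_dir / "relaxation_series.csv", index=False)
    inputs = [Path(decays_path), Path(irf_path), Path(steady_state_path)]
    if solvent_series_path is not None:
        inputs.append(Path(solvent_series_path))
    _write_manifest(out_dir, config, inputs)
    logger.info(
        "TDFS: delta_nu = %.0f cm^-1, tau_R = %.3f ns%s",
        result.delta_nu,
        result.tau_r,
        "" if result.relaxation_complete else " (incomplete relaxation)",
    )
    return result
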