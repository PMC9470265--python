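import pytest

from memprobe import synthetic
from memprobe.gp_pipeline import GPConfig


@pytest.fixture(scope="session")
def nr_config() -> GPConfig:
    return GPConfig.for_probe("nr12s")


def three_vesicle_scene(seed: int = 1) -> synthetic.VesicleSceneSpec:
    """3 circular vesicles + 2 elliptical (2:1) decoys, peak S/N 30."""
    spec_a = synthetic.GaussianSpectrum(600.0, 30.0, 900.0)
    spec_b = synthetic.GaussianSpectrum(620.0, 30.0, 900.0)
    spec_c1 = synthetic.GaussianSpectrum(580.0, 30.0, 900.0)
    spec_c2 = synthetic.GaussianSpectrum(650.0, 30.0, 900.0)
    return synthetic.VesicleSceneSpec(
        image_size=(256, 256),
        vesicles=[
            synthetic.VesicleSpec(center=(60, 60), radius=30, phases=[(0, 360, spec_a)]),
            synthetic.VesicleSpec(center=(60, 190), radius=30, phases=[(0, 360, spec_b)]),
            synthetic.VesicleSpec(
                center=(190, 60),
                radius=30,
                phases=[(0, 180, spec_c1), (180, 360, spec_c2)],
            ),
            synthetic.VesicleSpec(
                center=(190, 190), radius=36, axis_ratio=2.0,
                phases=[(0, 360, spec_a)],
            ),
            synthetic.VesicleSpec(
                center=(128, 128), radius=20, axis_ratio=2.0, angle_deg=30,
                phases=[(0, 360, spec_a)],
            ),
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def vesicle_scene():
    spec = three_vesicle_scene()
    img, truth = synthetic.make_vesicle_image(spec)
    return spec, img, truth
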