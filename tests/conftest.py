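import numpy as np
import pytest

from wristkin.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """One subject, both hands, a reduced protocol, low-resolution meshes,
    small pose perturbations and no vertex noise: fast, and every screw is
    recoverable essentially exactly."""
    cfg = ScenarioConfig(
        n_subjects=1,
        hands=("L", "R"),
        fe_positions_deg=(0.0, 30.0, -60.0),
        rud_positions_deg=(0.0, -40.0),
        perturb_rot_deg=5.0,
        perturb_trans_mm=5.0,
        vertex_noise_mm=0.0,
        bone_subdivisions=3,
        radius_subdivisions=4,
        seed=42,
    )
    return generate_scenario(cfg, tmp_path_factory.mktemp("scenario"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
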