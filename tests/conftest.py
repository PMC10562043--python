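import numpy as np
import pytest

from gkvol import detectors, synthetic, workflow


@pytest.fixture(scope="session")
def library():
    return detectors.load_detector_library()


@pytest.fixture(scope="session")
def lib_by_name(library):
    return {d.name: d for d in library}


@pytest.fixture(scope="session")
def fixture_fields():
    """Analytic flat-top fixture fields for the three collimators."""
    return {size: synthetic.default_field(size) for size in (16, 8, 4)}


@pytest.fixture(scope="session")
def fitted():
    """Full pipeline per collimator: noisy synthetic profiles fitted with
    the standard term counts, composed into 3D fields.

    Returns {field_size: (DoseField, {axis: FitReport})}.
    """
    out = {}
    for size in (16, 8, 4):
        specs = synthetic.default_profile_specs(size, noise_sd=0.1, seed=11)
        curves = {ax: synthetic.generate_profile(sp) for ax, sp in specs.items()}
        out[size] = workflow.build_field(size, curves, n_starts=3, seed=0)
    return out


@pytest.fixture()
def uniform_field():
    """Field whose three profiles are constant: D == 1 everywhere."""
    from gkvol.dosefield import DoseField
    const = lambda k: np.full_like(np.asarray(k, float), 100.0)
    return DoseField(field_size_mm=16, model_x=const, model_y=const, model_z=const)
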