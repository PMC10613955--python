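import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def oxime_bundle():
    """Synthetic oxime-layout study at generator defaults, fixed seed."""
    from shiftcal import GeneratorSpec, generate_study

    bundle, truth = generate_study(GeneratorSpec(seed=20230))
    return bundle, truth


@pytest.fixture()
def noise_free_bundle():
    """Single-conformer, zero-noise study: the pipeline must be exact."""
    from shiftcal import GeneratorSpec, NucleusModel, generate_study

    spec = GeneratorSpec(
        seed=7,
        n_conformers=1,
        carbon=NucleusModel(true_slope=-1.05, true_intercept=186.0,
                            conformer_sd=0.0, atom_sd=0.0),
        proton=NucleusModel(true_slope=-1.02, true_intercept=31.6,
                            conformer_sd=0.0, atom_sd=0.0),
    )
    return generate_study(spec)
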