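import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome_baseline_analytic():
    """Exact expected baseline of the synthetic CG-suppressed genome."""
    from dinusig.simulate import analytic_genome_baseline

    return analytic_genome_baseline()


@pytest.fixture(scope="session")
def lncrna_pop_small(genome_baseline_analytic):
    from dinusig.simulate import FixedLength, generate_population, preset_spec

    spec = preset_spec("lncrna", n=60, seed=7, length_model=FixedLength(1500))
    return generate_population(spec)


@pytest.fixture(scope="session")
def mrna_pop_small():
    from dinusig.simulate import FixedLength, generate_population, preset_spec

    spec = preset_spec("mrna", n=60, seed=8, length_model=FixedLength(1500))
    return generate_population(spec)
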