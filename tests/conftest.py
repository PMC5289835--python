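import pytest
from hypothesis import HealthCheck, settings

from termsignal.pipeline import RunConfig
from termsignal.simulate import SpeciesSpec, generate_species, write_species_files

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic species reused by read-only tests."""
    return generate_species(SpeciesSpec(species_id="sp_fix", n_genes=400, seed=11))


@pytest.fixture(scope="session")
def species_dir(small_bundle, tmp_path_factory):
    """The small bundle serialised as a FASTA + feature-table input dir."""
    out = tmp_path_factory.mktemp("species") / "sp_fix"
    write_species_files(small_bundle, out)
    return out


@pytest.fixture()
def default_config():
    return RunConfig(species_inputs=[], out_dir=".")
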