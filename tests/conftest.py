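import pytest
from hypothesis import settings

from splicearc import ScenarioSpec, generate_locus, simulate_reads

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_scenario(tmp_path_factory):
    """A small 4-exon '+' strand locus with a 2-exon circle, on disk."""
    spec = ScenarioSpec(n_exons=4, backsplices=((1, 2, 12),), seed=7)
    root = tmp_path_factory.mktemp("toy")
    locus = generate_locus(spec, root)
    sim = simulate_reads(spec, locus, root)
    return spec, locus, sim
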