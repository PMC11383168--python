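import warnings

import pytest

from jointnet.network import NetworkParams, assign_regulatory_regions, build_network
from jointnet.simulate import simulate_cohort, small_config


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced three-group cohort with one planted TF program per group."""
    return simulate_cohort(small_config(seed=1))


@pytest.fixture(scope="session")
def small_networks(small_bundle):
    """Per-sample networks for the small cohort (shared scan cache)."""
    b = small_bundle
    region_map = assign_regulatory_regions(b.annotation, b.interactions)
    cache = {}
    nets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ps in b.peaksets:
            nets[ps.sample_id] = build_network(
                ps.sample_id, b.expression, ps, region_map,
                b.motifs, b.genome, NetworkParams(), cache,
            )
    return nets
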