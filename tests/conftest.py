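import pytest

import transporter_traits as tt


@pytest.fixture(scope="session")
def reference():
    """Default planted reference: 25 clusters, 25 decoy families, one hub."""
    return tt.simulate_reference(
        tt.default_reference_specs(), n_decoy_families=25, hub_spec=(1, 7), seed=11
    )


@pytest.fixture(scope="session")
def deep_run(reference):
    """One deep community simulation plus a full pipeline run.

    Depth 10^6 so that sampling error per category is well below one
    percentage point; shared across tests because the run is deterministic.
    """
    com = tt.simulate_community(
        tt.default_community(depth=1_000_000), reference.truth, seed=11
    )
    res = tt.run_pipeline(reference, com)
    return reference, com, res
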